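"""Degenerate consensus motif scanning for NRF2/SKN-1 binding sites.

The antioxidant response element (ARE) bound by NRF2 is represented by
the degenerate consensus ``GCNNNGTCA``; the monomeric SKN-1 site by
``WWTRTCAT`` (IUPAC: W = A/T, R = A/G). Sequences are scanned on both
strands; hit coordinates are 0-based half-open internally and 1-based
inclusive in written reports. Positions can be expressed relative to an
anchor base (the +1 of the transcription start site or the first base
of the ATG initiation codon) so that sites found in orthologous regions
of different species can be grouped into conservation classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "ARE",
    "SKN1",
    "BUILTIN_MOTIFS",
    "ConsensusMotif",
    "AnchoredSequence",
    "MotifHit",
    "matches_iupac",
    "read_fasta",
    "read_anchor_table",
    "scan",
    "anchor_offsets",
    "conservation_report",
    "hits_to_frame",
]

#: concrete bases denoted by each IUPAC nucleotide code
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate binding-site consensus over the IUPAC alphabet."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        for i, code in enumerate(self.pattern):
            if code not in IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC code {code!r} at position {i} of "
                    f"pattern {self.pattern!r}"
                )
        if not self.pattern:
            raise ValueError("empty motif pattern")

    def __len__(self) -> int:
        return len(self.pattern)


#: NRF2 antioxidant response element core consensus
ARE = ConsensusMotif("ARE", "GCNNNGTCA")
#: SKN-1 monomeric binding-site consensus
SKN1 = ConsensusMotif("SKN1", "WWTRTCAT")

BUILTIN_MOTIFS: dict[str, ConsensusMotif] = {"ARE": ARE, "SKN1": SKN1}


@dataclass(frozen=True)
class AnchoredSequence:
    """A DNA sequence with an optional anchor base (TSS +1 or ATG start)."""

    id: str
    sequence: str
    anchor_pos: int | None = None
    anchor_kind: Literal["ATG", "TSS", "none"] = "none"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if self.anchor_pos is not None and not (
            0 <= self.anchor_pos < len(self.sequence)
        ):
            raise ValueError(
                f"anchor_pos {self.anchor_pos} outside sequence {self.id!r} "
                f"of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One motif match on either strand, in forward-strand coordinates."""

    seq_id: str
    motif_name: str
    start: int  # 0-based, leftmost matched base
    end: int  # exclusive
    strand: Literal["+", "-"]
    matched: str  # forward-strand substring sequence[start:end]
    offset: int | None = None  # start − anchor_pos; negative = upstream


def matches_iupac(pattern: str, window: str) -> bool:
    """True iff ``window`` satisfies the degenerate ``pattern``.

    An ``N`` in the *sequence* (an unknown or masked base) matches only
    the pattern code ``N``; it never satisfies a concrete or partially
    degenerate code, so masked regions cannot produce spurious hits.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for i, (code, base) in enumerate(zip(pattern, window)):
        if code not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} at pattern position {i}")
        if base not in _SEQ_ALPHABET:
            raise ValueError(f"invalid sequence base {base!r} at position {i}")
        if base == "N":
            if code != "N":
                return False
        elif base not in IUPAC_SETS[code]:
            return False
    return True


def _parse_anchor_token(description: str) -> int | None:
    # header token `anchor=<pos>` carries a 1-based anchor position
    for token in description.split():
        if token.startswith("anchor="):
            return int(token.split("=", 1)[1]) - 1
    return None


def _parse_kind_token(description: str) -> str:
    for token in description.split():
        if token.startswith("anchor_kind="):
            return token.split("=", 1)[1]
    return "none"


def read_anchor_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (seq_id, 1-based anchor position) to 0-based."""
    table = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "anchor"])
    return {str(r.seq_id): int(r.anchor) - 1 for r in table.itertuples()}


def read_fasta(
    path: str | Path,
    anchors: Mapping[str, int] | str | Path | None = None,
    anchor_kind: Literal["ATG", "TSS", "none"] = "none",
) -> list[AnchoredSequence]:
    """Read FASTA records as :class:`AnchoredSequence`.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``. Anchors
    may come from a sidecar table (``anchors``, 1-based positions) or
    from a ``anchor=<pos>`` token in the FASTA header; the sidecar wins.
    An empty file yields an empty list.
    """
    if anchors is not None and not isinstance(anchors, Mapping):
        anchors = read_anchor_table(anchors)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if anchors is not None and rec.id in anchors:
            pos: int | None = int(anchors[rec.id])
            kind = anchor_kind if anchor_kind != "none" else "ATG"
        else:
            pos = _parse_anchor_token(rec.description)
            kind = (
                _parse_kind_token(rec.description)
                if pos is not None
                else "none"
            )
            if pos is not None and kind == "none":
                kind = anchor_kind if anchor_kind != "none" else "ATG"
        records.append(
            AnchoredSequence(
                id=rec.id,
                sequence=seq,
                anchor_pos=pos,
                anchor_kind=kind if pos is not None else "none",
            )
        )
    return records


def scan(
    seq: AnchoredSequence | str,
    motif: ConsensusMotif,
    strands: Literal["both", "+", "-"] = "both",
) -> list[MotifHit]:
    """Scan one sequence for all (possibly overlapping) motif matches.

    Every window is tested on the requested strands; a palindromic
    double-strand match yields two hits. Hits are sorted by start, then
    ``+`` before ``-``. A sequence shorter than the motif yields an
    empty list.
    """
    if isinstance(seq, str):
        seq = AnchoredSequence(id="seq", sequence=seq.upper())
    m = len(motif)
    s = seq.sequence
    hits: list[MotifHit] = []
    if m > len(s):
        return hits
    for start in range(len(s) - m + 1):
        window = s[start : start + m]
        if strands in ("both", "+") and matches_iupac(motif.pattern, window):
            hits.append(
                MotifHit(seq.id, motif.name, start, start + m, "+", window)
            )
        if strands in ("both", "-"):
            rc = str(Seq(window).reverse_complement())
            if matches_iupac(motif.pattern, rc):
                hits.append(
                    MotifHit(seq.id, motif.name, start, start + m, "-", window)
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def anchor_offsets(hits: Iterable[MotifHit], seq: AnchoredSequence) -> list[MotifHit]:
    """Fill each hit's signed anchor-relative offset (start − anchor)."""
    if seq.anchor_pos is None:
        raise ValueError(
            f"sequence {seq.id!r} has no anchor; supply one via a sidecar "
            "table or an anchor=<pos> header token"
        )
    return [replace(h, offset=h.start - seq.anchor_pos) for h in hits]


def conservation_report(
    hits_by_species: Mapping[str, Sequence[MotifHit]],
    window_bp: int = 50,
) -> pd.DataFrame:
    """Group anchor-relative hits across species into putative conserved sites.

    Two hits belong to the same group when their offsets differ by at
    most ``window_bp`` from the group seed (single-linkage on sorted
    offsets, one hit per species per group at most is *not* enforced:
    tandem sites within the window collapse together). A group present
    in every species is flagged ``conserved``.
    """
    species = list(hits_by_species)
    if len(species) < 2:
        warnings.warn(
            "conservation_report with fewer than 2 species is a passthrough",
            stacklevel=2,
        )
    pool = []
    for sp, hits in hits_by_species.items():
        for h in hits:
            if h.offset is None:
                raise ValueError(
                    f"hit {h.seq_id}:{h.start} lacks an offset; run "
                    "anchor_offsets first"
                )
            pool.append((sp, h))
    pool.sort(key=lambda t: t[1].offset)

    groups: list[list[tuple[str, MotifHit]]] = []
    for sp, h in pool:
        if groups and h.offset - groups[-1][0][1].offset <= window_bp:
            groups[-1].append((sp, h))
        else:
            groups.append([(sp, h)])

    rows = []
    for gi, grp in enumerate(groups):
        sps = sorted({sp for sp, _ in grp})
        offs = [h.offset for _, h in grp]
        rows.append(
            {
                "group": gi,
                "n_species": len(sps),
                "species": ",".join(sps),
                "offset_min": min(offs),
                "offset_max": max(offs),
                "matched": ",".join(sorted({h.matched for _, h in grp})),
                "conserved": len(sps) == len(species) and len(species) >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_species",
            "species",
            "offset_min",
            "offset_max",
            "matched",
            "conserved",
        ],
    )


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabulate hits with 1-based inclusive coordinates for reports."""
    rows = [
        {
            "seq_id": h.seq_id,
            "motif": h.motif_name,
            "start_1based": h.start + 1,
            "end_1based": h.end,
            "strand": h.strand,
            "matched": h.matched,
            "offset": h.offset,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "motif",
            "start_1based",
            "end_1based",
            "strand",
            "matched",
            "offset",
        ],
    )
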