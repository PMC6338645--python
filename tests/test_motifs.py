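"""Degenerate-motif scanning: IUPAC semantics, strandedness, anchors,
conservation grouping, and equivalence with a brute-force oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from nrfloop.motifs import (
    ARE,
    SKN1,
    IUPAC_SETS,
    AnchoredSequence,
    ConsensusMotif,
    anchor_offsets,
    conservation_report,
    matches_iupac,
    read_fasta,
    scan,
)

QUERY_PROBE = "AAACCATGACTCTGCATAAAA"
CONSENSUS_PROBE = "AAACCATGACACAGCATAAAA"


def brute_force_scan(sequence: str, pattern: str, strands: str = "both"):
    """Independent oracle: explicit double loop over positions and strands."""
    m = len(pattern)
    out = []
    for start in range(len(sequence) - m + 1):
        window = sequence[start : start + m]
        if strands in ("both", "+") and matches_iupac(pattern, window):
            out.append((start, "+"))
        if strands in ("both", "-"):
            rc = str(Seq(window).reverse_complement())
            if matches_iupac(pattern, rc):
                out.append((start, "-"))
    return sorted(out)


class TestMatchesIupac:
    @pytest.mark.parametrize(
        "pattern,window,expected",
        [
            ("GCNNNGTCA", "GCAGAGTCA", True),
            ("GCNNNGTCA", "GCTGTGTCA", True),
            ("WWTRTCAT", "TATATCAT", True),
            ("WWTRTCAT", "TGTGTCAT", False),
            ("WWTRTCAT", "AATGTCAT", True),
            ("N", "A", True),
            ("A", "N", False),  # masked sequence base never matches a concrete code
            ("N", "N", True),
            ("R", "G", True),
            ("R", "C", False),
        ],
    )
    def test_examples(self, pattern, window, expected):
        assert matches_iupac(pattern, window) is expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            matches_iupac("GCN", "GC")

    def test_invalid_code_names_position(self):
        with pytest.raises(ValueError, match="position 1"):
            matches_iupac("AZT", "ACT")

    def test_every_iupac_code_accepts_exactly_its_set(self):
        for code, bases in IUPAC_SETS.items():
            for base in "ACGT":
                assert matches_iupac(code, base) is (base in bases)


class TestReadFasta:
    def test_emsa_probe_roundtrip(self, write_fasta):
        path = write_fasta(f">probe\n{QUERY_PROBE}\n")
        records = read_fasta(path)
        assert len(records) == 1
        assert records[0].sequence == QUERY_PROBE
        assert len(records[0]) == 21

    def test_empty_file_gives_empty_list(self, write_fasta):
        assert read_fasta(write_fasta("")) == []

    def test_lowercase_and_rna_normalized(self, write_fasta):
        records = read_fasta(write_fasta(">r\nacgu\n"))
        assert records[0].sequence == "ACGT"

    def test_malformed_fasta_raises(self, write_fasta):
        with pytest.raises(ValueError):
            read_fasta(write_fasta("ACGT\nnot a fasta\n"))

    def test_anchor_header_token(self, write_fasta):
        records = read_fasta(write_fasta(">r anchor=3 anchor_kind=TSS\nACGTACGT\n"))
        assert records[0].anchor_pos == 2  # 1-based token -> 0-based
        assert records[0].anchor_kind == "TSS"

    def test_sidecar_anchor_table_wins(self, write_fasta, tmp_path):
        fasta = write_fasta(">r anchor=3\nACGTACGT\n")
        table = tmp_path / "anchors.tsv"
        table.write_text("r\t5\n")
        records = read_fasta(fasta, anchors=table)
        assert records[0].anchor_pos == 4


class TestScan:
    @pytest.mark.parametrize(
        "probe,matched",
        [(QUERY_PROBE, "TGACTCTGC"), (CONSENSUS_PROBE, "TGACACAGC")],
    )
    def test_emsa_probes_single_minus_strand_hit(self, probe, matched):
        hits = scan(probe, ARE, "both")
        assert len(hits) == 1
        (hit,) = hits
        assert hit.strand == "-"
        assert hit.matched == matched
        assert hit.end - hit.start == len(ARE)
        assert probe[hit.start : hit.end] == hit.matched
        assert matches_iupac(ARE.pattern, str(Seq(hit.matched).reverse_complement()))

    def test_sequence_shorter_than_motif(self):
        assert scan("ACGT", ARE) == []

    def test_palindromic_site_reported_on_both_strands(self):
        motif = ConsensusMotif("pal", "ACGT")
        hits = scan("AACGTA", motif, "both")
        strands = {(h.start, h.strand) for h in hits}
        assert (1, "+") in strands and (1, "-") in strands

    def test_overlapping_hits_all_reported(self):
        motif = ConsensusMotif("aa", "AA")
        hits = scan("AAAA", motif, "+")
        assert [h.start for h in hits] == [0, 1, 2]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            fwd = scan(seq, SKN1, "both")
            rev = scan(str(Seq(seq).reverse_complement()), SKN1, "both")
            assert len(fwd) == len(rev)
            mirrored = sorted(
                (len(seq) - h.end, "+" if h.strand == "-" else "-") for h in rev
            )
            assert mirrored == sorted((h.start, h.strand) for h in fwd)

    def test_count_monotone_under_append(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            extra = "".join(rng.choice(list("ACGT"), size=20))
            before = {(h.start, h.strand) for h in scan(seq, ARE)}
            after = {(h.start, h.strand) for h in scan(seq + extra, ARE)}
            assert before <= after

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=120),
        motif=st.sampled_from([ARE, SKN1]),
    )
    def test_scan_equals_oracle_property(self, seq, motif):
        got = sorted((h.start, h.strand) for h in scan(seq, motif))
        assert got == brute_force_scan(seq, motif.pattern)

    @pytest.mark.parametrize("motif", [ARE, SKN1], ids=lambda m: m.name)
    def test_matches_brute_force_oracle(self, motif):
        rng = np.random.default_rng(20181002)
        for _ in range(300):
            n = int(rng.integers(4, 120))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            got = sorted((h.start, h.strand) for h in scan(seq, motif))
            assert got == brute_force_scan(seq, motif.pattern)


class TestAnchors:
    def test_offset_zero_at_anchor(self):
        seq = AnchoredSequence("s", "TATATCATAA", anchor_pos=0, anchor_kind="ATG")
        hits = anchor_offsets(scan(seq, SKN1, "+"), seq)
        assert hits[0].offset == 0

    def test_upstream_negative(self):
        seq = AnchoredSequence("s", "TATATCAT" + "A" * 92 + "C" * 10,
                               anchor_pos=100, anchor_kind="ATG")
        hits = anchor_offsets(scan(seq, SKN1, "+"), seq)
        assert hits[0].offset == -100

    def test_missing_anchor_raises(self):
        seq = AnchoredSequence("s", "TATATCAT")
        with pytest.raises(ValueError, match="anchor"):
            anchor_offsets(scan(seq, SKN1, "+"), seq)

    def test_offset_stable_under_downstream_extension(self):
        core = "G" * 40 + "TATATCAT" + "G" * 10
        for tail in ("", "ACGT" * 12):
            seq = AnchoredSequence("s", core + tail, anchor_pos=20, anchor_kind="ATG")
            hits = anchor_offsets(scan(seq, SKN1, "+"), seq)
            assert hits[0].offset == 20


class TestConservation:
    @staticmethod
    def _hits_at(offsets, species="sp"):
        from nrfloop.motifs import MotifHit

        return [
            MotifHit(species, "SKN1", 0, 8, "+", "TATATCAT", offset=o)
            for o in offsets
        ]

    def test_identical_species_conserved(self):
        hits = {f"sp{i}": self._hits_at([-100]) for i in range(3)}
        report = conservation_report(hits, window_bp=50)
        assert len(report) == 1
        assert report.loc[0, "n_species"] == 3
        assert bool(report.loc[0, "conserved"])

    def test_window_boundary_splits_groups(self):
        w = 50
        hits = {"a": self._hits_at([-100]), "b": self._hits_at([-100 + w + 1])}
        assert len(conservation_report(hits, window_bp=w)) == 2
        hits = {"a": self._hits_at([-100]), "b": self._hits_at([-100 + w])}
        assert len(conservation_report(hits, window_bp=w)) == 1

    def test_species_without_hits_not_counted(self):
        hits = {"a": self._hits_at([-100]), "b": self._hits_at([-100]), "c": []}
        report = conservation_report(hits, window_bp=50)
        assert report.loc[0, "n_species"] == 2
        assert not bool(report.loc[0, "conserved"])

    def test_single_species_warns(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            report = conservation_report({"a": self._hits_at([-100])}, 50)
        assert len(report) == 1

    def test_missing_offsets_raise(self):
        from nrfloop.motifs import MotifHit

        bad = {"a": [MotifHit("a", "SKN1", 0, 8, "+", "TATATCAT")],
               "b": self._hits_at([0])}
        with pytest.raises(ValueError, match="offset"):
            conservation_report(bad, 50)
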