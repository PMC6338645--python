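"""Seeded generators of synthetic datasets shaped like the study's assays.

No raw measurements are deposited with the study, so every pipeline
stage is exercised on synthetic data carrying the same statistical
structure: densitometry time courses (0–4 h, 3 replicates,
multiplicative lognormal noise), per-worm GFP::LGG-1 area fractions
(Beta-distributed), hourly-observed paralysis cohorts, and DNA
sequences with planted degenerate-motif instances. All generators are
pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nrfloop.model import Trajectory, readout
from nrfloop.motifs import IUPAC_SETS, AnchoredSequence, ConsensusMotif, scan
from nrfloop.phenotype import ParalysisCurve

__all__ = [
    "ANALYTE_STATES",
    "DENSITOMETRY_TIMES",
    "gen_densitometry",
    "gen_puncta_cohort",
    "gen_paralysis_cohort",
    "gen_planted_sequences",
]

#: western-blot analytes and the model state each band reports on.
#: NQO1 and HO-1 are canonical NRF2 target genes, so both report active
#: NRF2; the LC3-II/LC3-I ratio tracks autophagosome abundance.
ANALYTE_STATES: dict[str, str] = {
    "AMPK-T": "A",
    "AMPK-P": "Ap",
    "NRF2": "N",
    "NQO1": "N",
    "HO-1": "N",
    "LC3-II/LC3-I": "L",
    "p62": "P",
    "ULK555-P": "U",
}

DENSITOMETRY_TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)


def gen_densitometry(
    traj_map: Mapping[str, Trajectory],
    noise_sd: float = 0.2,
    n_reps: int = 3,
    seed: int = 0,
    times: Sequence[float] = DENSITOMETRY_TIMES,
) -> pd.DataFrame:
    """Densitometry table: analyte x condition x time x replicate.

    Each value is the model readout (state relative to the condition's
    own t = 0 level) times a median-unbiased LogNormal(0, noise_sd)
    factor, mimicking GAPDH-normalized band intensities.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, traj in traj_map.items():
        for analyte, state in ANALYTE_STATES.items():
            for t in times:
                true = readout(traj, f"rel_{state}({t})")
                noise = (
                    np.exp(rng.normal(0.0, noise_sd, size=n_reps))
                    if noise_sd > 0
                    else np.ones(n_reps)
                )
                for rep in range(n_reps):
                    rows.append(
                        {
                            "analyte": analyte,
                            "condition": cond,
                            "time_h": t,
                            "replicate": rep + 1,
                            "value": true * float(noise[rep]),
                        }
                    )
    return pd.DataFrame(rows)


def gen_puncta_cohort(
    mean_fraction: float,
    concentration: float,
    n_worms: int,
    seed: int = 0,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Per-worm GFP::LGG-1 area fractions ~ Beta(mean, concentration)."""
    if not (0 < mean_fraction < 1):
        raise ValueError("mean_fraction must be in (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    concentration = min(concentration, 1e6)
    if n_worms < 0:
        raise ValueError("n_worms must be >= 0")
    rng = np.random.default_rng(seed)
    a = mean_fraction * concentration
    b = (1.0 - mean_fraction) * concentration
    frac = rng.beta(a, b, size=n_worms)
    return pd.DataFrame(
        {"genotype": genotype, "worm": np.arange(1, n_worms + 1), "area_fraction": frac}
    )


def gen_paralysis_cohort(
    curve: ParalysisCurve, n_worms: int, seed: int = 0
) -> pd.DataFrame:
    """Hourly-observed paralysis times drawn from the discrete hazard of F(t).

    Each worm paralyzes in hour k with the conditional probability
    implied by the curve's increments; worms still mobile at the last
    observation are censored there.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.asarray(curve.t, dtype=float)
    F = np.asarray(curve.F, dtype=float)
    # conditional paralysis probability within each interval
    S = 1.0 - F
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(S[:-1] > 0, (F[1:] - F[:-1]) / S[:-1], 1.0)
    rows = []
    for w in range(n_worms):
        u = rng.uniform(size=len(p_cond))
        hit = np.nonzero(u < p_cond)[0]
        if hit.size:
            rows.append(
                {"worm": w + 1, "time_h": float(t[hit[0] + 1]), "censored": False}
            )
        else:
            rows.append({"worm": w + 1, "time_h": float(t[-1]), "censored": True})
    out = pd.DataFrame(rows)
    out.insert(0, "genotype", curve.genotype)
    return out


def _concrete_instance(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    # resolve each degenerate code uniformly over its base set
    return "".join(
        rng.choice(sorted(IUPAC_SETS[c] - {"N"} or {"A"})) if c != "N"
        else rng.choice(list("ACGT"))
        for c in motif.pattern
    )


def gen_planted_sequences(
    n_species: int,
    length: int,
    site_offsets: Sequence[int],
    motif: ConsensusMotif,
    seed: int = 0,
    anchor_pos: int | None = None,
    exclusive: bool = False,
    max_tries: int = 200,
) -> str:
    """FASTA text: random backgrounds with motif instances planted at
    anchor-relative offsets.

    ``anchor_pos`` (0-based) defaults to just upstream-padding the most
    negative offset. Headers carry ``anchor=<1-based>`` tokens so
    :func:`nrfloop.motifs.read_fasta` recovers the anchors. With
    ``exclusive`` the background is resampled until a both-strand scan
    finds exactly the planted sites.
    """
    if length < len(motif):
        raise ValueError("sequence length shorter than motif")
    offsets = sorted(int(o) for o in site_offsets)
    for a, b in zip(offsets, offsets[1:]):
        if b - a < len(motif):
            raise ValueError(f"planted sites at offsets {a} and {b} overlap")
    if anchor_pos is None:
        anchor_pos = max(0, -min(offsets)) + 10 if offsets else 0
    starts = [anchor_pos + o for o in offsets]
    if starts and (min(starts) < 0 or max(starts) + len(motif) > length):
        raise ValueError("planted offsets fall outside the sequence")

    rng = np.random.default_rng(seed)
    records = []
    for sp in range(n_species):
        for _ in range(max_tries):
            seq = rng.choice(list("ACGT"), size=length)
            for st in starts:
                seq[st : st + len(motif)] = list(_concrete_instance(motif, rng))
            text = "".join(seq)
            if not exclusive:
                break
            hits = scan(AnchoredSequence(id="tmp", sequence=text), motif, "both")
            if sorted({h.start for h in hits}) == starts:
                break
        else:
            raise RuntimeError("could not generate an exclusive background")
        records.append(
            f">species_{sp + 1} anchor={anchor_pos + 1} anchor_kind=ATG\n{text}"
        )
    return "\n".join(records) + "\n"
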