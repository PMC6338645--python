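"""Fit the shared paralysis hazard (h0, gamma) and the assay dose
multiplier to the printed 7-h paralyzed fractions across genotypes.

Genotype differences enter only through the simulated autophagosome
trajectories L(t); the hazard law h(t) = h0 + gamma*L(t) is common to
all genotypes, so the ordering of the predicted fractions is a genuine
prediction of the dynamics model. Writes results/paralysis_fit.tsv and
per-genotype curves results/paralysis_curves.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nrfloop.model import default_parameters, simulate
from nrfloop.phenotype import (
    PRINTED_FRACTIONS,
    fit_phenotype,
    paralysis_curve,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

params = default_parameters("worm")
t_grid = np.linspace(0.0, 7.0, 141)


def provider(dose):
    return {g: simulate(params, g, dose=dose, t_grid=t_grid, system="worm")
            for g in PRINTED_FRACTIONS}


hp, dose, pred, converged = fit_phenotype(provider, seed=20181002)

table = pd.DataFrame(
    {
        "genotype": list(PRINTED_FRACTIONS),
        "printed_fraction": list(PRINTED_FRACTIONS.values()),
        "model_fraction": [round(pred[g], 4) for g in PRINTED_FRACTIONS],
        "abs_error": [round(pred[g] - PRINTED_FRACTIONS[g], 4)
                      for g in PRINTED_FRACTIONS],
    }
)
table.to_csv(RESULTS / "paralysis_fit.tsv", sep="\t", index=False)

curves = []
trajs = provider(dose)
for g, traj in trajs.items():
    curves.append(paralysis_curve(traj, hp, dose).to_frame())
pd.concat(curves).to_csv(RESULTS / "paralysis_curves.tsv", sep="\t", index=False, float_format="%.5g")

print(f"shared hazard: h0 = {hp.h0:.4f} /h, gamma = {hp.gamma:.3f} /h per L unit,"
      f" assay dose multiplier = {dose:.2f} (converged={converged})")
print(table.to_string(index=False))
print("\nordering check: skn-1 RNAi > WT > protected mutants:",
      pred["skn1_RNAi"] > pred["WT"]
      > max(pred["aak2_null"], pred["atg11_null"], pred["aak2_skn1_RNAi"]))
print("note: the printed atg-11 (16%) > aak-2 (11%) inversion cannot arise "
      "from a shared nonnegative hazard, since atg-11 has no autophagosomes; "
      "both land near the baseline-hazard floor instead")
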