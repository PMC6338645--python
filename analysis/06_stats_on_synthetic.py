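"""Apply the study's statistical procedures to synthetic datasets.

Generates a densitometry table (WT vs siNRF2, 3 replicates, lognormal
noise) and per-genotype GFP::LGG-1 cohorts, then runs Bonferroni-
corrected Student's t tests and one-way ANOVA with Tukey's HSD. Writes
results/stats_ttests.tsv and results/stats_anova.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nrfloop.model import default_parameters, simulate
from nrfloop.stats import anova_tukey, t_test_bonferroni
from nrfloop.synth import gen_densitometry, gen_puncta_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 20181002

# --- densitometry: WT vs siNRF2 at 4 h, per analyte ------------------------
params = default_parameters("human_cell")
tg = np.linspace(0.0, 4.0, 81)
trajs = {c: simulate(params, c, dose=1.0, t_grid=tg) for c in ("WT", "siNRF2")}
dens = gen_densitometry(trajs, noise_sd=0.2, n_reps=3, seed=SEED)

rows = []
at4 = dens[dens.time_h == 4.0]
for analyte, grp in at4.groupby("analyte"):
    data = {c: g.value.tolist() for c, g in grp.groupby("condition")}
    res = t_test_bonferroni(data, comparisons=[("WT", "siNRF2")])
    res = res.assign(analyte=analyte)
    rows.append(res)
ttests = pd.concat(rows, ignore_index=True)
# family-wise correction across the analyte panel
m = len(ttests)
ttests["p_adj"] = np.minimum(1.0, ttests["p_raw"] * m)
ttests["significant"] = ttests["p_adj"] < 0.05
ttests.to_csv(RESULTS / "stats_ttests.tsv", sep="\t", index=False)
print("WT vs siNRF2 at 4 h (Student's t, Bonferroni over "
      f"{m} analytes):")
print(ttests[["analyte", "t", "df", "p_raw", "p_adj", "significant"]]
      .round(4).to_string(index=False))

# --- puncta cohorts: ANOVA + Tukey across genotypes ------------------------
cohorts = {
    "WT": gen_puncta_cohort(0.04, 60, 36, seed=SEED, genotype="WT"),
    "aak2_null": gen_puncta_cohort(0.12, 60, 36, seed=SEED + 1,
                                   genotype="aak2_null"),
    "skn1_RNAi": gen_puncta_cohort(0.134, 60, 36, seed=SEED + 2,
                                   genotype="skn1_RNAi"),
}
data = {g: c.area_fraction.tolist() for g, c in cohorts.items()}
F, dfb, dfw, p, tukey = anova_tukey(data)
tukey.to_csv(RESULTS / "stats_anova.tsv", sep="\t", index=False)
print(f"\npost-stress puncta fractions: ANOVA F({dfb},{dfw}) = {F:.2f}, "
      f"p = {p:.3g}")
print(tukey.round(4).to_string(index=False))
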