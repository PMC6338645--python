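# Methods

## Scope and design

`nrfloop` couples two computational layers around one biological claim:
that NRF2 (SKN-1 in *C. elegans*) prevents autophagy hyperactivation
under prolonged oxidative stress by transcriptionally repressing AMPK
(*aak-2*), closing a delayed negative feedback loop
stress → AMPK → NRF2 ⊣ AMPK → autophagy.

1. a **sequence layer** that locates the degenerate NRF2/SKN-1 binding
   consensus in DNA and summarises its conservation across species, and
2. a **dynamics layer**: an ODE reconstruction of the feedback loop,
   calibrated per system (human cell line, worm) to published
   fold-changes, extended to organism-level readouts (GFP::LGG-1 puncta
   area, paralysis fractions) by a hazard model.

No raw measurements are available for either layer, so calibration
targets are transcribed printed summary values (shipped as a TSV
fixture), and all pipeline stages are exercised on seeded synthetic
data generated by `nrfloop.synth`.

## Motif scanning

Consensus sites are IUPAC strings — the antioxidant response element
(ARE) `GCNNNGTCA` and the monomeric SKN-1 site `WWTRTCAT` — matched by
per-position membership in the full IUPAC degeneracy table; no
position-weight scoring is attempted. Both strands are scanned; a minus
strand hit is reported in forward-strand coordinates with the matched
forward substring, and a palindromic locus yields two hits. Overlapping
hits are all reported. Coordinates are 0-based half-open internally and
1-based inclusive in written tables.

Two deliberate semantic choices:

- an `N` in the *sequence* (unknown or masked base) matches only the
  pattern code `N`, never a concrete or partially degenerate code, so
  masked regions cannot produce spurious hits;
- anchors (transcription start site `+1` or first base of the ATG
  codon) are caller-supplied metadata. The two anchor conventions are
  both supported and never conflated: site positions in the literature
  are quoted sometimes against the TSS and sometimes against the ATG,
  and the scanner takes no position on their equivalence.

Conservation grouping is single-linkage clustering of anchor-relative
offsets with a user window (default ±50 bp); a group containing every
input species is flagged conserved. This is deliberately lightweight —
no alignment or phylogenetic footprinting — because the scientific use
here is recovering planted or curated sites, not genome-wide discovery.

## The feedback model

State variables (arbitrary units): AMPK mRNA `mA`, total AMPK protein
`A`, Thr172-phosphorylated AMPK `Ap` (a sub-pool of `A`), NRF2 mRNA
`mN`, active NRF2 `N`, ULK1 phosphorylated at Ser555 `U` (bounded by a
pool `U_T`), autophagosome abundance `L` (LC3-II / GFP::LGG-1 proxy),
and p62 `P`. Stress is a sustained step `s(t) = dose` from `t = 0`.
Time is in hours; the wild-type stress-free steady state is normalized
to `mA = A = 1`.

```
mA' = k_mA / (1 + (N/K_N)^h)            - d_mA mA
A'  = k_A (1 + e_A s) mA                - d_A A
Ap' = (k_p0 + k_p s)(A - Ap)            - (k_dp + d_A) Ap
mN' = k_mN (1 + c_N s)                  - d_mN mN
N'  = k_N mN (k_N0 + k_N1 s + k_N2 Ap)  - d_N N
U'  = (k_U0 + k_U Ap)(U_T - U)          - d_U U
L'  = k_L U                             - d_L (1 + g_L s) L
P'  = k_P (1 + b_P N)                   - d_P0 P - d_P1 L P
```

There is no explicit delay term: the lag of the negative feedback
emerges from the mRNA → protein → active-TF cascade. Repression acts on
AMPK *transcription* only (a decreasing Hill term), matching the
localization of the effect to the mRNA level. The rise of AMPK protein
while its mRNA falls is carried by a stress-enhanced synthesis factor
`e_A·s`; the alternative (stress-inhibited degradation) was rejected
for identifiability. mTOR is not an explicit state; its inhibition by
AMPK is absorbed into `k_U`.

Three terms extend the minimal topology, each forced by an observable:

- **`k_p0` (basal Thr172 phosphorylation)** — without it the stress-free
  steady state has `Ap = U = L = 0` and every fold-change readout on
  autophagy is 0/0; untreated cells and worms demonstrably have basal
  autophagosomes.
- **`k_U0` (basal ULK1 drive)** — without it an *aak-2* deletion has
  `L ≡ 0`, whereas *aak-2* mutants retain basal GFP::LGG-1 puncta and
  show a 40% stress-induced reduction.
- **`g_L` (stress-enhanced autophagosome clearance)** — the only
  AMPK-independent route by which stress lowers `L`; required because
  LGG-1 puncta fall under stress even in *aak-2* null and *skn-1*
  RNAi animals. The calibrated human set keeps `g_L ≈ 0`, so the human
  transient is shaped purely by the feedback.

The `Ap` equation includes protein turnover `d_A·Ap`: `Ap` is a
sub-pool of `A`, and without that term total AMPK can fall through its
phosphorylated fraction during the post-peak collapse, violating
`Ap ≤ A`.

Genotypes/treatments are multiplier maps on parameters: siRNA/RNAi
scales both NRF2 synthesis steps (`k_mN`, `k_N`) by 0.05 — scaling the
transcript step alone leaves the AMPK-P-driven activation route intact
and only weakens, rather than breaks, the loop, contradicting the
persistently high autophagy seen without NRF2; *skn-1(gf)* scales `k_N`
by 3; *aak-2(gt33)* sets `k_A = 0`; *atg-11* sets `k_L = 0`; compound
genotypes compose multipliers.

### Numerics

Integration uses LSODA with `rtol 1e-8`, `atol 1e-10`; trajectories are
initialized at the condition-specific stress-free steady state, found
by a damped scalar fixed-point iteration (the basal point closes on `A`
alone) refined by a Newton root-find on the full right-hand side.
Nonnegativity is checked against integrator tolerance (−1e−6), not
enforced by clipping. Readouts interpolate linearly between grid
points; halving the step or tightening tolerances moves readouts by
less than 1e−4 relative. Fold-change readouts divide by the condition's
own `t = 0` value; only the basal-AMPK ratio is cross-condition
(silenced over wild type).

## Calibration

Each printed quantitative statement becomes a constraint (readout,
target, relative tolerance 0.10, weight, comparison). Human-cell
equalities: `mA(4)/mA(0) = 0.41`, `mN(4)/mN(0) = 1.94`, peak
`L/L(0) = 5`, silenced/WT basal AMPK `= 7`; inequalities: peak
`A/A(0)` within `[4, 9]` (a printed *range*, hence two one-sided
constraints) and `L(4)/L(0) ≤ 1.5` (return to near basal). Worm
equalities: `L(3)/L(0)` of 0.20 (WT), 0.60 (*aak-2*), 0.67 (*skn-1*
RNAi), each held to ±0.05 absolute.

Fitting is multistart bounded least squares on relative residuals in
log-parameter space (positivity, scale-spanning; default box
`[1e-3, 1e3]` widened to include the supplied start), seeded for
reproducibility (default seed 20181002). Inequalities contribute only
their violation. Joint satisfiability is the claim under test: a single
parameter set per system must satisfy its whole table, and the shipped
defaults do (all equalities at target to numerical precision).

The calibrated human dynamics are a strongly damped relaxation
oscillation: AMPK-P both *activates* NRF2 (`k_N2` dominant over basal
and direct-stress activation) and is repressed by it, so active NRF2
tracks AMPK-P with a lag. This is what lets autophagosomes fall back to
half their basal level at 4 h while AMPK mRNA is already recovering
through 41% — a monotone-decline parameter regime cannot reproduce the
peak-to-4 h contrast of the autophagy readout together with the mRNA
value (their product is pinned in any quasi-steady chain).

The worm set shares the equations with independent parameters: weak
basal repression (basal Hill occupancy ≈ 0.1, so genotypes have
comparable basal autophagy), a small stress boost to synthesis, and
nonzero `g_L`. Its wild type dips to 20% of basal LGG-1 signal at 3 h
and then partially rebounds toward the clearance-limited level — the
same loop signature as the human set on a faster observable.

### Identifiability

With four equality readouts, four parameters form the declared
identifiable subset: `c_N` (NRF2 mRNA induction), `d_mA` (AMPK mRNA
turnover), `K_N` (repression threshold), `k_p` (stress
phosphorylation gain). The recovery experiment regenerates the four
readout targets from the shipped optimum, perturbs them with
median-unbiased lognormal noise, and refits the subset: noiseless
recovery is exact; at noise sd 0.1 the pooled median absolute relative
error over 20 replicates is ≈ 0.10 (worst single parameter ≈ 0.17).
Other parameters are deliberately not claimed identifiable from this
constraint set; profile-likelihood analysis is out of scope.

## Phenotype layer

The GFP::LGG-1 area fraction is `clamp(scale·L, 0, 1)` with relative
change against the genotype's own untreated value. Paralysis is a
survival process with hazard affine in autophagosome load,

```
h(t) = (h0 + gamma * L(t)) * 1{dose > 0},   F(t) = 1 - exp(-∫ h dτ),
```

the simplest monotone law encoding the finding that sustained autophagy
is harmful under prolonged stress. `(h0, gamma)` are shared across all
genotypes; genotype identity enters only through `L(t)`, so the
predicted ordering of paralysis fractions is a genuine structural
prediction. A single dose multiplier maps the puncta assay's stress
input to the paralysis assay's; fitted jointly with the hazard, it
settles at its lower bound 1 — i.e. the effective stress input
saturates between the two TBHP concentrations, which is consistent
with the dose-dependent inhibition observed to reach its maximum well
below the paralysis-assay concentration.

Known structural limits, visible in the fit residuals and documented
rather than patched:

- *atg-11* (no autophagosomes, `L ≡ 0`) defines the pure-`h0` floor, so
  no nonnegative shared hazard can rank *aak-2* (which retains basal
  autophagosomes) strictly *below* it as the printed 11% vs 16% would
  require; both genotypes land together near the floor, each within
  0.08 of its printed value.
- *skn-1(gf)* + RNAi is excluded from the hazard least squares (weight
  0): with the Hill exponent of the calibrated loop, 3 × 0.05 NRF2
  synthesis is as complete a knockout as 0.05 alone, so its trajectory
  is identical to plain *skn-1* RNAi, while its printed 30% paralysis
  reflects incomplete neuronal silencing — a per-tissue RNAi-penetrance
  effect a whole-animal model cannot represent. It is still simulated
  and reported. The *skn-1(gf)* single mutant stays in the fit at
  weight 0.5 (its printed value is qualitative).

## Synthetic data

All generators are pure functions of their arguments and a seed.
Densitometry tables follow the wet-lab design (8 analytes × conditions
× 6 time points × 3 replicates) with multiplicative, median-unbiased
lognormal noise (band intensities are positive and ratio-scaled);
`NQO1`/`HO-1` report active NRF2, as canonical target genes.
Per-worm puncta fractions are Beta-distributed with specified mean and
concentration; paralysis cohorts draw each worm's failure hour from the
discrete hazard implied by a `ParalysisCurve`, censoring at the last
observation. Planted-motif FASTA generation resolves degenerate codes
uniformly and, in exclusive mode, resamples the background until a
both-strand scan recovers exactly the planted sites.

What the generators do *not* emulate: correlated replicate error (gel-
or batch-level effects), dose non-monotonicity of NRF2 mRNA reported at
high TBHP, per-tissue expression differences, image segmentation
artefacts. Passing tests therefore show internal consistency of the
pipeline under the stated noise laws, not robustness to those real-data
features. The default noise sd 0.2 is a choice — no variance estimates
accompany the printed values.

## Statistics

Independent two-sample Student's t tests (pooled variance, per the
stated method; Welch behind a flag) with Bonferroni correction
(`p_adj = min(1, m·p)`), and one-way fixed-effects ANOVA with Tukey's
HSD post hoc test (Tukey–Kramer for unbalanced designs), all two-sided
at α = 0.05. Degenerate input (zero within-group variance, unequal
means) yields `F = ∞, p = 0` flagged rather than an error. Null
calibration is asserted by simulation: per-test rejection 0.05 ± 0.01
and Bonferroni family-wise error ≤ 0.06 under 10,000 seeded null
datasets (3 groups × n = 5).

## Problem sizes

Default test and analysis runs use: 4-h (human) and 3–7-h (worm)
horizons at 0.02–0.05 h output steps; 2–3 multistart fits per
calibration seeded from the shipped optimum; 20 recovery replicates;
1,000 random sequences (≤ 200 bp) for scanner–oracle equivalence; and
10,000 null simulations for the type-I check. These sizes make the full
suite and the reproduction script each run in minutes on one core while
leaving every statistical assertion comfortably powered.
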