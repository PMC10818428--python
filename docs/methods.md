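# Methods

## Scope and model chain

`reyrisk` evaluates an element-concentration panel (samples × elements,
mg/kg dry weight) of coal fly/bottom ash through four layers: descriptive
statistics and normality screening, REY geochemistry, ecological indices,
and the USEPA residential exposure model with optional Monte Carlo
propagation. Each layer is a pure function of the table plus shipped
reference constants; the pipeline only sequences them, so any stage can be
re-run from an intermediate CSV.

## Reference constants

* **Background (UCC)**: the Rudnick & Gao (2003) upper-continental-crust
  compilation, used by EF, Igeo and E_r. Chosen because it is the standard
  modern compilation and reproduces published index values computed from
  crustal backgrounds (e.g. E_r(Lu) ≈ 58 for Chinese average fly ash,
  UCC-normalized Gd ≈ 3.5).
* **Normalization (NASC)**: Gromet et al. (1984) North American Shale
  Composite for anomaly work. Pr, Gd, Dy, Ho and Tm are the commonly
  tabulated companion interpolations (the original report covers the
  instrumentally determined subset); the CSV's `source` column marks them.
  Published per-sample anomalies are sensitive to which NASC variant a lab
  used, so anomaly outputs are validated by their mathematical properties
  (flat pattern → 1, scale invariance, numerator linearity), not against
  any specific published table.
* **Toxicity-response coefficients (T_r)**: the Hakanson values for ten
  HMs (Hg 40, Cd 30, As 10, Cu/Ni/Co/Pb 5, Cr 2, Mn/Zn 1) and the REY
  extension (Lu 20; Ho/Tb/Tm/Eu 10; Pr/Sm/Yb/Dy/Er/Gd 5; Y/Nd 2; Ce/La 1).
  The 15 REY coefficients sum to 96, which pins RI at unit concentration
  ratios and is asserted in the tests. Ba, V and Mo carry no T_r and are
  rejected from E_r computation by name.
* **Dose–response**: every REY uses the family-wide oral RfD of
  0.02 mg kg⁻¹ day⁻¹ and CSF of 3.2 × 10⁻¹² (mg kg⁻¹ day⁻¹)⁻¹. HM values
  are USEPA IRIS/RSL oral conventions under a worst-case speciation rule —
  Cr as Cr(VI), Hg as Hg(II), As inorganic. Elements without a published
  oral CSF (Hg, Mn, Ba, Cu, Mo, V, Zn) contribute zero to TCR rather than
  erroring, so mixed panels score in one call.

## Anomaly orientation

The cerium anomaly interpolates its neighbours La and Pr, the europium
anomaly Sm and Gd, each as the geometric mean of the normalized values:
Ce/Ce\* = Ce_N/√(La_N·Pr_N), Eu/Eu\* = Eu_N/√(Sm_N·Gd_N). This is the
standard geochemical orientation; source texts occasionally transpose the
two right-hand sides typographically, and the package deliberately fixes
the conventional assignment. Anomalies are computed on NASC-normalized
patterns; UCC normalization serves enrichment-style plots and the
background-ratio indices.

## Exposure model

Doses follow the standard USEPA residential soil equations
(ingestion `C·IR·EF·ED/(BW·AT·10⁶)`, dermal
`C·SA·AF·ABS·EF·ED/(BW·AT·10⁶)`, inhalation
`C·InhR·EF·ED/(PEF·BW·AT)`), with defaults: ingestion 200/100 mg/day
(child/adult), exposure frequency 350 d/y, duration 6/24 y, body weight
15/70 kg, skin area 2373/6032 cm², adherence 0.2/0.07 mg/cm², dermal
absorption 0.001, inhalation 7.6/20 m³/day, PEF 1.36 × 10⁹ m³/kg,
carcinogenic averaging time 70 years. A single oral RfD per element is
applied to all three pathways (no gastrointestinal-absorption dermal
adjustment or inhalation RfC), since one RfD per element is how such
panels are normally published; users can supply pathway-specific tables
through the toxicology CSV hook if needed. Cancer risk applies the oral
CSF to the ingestion lifetime dose only — the shipped slope factors are
oral, and under these defaults ingestion carries > 95% of dose anyway
(asserted in tests). An inhalation-unit-risk extension would attach at the
same hook and is deliberately out of scope.

With these defaults the chain reproduces published coal-ash results: a
mean total REY of 240.5 mg/kg gives child/adult HI of 0.154/0.0165
(printed 0.15/0.017 at two significant figures) and TCR of
8.4 × 10⁻¹⁶ / 3.6 × 10⁻¹⁶.

## Monte Carlo

Inputs are drawn jointly and pushed through the same vectorized dose
equations, so point-mass distributions reproduce the deterministic result
exactly (to float summation order) — the key consistency check between
the probabilistic and deterministic modules. Default distributions, all
overridable: body weight normal with CV 0.2 truncated at zero; ingestion
rate triangular at the deterministic mode ± 50%; exposure frequency
triangular (180, 350, 365) d/y; per-element concentrations normal at the
sample mean/SD truncated at zero; every other factor a point mass.
Lognormal specs take arithmetic moments and convert internally.
Sensitivity is the Spearman rank correlation between each varying input
and the endpoint, ranked by absolute value with alphabetical tie-break;
under the defaults the top exposure factors are body weight, ingestion
rate and exposure frequency, in line with what probabilistic soil-exposure
assessments generally find. Default 10,000 iterations (seconds of
runtime); a seed is mandatory and, with the configuration, fully
determines the output.

## Normality screening

The Ryan–Joiner statistic is the Pearson correlation between the ordered
data and Blom normal scores Φ⁻¹((i − 3/8)/(n + 1/4)), compared with the
standard critical-value approximation at α = 0.10/0.05/0.01. Blom's
plotting position is the common software default. The statistic is
location/scale invariant; constant input is rejected as undefined.

## Synthetic generator

The generator emulates what the analysis assumes of real ash panels:
per-element concentrations ~normal around group means, inter-REY Pearson
correlations in a 0.80–0.98 band, LREY:HREY near 4:1, and HM columns at
coal-ash magnitudes. REY correlation comes from a single common factor —
element *e* is `μ_e(1 + cv·(λ_e F + √(1−λ_e²) ε_e))` with loadings spaced
over [√0.80, √0.98], giving pairwise correlations λ_i·λ_j with a
closed-form oracle used in the recovery tests. One shared factor is the
simplest structure consistent with the uniformly strong positive
correlations that co-genetic REYs exhibit. HMs are independent apart from
a configurable equicorrelated As–Cd–Hg block (ρ = 0.7), reflecting the
volatile chalcophile association. Default group means: the shipped
worldwide REY group-mean table (Serbian fly/bottom columns); HM means are
mid-range coal-ash magnitudes, with As (92 mg/kg) and Cr (185 mg/kg) set
by inverting the dose equation from published mean child hazard quotients
for a heavily As-burdened ash, so a default panel lands at realistic
HM-dominated risk levels. Default CV 0.2, n = 5 + 5, truncation at zero by
row-wise rejection (resample count logged).

What the generator does *not* emulate: spatial/plant-level structure,
inter-group (fly vs bottom) correlation, analytical censoring near
detection limits, and heavy-tailed single-sample excursions (e.g. one
plant with an order-of-magnitude As spike). Passing tests on synthetic
data therefore demonstrate correctness of the index chain and its
statistical plumbing, not field representativeness of any specific ash.

## Numerical choices

* Risk-class boundaries: RI < 150 low, 150 ≤ RI ≤ 300 moderate,
  300 < RI < 600 high, RI ≥ 600 very high (600 resolves upward). EF and
  Igeo use the standard five- and seven-class literature tables,
  overridable via the `bins` arguments.
* Zero or negative concentrations are rejected with the offending
  sample/element named, rather than silently propagating NaN/−inf through
  the log and ratio indices.
* HQ/HI/TCR are kept at full precision; rounding to reporting precision
  (two significant figures) happens only in display/acceptance output.
* Constant columns in the correlation matrix yield NaN with a warning
  (undefined, not an error), so a panel with one censored element still
  processes.
* Truncated sampling uses rejection with a bounded retry count; a
  truncation that rejects nearly everything raises a configuration error
  rather than looping.

## Problem sizes

The test suite and acceptance script are desk-scale: deterministic chains
on one- or nine-row tables, Monte Carlo at 300–10,000 iterations, and
generator-recovery checks at n = 1000, which is ample for correlation
recovery within ±0.05. The whole suite runs in a few seconds.

## Known limitations

* Anomaly values depend on the NASC variant; cross-study comparison
  requires using the same normalization table.
* The two fixed receptors do not cover age-integrated lifetime weighting
  or occupational scenarios.
* No leaching, dietary or groundwater pathways; the model treats bulk ash
  concentration as the exposure medium.
* Sensitivity is rank-correlation (first-order, monotone); no
  variance-based (Sobol) decomposition.
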