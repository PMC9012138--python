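# Methods

## Model

The model lumps the capillary bed of a tissue volume into a single
effective exchanger. Net oxygen flux to tissue is

    J = D · (PO2_C_avg − PO2_T_avg)

with `D` the effective capillary oxygen diffusivity per volume,
proportional to capillary length density (`D = C_d · N_C · L_C / V`; the
dimensionless constant `C_d` is carried symbolically and cancels from every
normalized quantity, so no numeric value is adopted). The mean capillary
tension comes from inverting the hemoglobin Hill curve at the mean
capillary saturation, approximated by the linear axial profile
`S_avg = 1 − OEF/2`:

    PO2_C_avg = P50 · (2/OEF − 1)^(1/h)

No axial integration of the saturation profile is performed; the
`(2/OEF − 1)` form *is* the model. At steady state `J = rCMRO2`, and the
awake baseline fixes `D_o` through `J_o = OEF_o · CBF_o · [O2_A]` and the
baseline gradient. Two equivalent routes to the baseline ratio
`D_o/CBF_o` — explicit calibration and the closed form
`([O2_A]/P50) · OEF_o / ((2/OEF_o − 1)^(1/h) − PO2_T/P50)` — are both
implemented and tested for agreement to 1e-12 relative, as an internal
consistency check of the algebra.

### State curve

Normalizing by the baseline yields, for `J′ ≥ 1` (diffusivity pinned at
`D_o`, tissue tension homeostatic):

    CBF′ = (OEF_o · J′/2) · (1 + [(J′ · J_o/D_o + PO2_T_act)/P50]^h)

Below baseline, the empirical near-linear fall of both `D` and flow with
metabolism is modeled as `D = D_o · CBF′`, whose unique steady state is the
identity `CBF′ = J′` (the two sides of the implicit equation are monotone
in opposite directions, so no root search is needed there). At `J′ = 1`
with unchanged tissue tension the forward map returns exactly 1.0: the
algebra forces it, and the implementation short-circuits that case so the
identity holds to the last bit.

### Activation tissue tension

Lowered-tissue-tension scenarios keep the baseline calibration (`J_o/D_o`
computed at `po2_t_base`) and substitute the lowered tension only in the
operating term (`po2_t_act`). This two-tension reading reproduces the
1.75-fold ceiling at 17 torr; recalibrating the baseline at the lowered
tension does not, which is why `ModelParams` distinguishes the two fields.
The `curve_family` sweep over `po2_t_act` uses the same convention
(baseline calibration fixed); the sweep over `oef_o` instead re-bases every
curve so each passes through (1, 1).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `OEF_o` | 0.40 | – | cross-species awake extraction fraction |
| `P50` | 26.6 | torr | adult human hemoglobin half-saturation |
| `h` | 2.8 | – | hemoglobin Hill coefficient |
| `PO2_T` (base) | 27 | torr | awake tissue tension, homeostatic set point |
| `po2_t_act` | = base | torr | 17 torr models the mitochondrial floor |
| `CBF′_max` | 2.0 | – | physiological regional flow ceiling |
| `PO2_A` | 100 | torr | arterial tension; only enters the delivery ceiling |
| `[O2_A]` | 8.7 | µmol/ml | arterial O2 content; cancels from normalized results |

All are overridable via the YAML config or the CLI flags (`--oef0`,
`--p50`, `--hill-h`, `--po2t`, `--po2t-act`, `--cbf-max`). Units follow the
field convention: CBF in ml·100g⁻¹·min⁻¹, oxygen rates in
µmol·100g⁻¹·min⁻¹, tensions in torr. Temperature/pH (Bohr) shifts of P50
and species-specific hemoglobin curves are out of scope: the body-mass
dependence of P50 and arterial content is shallow enough that the
normalized model treats them as constants.

## Numerics

The forward map `J′ → CBF′` is closed-form. The inverse is solved by
Brent's method on the strictly increasing forward map, with the upper
bracket grown geometrically from `J′ = 1` (doubling, up to 64 expansions),
`xtol = 1e-12`, and a post-hoc residual check at 1e-10; bracket failure
raises a numerical error naming the searched interval. Degenerate inputs
(non-positive gradients, tissue tension at or above the mean capillary
tension, zero-variance regressors) raise typed errors rather than
returning NaN. Extraction fractions in [1, 2) are accepted by the
mean-tension formula (the mean saturation stays in (0, ½]) but warn, since
physiological OEF < 1. Curve tabulation defaults to `J′ ∈ [0.4, 1.8]` in
steps of 0.01.

## Meta-analysis conventions

Group summaries use the sample standard deviation (n−1), which reproduces
the printed cross-species tissue-PO2 summaries exactly at one decimal.
Regressions are ordinary least squares via statsmodels; the
fractional-change stimulation slope is fit through the origin by default
(zero metabolic change implies zero flow change) with the free-intercept
variant also reported, while the measured-vs-predicted flow regression
defaults to a free intercept. Seizure records are excluded from
stimulation fits by default (they exceed the normophysiological ceiling);
anesthetized records are pooled into OEF summaries by default, both
behaviors flag-controlled. No multiple-testing correction is applied: each
fit is a single pre-specified regression, and p-values are per-fit t-test
values. Formal meta-analytic weighting (inverse-variance, random effects)
is deliberately out of scope — the analyses pool raw values.

## Synthetic data

The generator emulates the three table families the analyses consume,
under the study conditions the analyses assume:

- **Regions**: 4 species × 12 regions; species-level extraction fractions
  drawn from a truncated normal around a true `OEF_o = 0.40` with SD 0.02
  (matching the observed spread of species means, 0.35–0.41); flow uniform
  over 30–110 ml·100g⁻¹·min⁻¹; metabolism set to `OEF·CBF·[O2_A]` with 5%
  multiplicative Gaussian noise (physiological measurement error is
  scale-proportional, and 5% reproduces the observed OEF scatter of ~0.06
  SD).
- **Stimulation**: 40 points with `J′` uniform on [1.05, 1.45], flow from
  the state curve, both converted to fractional changes with 5%
  multiplicative noise; ranges extending below 1 produce sleep-branch
  records.
- **Capillary density**: densities uniform over 300–1000 sections/mm² with
  glucose use and flow linear in density (slopes 0.0015 and 0.0022,
  typical of rat cortex morphometry) plus 10% noise.

A single integer seed fully determines every table (per-table-type
substreams derived via CRC32, so adding one generator never perturbs
another). What the generator does **not** emulate: per-study method biases
(PET vs autoradiography vs optical), regional correlation structure,
arteriolar oxygen exchange, or heteroscedasticity beyond a single CV — so
passing tests demonstrate that the pipeline recovers its own generating
process, not that real tables are this clean.

The inverse problem (`fit_oef_o`) minimizes the squared deviation between
measured and predicted normalized flow over `OEF_o ∈ (0.2, 0.8)` by
bounded scalar minimization (`xatol = 1e-6`); it requires at least five
above-baseline records.

## Known limitations and non-reproduced scenarios

Three literature scenarios are computed and flagged rather than asserted,
because the model with the adopted parameters gives different numbers: the
metabolic ceiling at `OEF_o = 0.6` comes out ≈1.54-fold (quoted: 1.8), at
`OEF_o = 0.3` ≈1.37-fold (quoted: <1.25), and the flow needed to sustain
`J′ = 1.4` at 15 torr tissue tension ≈1.06 (quoted: 1.25). The pipeline
report carries all three with an `agrees` flag, and the log warns on each.

Out of scope by design: the spatially resolved Krogh-cylinder PDE (only
the lumped algebraic form is implemented), BOLD-signal generation, capillary
recruitment (ruled out in brain by direct red-cell observation), glucose
oxidation stoichiometry, and dynamic flow transients.

## Problem sizes

Randomized consistency checks use 1,000 parameter draws for the algebraic
identities and 200 for curve-vs-numerical-solve agreement; parameter
recovery uses 200 seeds at 40 stimulation points each. These sizes give
stable estimates of the bias and agreement statistics they test while
keeping the full suite in a few seconds.
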