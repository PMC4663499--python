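# Methods

## Endpoints and quality control

The primary endpoint is the effective quantum yield of photosystem II under
illumination, ΔF/Fm′ = (Fm′ − F)/Fm′, where F and Fm′ are the minimum and
saturating-pulse maximum chlorophyll fluorescence of a light-adapted leaf.
The dark-adapted analogue Fv/Fm = (Fm − F0)/Fm indexes the intactness of the
PSII apparatus and is used for quality control, not for dose-response:

* **leaf screening** — only leaves with Fv/Fm strictly greater than 0.65
  enter an assay. The boundary is strict: a leaf at exactly 0.65 is rejected.
  Leaves without dark-adapted readings cannot be screened and are rejected
  with reason "unscreened".
* **control drift** — the mean Fv/Fm of solvent controls must decline by less
  than 8.5 % from the 0 h baseline at every later timepoint (24/48 h),
  otherwise the batch fails QC. Readings within ±1 h of a nominal timepoint
  are binned to it.

Phytotoxicity is expressed as percent inhibition relative to the solvent
control, I(%) = 100·(Y_control − Y_sample)/Y_control. Two choices here are
deliberate: the control reference is the **mean** solvent-control yield of
the same batch and timepoint (matching SE-style reporting of replicate
variation), and **negative inhibition is preserved** — clipping stimulation
at zero would bias the lower asymptote of the logistic fit upward.

## Concentration-response model

Inhibition as a function of dose x follows the four-parameter logistic

    I(x) = B + (T − B) / (1 + (IC50/x)^h)

with bottom B, top T, Hill slope h, and midpoint IC50. Fitting choices:

* **parameterisation** — the model is fitted against z = log10 x with
  m = log10 IC50 as the free parameter. This conditions the optimiser well
  and makes the delta-method CI symmetric on the log scale, where sampling
  distributions of potency estimates are closest to normal.
* **controls excluded** — dose-0 wells define the 0 % scale during
  normalisation; including them again in the nonlinear fit would
  double-count that information (and log dose is undefined at 0).
* **bounded least squares** — parameters are estimated by trust-region
  least squares with analytic Jacobian under generous data-driven bounds:
  asymptotes within one response span of the observed range, h ∈ [0.05, 20],
  m within two decades of the dose grid. The bounds exist because the
  unconstrained 4PL has a degenerate ridge (B → −∞ with h → 0 mimicking a
  log-linear segment) that occasionally captures noisy fits; within the
  bounds the estimates are interior for all realistic data.
* **multi-start** — nine deterministic starts (m at the dose-grid midpoint
  and ±1 decade × h ∈ {0.5, 1, 2}; B, T at the response extremes). Best
  residual SS wins; ties break to the start closest to the grid midpoint.
  Fits are therefore exactly reproducible.
* **canonical orientation** — the 4PL is invariant under
  (B, T, h) → (T, B, −h); fits are reported with h > 0, and a fitted T < B
  (non-increasing response) triggers a warning.
* **constrained mode** — optionally B = 0, T = 100 (fit only h, m) for
  assays where the inhibition scale is trusted end to end.
* **degenerate input** — identical responses at all doses, or fewer than
  five distinct positive doses, raise a fit error rather than returning a
  meaningless curve.

An independent brute-force minimiser (`pamtox.validation.grid_fit_4pl`)
profiles B and T out linearly for each (h, m) candidate and refines a zooming
grid over (log h, m); it shares no code with the trust-region path and is
used as the oracle for fit correctness.

### ICx and confidence intervals

ICx is reported in **absolute** mode by default: the dose where the fitted
curve crosses x % inhibition, x = IC50·((x − B)/(T − x))^(1/h). This is the
quantity a threshold comparison needs (an ETV must sit below the absolute
10 % effect dose). The **relative** mode (x % of the B→T span,
IC50·(x/(100−x))^(1/h)) is available for comparison with packages that
define ICx that way; the mode is recorded in every estimate.

The default CI is the delta method on log10 ICx using the full parameter
covariance and a t quantile with the fit's residual degrees of freedom. A
nonparametric bootstrap (resampling replicates within dose, seeded, default
1000 draws) is available as `ci_method: bootstrap`. In the recovery study
below the delta CI covers the true IC50 in 92–98 % of simulated assays,
slightly anticonservative but close to nominal.

### Relative potency

ReP = IC50(reference)/IC50(test), reference diuron. The reference IC50 is the
**24 h diuron value for all rows, including 48 h endpoints** — that is the
basis on which the published 48 h potency ratios were computed (no 48 h
diuron endpoint exists), and it keeps all ReP values on a single scale.

### Curve comparison

Whether curves share an IC50 is tested with the extra-sum-of-squares F test:
the reduced model fits one common IC50, the full model one per curve, and

    F = [(SS_red − SS_full)/(df_red − df_full)] / (SS_full/df_full).

Under the default `shared_bth` scheme B, T and h are shared globally in both
models — appropriate for same-endpoint, same-mode curves where only potency
should differ, and the scheme with the most stable small-sample behaviour.
A `separate_all` scheme (each curve keeps its own B, T, h) is available; the
scheme is configurable because the degrees of freedom of the original
analysis could not be reconstructed from the published design. Post-hoc
output is the full table of uncorrected pairwise two-curve F tests (matching
letter-group presentation conventions) with a Holm-adjusted column alongside.

## Mixture analysis

Toxic Units normalise each component by its own potency: TU = C/IC50, and
TU_sum = Σᵢ Cᵢ/IC50ᵢ. The TU basis is the **24 h IC50 table by default**,
even for compounds that act more slowly — mixtures are assayed at 24 h, so
toxic units must be expressed on the 24 h basis; the basis is recorded in
every output and mixing 24 h and 48 h bases raises an error.

Mixture proportions are **shares of TU contribution**, not of mass: an
equal binary mixture doses each component at 0.5·L·IC50ᵢ for TU level L,
which reproduces the published dosing design exactly. The dilution series is
(0, 0.25, 0.5, 0.75, 1, 1.5, 2, 4) TU.

Under Concentration Addition a same-mode mixture behaves like a single
compound with IC50 = 1 TU_sum, irrespective of proportions. The decision
rule, in order of precedence:

1. fit the mixture's TU-scale 4PL and take its absolute IC50 (the published
   TU endpoints are absolute 50 % crossings, not the raw midpoint parameter);
2. compare against sham reference mixtures ([X+X] self-mixtures of the two
   dominant components, generalisable to any references) by pairwise F test
   at α = 0.05. The mixture is **non-additive only if it differs
   significantly from every reference**: a difference from one sham but not
   the other is within the shams' own spread — self-mixtures are additive by
   construction, so their scatter calibrates the comparison;
3. non-additive mixtures are **synergistic** below 1 TU and **antagonistic**
   above it;
4. with no references, the fallback is whether the IC50's 95 % CI contains
   1 TU, flagged as `ci_contains_1` in the result.

The significance test dominates the point estimate's direction: an IC50 of
0.90 TU consistent with the references is additive, not synergistic.

## Guideline screening

An ecotoxicity threshold value protects the photosynthetic endpoint only if
it lies below the concentration at which inhibition begins; the IC10 is that
onset. The rule is **protective ⇔ ETV < IC10**, with equality flagged
non-protective (at ETV = IC10 the endpoint is already 10 % inhibited; no
printed cell sits exactly at the boundary, so the convention is fixed here by
documentation). For the four slow-acting compounds with measured 48 h
endpoints (ametryn, metribuzin, prometryn, hexazinone) the 48 h IC10 is used,
matching the published comparison; missing ETVs are emitted as
not-assessable.

One cell of the shipped guideline table is internally inconsistent with this
rule as printed: the regional 90 % threshold for tebuthiuron (20 µg/l, IC10
3.9 µg/l) is marked protective in the source although an identical 20 µg/l
value in the neighbouring guideline set is marked non-protective. The fixture
reproduces the printed marking verbatim; the test suite asserts the
discrepancy explicitly rather than hiding it.

## Synthetic-assay generator

The generator emulates the study design: 12-well plates, 9 replicate leaves
per concentration, solvent controls, a 7-point geometric concentration series
spanning IC50/30 to 30·IC50 (the published single-compound series is not
printed; a symmetric two-decade ladder around the IC50 is standard range-
finding practice), and the fixed TU series for mixtures.

* **truths** — the published IC10/IC50 endpoint table, as 4PL curves with
  B = 0, T = 100 and Hill slope 1 (the canonical single-site binding shape;
  the published table prints no slopes).
* **noise** — Gaussian on the inhibition scale, homoscedastic,
  sd = 5 inhibition points. No numeric replicate SD is published; 5 points
  gives replicate SEs of ≈1.7 points at n = 9, consistent with small
  figure-style error bars, and is deliberately a documented guess. The
  raw-plate path induces realistic heteroscedasticity instead: yields are
  clipped to [0, 1] before conversion to fluorescence (clip events counted),
  so inhibition noise shrinks near the 0 % and 100 % rails.
* **controls** — dose-0 wells draw around 0 % inhibition; control effective
  yield defaults to 0.70 (a healthy-leaf value above the 0.65 screening
  floor; a configuration default, not a measured value).
* **mixtures** — the response mean at nominal TU_sum L is a reference
  TU-scale truth curve (default 0–100 %, h = 1, IC50 = 1 TU) evaluated at
  `deviation_factor · L`; factor 1 is exact CA, factor k makes each nominal
  TU act as k TU (k > 1 synergy, k < 1 antagonism).
* **determinism** — one integer seed; every treatment draws from a substream
  keyed by a CRC-32 of its name, so outputs are byte-identical across runs
  and processes.

What passing simulation tests shows — and what it does not: the studies
validate the estimation machinery under Gaussian, independent, exchangeable-
replicate noise with exactly logistic truth curves. Real leaf assays have
between-leaf heterogeneity, plate effects (randomised away in the design, not
simulated), time-dependent uptake between 12 and 48 h, and possibly
non-logistic tails; none of these are emulated, so the studies certify the
statistics, not the biology.

## Simulation studies (problem sizes)

Run both by `tests/test_acceptance.py` and by `scripts/acceptance.py`:

* oracle equivalence — 9 noiseless curves (h ∈ {0.6, 1, 2.5} ×
  IC50 ∈ {0.5, 10, 250});
* recovery — 200 simulated assays per published truth (14 truths,
  2 800 fits): median |log10(IC50̂/IC50)| and 95 % CI coverage;
* CA null — 200 seeds × 4 mixtures under exact additivity: mean fitted
  IC50 (TU) and the pairwise F-test rejection rate at α = 0.05
  (1 200 tests);
* synergy power — 200 seeds at deviation factor 2, classified against two
  sham references.

These sizes keep each full study run to a few minutes while making the
binomial uncertainty on coverage and type-I rates small (≈±1.5 % at n = 200).

## Known limitations

* Raw well-level data behind the published endpoint tables are not deposited,
  so the fitted IC50s themselves are validated by simulation under the same
  design, not recomputed from data.
* The delta-method CI is mildly anticonservative (≈92–96 % observed coverage
  at nominal 95 %); the bootstrap option trades runtime for better small-
  sample behaviour.
* Hormesis (stimulation at sub-inhibitory doses beyond noise) is not
  modelled; negative inhibition is carried through but the 4PL has no
  hormetic bump term.
* Time-course kinetics are treated as data attributes (24 vs 48 h endpoints),
  not modelled; TU bases from different durations cannot be mixed.
* Independent Action / response-addition mixture models are out of scope; CA
  is only valid for same-mode toxicants.
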