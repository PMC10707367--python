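# Methods

## Model and assumptions

The tracer system is a linear two-compartment model of plasma cholesteryl
ester (CE): compartment 1 is the HDL-CE pool, compartment 2 the combined
VLDL/LDL-CE pool.  Two structural assumptions are inherited from the study
design being emulated: (1) VLDL and LDL are treated as a single kinetic
pool, because VLDL-CE concentration is comparatively negligible; (2) all
label enters through the HDL pool (the injected bolus is HDL-[³H]-CE).
The four transfer coefficients are first-order and time-invariant, and the
animals are assumed to be in steady state over the 5-h study (pool sizes
constant), which is what licenses the production-rate formula
PR = FCR × CE concentration × plasma volume / body weight.

`solve_model` evaluates the analytic matrix exponential of the 2×2 system
via its eigen-decomposition.  Both eigenvalues are always real (the
off-diagonal product is non-negative); when their relative gap is below
1e-12 the repeated-root branch `(A + Bt)e^{λt}` is used.  Exact
floating-point round-off below zero is clipped.

Direction convention: the coefficient names spell out the transfer
direction (`k_hdl_to_vldl` is HDL → VLDL/LDL, conventionally printed
K(1,2); `k_hdl_out`/`k_vldl_out` are the irreversible removals K(1,0) and
K(2,0)).  Classical compartmental software sometimes indexes
destination-first; the K(i,j) labels here are presentation only, and the
explicit field names remove the ambiguity.

Mass fluxes multiply each rate constant by the CE concentration of its
*source* compartment (first-order mass action); total outflow is the sum
of the two removal fluxes.  Units: rates min⁻¹, pools μmol/L, fluxes
μmol·L⁻¹·min⁻¹.  FCR and PR are reported in h⁻¹ and mg·kg⁻¹·h⁻¹; the
single ×60 conversion lives in `kinetics.per_minute_to_per_hour`.

## FCR definition and the two estimation routes

FCR is defined as the reciprocal of the area under the normalized
fraction-remaining curve of the HDL pool (the Matthews convention):
FCR = 60/(A/α + B/β) for the biexponential, and the closed form
60·[K(1,0) + K(1,2)K(2,0)/(K(2,1)+K(2,0))] for the compartmental model —
the second factor being the fraction of each HDL→VLDL/LDL transfer that is
eventually removed rather than recycled.  On noiseless model-generated
data the two routes agree to numerical precision (property-tested against
adaptive quadrature of the analytic curve), which is the package's
internal consistency check between them.

Both fits are bounded least squares (`scipy.optimize.least_squares`) with
multistart: curve-peeling initial values plus a seeded log-uniform random
batch for the biexponential; a log-spaced lattice (3e-4 … 1e-2 min⁻¹)
plus a seeded random batch (≥ 8 starts) for the compartmental fit.  The
winner is the lowest-RSS converged solution, ties broken by smaller
parameter norm.  Convergence: relative RSS change < 1e-10 or step < 1e-8,
max 10,000 evaluations per start.  Weighting is uniform by default with a
proportional (1/y²) option in the configuration.  Fit reports record the
seed, the winning start and the RSS for audit; identical input and seed
give bit-identical reports.  A residual-based covariance estimate flags
(without failing) compartmental fits whose relative parameter uncertainty
exceeds 100% — with 11 samples per series, the return transfer K(2,1) is
the usual culprit.

### Slow-phase identifiability and the peeling fallback

With sampling truncated at 300 min, a slow phase with half-life beyond
~10 h is barely expressed in the data: for slow-turnover rate sets the
weighted-least-squares optimum of the biexponential regularly sits at
β = 0 with a non-trivial fraction B — a non-decaying tracer component,
inadmissible under steady-state catabolism (all CE is eventually
catabolized, so the curve must decay to zero).  This is a genuine feature
of the likelihood at these study conditions, not an optimizer artifact:
descent from the true parameters reaches the same boundary solution.
When the winning solution pins the slow rate at the numerical floor, the
fit falls back to classical curve peeling — the slow rate is fixed to the
log-linear slope of the last four samples and the fast phase re-estimated
under the A + B = 1 constraint — and the report is flagged
`slow_phase_unidentifiable`.

Measured estimator behavior at the default study conditions (11 samples,
3% proportional noise, 200 seeded replicates): the compartmental route is
essentially unbiased (median FCR within ~4% of truth for both the
sham-like and ntx-like rate sets, log-scale SD ≈ 0.07–0.11) because the
VLDL/LDL series constrains the exchange; the biexponential route is
median-biased upward by about +11% (sham-like) to +20% (ntx-like), the
conditioning effect of the identifiability boundary described above.
Tests assert the compartmental route at the 10% tolerance and the
biexponential route at a documented 15% envelope for the sham-like set.
Per-animal analyses should prefer the compartmental FCR when both tracer
series are available; the biexponential route is retained because it is
the classical single-series estimator and the two-route agreement on
clean data is itself a check.

## Densitometry

Marker proteins of known hydrodynamic diameter calibrate the migration
axis with log-diameter linear in position (the standard behavior of
native gradient gels); markers are canonically sorted, the mapping must
be strictly monotone, and extrapolation is limited to 5% of the marker
range.  Subclass fractions are trapezoidal AUCs of the stain signal over
the five diameter windows divided by the AUC over the full 7.94–13.59 nm
span.  Integration happens on the calibrated nm axis, so a nonuniform
calibration cannot bias window masses.  Windows partition the span
half-open [low, high) with the last closed — immaterial for integrals but
stated for boundary bookkeeping.  Optional constant-baseline subtraction
(minimum signal over the span) is off by default.  Per-subclass
concentrations are proportional apportionment (fraction × total HDL
concentration of that lipid), the only reading consistent with the
percent-AUC definition; per-subclass CE is per-subclass TC − FC, so the
CE/PH = TC/PH − FC/PH identity holds exactly at the per-sample level
(published tables report medians of ratios, where it holds only
approximately).

## Synthetic cohorts

The generator emulates the two-group design: n = 6 animals per group,
body weight uniform on 3.0–3.5 kg, the 11-draw schedule with the 5-min
sample as the 100%/0% normalization reference, and a 1×10⁶ cpm dose.
Per-parameter between-animal variation is log-normal with μ = ln(median)
and σ = ln(q3/q1)/(2·z₀.₇₅), so medians and quartile ratios converge to
their targets as n grows (verified at n = 10,000).  Targets default to
the published group biochemistry (lipid panels in mmol/L) and FCR medians
0.24 (0.17–0.36) h⁻¹ (sham) vs 0.14 (0.10–0.19) h⁻¹ (ntx).  Each
animal's rate set is the group's base rate set scaled by one common
log-normal factor matched to the FCR targets: turnover speed varies
between animals, exchange topology does not.  Marginals are matched only
— the real study's joint between-animal covariance is unknown — and HDL
total cholesterol is built as FC + CE so the cholesterol identity holds
within every animal.  The VLDL/LDL CE pool is taken as 75% of non-HDL
total cholesterol (a typical esterified fraction; configurable), which is
also the plasma-CE completion used for PR in the pipeline.

Counting noise is proportional Gaussian at CV 3% by default; at ≥10⁴ cpm
per sample this is indistinguishable from Poisson on raw counts (a
Poisson mode is available) while keeping the percent scale exact.  Noisy
curves are renormalized by their first sample, mirroring the laboratory
convention; negative noisy counts are clipped at zero and logged.
Densitograms are five Gaussians at the window midpoints with σ = 1/8 of
the window width (> 99.99% of each component inside its window), rendered
on a uniform nm grid over 7.6–13.9 nm and mapped into gel coordinates
through a two-marker calibration (positions 10/90 ↔ 17.0/7.1 nm), so the
file-level inputs look like scanned gels and round-trip exactly through
`calibrate_sizes`.

What passing tests show — and do not show — about real data: the
generator reproduces the marginal medians/IQRs, the noise scale, and the
normalization convention of the emulated study, so recovery tests
demonstrate the estimators work under those conditions; it does not
reproduce unknown between-animal correlations, non-proportional counting
error, gel artifacts (baseline drift, streaking), or any deviation from
first-order kinetics, so field data can behave worse.

Group-contrast detection: with spread matched to the published IQRs the
two FCR distributions overlap substantially — P(sham > ntx) ≈ 0.77 —
which caps exact Mann–Whitney power at n = 6/6 near 0.3 regardless of the
estimator.  Measured over cohort seeds 0–39 at the default conditions,
the fitted-FCR contrast reaches p < 0.05 in 30% of cohorts; the test
suite asserts detection well above the 5% false-positive rate (≥ 15%)
and documents the measured rate here.  The published study's own
significant result is consistent with this: a single cohort draw, not a
power statement.

## Group statistics

Summaries are median (q1–q3) with linear-interpolation quartiles (the
common spreadsheet/statistics default; configurable conventions cannot be
adjudicated from published IQRs).  The Mann–Whitney U test reports
U = min(Ux, Uy); for tie-free groups with both n ≤ 10 the exact null
distribution of U is enumerated by the standard counting recursion and
the two-sided p is twice the lower tail, capped at 1 (the classical-table
convention).  With ties or larger groups the mid-rank normal
approximation with tie and continuity correction is used and flagged.
The exact path is property-tested against brute-force enumeration of all
C(n+m, n) assignments; its type-I error at nominal α = 0.05, estimated
over 2,000 seeded null cohorts at n = 6/6, is conservative (≈ 0.02–0.04)
because of discreteness.  No multiple-testing correction is applied, and
the report says so — per-variable α = 0.05 mirrors the reporting
convention of the emulated study.

## Numerical and design choices

- mmol/L ↔ mg/L conversion for CE uses a configurable molar mass,
  default 650 g/mol (typical cholesteryl ester).
- Plasma volume: 0.0328 L/kg body weight (rabbit); body weight cancels in
  PR but is kept as a parameter for traceability.
- Time-activity ingestion shifts the first sample to t = 0 and
  renormalizes to 100%/0% when the first sample is within 2 percentage
  points of that convention (one common factor rescales both series after
  baseline subtraction); larger deviations are rejected with the row
  identified.
- CSV dialect: comma-separated UTF-8 with header row and "." decimals;
  every writer has a paired reader and round-trips to double precision.
- Degenerate inputs: zero total densitogram AUC, trapped-tracer rate
  configurations (transfer into VLDL/LDL with no exit), closed systems
  (no removal path), inverted quartile targets, and non-monotone
  schedules all raise typed errors rather than returning NaN.
- Test problem sizes: the heavier properties run at 100 compartmental /
  200 biexponential noisy replicates, 40 power cohorts, 2,000 null
  cohorts for the type-I check, and n = 10,000 per group for median
  convergence — sizes chosen to hold Monte-Carlo error well below the
  asserted tolerances.

## Known limitations

- Per-animal fits only; no population (NLME) model and no
  free-cholesterol kinetics.
- The biexponential route's upward median bias under slow turnover is
  inherent to the truncated sampling window (see above); extending
  sampling beyond 300 min is the only real cure.
- The synthetic flux tables inherit the generator's FCR-consistent rate
  scale and therefore sit in the low μmol·L⁻¹·min⁻¹ range; the package
  makes no attempt to force group flux medians to any particular printed
  value, and the flux arithmetic is verified separately on constructed
  rate/pool decompositions.
- Exact Mann–Whitney requires tie-free data; heavily tied variables fall
  back to the approximate path (flagged in the output).
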