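# Methods

## Scope and data

The package implements the statistical workflow of a spray-drying
microencapsulation formulation study: a two-factor central composite design
(CCD) over the core:shell and maltodextrin:gum-arabic (MD:GA) ratios,
second-order response-surface fits for the encapsulation responses,
multi-response desirability optimization, and release-kinetics model
fitting for dissolution time series. The bundled dataset
(`microenc/data/*.csv`) is the study's 13-run design and per-run response
means ± SD; raw release curves and assay-replicate values were never
published, so everything at those levels is exercised through the synthetic
generators instead.

## Design construction and factor coding

Factors are coded so the factorial levels are ±1 and the center is 0;
`actual = center + step * coded`. Each two-component mixture ratio (a:b
with a+b fixed) is represented by its first coordinate — core mass with
shell fixed at 5, MD mass with MD+GA = 5 — and rendered as a ratio only for
display. A k-factor CCD is the 2^k factorial, 2k axial points at distance
α, and n_center center replicates, in that canonical order. Rotatable
α = 2^(k/4); for k = 2 this is 1.414, which matches the bundled design's
coded axial entries.

The bundled design stores the published actual values verbatim. For the two
MD:GA axial runs those actuals (1.5 and 3.5) correspond to coded ±2 under
center 2.5 / step 0.5, not to the coded ±1.414 they are printed beside.
Which levels were physically run cannot be resolved from the published
record, so both are preserved: regression always uses the coded columns
(refits of the published coefficient table confirm that choice), and
`validate_design` flags the coded/actual mismatch rather than silently
repairing either side.

## Encapsulation responses

EY = 100 × powder collected / solids fed. With phenolic contents expressed
in g per 100 g of powder, LC = total − surface phenolics, and EE = 100 ×
(total − surface) / theoretical. "Theoretical phenolic content" is defined
here as the core mass fraction of total solids × 100 — the tannin-extract
core treated as entirely phenolic. This is a package decision (the quantity
has no published definition); it is the only convention that back-computes
the tabulated EE values from the tabulated inputs, and it makes
LC = EE × core-fraction an exact identity. One tabulated EE cell (run 6)
is not derivable from its printed inputs under any convention we tried and
is treated as a data artifact. Moisture, water activity and CIELAB color
columns are carried as passthrough data and never modeled.

## Response-surface fitting

The full quadratic on coded factors is fitted by OLS (statsmodels behind
the module surface; tests cross-check against an explicit normal-equations
solve). Fits use the 13 per-run means: with balanced replication the OLS
point estimates equal replicate-level ones, and the published coefficients
reproduce this way. Coefficient inference uses two-sided t tests with
N − p residual df, no multiplicity correction. The full model is always
reported; non-significant terms are starred (or not), never dropped.

Residual variation is split into pure error (within replicated design
points, here the 5 center runs: N − n_distinct = 4 df) and lack of fit
(n_distinct − p = 3 df), tested by F = MS_LOF / MS_PE. A caveat that
matters when reading the bundled-study output: pure error computed from
the center-run *means* is much smaller than triplicate-level assay error,
so lack-of-fit p-values on the bundled tables come out small even though
the same models were reported as adequate when fitted to replicate-level
data. The LOF machinery is therefore validated on synthetic data (exact SS
decomposition, zero LOF for noiseless quadratics, calibrated p under
replicate-level noise) rather than against the published LOF line.

Two unit/typo decisions are applied and logged in every report header:
tannin content is regressed in mg/g (10× its tabulated g/100 g — the only
scale on which the published TC coefficients live), and the run-7
encapsulation yield is optionally replaced by the study-text value 29.75
(the tabulated 39.75 is irreconcilable with the published EY coefficients;
the corrected value reproduces them). Both variants of the EY column are
retained. The published EE coefficient column is not reproducible from the
tabulated EE means under any tested treatment; EE fits are checked for
internal consistency only.

## Desirability optimization

Individual desirabilities follow Derringer–Suich: for maximization, 0 at
or below the lower anchor, ((y − lower)/(upper − lower))^weight between,
1 at or above the upper anchor; minimization mirrored; target goals rise to
1 at the target and fall back. Defaults are package decisions where the
study stated none: anchors "auto" (the response's fitted min/max over the
search region — parameter-free and reproducible), weights 1, search region
the factorial square [−1, +1]² (the study kept factors "in range", and its
reported optimum lies on the factorial boundary). The overall D is the
geometric mean; optimization is a deterministic 201×201 grid scan (ties
resolved to the first, lexicographically smallest grid point) followed by
bounded L-BFGS-B polish, so results carry no seed. The study's reported
D = 0.9 is not reproducible without knowing its anchors and weights; the
package reports D under its own documented convention (≈0.77 for the
four-response maximization) and asserts only the optimum's location
properties, which are anchor-independent for single responses.

## Release kinetics

Dissolution series record the concentration measured in each 1 mL aliquot
drawn from a 50 mL vessel at 0.5, 1, 2, 4, 8 and 24 h with medium
replacement. The replaced-aliquot correction
`Qt_i = C_i + (v/V) Σ_{j<i} C_j` (the standard dissolution-testing
convention; the study states only that a volume correction was applied)
restores cumulative release. All four models are fitted on their
linearized axes — exactly the straight-line form dissolution tables report
— not by nonlinear least squares: Qt vs t (zero order), log10 Qt vs t
(first order, signed slope reported as fitted; the printed model has k1
subtracted even though release grows), Qt vs √t (Higuchi), log Qt vs log t
(Korsmeyer–Peppas; exponent n is log-base invariant). Intercepts are free
by default (published fits have nonzero intercepts); regression through
the origin is an option. The Korsmeyer–Peppas fit drops non-positive Qt
points (warning) and applies no first-60%-of-release truncation by default
(available as an option). Model selection ranks linearized R² descending
with ties broken by parameter count then fixed model order. Transport
classes for spheres: n ≤ 0.43 Fickian, 0.43 < n < 0.85 anomalous, n ≈ 0.85
(±0.01) Case II, larger Super Case II — the thresholds are a documented
decision; only the categories are standard.

## Synthetic generators

`simulate_surface` draws y = (full quadratic at the design point) +
N(0, σ²), replicates sharing the point; `simulate_release` evaluates the
chosen law on the time grid, converts to per-draw concentrations by the
exact inverse of the volume correction, and applies multiplicative
Gaussian noise (fraction σ) per draw, clipping at zero. Gaussian noise is
the minimal assumption consistent with mean ± SD reporting; the generators
are pure functions of their spec (seeded `default_rng`), so identical
specs give byte-identical output. What they do not emulate: assay
calibration error, inter-batch spray-dryer drift, correlated draws within
a dissolution run, or non-Gaussian tails — passing recovery tests
demonstrates correctness of the estimators under the assumed error model,
not robustness to real-data pathologies.

Study-condition defaults used by the recovery studies: surface noise
σ = 0.3 on a response of magnitude ~12 (roughly the bundled study's
center-run SDs), 500 Monte-Carlo replicates for the unbiasedness check;
release noise σ = 5% per draw, 200 replicates, Higuchi k_H = 10 with burst
intercept Q0 = 12 (the published Higuchi lines with k_H ≈ 10 carry
intercepts of 8.9–15.2). These sizes keep the full suite and the
acceptance script to a few seconds.

A known limitation surfaced by the selection study: a Higuchi curve with
burst intercept is approximated by the free-exponent power law to
R² ≈ 0.99 even without noise, so under 5% draw noise the four-model
linearized-R² ranking picks Korsmeyer–Peppas in roughly one replicate in
eight. The measured Higuchi selection rate is ~85–88% across realistic
intercepts (and ~66% at Q0 = 0, where the two models coincide exactly);
ranking on a common back-transformed scale is slightly worse. Selection
by linearized R² among models of unequal flexibility is inherited from
standard dissolution practice and should be read accordingly.

## Numerical notes

- Orthogonality of generated CCD coded columns holds to 1e-12 and is
  asserted at that tolerance; the fixture's printed ±1.414 columns are
  exactly balanced.
- Constant responses (zero total variance) define R² = 1 for a perfect
  fit rather than 0/0; the lack-of-fit F is reported as undefined when
  pure error is exactly zero.
- Rank-deficient model matrices raise with the aliased terms named
  (pivoted-QR detection).
- Desirability anchors collapse (flat surface) to a degenerate 1e-12
  window rather than dividing by zero; D uses log-space accumulation so a
  single d = 0 yields exactly 0.
- Text reports render at journal precision (3 decimals for coefficients);
  JSON keeps full precision. Pipelines are byte-deterministic for a fixed
  configuration.
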