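# Methods

## The reporter and what the assay measures

The reporter is GFP fused to the tetraspanin CD63 through a protease
cleavage site, with a nuclear localization signal on the GFP side. CD63
distributes between the limiting membrane (LM) of multivesicular bodies
(MVBs) and their intraluminal vesicles (ILVs); immunogold EM puts that
ILV:LM abundance ratio ρ near 2. A split protease reconstituted by a small-
molecule dimerizer cleaves only reporter whose cleavage site faces the
cytosol — the LM pool (and the cell-surface pool), never the intraluminal
pool. Endolysosomal GFP loss beyond the LM share `1/(1+ρ)` therefore
reports retrofusion: ILVs fusing back with the LM and re-exposing cargo.

## Kinetic model

Six pools, all expressed as fractions of the initial endolysosomal signal:
`L` (LM), `I_dyn` (retrofusion-competent intraluminal), `I_inert`
(retrofusion-inert intraluminal), `N` (cleaved, nuclear), `D` (degraded),
`S` (secreted in exosomes). Dynamics are linear first order (see the README
for the equations); the assay's observable is `L + I_dyn + I_inert`.

Assumptions worth stating explicitly:

* Cleavage is first order in `L` with a single rate `k_cleave`; protease
  abundance is not modelled.
* Retrofusion moves reporter from `I_dyn` to `L` at rate `k_retro`;
  the competent fraction of the intraluminal pool is `phi_dynamic`.
* Degradation and secretion act on the intraluminal pools only; the LM
  pool is consumed by cleavage, which dominates on the 6-h timescale.
  This attribution is configurable in spirit (see the fate bound below)
  but fixed in the ODE system.
* The system is solved with the matrix exponential of its 6×6 generator —
  exact for a linear system, so mass conservation holds to round-off and
  there is no step-size tuning. Independent cross-checks in the test suite
  use a hand-derived multi-exponential closed form and `solve_ivp` at
  tight tolerance.

Parameters, units, defaults: ρ (dimensionless, 2.0 — the immunogold
measurement); `phi_dynamic` (fraction, 0 unless stated); `k_cleave`,
`k_retro`, `k_sec` (per minute); `half_life_h` (hours, default 24 — the
pulse-chase bound "longer than 24 h" taken conservatively at 24;
`math.inf` disables degradation); fit window 90–360 min (the observed
near-linear phase after the equilibration transient, whose mechanistic
origin — protease reconstitution vs probe equilibration — we do not model;
it enters only as a window choice).

`predict_plateau` applies to the pure-cleavage limit (`k_deg = k_sec = 0`,
`k_cleave > 0`): the limit is `f_ilv` without retrofusion and
`f_ilv·(1−phi_dynamic)` with it. At ρ = 2 these are 66.7 % and below —
the basis of the 66–70 % no-retrofusion band.

Fitting (`fit_kinetics`) estimates `(k_cleave, k_retro, phi_dynamic)` with
ρ, half-life and `k_sec` fixed, by bounded trust-region least squares from
five seeded starts (one central, four log-uniform); ties are broken by
lower residual, then lower `k_retro`. Non-convergence is flagged on the
result, never silent. On noiseless model curves the generating parameters
are recovered to well under 1 %; at 1 % Gaussian noise `phi_dynamic` is
recovered within ±0.02 over 20 seeds (the test asserts the looser ±0.1).

## Segmentation

The batch re-implementation of the interactive quantification macro:

* EL from the far-red lysosome-probe channel, N from the red nuclear
  channel, PM from the GFP channel restricted to the region outside
  N and EL, CYTO as the remaining above-background cell area.
* EL and PM thresholds are set on the first and last frame and linearly
  interpolated between; N uses a single value (the nuclear marker is
  bright and stable).
* Thresholds are closed (`>=`) comparisons on (row, col) 0-based grids.
* Overlaps are resolved by the fixed precedence EL > N > PM > CYTO; the
  `CompartmentMasks` constructor hard-asserts pairwise disjointness.
* Thresholds are either explicit (reproducible batch mode) or Otsu on the
  first/last frames. For the PM channel the Otsu region is limited to
  in-cell pixels (above 5 % of the frame maximum, the same gate that
  defines "cell area" for CYTO); a flat region (surface pool fully
  cleaved) degrades to an empty PM mask instead of swallowing cytosol.
* No morphological post-processing by default, since the original
  procedure describes none; an optional minimum-object-size filter exists
  and warns when used.

The decay readout divides out all multiplicative gain: the EL median minus
the cytosol median, normalized to the first frame. Negative corrected
values under noise are kept (clipping would bias the tail) and logged.
Slope A is an OLS slope on the normalized trace against hours inside the
window — the paper-scale unit "normalized fraction per hour" had to be
fixed here since published slopes are only reported relative to control.
Replicates aggregate as mean ± SD; gold-count data as median ± IQR.
The fit is run on the median trace (the macro's own analysis path).

## Synthetic data: what it emulates, what it does not

The generator draws non-overlapping disc cells with a nucleus and punctate
endolysosomes (rejection sampling with a bounded retry budget; radii and
placements seeded), then renders each frame from the kinetic trajectory:
EL GFP = cytosolic background + gain × observable; nuclear GFP grows with
`N` plus a surface-derived term (the cell-surface pool is cleaved with the
same `k_cleave` and also carries the NLS); the PM rim carries that surface
pool; the red channel is constant in nuclei; the far-red channel is
constant per endolysosome with a mild global linear drift (default −10 %
over the movie — exercising threshold interpolation; the real probe's
drift is not documented, so this is a free knob). Defaults follow the
acquisition protocol: 512×512 field, one frame per 180 s, 120 frames ≈
6 h. Noise (Poisson shot noise, Gaussian read noise) is applied only after
ground truth is recorded; with the default flags the render is noiseless.

Deliberately absent: optical PSF and diffraction blur, 3-D structure,
organelle motility, bleaching by default, camera-specific noise
calibration. Passing round-trip tests therefore show the *arithmetic* of
the pipeline is faithful (masks, medians, background subtraction,
normalization, windowed slope), not that segmentation is robust to
real-microscope artefacts.

Side-table generators: pulse-chase bands with mature fraction
`2^(−t/half-life)` and a high-mannose band growing as its complement
(synthesis balancing degradation, so total signal is homeostatic);
immunogold counts as Poisson totals thinned binomially with
`p = ρ/(1+ρ)`; exosome blot replicates with mean-one lognormal noise
(the standard multiplicative densitometry model), constructed so the
per-replicate GFP/normalizer ratio is exactly unbiased for the specified
truth — independent numerator/denominator noise would carry a ~CV² ratio
bias that the generator should not smuggle in.

## Fate partition

* Half-life: `ln m(t)` regressed on time through the origin (normalization
  pins the intercept), unweighted; a non-decaying series returns an
  infinite-half-life flag, and a finite estimate whose rate CI touches
  zero is flagged censored ("at least this long"). Accepts two-point
  tables (the definitional case) although real series have more.
* Exosome share of the MVB pool: `exo_frac_wcl / mvb_frac` — scale
  invariant, 0.06/0.62 ≈ 9.7 %.
* Ratio changes are quoted as reductions (positive = decrease). Replicates
  with a zero normalizer band are dropped with a warning.
* Immunogold ratios: per-MVB `gold_ilv/gold_lm`; MVBs with zero LM
  particles are excluded from the median (the ratio is undefined) and
  counted separately.
* Retrofusion lower bound: intraluminal loss `f_ilv − remaining(6 h)`,
  minus the window's degradation `1 − 2^(−w/hl)` charged to the
  intraluminal pool, minus the exosome-secreted share of the MVB pool,
  all divided by `f_ilv` and clamped at 0. The attribution of degradation
  and secretion between LM and ILV pools is not uniquely fixed by the
  measurements; the two alternative conventions (degradation on the total
  pool; secretion referenced to the intraluminal pool) are selectable by
  keyword and bracket the default — at the study inputs (0.41, ρ=2, 24 h,
  0.06, 0.62, 6 h) the three conventions give 8.1 %, 0.1 % and 12.9 %.
  The bound is a floor in any convention: cleavage misses some re-exposed
  molecules.

## Numerical and design choices

* Degenerate inputs: all-zero frames segment to empty masks (Otsu on a
  constant image thresholds above it); empty compartments produce recorded
  zero-area rows with missing statistics, not crashes; an EL mask empty on
  more than half the frames aborts the CLI run with a data error.
* A control condition with numerically zero slope (|slope| < 1e-12/h)
  cannot normalize other conditions and raises.
* The curve container enforces `values[0] = 1` (to 1e-6) and strictly
  increasing times; the first value is set exactly to 1 after division.
* Problem sizes in the shipped drivers and tests (256×256 or 128×128
  fields, 2–3 cells, 60–121 frames, 10⁴ MVBs for gold counts) were chosen
  as the smallest sizes at which every estimator's sampling error is far
  inside the asserted tolerances.
* Seeds: every stochastic generator takes an explicit seed; the fitter's
  multi-start rng is seeded (default 0) so fits are reproducible.

## Known limitations

The model is deterministic and well mixed — no per-MVB heterogeneity, no
stochastic single-vesicle events, no pH or lipid mechanism; perturbations
(V-ATPase inhibition, lipid accumulation, IFITM3 expression) are
represented purely as reductions of `k_retro` and/or `phi_dynamic`.
Whether the LM pool is itself subject to degradation/secretion is not
settled by the data; we exclude it, and the exclusion matters only on
timescales where cleavage does not dominate. The 62 % MVB-residence and
6 % exosome-secretion figures enter as scalars; their upstream imaging and
blot pipelines are out of scope.
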