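# Methods

## Field conventions

Fields are symmetric rectangles shaped by a high-definition MLC (2.5 mm
leaf width at isocenter) and named Y × X in centimeters, X being the
leaf-motion (leaf-end) direction and Y the leaf-side direction.  The
working matrix is 7 × 7 sides (0.5, 1, 1.5, 2, 2.5, 3, 4 cm; 49 fields),
jaws fixed at 4.4 × 4.4 cm² so the MLC is always the collimating device
and jaw scatter to the monitor chamber is constant.  All outputs refer to
the isocenter point at 10 cm depth in water.  Lengths are isocenter-plane
centimeters for field sides and millimeters for profiles and spot sizes
(the conversion factor at module boundaries is exactly 10).

## Output factors (TRS-483 formalism)

`compute_fof` forms Ω = (M_clin / M_msr) · k with the 4 × 4 cm² MLC field
as the machine-specific reference (intermediate-field normalization).
The correction factor k is looked up by the equivalent square side:

* **Elongated-field formula** (default): ESF = 2·min^a·max^(2−a)/(A+B)
  with a = 1.12.  Symmetric in its arguments and equal to the side for
  square fields at any exponent.  The two-sided bound
  min ≤ ESF ≤ max holds at a = 1.12 for every aspect ratio above ~1:250;
  it provably fails for exponents near 2 on elongated pairs
  (ESF → 2·min²/(min+max) < min), so the bound is asserted only at the
  default exponent while symmetry and the upper bound are asserted over
  the full allowed range a ∈ [1, 2].
* **Sterling**: 2AB/(A+B), the a = 1 special case.
* **Equivalent area**: √(A·B), rejected outside the open aspect-ratio
  window (0.7, 1.4) when enforcement is on.

Either nominal or FWHM-measured sides may be fed in; `DosimetricSize`
records which.  Sides below 0.01 cm are rejected — they are beneath any
OCF table's domain and extrapolation there is meaningless.

OCF tables are user-supplied CSV (the published reference tables are
copyrighted; the repository ships only synthetic examples).  Entries more
than 5% from unity are filtered out before use.  Lookup is
piecewise-linear in field side: the tables are dense and smooth over this
range, the source material does not state its interpolation scheme, and
linear interpolation is reproducible bit-for-bit.  Queries below the
table domain raise (detector validity limits are domain limits, never
silently clamped); queries above it return 1.0 only when the table
explicitly ends at unity.

Difference grids default to the relative convention
100·(calc − meas)/meas; an absolute-points convention (100·(calc − meas))
is available and every report records which was used.  The printed
benchmark tables do not state their convention — at FOF ≈ 1 the two are
indistinguishable, and the packaged difference grids are used as printed,
so no conversion is ever applied to them.  Summary statistics use the
sample SD (n − 1); for the packaged grids sample and population SD round
to the same one-decimal value.  The reference cell (identically zero by
self-normalization) is included by default; `exclude_msr` exists because
the published 6FFF range minimum (0.1%) is only reproduced without it.
Display rounding is half-away-from-zero to one decimal; full precision is
kept internally.

## Profile metrics

Profiles are 1-D samples (strictly increasing positions, ≥ 8 points).
Normalization scales the maximum to 100% — matching the practice of
positioning the detector at the maximum reading — with a central-value
option for off-peak normalization.  The beam center is the midpoint of
the two 50% crossings, the dosimetric field size (FWHM) their distance,
and the 20–80% penumbra the per-shoulder distance between the 20% and
80% crossings located moving outward from the center; all crossings are
linearly interpolated between samples.  Non-monotone shoulders use the
crossing nearest the field edge with a warning.  No smoothing is applied
unless a median filter (window 3) is explicitly requested, and the choice
is logged.  For a Gaussian-blurred edge the 20–80% width is
(z₀.₈ − z₀.₂)·σ = 1.68324·σ, the closed form the extraction is tested
against.

## Synthetic forward engine

The engine emulates the mechanism that couples small-field output and
penumbra to the focal spot, not any particular commercial implementation.
Per scatter-kernel component k with per-axis effective sigma
s = √((p·ESS)² + σ_k²), the central dose of a W_x × W_y aperture is

    D = Σ_k w_k · erf(W_x / (2√2 s_x,k)) · erf(W_y / (2√2 s_y,k)),

with p the source-blur projection factor (SAD − d_c)/d_c, default
SAD = 1000 mm and d_c = 500 mm, hence p = 1.  Profiles are the separable
closed form (difference of Gaussian CDFs per component, the orthogonal
axis contributing its central factor), optionally averaged over a top-hat
detector footprint (15-point midpoint quadrature).  Simulated FOF grids
divide each field's central dose by the reference field's; the reference
cell is exactly 1.

Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| ESSx, ESSy | — | per-axis Gaussian source width, mm; 0–5 allowed, 0–1.5 swept |
| ESS interpretation | sigma | `fwhm` mode divides by 2·√(2 ln 2) ≈ 2.3548; a bare "Gaussian width" is ambiguous, so both readings are supported and recorded |
| kernel | (0.88, σ 1.5 mm), (0.12, σ 18 mm) | narrow primary + wide scatter; chosen so the 6X-like grid gives FOF ≈ 0.6–0.8 at 0.5 cm sides and output grows with field size, qualitatively matching the benchmark.  No quantitative fidelity to any commercial engine is claimed — parameter recovery and monotonicity, not value matching, are the engine's contract |
| noise | 1.8% / 0.9% (1 SD) | multiplicative Gaussian per cell: 1.8% when the smaller side is below 1 cm, 0.9% otherwise — the reported measurement uncertainty at those sizes.  Independent across cells, single seeded generator, reference cell untouched |
| sampling | 0.1 mm | profile sampling, deliberately finer than the 1 mm grid of clinical engines; an optional resampling can emulate that limitation |

The closed form is verified against an independent brute-force oracle
(area-weighted rasterized aperture, 2-D FFT convolution with the sampled
source Gaussian, integration against each sampled kernel component on a
0.05 mm grid); agreement is ~1e-5 relative, asserted at 1e-3.

A note on ordering: raw central doses at ESS = (0,0) strictly majorize
those at (1.5, 1.5), but FOF grids inherit this only up to ~1.5e-4,
because the reference dose also falls with ESS and slightly boosts the
ratios of ESS-insensitive cells.

`fit_kernel` adjusts isotropic component weights (softmax parametrized)
and sigmas (log parametrized) by least squares against a target grid;
under-parametrized fits converge to a reported positive residual.

### What the generator does and does not emulate

It reproduces: source-occlusion output loss, field-size-dependent scatter
buildup, per-axis penumbra sensitivity to the matching ESS, detector
volume averaging, and field-size-dependent multiplicative measurement
noise.  It omits: rounded-leaf-end transmission detail, tongue-and-groove
and interleaf leakage, off-axis spectral softening, depth dependence,
collimator-angle effects, and the 1 mm dose-grid quantization of clinical
engines.  Passing tests therefore demonstrate that the *procedures*
(formalism, metrics, optimization) behave correctly on data with the
right structure — not that any clinical engine is accurately modelled.

## Spot-size optimization

Candidates default to 0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.5 mm (finer
0.1 mm steps between 0.5 and 1 mm).  The sequential procedure starts at
the vendor suggestion (0.5, 0.7) mm, minimizes |calc − meas| at the
4 × 0.5 cm² cell over ESSx, then at the 0.5 × 4 cm² cell over ESSy.
"Smallest difference" is read as smallest absolute difference; the sign
structure (positive below the optimum — too little blur overestimates the
dose — negative above) is surfaced separately by `sign_diagnosis` rather
than folded into the objective.  Candidates within the tie tolerance
(0.02 percentage points) of the minimum are reported as an interval:
dose engines quantize the spot size internally, so adjacent candidates
can yield identical grids, and an objective-space tolerance detects such
plateaus without assuming bit-identical outputs.  The value carried into
step 2 is the tie-broken argmin (smallest objective, then smallest
candidate).  An exhaustive joint search (max-abs or sum-abs
scalarization) cross-checks the sequential result; a fully tied joint
objective is reported as degenerate with a warning.

The engine interface is abstract — the synthetic model, a directory of
per-ESS grids exported from a planning system, or transcribed sweep
tables — so the same optimizer runs against a clinic's own engine without
this package calling it.  Failed candidate evaluations (missing export,
engine error) are recorded as failed trace rows and skipped.

Noise sensitivity: the FOF of a 0.5 cm-sided field changes by roughly
1%/0.1 mm of the matching ESS near the optimum (both in the synthetic
engine and in the benchmark sweep tables), while a single measured grid
carries 1.8% noise on those cells.  One noisy grid therefore constrains
each spot size to about ±0.2 mm; with the default candidate spacing the
sequential procedure recovers a known pair within one candidate step in
every noiseless run but only ~60% of noisy single-grid runs.  Averaged
repeat measurements (the 3–5 repeats `ReadingSet` carries) are the
practical way to tighten this.

## Problem sizes and numerics

Tests use the full 7 × 7 grid throughout; recovery studies use 50 random
truths; the oracle comparison uses 20 random parameter sets on a 0.05 mm
grid; penumbra closed-form checks use σ ∈ {0.5, 1, 2, 3} mm at 0.05 mm
sampling.  Crossing interpolation is linear; ties in the optimizer break
deterministically; profile symmetry is exact by construction (symmetric
sample positions, even closed form).  Degenerate inputs (non-positive
sides, empty filtered OCF tables, all-failed sweeps) raise typed errors
listed per module.

## Known limitations

Off-axis and asymmetric fields, collimator rotation (and any spot
rotation with it), depth dependence, 2-D dose-plane analysis, and
uncertainty-budget propagation are out of scope.  The transcribed
benchmark covers 6X and 6FFF only; 10X/10FFF optimal-ESS intervals are
carried as metadata without their grids.  The equivalent-area validity
window and the 5% OCF rule are enforced as hard limits rather than
warnings by design.
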