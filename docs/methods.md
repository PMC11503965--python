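# Methods

## Model and procedure

The package designs sparse energy-sampling schemes for XAS /
spectro-microscopy from a prior library `A ∈ R^{m×n}` of spectra on a
common energy grid (m energies, n states: reference standards, previous
scans, background variants).

**Reduced basis.** `A = U Σ Vᵀ` (thin SVD, `numpy.linalg.svd`). Right
singular vectors are discarded; only the energy-side basis `U` is needed
for sampling design. By default the library is *not* mean-centered: the
library deliberately contains offset-like directions (the flat background
state), and a plain SVD keeps components interpretable as spectra.
Mean-centering (classical PCA) is available as an option; it removes one
direction, so the retained mode count drops by one. Each basis vector's
sign is fixed so its largest-magnitude entry is positive; without this
the SVD sign ambiguity would make greedy selection machine-dependent in
tie cases.

**Greedy point selection.** Standard DEIM: `p₁ = argmax|u₁|`, then for
each subsequent basis vector the residual against interpolation at the
already-chosen rows, `r = u_j − U_{j−1} (P^T U_{j−1})^{−1} P^T u_j`, and
`p_j = argmax|r|`. Ties break to the smallest index (determinism). The
residual vanishes exactly at chosen rows, so indices are distinct; a
repeat can only arise from a degenerate basis and raises an error naming
the step. The implementation solves the small `j×j` system each step; a
test oracle rebuilds the full projector `Π = U(PᵀU)^{−1}Pᵀ` from scratch
and must agree index-for-index.

**Coefficient solve and reconstruction.** With `s = k` samples,
`C = (PᵀU_k)^{−1} PᵀA` (interpolatory: the reconstruction equals the data
exactly at the sampled energies). With `s > k` — e.g. plans aggregated
from region-wise selection — the least-squares (gappy-POD) solution is
used. The condition number of `PᵀU_k` is monitored; above 1e12 a warning
is recorded rather than failing, since noisy real data may legitimately
be ill-conditioned and the user should decide.

**Regional oversampling.** `regional_deim` restricts the library rows to
each requested energy interval, computes a fresh local SVD there, runs
the greedy selection locally, and aggregates the union of the global
indices (first-selection order, duplicates dropped — so two regions with
7 points each may yield fewer than 14 unique energies). A fresh local
SVD, rather than slicing rows of the global basis, keeps each region's
basis orthonormal and well conditioned. Requested per-region ranks are
capped at the local numerical rank (1e-10 relative) so noise-floor modes
are never selected.

## Background augmentation

Additive drift is modelled by two anchored polynomial families, scaled to
each parent standard's edge step:

* pre-edge: the unique quadratic through `(pre_anchor, 0)` and two
  control points at uniform-random energies in the pre-edge window with
  uniform-random offsets in `± offset_range × edge_step`; applied over
  the **full** grid;
* post-edge: the unique cubic through `(post_anchor, 0)` and three such
  control points in the post-edge window; applied only at and above
  `post_anchor` (continuous by the anchoring).

Because each family is an anchored interpolating polynomial, the possible
pre curves span exactly a 2-dimensional space and the post curves a
3-dimensional one — additive augmentation therefore raises the library
rank by exactly 2 (pre only) or 5 (pre and post), independent of the
number of variants (≥ 2 resp. ≥ 3) and of the random seed. This is the
linear-algebra fact that ties the sampling budget to
"number of states + 2 (or 5)". A parametric-Bézier realization of the
same control points exists behind `mode="bezier"` for experimentation; it
is not exactly low-rank and is off by default.

Defaults (chosen as typical for a transition-metal K edge; the method is
insensitive to the exact values because only the *dimension* of the
family matters): `offset_range = 0.1` (10 % of the edge step),
pre anchor at the first grid energy, post anchor at edge + 10 eV, control
windows from the grid start to edge − 10 eV and from edge + 10 eV to the
grid end, 500 variants per standard.

## Truncation-rank selection

`select_rank` offers:

* `count` — the assumed number of chemical states / standards;
* `variance_threshold` — smallest k with cumulative explained-variance
  ratio ≥ τ;
* `elbow` — the sharpest bend (most negative second difference) of the
  log explained-variance curve. The log scale is deliberate: for an
  exact-rank-r library the ratios drop by many decades at r+1 and the
  bend is unambiguous, whereas curvature of the raw cumulative curve
  peaks at k = 1 for generic decaying spectra and does not find r;
* `auto` — every component above the numerical noise floor
  (σ > max(m, n)·eps·σ₁).

For background-augmented designs the pipeline's `auto` rank is the
states-plus-background rule: (number of independent directions of the
standards matrix at machine-precision tolerance) + (rank increase of the
augmented library at 1e-8 relative tolerance), both computed at run time.
The distinction matters because a deliberately tiny prior state — the
flat 1e-8 column representing a near-zero background — carries a variance
share of order 1e-17: no variance threshold can retain it, yet its
direction is still needed to interpolate near-empty pixels. For the
13-standard dictionary with full background augmentation this yields
k = 13 + 5 = 18 sampling energies.

## Synthetic data

`synthetic_spectra` emulates Fe K-edge-like XANES standards:
`step·(1/2 + arctan((E−E₀)/Γ)/π)` (edge jump, core-hole lifetime
broadening Γ ≈ 1–2 eV), Gaussian near-edge features (white line,
pre-edge peaks; centers within −8…+35 eV of the edge, amplitudes
0.05–0.35, widths 1.5–5 eV), and damped post-edge sinusoids (periods
20–60 eV, decay 30–120 eV) standing in for fine structure. Randomized
standards shift the edge by −3…+5 eV (chemical shift) and draw the edge
jump in 0.6–1.2. The default energy grid is piecewise, as scans are run
in practice: 10 eV pre-edge steps from −150 eV, 0.5 eV steps across
−20…+30 eV, then steps growing ×1.15 out to +250 eV (139 points).

Noise: "± x %" is read as a *bounded* uniform amplitude,
`Uniform(−x, +x) × edge_step`, matching the ± phrasing used for beamline
noise figures; a Gaussian alternative (`σ = x/2 × edge_step`) is provided
since the true noise law is instrument-dependent.

Phantom maps place pure or mixed phases in pixel regions
(`thickness × Σ wᵢ·standardᵢ`, optional per-pixel background draw and
noise) and store ground-truth labels and weights alongside the stack.

What the generator does **not** emulate: multiple-scattering physics
(no FEFF-style simulation — only the statistical structure the SVD/DEIM
machinery assumes), detector deadtime, energy-calibration drift between
scan and standards, spatially correlated noise, and partial-volume edge
pixels. Passing tests therefore demonstrate the correctness and noise
behaviour of the *sampling mathematics*, not robustness to every
instrumental artifact; conventional XAS normalisation is still required
downstream of any reconstruction (only an edge-step estimate is
provided).

## Kramers–Kronig transform

The absorption→dispersion transform
`out(Eᵢ) = (2/π) Σ_{j−i odd} E_j·in(E_j)/(E_j²−E_i²) · 2h` (Maclaurin
alternating-point rule on a uniform grid) is linear, deterministic, and
second-order accurate in h; the alternating pattern never evaluates the
pole. Finite windows are handled by removing the straight line through
the spectrum's two end values before transforming (so constants map to
exactly zero); the subtracted baseline's dispersive response is out of
scope, and outputs are defined up to that baseline and the kernel's
scale. Note the full kernel is not exactly antisymmetric about a feature:
an even line shape maps to an odd output only up to a relative
`~width/(2E₀)` contribution from the `1/(E′+E)` part — at a 7 keV edge
with a ±100 eV window, below one percent. Phase libraries are built by
transforming (optionally background-augmented) absorption columns, so
background variation enters before the transform.

## Numerical choices and degenerate inputs

* Duplicate energies in input files are rejected, not averaged (ambiguous
  intent); regridding is linear and refuses extrapolation so pre/post-edge
  tails are never fabricated.
* Plans serialize both zero-based indices and eV energies; on reload
  against a grid the energies are authoritative (matched to 1e-6 eV).
* k-means uses scikit-learn with `n_restarts` seeded initializations;
  cluster centers are recomputed as exact member means after the fit,
  which is the property downstream reconstruction relies on. The cluster
  count K is a user input with silhouette as an advisory diagnostic.
* Zero-norm truth columns in error metrics are flagged, not divided.
* All randomness flows through `numpy.random.default_rng` seeds; the CLI
  fans one global seed into fixed per-stage offsets.

## Problem sizes used in the test suite

Unit and property tests run on small seeded instances (20–80 grid points,
4–10 basis vectors). The end-to-end checks use the study-scale
configuration: a 139-point Fe-edge grid, 12 + 1 standards, 500 background
variants per standard (6500 columns), a 100×100-pixel three-phase
phantom, 200-trial noise/oversampling comparisons, and 1000-column
interpolation/recovery batches. The whole suite completes in a few
seconds on one CPU.

## Known limitations

* The states-plus-background rank rule assumes the standards matrix is
  numerically full column rank (true unless two standards are byte-equal).
* Regional aggregation can return fewer unique points than the sum of
  per-region requests; callers needing a fixed budget should check
  `plan.s`.
* The Kramers–Kronig output scale is relative, not absolute f′/δ units.
* Clustering on raw sampled vectors is thickness-sensitive; use
  `normalize=True` for strongly thickness-dominated maps.
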