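# Methods

`trxs` implements the inference chain that turns time-resolved difference
X-ray solution scattering plus pools of candidate conformers into (a) kinetic
components with half-times and (b) a bend/twist structural-change landscape.
This note documents the models, the choices behind them, and what the
synthetic-data tests do and do not demonstrate.

## Scattering model

Scattering curves are computed with the exact Debye equation for point
scatterers,

    I(q) = Σᵢ Σⱼ fᵢ fⱼ sin(q rᵢⱼ) / (q rᵢⱼ),

with the diagonal and q = 0 terms taken at the sinc limit, coordinates in nm
and q = 4π sin θ / λ in nm⁻¹ (PDB ångström are divided by 10 on ingest).
Three weight schemes are provided: `electrons` (per-atom electron counts),
`calpha` (one bead per residue at the Cα position, weight = total residue
electron count; the default, and the natural scheme when comparing thousands
of conformers), and `uniform`.

No excluded-volume or hydration-layer correction is applied. Difference
scattering between conformers of the *same* protein cancels most solvent
terms, and the pair scoring allows a free scale factor, so the omission
mainly affects absolute intensities, which the pipeline never interprets.
This is a known approximation: curves from this module should not be compared
with absolute-scale measurements of a single state.

For large models, `debye_scattering_binned` accumulates the pair distances
into a histogram (default bin width 0.01 nm) and evaluates the sinc kernel at
each bin's *weighted mean distance*, which cancels the first-order binning
error; for 0.01 nm bins the relative deviation from the exact sum stays below
10⁻³ for q ≤ 5 nm⁻¹, and it vanishes identically for a model with one pair
distance per bin.

## Pair fitting (scale-optimized SSE)

An experimental difference curve ΔS(q) is scored against every (Pfr, Pr)
conformer pair by

    SSE(pfr, pr) = min_k Σ_q ( ΔS(q) − k · (S_pfr(q) − S_pr(q)) )²,

summed over grid points in a scoring window (default 0.5–2.5 nm⁻¹, the range
reporting on large-scale domain motion; endpoints inclusive). The minimizing
scale has the closed form k = Σ ΔS·D / Σ D² with D = S_pfr − S_pr; k is
unconstrained in sign, since the minimization itself is unconstrained and the
scale physically absorbs photoactivation turnover. The sum is unweighted by
default (a 1/σ² variant exists but is off). Residuals are evaluated
explicitly rather than through the expanded quadratic form, which cancels
catastrophically near SSE = 0. Ties in the ranking are broken by index order
so scans are reproducible. The scan is exhaustive; a `max_pairs` option
subsamples the ensembles for quick demonstrations but never prunes a full
ranking.

### Identifiability: the k–magnitude valley

Because the curve response to small hinge rotations is locally linear, a pair
whose (Δbend, Δtwist) is c times the true change produces nearly the same
difference *shape*, with the mismatch absorbed by k ≈ 1/c. SSE therefore has
a soft valley along the ray c·(Δbend, Δtwist): the *direction* of the
structural change is strongly identified, its *magnitude* only through
second-order curvature. Consequences verified numerically:

* recovery of a planted pair sharpens with the number of q points in the
  scoring window (mismatch accumulates per point while noise averages as
  √n_q) — analyses here sample 201 points over 0.5–2.5 nm⁻¹, the bin density
  a hybrid-pixel detector delivers there;
* a landscape built from tightly clustered ensembles cannot distinguish the
  true bin from its valley neighbours at 2 % noise; broad candidate sampling
  (see below) separates competitors.

## Bend/twist coordinates and the landscape

Two scalar coordinates quantify the domain motion, measured on Cα markers
(defaults: chain A, residues 300/317/439 for the bend; 288/300/317/439 for
the dihedral):

* **bend** — interior angle at the hinge marker, arccos of the normalized dot
  product, clamped to [−1, 1]; range [0°, 180°];
* **dihedral (twist)** — signed torsion about the 300→317 axis between the
  reference plane (288, 300, 317) and the variable plane (300, 317, 439),
  atan2 form, IUPAC sign convention, range (−180°, 180°]. Angle *changes*
  (Pfr − Pr, signed) are wrapped to (−180°, 180°] to avoid 359° ≡ −1°
  artifacts.

Scanned pairs are binned by (Δbend, Δdihedral) on a 2° grid (resolving the
expected 5°/20° scale while keeping bins populated); each occupied bin is
summarized by the mean SSE of its lowest 10 % (ceil(0.1·n) members, so a
singleton bin reports its own SSE), and the landscape minimum is the
bin-center with the smallest statistic. The best-fraction statistic is
deliberately occupancy-normalizing, which also means sparsely and densely
populated bins are summarized with different averaging depths — landscapes
from very uneven sampling should be read with the per-bin counts alongside.

## Kinetic decomposition

A time series of difference curves is decomposed onto two fixed basis
patterns — by default the curve at the earliest microsecond delay and the
mean of the steady-state window (100 ms–2000 ms), both taken from the series
itself. "Matrix division" is implemented as ordinary per-time linear least
squares (equivalently the pseudo-inverse applied to the data matrix); a
rank-deficient basis is rejected with a condition-number diagnostic.
Amplitude traces are reported raw, not normalized at the defining times.

Half-times are fit directly in half-time parameterization,

    rise:  A·(1 − 2^(−t/t½)),    decay:  A·2^(−t/t½),

because half-times are the quantity of interest; initialization scans a
log-spaced t½ grid spanning the sampled time range with closed-form
amplitudes, then refines with Levenberg–Marquardt; standard errors come from
the Jacobian. Degenerate inputs (constant trace, < 4 points) are rejected.
The fast microsecond component is treated purely as a basis pattern and is
assigned no mechanism.

## Reduction

Detector images are ring-integrated with q = (4π/λ)·sin(θ/2) per pixel; each
ring reports the *mean* intensity (masked-pixel fractions cancel) at the mean
q of its contributing pixels. Curves are normalized to unit mean over
14–16 nm⁻¹, where water scattering dominates. Radiation-damage drift is
removed by subtracting the average of the flanking laser-off acquisitions
(exactly cancelling any linear drift); small- and wide-angle detectors are
merged by a least-squares scalar over their q overlap (evaluated on the finer
grid, spliced at the overlap midpoint); the solvent heating pattern is
removed by a least-squares coefficient over a fit window (default
1.0–2.0 nm⁻¹, where thermal-expansion signals dominate in aqueous SAXS; the
window is explicit and configurable). Polarization and solid-angle
corrections are omitted: they cancel in differences.

## Synthetic data: what it emulates

The generator builds a two-domain bead model at the scale of a ~55 kDa
photosensory module: a static 120-bead body, a 2.2 nm helical hinge segment,
and an 80-bead mobile domain 3.9 nm beyond the hinge. Marker beads are laid
out so the default angle selectors measure the planted coordinates *exactly*
(the twist is a rotation about the hinge axis; the bend then rotates in the
meridian plane of the twisted arm, leaving the torsion untouched). The
photoproduct family differs by a 5° bend and 20° twist by default, and the
geometry was chosen once so the Pfr−Pr difference curve carries its positive
feature near q ≈ 0.8 nm⁻¹ — the fingerprint of a tertiary-scale motion.

Families sample their two hinge coordinates with Gaussian jitter (default
3° sd, enough that members are distinguishable at the percent noise level;
landscape analyses use 6° sd so pairs span the full (Δbend, Δdihedral)
plane) or uniformly on ±w for broad, trajectory-like sweeps. Kinetic series
use a fast 20 µs decay and a slow 10 ms rise on 30 log-spaced delays from
1 µs to 2 s with Gaussian noise scaled to max |ΔS|. Every generator is
deterministic given its seed and returns a truth manifest sufficient to score
recovery.

What the bead models do **not** emulate: side chains, internal domain
flexibility, solvent and hydration-shell contrast, correlated MD-like
conformational modes, and experimental systematics (beam drift, detector
artifacts beyond a border mask). Passing recovery tests therefore
demonstrates the *inference machinery* — scoring, ranking, binning,
decomposition — under controlled truth, not the adequacy of bead models for
real proteins.

## Numerical choices and limitations

* q = 0 and coincident atoms are handled by the sinc limit, never division.
* Curves are never silently interpolated: grid mismatches raise.
* The pairwise scan is O(n_pr · n_pfr · n_q) with matrix-product assembly of
  the projections; the per-row residual pass bounds memory at one ensemble
  row of pairs.
* Landscape bins are right-open with the top edge inclusive, so boundary
  pairs are kept; empty bins carry NaN and are excluded from the minimum.
* Rigid-body invariance of the Debye sum and both angle operators holds to
  ~1e-12 relative and is enforced by tests.
* Problem sizes in the test-suite recovery studies (20×20 ensembles, 200-bead
  models, 201-point grids, 20–200 Monte-Carlo trials) are chosen as the
  smallest at which the statistical claims are stable; larger runs only
  sharpen the same margins.
* The magnitude of the structural change along the bend/twist ray is weakly
  identified at percent-level noise (see the valley analysis above); report
  landscape minima together with their valley extent when noise is high.
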