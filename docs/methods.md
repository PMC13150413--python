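# Methods

This note documents the estimators, conventions, and numerical choices
behind each analysis, what the synthetic fixtures emulate, and the known
limitations. Units are Å for distance, fs for time, and Å²/ps for diffusion
coefficients throughout; atom indices are 0-based.

## Trajectory model and periodic geometry

A trajectory is an ordered list of frames (N×3 Cartesian positions plus
element symbols) with a shared simulation cell — a 3×3 matrix whose rows are
the cell vectors — and per-axis periodicity flags. Individual frames may
carry their own cell (constant-pressure runs); all geometry then uses the
per-frame cell. Readers never wrap coordinates; analyses that need images
apply the minimum-image convention on demand.

**Minimum image.** Displacements are mapped to the nearest periodic image by
rounding fractional coordinates, which is exact for orthorhombic cells. For
skewed (triclinic) cells the rounded image is refined by an exhaustive
search over the 27 neighboring images; this is exact whenever the distances
of interest stay below half the smallest perpendicular cell height
h_i = V / |a_j × a_k|. Cutoffs beyond that bound draw a warning — the
nearest image is then not unique and counts can miss farther copies.

**Neighbor search.** Pair searches are dense distance-matrix scans (the
analyses here operate on selections of at most a few thousand atoms per
frame, where a cell list would not pay off). Distances exactly equal to a
cutoff count as inside (closed interval) everywhere.

## Error analysis of scalar observables

Two independent routes to the standard error of the mean of a correlated
series x₁…x_N with spacing Δt:

**ACF route.** The normalized ACF ρ(k) uses the biased (1/N) mean-removed
autocovariance, computed by FFT — the standard choice for integrated-time
estimation because it damps the noisy large-lag tail. The statistical
inefficiency is

    g = 1 + 2 Σ_{k=1}^{K} (1 − k/N) ρ(k),

with the triangular finite-sample correction, and the sum truncated at the
first lag where ρ < 0 (first-negative-crossing rule — a conservative
standard; an explicit max-lag override is exposed). Then SEM = s·√(g/N)
with s the sample standard deviation (ddof = 1), τ_int = g·Δt/2, and
N_eff = N/g. Sampling noise can push g marginally below 1; it is floored
at 1.

**Block route.** The series is cut into n_b contiguous equal blocks (tail
remainder dropped, keeping blocks equal length and the estimate unbiased);
SEM = std(block means, ddof=1)/√n_b. n_b may range up to N, where the
estimate reduces to s/√N exactly. A scan over log-spaced block counts
(default 4 … N/10, 14 points) locates the plateau automatically: walking
from the smallest block size upward, the first three consecutive SEM values
that agree pairwise within 10% win, and their median is reported; if no
such window exists, the largest-block SEM is returned and flagged. Blocks
must exceed the correlation time g·Δt for the block SEM to converge to the
ACF SEM — the plateau criterion encodes exactly that.

The AR(1) fixture x_{t+1} = φ·x_t + ε provides analytic ground truth:
ρ(k) = φᵏ and g = (1+φ)/(1−φ). At φ = 0.9, N = 10⁵ both routes recover
g = 19 within estimator noise; real MD observables are not exactly AR(1),
but the estimators make no such assumption.

## Diffusion from windowed MSD

Paths are first unwrapped: each frame-to-frame displacement is replaced by
its minimum image and cumulatively summed, which reconstructs the continuous
path exactly as long as no atom moves farther than half the smallest cell
height per stored frame (violations raise an error advising a smaller
frame_skip). The windowed MSD averages |r(t₀+τ) − r(t₀)|² over all time
origins (stride 1 by default — maximal averaging; overlapping origins are
correlated but unweighted, and a stride option exists for speed) and all
selected atoms.

The Einstein fit M ≈ 2·d·D·t + b runs over a lag interval (default: all
available lags) split into n contiguous equal sub-windows (default 5); each
sub-window gets an independent least-squares line, D is the mean of the
sub-window slopes over 2d, and sem_D their standard error. n = 1 reproduces
a single global fit bit-exactly, with sem reported as 0 and flagged
undefined. Because sub-windows share the underlying trajectory, their
estimates are positively correlated and the sub-window SEM understates the
full seed-to-seed error by roughly 2–3× on the Brownian fixture — it
quantifies fit-interval sensitivity, not total sampling error. Averaging
over independent trajectories (as the validation does) is the remedy.

Finite-size corrections toward the infinite-box limit are out of scope: the
reported D is the finite-box coefficient.

## Partial RDFs and coordination

For selections A and B, every frame's minimum-image A–B distances (self
pairs i = j excluded) are histogrammed on uniform bins (default width
0.05 Å — always an explicit parameter, never inferred) and normalized by
the ideal-gas expectation N_A·ρ_B·V_shell with the per-frame cell volume
(NPT-safe). When the selections share atoms, ρ_B uses N_B − 1 (an atom is
never its own neighbor); this makes index-subset selections share the same
normalization logic, so a random half of a uniform system still converges
to g = 1. g_AB ≡ g_BA holds bin-wise by construction.

**First minimum.** g(r) is smoothed with a 5-bin edge-corrected moving
average before extremum detection (raw bins are too noisy for a stable
argmin); the first local minimum after the first peak must lie at least 1%
of the peak height below it, rejecting flat plateaus. Monotone curves raise
a no-minimum error rather than fabricating a cutoff.

**Coordination numbers** count neighbors within a cutoff per center atom,
averaged over centers and frames. Three cutoff modes: fixed (user Å),
dynamic (first minimum of the centers–neighbors RDF, computed once per
trajectory — not per frame), and vdW (per element pair,
(r_A + r_B)·scale, radii from the shipped Bondi-style table, overridable
per element).

## Hydrogen-bond networks

Hydrogens are first assigned to their nearest donor-candidate within
1.2 Å (ties break to the lower donor index); a bond D–H···A exists when the
minimum-image H···A distance is ≤ 2.5 Å and the internal D–H···A angle
(180° = linear) is ≥ 130°, with A ≠ D. These defaults are a widely used
water criterion; all three cutoffs are mandatory CLI parameters, since no
single geometric definition is canonical. Bonds across periodic images are
found via minimum-image geometry.

Network statistics identify molecules with their heavy atoms (union of the
donor and acceptor selections) and build a per-frame graph with bonds as
edges. The headline per-molecule average counts each bond for both partner
molecules (donated + accepted — the convention under which bulk water
averages ≈3.8); a donated-only mode halves it. The spread across frames is
reported as a standard deviation, and connected-component counts describe
network fragmentation (isolated molecules count as their own components).

## Cluster dynamics

DBSCAN runs per frame on the minimum-image distance matrix of the selected
atoms (scikit-learn, precomputed metric), so clumps straddling a periodic
boundary cluster identically to their centered translates. min_samples
counts the point itself (standard inclusive convention). Cluster ids are
canonicalized by ascending minimal member index, making labels
deterministic and permutation-equivariant.

Outliers (points in no cluster) are handled both ways, always: the headline
average cluster size excludes them — an isolated atom is not a cluster —
while the inclusive variant counts each outlier as a size-1 cluster. A
split like {4 atoms + 1 stray} therefore reports 4.0 (exclusive) and 2.5
(inclusive). Frames whose cluster count exceeds the modal count over the
trajectory are flagged as fragmentation events.

## Diversity subsampling (FPS)

Farthest-point sampling greedily selects the structure maximizing the
minimal descriptor-space distance to the already-selected set (Euclidean;
exact ties break to the lowest index, so the ordering is deterministic with
no seed). The recorded max-min distance at each pick is non-increasing (the
covering radius of the selected set); the diversity curve normalizes it to
the first recorded distance and reports the smallest k at or below 5% of
it — the point past which additional structures are nearly redundant.

The built-in descriptor is the per-structure histogram of all raw pair
distances, normalized per pair: exactly invariant under rigid translation,
rotation, and atom permutation, and computable offline. It ignores element
identity and three-body geometry; richer descriptors (e.g.
smooth-overlap-of-atomic-positions vectors) plug in through the same
matrix contract, with their hyperparameters as explicit configuration. The
default start index is 0; a random start would make the ranking
seed-dependent for no benefit in practice.

## Volumetric density

Selected atoms are wrapped by fractional coordinate into half-open [0,1)
voxels (an atom exactly on a boundary lands in the higher-index voxel) and
accumulated over frames; density = counts/(n_samples·V_voxel) integrates to
1 over the cell to machine precision. Plane projections sum over the
orthogonal axis weighted by the voxel extent, giving 2D densities that
equal the 3D marginals exactly and integrate to 1 over their plane. No
smoothing is applied by default; the default grid is 50³. Non-periodic
structures use the axis-aligned bounding box of the selection over the
whole trajectory. Output formats are long-form CSV and Gaussian cube.

## Parallel contract

Every trajectory analysis is a map over frame indices followed by an
order-preserving reduction, executed through joblib's thread backend
(per-frame work is numpy-dominated, so threads parallelize without
serializing trajectories). Outputs are bit-identical for any worker count,
including 1 — asserted by the test suite on CSV bytes.

## What the fixtures do and do not show

The generators produce inputs with *known* answers: AR(1) series (exact g),
Brownian walkers (exact D, and raw paths kept so wrap/unwrap is checkable
to 10⁻⁹ Å), simple-cubic lattices (exact first shell of 6), water
dimers/chains with exact H-bond geometry by construction, Gaussian clumps
with known memberships, and uniform ideal gases (g(r) ≡ 1, flat density).
Validation against them establishes that the estimators and conventions are
implemented correctly at realistic problem sizes (e.g. 256 walkers × 2000
frames, 500-atom boxes, 64-molecule water).

They deliberately do not emulate physical water or zeolite dynamics: no
force field, no vibrations, no realistic H-bond lifetimes. Passing tests
therefore certify the *analysis machinery*, not any claim about a specific
physical system; applying the toolkit to real AIMD/NNP trajectories is the
intended use but requires those trajectories.

## Known limitations

* Dense O(N_A·N_B) distance matrices per frame: fine up to a few thousand
  selected atoms, no cell-list acceleration for very large selections.
* Binary trajectory formats (DCD/XTC/TRR) are not read; extended XYZ and
  plain XYZ only.
* The sub-window diffusion SEM understates total sampling error (see
  above); treat it as a lower bound.
* The dynamic coordination cutoff is computed once per trajectory, not per
  frame.
* Element-blind built-in descriptor for FPS; species-aware descriptors must
  come from an external backend.
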