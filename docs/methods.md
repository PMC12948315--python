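# Methods

## Model and assumptions

The network is a Hopfield-type binary model with synchronous updates and
asymmetric weights. Each region contributes one excitatory (E) and one
inhibitory (I) threshold unit; only E units project between regions,
through a directed, non-negative connectivity matrix stored with the
convention row = target, column = source (the recurrent input to region
`i` is `W[i, :] @ A_E`). One update step equals one fMRI repetition time
(TR = 1.2 s), so all sub-second neural dynamics is deliberately out of
scope. Ties at the firing threshold fire: the Heaviside activation assigns
1 at exactly zero input. Noise is i.i.d. Gaussian with a single SD σ for
both E and I populations, drawn in population-major order per step from one
named generator per simulation, so replays with the same seed are
bit-identical.

The simulated fMRI signal is the total synaptic input current to each E
population (no noise term); the rationale is that BOLD tracks synaptic
activity more closely than spiking. A 6-lag synaptic-to-BOLD kernel
(values `[0.116, 0.461, 0.572, 0.212, 0.067, 0.008]`, gain 1.436, peak at
lag 3) is available for convolved-BOLD analyses; the static FC of
convolved and unconvolved signals agrees to r ≈ 0.97 on the study
configuration, which is why the unconvolved signal is the default.

The linear variant replaces the Heaviside activation by the identity
without clipping; attractor analysis is restricted to the binary variant,
whose finite state space (2^(2N) states) guarantees that every noise-free
trajectory becomes eventually periodic.

## Attractor machinery

Noise-free descent iterates the deterministic map, hashes visited states,
and extracts the cycle between the first revisit. Cycles are stored in
canonical rotation (lexicographically minimal concatenated bit-string), so
attractor identity is bit-exact cycle equality and needs no tolerance. A
shared cache with path compression amortizes repeated basin look-ups.

Detection runs noisy restarts: a uniform random initial state, a
stochastic transient (default 100 steps, enough for the network statistics
to become stationary), then descent. The stationary repertoire saturates
quickly; the oscillatory repertoire is typically recovered only partially,
so oscillatory counts are always reported together with the number of
restarts. On networks of up to ~10 binary units the package instead
enumerates every initial state exactly.

Basin occupancy and the per-basin fMRI templates are estimated from long
noisy runs: every visited state is assigned to its basin by memoized
descent, occupancy is the fraction of frames per basin, and the template
is the basin-mean of the per-region z-scored synaptic signal (z-scored
over all pooled frames). Individual oscillation basins have vanishing
occupancy, so for mapping they are collapsed into a single macroscopic
basin (a flag, off when counting attractors). Occupancy can alternatively
be read from the detection restarts (`restart_hits`); both estimates are
exposed because they answer slightly different questions (stationary
measure of the chain vs basin volume under the restart distribution).
Basins never visited during template estimation have undefined (NaN)
templates and are excluded from classification rather than silently
treated as zero vectors.

Homotopicity: a state is mirrored by permuting E entries (and I entries)
with the hemisphere mirror map; an attractor is homotopic when its
mirrored cycle equals itself up to rotation (a phase shift between the two
hemispheres' mirrored cycles is accepted). On a mirror-symmetric
connectome the update map commutes with mirroring, so the attractor set is
closed under it; an unpaired non-homotopic attractor therefore signals
incomplete detection and triggers a warning, not an error. The
inter-hemispheric Hamming distance (mean mismatch fraction between
homologous E units) measures non-homotopicity without computing attractors.

## Mapping, CAPs, statistics

The attractor mapping algorithm z-scores the input series per region
(population SD; zero-variance regions get z = 0 and are flagged), labels
every frame with the Euclidean-nearest basin template (ties break to the
lowest index), and reports label frequencies (reconstructed occupancy) and
per-label mean z-scored frames (reconstructed topography). Multi-subject
recordings are z-scored and labeled per subject, then pooled — the
per-subject z-score makes the labels invariant to any per-region affine
rescaling of each subject's data. Enforced-homotopicity analyses pool each
mirror pair of basins into one, with occupancy-weighted mean templates.

CAPs are extracted by k-means under the correlation distance
d(x, y) = 1 − Pearson(x, y): k-means++ seeding, Lloyd iterations with
mean centroids, empty clusters re-seeded from the farthest frame, best of
`replicates` restarts by total within-cluster distance. Defaults (k = 6,
15 replicates, 500 iterations) follow the standard rodent CAP pipeline;
frames are z-scored per region before clustering, and zero-variance frames
are excluded with a warning. CAP↔attractor correspondence uses the joint
per-frame labels: each CAP is reconstructed as the basin-topography
mixture weighted by P(basin | CAP), a convex combination by construction.
Anti-CAP pairing reports the most negatively correlated centroid pairs.

First-order statistic: regional time averages, centered on the
across-region mean and normalized by the maximum absolute value (entries
in [−1, 1]). Second-order: Pearson FC over the whole series, averaged
entrywise across subjects or repetitions (plain averaging by default, a
Fisher-z option exists). Global signal regression removes the
across-region mean series from every region by OLS with intercept, leaving
residuals exactly orthogonal to the global signal. Distribution overlaps
histogram both samples on 30 equi-spaced bins over the joint range and sum
the bin-wise minima. Matrix similarities vectorize the upper triangle for
symmetric comparisons and all entries for asymmetric blocks; the partial
correlation controlling for anatomy residualizes both FC vectors on the
vectorized anatomical matrix (a zero residual — FC exactly explained by
anatomy — yields partial r = 0). Community detection delegates to
igraph's leading-eigenvector method on the thresholded FC graph, since the
algorithm is standard.

## Fitting

The loss is the equally weighted sum of mean squared errors of the two
target statistics (FC term over the off-diagonal upper triangle), with
model statistics averaged over `n_reps` seeded 450-frame simulations.
Degenerate output (constant signals, undefined statistics) maps to a large
finite penalty (1e6) so the optimizer can leave dead regions. All loss
evaluations within one fit reuse the same seed (common random numbers) —
without this, a stochastic loss makes "descent" ill-defined.

Phase 1 is a coarse grid search over scalar parameters with J_EI uniform
across regions; the grid is traversed in insertion order and ties break to
the first point. Phase 2 is steepest descent: every free parameter
(scalars plus, by default, each per-region J_EI entry) is probed one
finite-difference step in both directions and the single best improving
move is accepted; when nothing improves, all steps are halved, and the
search stops at `max_iter` accepted moves or when steps fall below a
quarter of their initial size. Sign constraints (J_EI ≤ 0, J_IE ≥ 0,
J_II ≤ 0, g ≥ 0, σ ≥ 0) are enforced by clipping. Grid ranges, step sizes
and simulation budgets are caller-supplied with documented defaults.

## Synthetic study conditions

The generator emulates the structural features that drive the model's
dynamics: directed, non-negative, mirror-symmetric weights (left
hemisphere blocks drawn, right blocks reflected, so
`W[i,j] == W[mirror(i),mirror(j)]` holds exactly), log-normal weight
magnitudes normalized to unit maximum (heavy tail: a strong-connection
backbone over many weak links, giving a meaningful sparsification sweep),
intra-/inter-hemispheric densities 0.6/0.3, inter-hemispheric strength
0.6, and a ×2 boost of the diagonal self-loops reflecting dominant
intra-regional connectivity. It does not emulate atlas geometry, distance-
dependent wiring, or realistic fMRI noise spectra — so passing tests show
the pipeline's internal consistency on model-generated data, not fidelity
to any particular animal.

The fitted-like parameter defaults place the network in the coexistence
regime: `v_thr = 0.35`; `g = 3.6·v_thr / mean row sum` (so the mean fully
active input is 3.6 thresholds and many regions sit near criticality);
`j_ie = 0.5 ≥ v_thr` (an active E recruits its interneuron) with
`j_ie + j_ii = 0.4 ≥ v_thr` (the recruited pair can persist);
`j_ei = −0.3`, putting regions whose recurrent input falls in
`[v_thr, v_thr + 0.3)` into E–I limit cycles while stronger-driven regions
freeze; and `σ = 0.18 ≈ v_thr/2`, large enough to drive transitions
between basins every few tens of frames. The reference realization
(generator seed 16, 10 regions) exhibits 14 stationary attractors — 4
homotopic, 10 in five spatially opposed mirror pairs — plus oscillations,
with occupancy spread over a dozen basins: the qualitative structure the
analyses need. These defaults are study conditions, chosen once; they are
not tuning knobs.

Default recording dimensions are 15 subjects × 450 frames (a 9-minute
session at TR = 1.2 s).

## Problem sizes and numerical choices

Exhaustive oracle analyses use 4-region (8-unit, 256-state) networks,
where orbit enumeration and the exact stationary distribution of the full
noisy Markov chain (unit k fires independently with probability
Φ((V_k − V_thr)/σ)) are both computable; simulated occupancy at 10^5 steps
matches the exact chain with overlap ≥ 0.95. Study-scale analyses use the
10-region reference network with 3000 detection restarts and 10^5-frame
occupancy runs — sizes at which every reported quantity is stable to the
third digit across seeds while the full pipeline completes in seconds.

Tolerances: occupancy distributions are validated to 1e-8 before overlap
computations; z-scoring treats SDs below 1e-12·(1+|mean|) as zero;
attractor comparisons are bit-exact. Tie-breaks are deterministic
throughout (lowest index wins).

## Known limitations

Oscillatory attractor counts are lower bounds (partial reconstruction by
design). The steepest-descent refinement is a local method on a seeded
stochastic loss: it inherits the grid winner's basin and the common random
numbers' sampling floor. The synthetic generator produces regimes whose
attractor richness varies across realizations; analyses that need a rich
repertoire should use the reference realization or check richness first.
Mapping assumes the data's region space matches the model's; no soft or
temporally smoothed assignment is provided.
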