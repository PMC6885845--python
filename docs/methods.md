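# Methods

## Problem and model

The package partitions weighted, undirected networks — typically
resting-state fMRI connectomes whose vertices are regions of interest
(ROIs) and whose edge weights are correlation strengths in [0, 1] —
into community modules by maximizing Newman's weighted modularity

    Q = (1/2m) Σ_ij [ a_ij − k_i k_j / 2m ] δ(c_i, c_j),

summed over all ordered vertex pairs (the diagonal is zero after
preprocessing, so i = j contributes only the null-model term). Q lies
in [−1, 1); a partition with all vertices in one community scores
exactly 0. The complementary score is the mean cluster conductance
φ(C) = cut(C)/min(vol(C), vol(C̄)), averaged over nonempty clusters,
with two conventions for degenerate cases: a zero-volume cluster
contributes 0, and a single-cluster partition scores 0 (its complement
is empty, making the cut 0/0). Both conventions keep the score in
[0, 1] and are exercised by tests. The conductance average runs over
all nonempty clusters rather than any "number of cuts minus one"
normalization; the former is the operational formula, and the two
differ only by a constant factor at fixed cluster count. All edge
accounting is weighted throughout — conductance uses edge weights, not
edge counts, consistently with modularity.

## Preprocessing

Raw connectivity matrices store Fisher z-transformed correlations. The
chain applied before optimization is:

1. optional reverse z-transform x′ = tanh(x), mapping into (−1, 1);
2. clamp negatives to 0 (negative correlations carry no community
   weight);
3. zero the diagonal — the input's self-correlation convention is
   unspecified in practice, and modularity's degree accounting assumes
   no self-loops;
4. symmetrize by averaging, rejecting inputs whose asymmetry exceeds
   1e-6 (beyond numerical noise the matrix is not a correlation matrix);
5. threshold: entries strictly below θ become 0 (the boundary value is
   kept), default θ = 0.2.

A result with zero total weight is rejected as an empty graph. Matrix
files may be comma-, tab- or whitespace-delimited (detected in that
order of precedence) with an optional header row plus label column; all
vertex and community indices in files and APIs are 0-based.

## Uniform design

The good-lattice-point array U(n, q), q prime, has entries
U[l1, l2] = (l1·σ^(l2−1) mod q) + 1 with σ taken from the standard
table for q ∈ {5, 7, 11, 13, 17, 19, 23, 29, 31}. Because q is prime,
multiplication by any unit is a bijection mod q, so every column is a
permutation of {1..q} for *any* exponent — which justifies the two
extensions the optimizer needs: σ is looked up with the factor count
clamped into the tabulated range (particle dimension d = K·N routinely
exceeds 30), and the array is extended to arbitrary n. Powers are
computed by modular exponentiation so large d never overflows.

Initialization bisects the search box [0,1]^d into S sub-boxes along
the first log2(S) coordinates (cycling when d < log2 S; S must be a
power of two), maps the q0 levels affinely onto each sub-box so levels
1 and Q0 hit opposite faces, scores all S·Q0 candidates, and keeps the
best N_pop. The crossover of two parents quantizes each coordinate
interval [min, max] into Q1 ascending equal steps and selects the Q1
offspring indexed by U(d, Q1); both operators are fully deterministic.
The ascending-level convention makes the interior levels consistent
with the endpoint levels (level 1 = min, level Q1 = max), so offspring
are contained in the parents' box by construction.

## The optimizer

A particle position is the concatenation of K centroids in [0,1]^N.
Decoding assigns vertex i to the centroid closest (Euclidean distance)
to its adjacency row a_i, ties to the lowest community index; the
distance is between full rows and centroids, the only reading
dimensionally consistent with centroid regulation, which averages
member rows. Empty communities are allowed; the effective (nonempty)
count is what gets reported, letting the K sweep self-prune.

Per fixed-K run: seeded initialization (uniform-design or random for
the ablation), centroid regulation, then iterations of linear inertia
ω(t) = w_max − t(w_max − w_min)/t_max, the three-attractor velocity
update with fresh uniform r1, r2, r3 drawn per particle per update
(a `vector_r` switch draws them per dimension instead), fitness and
regulation, personal/global best updates, and (full algorithm only) the
uniform-design crossover of every particle with its personal best and
the global best. All acceptance comparisons are strict (>): an
equal-fitness candidate never replaces the incumbent, which is what
makes the global-best trace nondecreasing and the stall test
well-defined. When crossover improves on the personal best it
overwrites both the current position and the personal best. Velocities
are clamped to [−1, 1] and positions to [0, 1]; edge weights live in
[0, 1], so centroids must too. Velocities are initialized equal to
positions.

Termination: t > t_max, or the global best unchanged (|ΔQ| ≤ 1e-12)
for ⌈stall_fraction · t_max⌉ consecutive iterations.

Defaults (the reference operating point for 264-ROI connectomes):
N_pop = 100, t_max = 100, w ∈ [0.1, 1.0], c1 = c2 = c3 = 2, S = 4,
Q0 = 31 (S·Q0 = 124 ≥ N_pop), Q1 = 5 (10 crossover evaluations per
particle per iteration), stall_fraction = 0.3, θ = 0.2. The K sweep
defaults to k_min = 1 .. k_max = min(N, 20) for tractability — the
full sweep to N costs O(t_max·N_pop·N) and remains available by
setting k_max = N. On ties across K the smallest K is kept.

Determinism: every stochastic component draws from a generator seeded
by `random_state`/`seed`; per-K runs use seeds spawned from it, so a
fixed seed reproduces results bit-for-bit. The batched fitness path
used inside the loop is the community-aggregated form of Q,
algebraically identical to the pairwise definition (asserted to 1e-12
in tests).

## Synthetic benchmarks

The generator plants block structure in a correlation-like matrix:
within-block entries ~ N(w_in_mean, w_in_sd) and between-block entries
~ N(w_out_mean, w_out_sd), clipped to [0, 1], symmetric, zero diagonal.
Gaussian-clipped weights were chosen over Beta draws for transparency;
with the default strong contrast (0.7/0.05 within, 0.1/0.05 between)
the clipping bias is negligible and thresholding at θ = 0.2 removes
almost every between-block edge, mirroring what preprocessing is meant
to do on real connectomes. The optional forward Fisher z encoding caps
entries at 0.999 (z of exactly 1 is infinite) so the preprocessing
chain can be round-trip tested to 1e-9.

What the generator does *not* emulate: heavy-tailed degree
heterogeneity, spatially autocorrelated noise, negative-correlation
blocks, or overlapping modules. Passing the recovery tests therefore
demonstrates correctness of the optimizer on well-separated block
structure, not performance on empirical connectomes.

## Validation problem sizes

The validation suite uses sizes chosen to make ground truth computable
exactly: oracle-equivalence runs on 6–7-vertex random weighted graphs
(all ≤ 877 set partitions enumerable) with N_pop = 50, t_max = 50 and
the K sweep to N; planted recovery on 36-node three-block graphs with
N_pop = 40, t_max = 60, K swept 2..6, Q0 = 11, S = 4; the ablation on
ten 24-node three-block graphs at weaker contrast (0.6/0.1 within,
0.2/0.1 between) with five seeds per graph at fixed K = 3. With strong
block contrast both variants usually reach the same optimum (ties);
the ablation test asserts the uniform design never hurts on average,
the qualitative property that motivates the hybrid.

## Known limitations

- The centroid encoding scales the particle dimension as K·N; very
  large networks or K sweeps to N are slow by design (the cost is
  O(t_max·N_pop·N) fitness evaluations, each O(N²)).
- The subspace scheme for initialization (recursive bisection) is a
  documented design choice; other space-filling decompositions are
  plausible and not implemented.
- Modularity's resolution limit applies: very small modules in large
  dense networks may be absorbed regardless of optimizer quality.
- Overlapping communities and negative-weight (signed) networks are out
  of scope.
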