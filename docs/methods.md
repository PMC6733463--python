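# Methods

## Model and state space

A state is a length-N binary vector; channel i maps to bit i of an
integer code (bit 0 least significant), so the 2^N states are enumerable
as codes 0 … 2^N − 1. The pairwise maximum-entropy model assigns energy

    E(V) = − Σ_i H_i σ_i − Σ_{i<j} J_ij σ_i σ_j

(each pair counted once; J symmetric with zero diagonal) and probability
p(V) ∝ exp(−E(V)). All expectations are exact sums over the enumerated
state space; operations that require enumeration refuse N > 20. There is
deliberately no pseudo-likelihood or mean-field fallback for larger N —
exactness is the point of the package — and no temporal model: samples
are treated as exchangeable draws from the equilibrium distribution,
which is an approximation for autocorrelated recordings.

## Fitting

`fit_pairwise_mem` performs coordinate-free gradient ascent in the
log-ratio parameterization: at each iteration the model moments are
recomputed by full enumeration and

    H_i  += a_g · log(⟨σ_i⟩ / ⟨σ_i⟩_m),
    J_ij += a_g · log(⟨σ_i σ_j⟩ / ⟨σ_i σ_j⟩_m).

Defaults: a_g = 0.1; convergence when the largest absolute log-ratio (the
update "gradient") is below tol = 10⁻⁵; cap of 5·10⁵ iterations, after
which non-convergence is flagged in the result rather than raised.
Initialization is the independent solution — H at the logit of the first
moments, J = 0 — so a dataset with no pairwise structure converges in one
check. Target moments exactly 0 or 1 make the log-ratio updates diverge;
they are clipped to [ε, 1−ε] with ε = 1/(2T) when the sample size T is
known (empirical moments carry it), and otherwise raise a
degenerate-moment error. The convergence tolerance bounds moment
mismatch, not parameter error; recovery tests that assert parameter error
< 10⁻³ run the fit at tol = 10⁻⁷.

Fit quality: D_k is the KL divergence (natural log, 0·log 0 = 0) of the
empirical distribution from the order-k model, S_k the model entropy, S_N
the empirical entropy. r_D = (D₁−D₂)/D₁, r_S = (S₁−S₂)/(S₁−S_N). These
ratios are base-invariant, so the log base is irrelevant to every
reported metric. The reliability is implemented as ER = r_S / r_D, with
an `er_mode="product"` option; both variants equal 1 under error-free
estimation, which is the property the metric is used for. D₁ = 0 or
S₁ = S_N raise an undefined-ratio error rather than returning NaN.

## Landscape

Neighborhood is exactly Hamming distance 1. A local minimum must be
*strictly* below all N neighbors; a state tied with a neighbor is not a
minimum, and any exact neighbor tie triggers a warning because downstream
tie-breaking then depends on code order. Minima are labeled LM1, LM2, …
in ascending energy (ties by smaller code); the global minimum is LM1.

Pair thresholds E_th (bottleneck energies) are computed by an
energy-ascending filtration: states are inserted in increasing energy
(ties by code) and union-found with already-inserted neighbors; two
minima connect exactly at the energy of the state whose insertion merges
their components. This is equivalent to iteratively extracting a shortest
path, thresholding at its maximum energy, deleting strictly-higher states
and repeating until disconnection — that literal loop is kept as a test
oracle (`pair_threshold_oracle`), with one addition needed for
termination: when strict deletion removes nothing, the non-endpoint
states attaining the threshold are deleted instead. The two algorithms
are asserted to agree exactly on randomized systems.

Barriers: pairwise E_B = E_th − max(E_i, E_j); directed
E_B(i→j) = E_th − E_i (used for rates). The disconnectivity tree is the
single-linkage merge structure of minima under rising E_th; because
bottleneck distances are ultrametric, the tree-implied merge heights
reproduce the threshold matrix exactly, which is tested. Newick export
places leaves at their own energies.

## Pathways and networks

For each minima pair the pathway is oriented from the higher-energy
minimum (exact energy ties orient toward the smaller code, i.e. toward
the earlier-ranked minimum, so tied pairs still flow toward the global
minimum). Within the subspace of states with E ≤ E_th the fewest-step
path is extracted; remaining ties are broken by the lexicographically
smallest code sequence, making extraction fully deterministic. The
rate-determining transition state is the first state along the path
attaining E_th (the tied state nearest the source). The transition rate
is exp(−E_B) with E_B referenced to the pathway's source.

STN-FS stamps each pathway's single rate on all of its step edges; when
two pathways share a step edge the larger rate is kept and a multiplicity
counter incremented (deduplication is otherwise unspecified). STN-GM
keeps the m−1 pathways whose target is the global minimum. STN-LM has
minima and distinct transition states as nodes with inward (source→TS)
and outward (TS→target) edges; a defensive branch handles a TS coinciding
with an endpoint, though for strict minima the path maximum always lies
strictly between the endpoints. Node degree is reported on the collapsed
undirected simple graph; the hub flag (degree > mean + 2 SD) is reported,
never asserted. `remove_state_and_reroute` deletes exactly one code per
call and recomputes all pairs, flagging disconnected ones; multi-removal
composes via the `excluded` argument. Removal can only shrink the path
set, so thresholds never decrease — an asserted invariant.

## Clustering and statistics

UPGMA (average linkage) runs on Euclidean distances between the minima's
feature vectors — rows of the barrier matrix (`mode="barrier"`) or of the
rate matrix exp(−E_B) with zero self-entries (`mode="rate"`); a
`feature_vectors=False` flag uses the pairwise values directly as
dissimilarities instead. The default cut is two groups. Note that
Euclidean feature distances are not invariant under the monotone
barrier→rate transform, so the two modes can partition differently:
barrier mode follows the community structure, rate mode is more sensitive
to minima depth. Complementary-pair separation is therefore asserted for
barrier mode. Pearson correlations use the two-sided t-test with n−2
degrees of freedom; constant inputs or n < 3 are errors. The coupling
sweep scales J ← αJ over a default grid α = 0.0, 0.1, …, 5.0 and records
minima counts plus STN-FS summaries where at least two minima survive.

## Synthetic data

The generator emulates the data regime the analysis assumes: N ≈ 8–19
binary channels whose marginals sit near 0.5 (the consequence of
binarizing globally-regressed signals at zero), mostly positive couplings
with a two-community organization, and landscapes containing mutually
complementary attractor pairs.

Two design choices matter and were made on structural grounds:

- **Field centering** (`center_h=True`): fields are drawn as
  H_i = −½ Σ_j J_ij + Normal(0, h_scale). In 0/1 coding this is the
  complement-symmetric point (zero field in ±1 spin coordinates); at
  h_scale = 0 the landscape is exactly invariant under global bit flips,
  so minima come in complementary pairs, and small h_scale perturbs
  rather than destroys that symmetry. Uncentered fields (available via
  `center_h=False`) generically break complementarity.
- **Coupling sparsity** (`j_density=0.5`): a *dense* two-community system
  (positive within, negative between) is gauge-equivalent to an
  unfrustrated ferromagnet and has exactly two minima — one complementary
  pair — regardless of scale. Sparse heterogeneous couplings, like those
  of fitted interaction matrices, support additional metastable domain
  states and hence several complementary pairs.

Default scales h_scale = 0.05, j_scale = 0.6 put typical |J| near 0.5
with field noise an order of magnitude smaller, giving 4–8 minima at
N = 8 with at least two complementary pairs in most seeds, an inverted-U
of minima count under coupling scaling (single minimum at small α,
community pair at large α), and two-group barrier clusterings separating
complements — the phenomenology the acceptance suite checks over five
seeds with a majority criterion.

Samplers: `sample_exact` draws i.i.d. states by inverse CDF over the
enumerated distribution; `sample_gibbs` runs single-site sequential
sweeps (conditional logistic(H_i + Σ J_ij σ_j)) with burn-in and
thinning, giving temporally correlated sequences closer to real
recordings; `sample_surrogate_continuous` maps Gibbs states to ±1 plus
Gaussian noise so the zero-threshold binarization path is exercised.
Binarization maps values strictly above the threshold to 1; a value
exactly at the threshold maps to 0, a fixed convention for
reproducibility (exact zeros are measure-zero in the intended inputs).
All generators are deterministic given their seed.

What the generator does **not** emulate: hemodynamics, spatial structure,
scanner noise spectra, inter-subject variability, or the autocorrelation
profile of any particular modality. Passing tests demonstrate the
correctness of the machinery on data satisfying the model's assumptions,
not that any particular recording satisfies them.

## Problem sizes and numerical choices

The test and acceptance suites run at N = 5–8 (full enumeration of 32–256
states), sample sizes up to 10⁶ for sampler checks and 10⁵ for fitting,
100 randomized systems for the threshold-oracle equivalence and 20 for
the minima brute-force check — sizes at which every oracle is exhaustive
and the whole suite completes in seconds. Probabilities are computed with
a max-subtraction (log-sum-exp) guard; distributions must sum to 1 within
10⁻¹², energy/probability consistency holds to 10⁻⁹. Determinism
throughout comes from explicit seeds (numpy `default_rng`), sorted
iteration orders, and the lexicographic path tie-break; two runs with the
same configuration produce byte-identical outputs.

## Known limitations

- Exact enumeration caps N at 20; the intended regime is N ≤ ~19.
- Equilibrium assumption: sampling order is ignored, so the model cannot
  distinguish dynamics with identical stationary statistics.
- The minimax pathway is a zero-temperature caricature of transition
  dynamics; entropic effects (path multiplicity) are not modeled beyond
  the step-multiplicity counters in the STN-FS.
- Exact energy ties (possible with hand-crafted rational parameters) make
  minima and tie-breaks depend on code order; the package warns when it
  detects them.
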