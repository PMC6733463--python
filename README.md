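# elanet

Energy-landscape and state-transition-network analysis of binary
multivariate dynamics with pairwise maximum-entropy (Ising) models.

`elanet` is written for researchers who record multichannel activity —
resting-state fMRI regions, neural populations, or any system whose
channels can be meaningfully binarized — and want to describe its dynamics
as movement on an energy landscape: which activity patterns are stable
(attractors), how high the barriers between them are, which saddle states
carry the traffic between attractors, and how the resulting transition
network is organized (hubs, detours, redundancy, response to coupling
perturbations).

## The model

An activity pattern over N channels is a binary vector
V = (σ₁, …, σ_N), σᵢ ∈ {0, 1}. The pairwise maximum-entropy model is the
least-structured distribution matching the empirical first moments ⟨σᵢ⟩
and second moments ⟨σᵢσⱼ⟩, a Boltzmann distribution

    p(V) ∝ exp(−E(V)),   E(V) = − Σᵢ Hᵢ σᵢ − Σ_{i<j} J_ij σᵢ σⱼ,

with baseline sensitivities Hᵢ and symmetric couplings J_ij, fitted by
exact-enumeration gradient ascent with log-ratio updates
Hᵢ ← Hᵢ + α_g log(⟨σᵢ⟩/⟨σᵢ⟩_m) (and the analogue for J), iterated until
every log-ratio falls below a tolerance (default 10⁻⁵). Fit quality is
summarized by the accuracy r_D = (D₁−D₂)/D₁ (KL divergences of the
empirical distribution from the independent and pairwise models), the
entropy ratio r_S = (S₁−S₂)/(S₁−S_N), and the reliability ER = r_S/r_D,
which equals 1 for an error-free fit.

On the fitted landscape, **local minima** are states strictly below all N
single-flip neighbors; the **connection threshold** E_th of a minima pair
is the minimax (bottleneck) energy over one-flip paths, computed by an
energy-ascending union-find filtration; the **barrier** from the
higher-energy minimum is E_B = E_th − E(source) and sets the transition
rate exp(−E_B). Three state-transition networks are assembled from the
minimax pathways (full-state STN-FS, global-minimum-directed STN-GM, and
the reduced minima+saddle STN-LM) and analyzed with degree profiles,
path-length decompositions, UPGMA clustering of minima, correlation
statistics, single-state removal (rerouting/redundancy), and coupling
scaling αJ.

A synthetic-data module generates ground-truth models (including sparse
two-community systems whose landscapes contain mutually complementary
attractor pairs) and exact, Gibbs, or noisy-continuous samples from them,
so the whole pipeline is testable end to end.

## Worked example

```bash
elanet pipeline --n-regions 8 --n-samples 50000 --seed 1 --out-dir demo
```

simulates an 8-channel two-community system, binarizes the noisy
continuous signals at zero, fits the pairwise model, and derives the
landscape and networks. It prints

```
pipeline complete: 7 minima, ER=0.9999, outputs in demo
```

`demo/fit_report.json` records the fit: converged after 2157 iterations
with accuracy r_D = 0.9811 and reliability ER = 0.9999 — the pairwise
model removes ~98% of the independent model's divergence from the data,
and the two fit-quality views agree almost perfectly. `demo/local_minima.tsv`
lists the attractors in ascending energy:

```
label  code  bitstring  energy                is_global_minimum
LM1    15    11110000   -0.65760115636361294  True
LM2    212   00101011   -0.6456096334906789   False
LM3    240   00001111   -0.6345593880802709   False
...
```

LM1 (first community active) and LM3 (its complement) are a complementary
attractor pair, the signature organization of two-community systems.
`demo/` also contains the barrier and threshold matrices, a
disconnectivity tree (`disconnectivity.nwk`, leaves at the minima
energies), the three transition networks as GraphML/TSV, node-degree and
group-transition tables, and an α-sweep is available via
`elanet perturb`. Every stage writes a provenance JSON with the seed and
package versions; identical seeds give byte-identical outputs.

The same operations are available as a library (`elanet.fit_pairwise_mem`,
`elanet.find_local_minima`, `elanet.build_stn_fs`, …); see
`docs/methods.md` for the underlying procedures and their assumptions.

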