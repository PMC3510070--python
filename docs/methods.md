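# Methods

`allodyn` predicts which residues of a protein domain experience
binding-induced changes in side-chain dynamics, from structures of the
bound and unbound states alone. The central idea is information-theoretic:
if a bound peptide redistributes conformational freedom through the domain,
the statistical coupling between pairs of side chains changes, and the
residues carrying those changes can be read off a matrix of
mutual-information differences without any large conformational change
being present. This document describes the model, the numerical choices,
and what the synthetic validation does and does not establish.

## Conformational sampling

Each residue's side chain is restricted to a discrete alphabet of χ-dihedral
combinations on a uniform grid (`bins_per_chi` bins of 360°/bins each,
default 6, i.e. 60° resolution; alanine and glycine have a single symbol).
The alphabet is deliberately backbone-independent so every conformation is
reachable from every backbone model.

Domain conformations are sampled by Metropolis Monte-Carlo at 298 K: a
residue and a replacement symbol are proposed uniformly (a symmetric
proposal, so detailed balance holds) and accepted with probability
p = min(1, exp(−ΔG/RT)), R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹. Before sampling, a
greedy best-symbol descent relaxes the chain to a low-energy start. One
chain is run per backbone model of the input ensemble and the full domain
state is recorded every `snapshot_interval` iterations (default 1000);
chains are concatenated into one residues × snapshots trajectory. The
defaults target 5000 snapshots, a desk-scale preset; the full-scale preset
(`SamplerConfig.FULL_SCALE_SNAPSHOTS = 751500`) is what a production run
on a ~100-residue domain would use.

The energy function is pluggable (`EnergyFunction.delta_g(state, residue,
new_symbol)`), deterministic given state and move. Three implementations
ship: `FlatEnergy` (uniform stationary law), `TableEnergy` (additive
per-symbol energies, whose stationary distribution is an exact Boltzmann
law — the reference model for sampler tests), and `SoftSphereEnergy`, a
steric model with a soft-core quadratic overlap penalty between heavy atoms
closer than 3.2 Å plus a 3-fold cosine torsion term favouring staggered χ.
The soft-sphere model is a deliberately simple steric energy; a wrapper
around a full force field can be plugged in through the same interface, and
absolute MI values (hence useful clustering thresholds) depend on that
choice.

## Mutual-information coupling and ΔMI

For residues A and B the coupling is the plug-in mutual information
I(A,B) = H(A) + H(B) − H(A,B) in bits (log base 2; the base cancels in the
thresholded and normalized quantities downstream). The preprocessing chain
per residue row is:

1. **Reparametrize** symbol index i of a size-k alphabet to i/(k−1) in
   [0,1]. MI is invariant to injective reparametrization of the marginals;
   the step removes alphabet-size differences between residues.
2. **Jitter** with zero-mean Gaussian noise of variance 10⁻¹²
   (sd 10⁻⁶) — a tie-breaker far below the symbol spacing.
3. **Fixed-frequency discretization (FFD)**: sorted values are cut into
   bins of m samples each (`samples_per_bin`, default 30), the last bin
   absorbing the remainder; runs of exactly equal values are never split.

Inside `mi_matrix` the frequency is raised to max(m, ⌈n/k⌉) so that the
discretization never refines beyond the residue's own alphabet. Without
this cap, n/m bins on nearly-discrete data produce a plug-in MI bias of
order (bins−1)²/(2n ln 2) — several bits for independent pairs at n = 10⁴ —
swamping the signal. With the cap, bins align with symbols up to quantile
boundary effects: because bin boundaries sit at empirical quantiles, a few
samples straddle symbol groups when marginals deviate from uniform, biasing
MI a few percent *low* (e.g. a perfectly copied pair at n = 10⁴, k = 4
measures ≈1.8 bits against H = 2.0). The bias is common to both states and
cancels to first order in the bound−unbound difference.

Pairs whose MI is indistinguishable from chance are zeroed by a permutation
null: the MI is recomputed on `n_null_permutations` (default 20)
independently shuffled copies of one row, and the entry survives only if it
exceeds mean_null + 3·sd_null (multiplier configurable). Each state's
matrix is filtered before differencing (order exposed as a flag in the
CLI). The signed ΔMI matrix is bound − unbound; clustering and ranking use
its absolute values, and heat-map style output uses the [0,1]-normalized
absolute matrix. Negative plug-in MI from floating point is floored at 0.

## CAST extraction of the informative group

The informative group — the predicted set of dynamically affected
residues — is extracted from |ΔMI| with the Cluster Affinity Search
Technique. The affinity of residue r to clique C is
a(r,C) = Σ_{c∈C, c≠r} |ΔMI(r,c)|, and membership requires the *average*
coupling to stay at or above the threshold t: a(r,C) ≥ t·|C|. A new clique
is seeded with the unassigned residue of maximal total affinity to the
remaining pool; add steps (best unassigned residue while it qualifies) and
remove steps (any member falling below t on the reduced clique) alternate
until stable, and the procedure repeats until all residues are assigned.
All ties break to the lowest residue index, making the partition
deterministic. The informative group is the union of cliques with at least
two members: singletons carry no coupling evidence. Sweeping t downwards
yields the inclusion ranking (first-entry threshold per residue; residues
never entering rank last, ordered by total affinity).

The mean-affinity acceptance rule is the canonical CAST formulation; on
block-structured matrices the recovered cliques equal the blocks for any t
strictly between the between-block and within-block coupling levels, which
is verified against exhaustive partition enumeration in the tests. Whether
negative (coupling-relaxation) ΔMI should enter the affinity with its sign
is an open scientific question; absolute values are the default and a
signed mode is left to the caller by passing the signed matrix.

## Contact networks and centrality baseline

Residues are graph nodes; an edge is added when any pair of their atoms
(all deposited atoms by default, hydrogens included; heavy-only as an
option) lies within 5.0 Å, sequence neighbours included. Small-world
statistics (mean local clustering, characteristic path length over
unordered pairs, diameter, average degree 2E/N) are computed on the graph,
falling back to the largest component with a warning when disconnected.
The structure-only baseline predictor ranks residues by normalized
shortest-path betweenness centrality. The dynamical network annotates
contact edges with signed ΔMI (sign = direction of coupling change,
weight = magnitude); coupled pairs without a physical contact are excluded
from this view, which is exported as GraphML or a TSV edge list.

## Backbone flexibility

From an NMR ensemble, all models are superposed by iterative least-squares
(Kabsch) alignment on Cα to their evolving mean until the mean moves by
less than 10⁻⁹ Å RMSD. The reference is initialized with the raw
coordinate mean rather than the first model: at the Procrustes fixed point
every model's optimal fit to the mean is the identity, so initializing at
the mean makes the superposition exactly idempotent, while identical
shapes under arbitrary rigid motions still converge (they all receive the
same fit onto any reference). Residue flexibility is the mean distance of
its Cα across models from their centroid. Bound−unbound differences are
standardized (population sd) after excluding four residues at each
terminus, whose flexibility reflects fraying rather than binding; z-score
tiers |z| ≥ 2 ("most") and 1 ≤ |z| < 2 ("moderate") are configurable
display bins. A degenerate ensemble with zero difference variance raises
an error rather than emitting undefined z-scores.

The side-chain and backbone predictors are combined by a weighted rank
sum r_i = α·rank_sc(i) + β·rank_bb(i) with α = 1.5, β = 1 (side-chain
information weighted 50% higher), ties broken uniformly at random under a
seed.

## Evaluation

Experimental labelings split the methyl-bearing residues into positives,
negatives and excluded (missing data); excluded residues never enter any
count. TPR = TP/(TP+FN), FPR = FP/(FP+TN). The ROC curve over the CAST
sweep takes one operating point per threshold; the AUC is the trapezoidal
integral of the curve closed at (0,0) and (1,1) (so a single diagonal
point yields 0.5), and the best threshold minimizes the Euclidean distance
to the top-left corner, ties to the larger threshold. Alanines are
conformationally invariant, hence zero-entropy and zero-MI by
construction; they receive the minimum score rather than being dropped,
and `ResidueLabels.without_alanines()` reproduces the alanine-free
evaluation variant.

For the hPDZ2 benchmark the package ships the published residue lists
(`allodyn.pdz2`). The exclusion set is a reconstruction: seven members are
named in the source experiments, and cross-method count consistency forces
A74 plus one of {A46, V58, L59} (A46 chosen; all three choices reproduce
every published count). The labeling is a plain TSV and user-editable.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes:

- **Toy structures**: idealized helix/strand Cα traces (3.8 Å spacing)
  with backbone atoms, CB and a CG pseudo-atom. Chemically plausible, not
  physical: no real side-chain geometry, no packing.
- **Flexibility ensembles**: a base structure with per-residue isotropic
  Gaussian rigid displacements (the planted σ profile), re-embedded under
  random global rigid motions so superposition is actually exercised.
  Real NMR ensembles have correlated, anisotropic variation; this
  generator does not emulate that.
- **Two-state trajectories**: i.i.d. uniform symbols, with planted pairs
  coupled through a copy-with-probability-c channel whose MI is available
  in closed form, I = log2 k − H(c + (1−c)/k, (1−c)/k, …). Real sampled
  trajectories are autocorrelated and their couplings are not pairwise
  independent; the generator provides exact ground truth, not realism.

Passing the synthetic suite therefore establishes estimator and algorithm
correctness (the MI chain recovers planted coupling changes with AUC ≥ 0.9
at 10⁴ snapshots; CAST matches exhaustive enumeration on ≤8-residue
matrices; the sampler reproduces Boltzmann occupancies, χ² p > 0.01 at 10⁵
snapshots; flexibility recovers a planted σ profile with Spearman ≥ 0.9 at
20 models). It does not establish that the simple steric energy yields the
same MI scale as a full force field: clustering thresholds calibrated on
one energy model (such as the published t₁ = 0.023 / t₂ = 0.027) do not
transfer to another.

## Default problem sizes

Trajectory-level validation uses 10⁴ snapshots (10⁵ for sampler
distribution checks), 12–14 residue systems, 20-model ensembles, and
20-matrix CAST batteries — sizes at which every closed-form oracle is
sharp while the full suite runs in seconds. Production runs on real
domains scale the same code up through `SamplerConfig`.

## Known limitations

- Alanine/glycine dynamics are invisible to the side-chain channel (single
  symbol, zero entropy); only the backbone predictor can rank them.
- The uniform χ-grid alphabet ignores rotamer statistics conditional on
  backbone; a statistical rotamer library would concentrate proposals on
  populated states.
- Quantile-based FFD on nearly-discrete data biases MI slightly low (see
  above); the bias largely cancels in ΔMI.
- The betweenness baseline is the standard normalized shortest-path
  variant, a close canonical relative of (not identical to) specialized
  centrality measures used in the residue-network literature.
- No backbone moves, loop modelling or replica exchange in the sampler.
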