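# Methods

## Contact networks

A residue chain is the ordered list of α-carbon coordinates of one
structure. Parsing follows a first-wins policy: only the first model of a
multi-model file and the first alternate location of a disordered atom are
read; hetero-residues are skipped, residues without a CA atom are skipped
with a warning; chains within a model are concatenated in file order
(configurable to first-chain-only), which treats the whole deposited
assembly — including quaternary structure — as one pattern. The contact
rule places an edge between residues whose α-carbons lie within
[lower, upper] Å, both ends closed, default [4, 8]: the lower bound
removes backbone-adjacent pairs (consecutive CAs sit ≈3.8 Å apart), the
upper bound reflects peptide-bond geometry. Node and edge labels are
deliberately absent.

Dataset quality filters drop structures with missing resolution,
resolution strictly above 3.0 Å (records at exactly 3.0 are kept), more
than 1500 residues, or more than one distinct EC top-level class. The
class label is the EC first digit 1–6; structures without an EC
annotation are labelled 7 (non-enzymes).

## The eight representations

All are graph-isomorphism invariants with configuration-determined
lengths (`RepresentationConfig`):

1. **Betti numbers** b0…b_max (default max dim 1) of the clique (flag)
   complex, over GF(2) via boundary-matrix ranks. b0 is the component
   count; b1 counts independent cycles not filled by triangles.
2. **Centrality profile**: mean and standard deviation over nodes of
   degree, closeness, betweenness, eigenvector centrality and the
   clustering coefficient (length 10). Eigenvector centrality of an
   edgeless graph is defined as all-zero.
3. **Graph energies**: Σ|λᵢ(A)| over adjacency eigenvalues and
   Σ|μᵢ(L) − 2m/n| over combinatorial-Laplacian eigenvalues.
4. **Network cartography**: modules from greedy modularity maximization;
   per node the within-module degree z-score (z = 0 when the module's
   degree spread is zero) and participation coefficient; nodes assigned
   to the seven classical roles (hub threshold z ≥ 2.5; participation
   breakpoints 0.05/0.62/0.80 for non-hubs and 0.30/0.75 for hubs);
   output is the seven role fractions plus the achieved modularity.
   Requires at least one edge.
5. **Heat-content invariants**: coefficients q1…q5 of the small-t
   expansion of Q(t) = Σₖ sₖ² e^{−λₖ t} of the symmetric normalized
   Laplacian (sₖ = eigenvector entry sum), qₘ = Σₖ sₖ²(−λₖ)ᵐ/m!.
6. **Heat-kernel trace** Σₖ e^{−λₖ t} of the combinatorial Laplacian on
   10 log-spaced times in [10⁻², 10]. The trace equals n at t = 0 and
   tends to the component count as t → ∞.
7. **Protein size**: the node count.
8. **Spectral density**: Gaussian KDE of the normalized-Laplacian
   spectrum on 100 uniform points in [0, 2]; Silverman bandwidth with a
   floor of 0.01 for degenerate spectra.

The split of spectral quantities — combinatorial Laplacian for the heat
trace and Laplacian energy, normalized Laplacian for heat content and
spectral density — follows the canonical definition of each named
invariant. Descriptor extraction isolates per-representation failures
and reports them tagged by view id.

## Dissimilarity spaces and the multiple kernel

Per representation, patterns are compared by a configurable measure
(Euclidean everywhere by default, since all eight vectors are fixed
-length and real). The train-vs-train matrix is symmetrized as
½(D + Dᵀ); validation and test patterns are described by their distances
to the training patterns. An optional flag z-scores each representation
with training statistics before distances are taken (off by default). A
binary prototype mask slices columns; the all-ones mask recovers the full
embedding. Full train matrices are computed once and sliced per
candidate, never recomputed.

Each reduced matrix's rows are the coordinates on which the per-view RBF
kernel exp(−γᵢ‖·‖²) is evaluated; the convex β-weighted sum is the
multiple kernel. Validity needs no regularisation: Gaussian kernels are
PSD, and non-negative combinations of PSD matrices are PSD (verified as a
property test, minimum eigenvalue ≥ −10⁻⁸ over random specifications).

The ν-SVM is solved on the precomputed kernel (scikit-learn/libsvm) with
fixed tolerance 10⁻³, recorded in the model, and an iteration cap of
2·10⁵ so that near-degenerate duals cannot stall a search. ν infeasible
for the class balance (ν > 2·min(n₊, n₋)/n) and solver failures on
degenerate kernels surface as typed errors; the genetic search maps them
to the worst fitness rather than aborting, keeping evolution total.
Models serialize to JSON (support indices, dual coefficients, intercept,
spec, mask) and reload to bit-identical decision scores.

## Genetic search

The genome is [ν, β, γ, w] with ν ∈ (0, 1] (numerical floor 10⁻³),
β on the probability simplex, γ ∈ (0, 100] and w a binary mask over
training patterns. Defaults follow the full-scale configuration: 100
individuals, 100 generations, 10% elitism, roulette-wheel selection on
the oriented fitness (f1 as-is; f2 flipped to 1 − f2 so higher is
better), scattered crossover (each gene from a random parent), and
mutation that adds zero-mean Gaussian noise whose scale decays linearly
from 10% to a 1% floor of each gene's range, then clips to bounds; mask
bits flip independently with probability 1/|w|. β is repaired after
every operator by clipping to [0, 1] and renormalising, with an all-zero
vector falling back to uniform — the simplest projection consistent with
the constraints. β is initialised from a flat Dirichlet, γ log-uniformly
over its range (distance scales vary across representations by orders of
magnitude, so a log-uniform start covers all useful kernel widths), mask
bits Bernoulli(0.5). Fixed generation budget, no early stopping. Every
objective evaluation runs the complete pipeline: mask-slice the
precomputed train stacks, build the multiple kernel, train the ν-SVM,
kernelise the validation patterns against the training prototypes,
predict, and score J̄ (f1) or ω(1−J̄) + (1−ω)·density (f2). With
prototype selection disabled the mask is pinned to all-ones and excluded
from the search, the configuration used for the head-to-head benchmark.
Runs are reproducible from the seed; multi-run experiments derive seeds
as base, base+1, ….

## One-class baseline

Patterns are the concatenated per-view dissimilarity vectors. The target
class is modelled by several (default 5, odd to avoid vote ties)
independently initialised k-medoids partitions under a weighted Euclidean
dissimilarity √((x₁−x₂)ᵀWᵀW(x₁−x₂)), W diagonal and non-negative. Each
cluster has average radius δ, threshold σ, decision boundary B = δ + σ,
and sigmoid membership μ(d) = 1/(1 + e^{(d−b)/a}) with a = δ and
b = δ + σ/2, so μ(b) = ½ exactly; singleton clusters (a = 0) degenerate
to an indicator at b. A query is accepted when its distance to the
closest cluster's medoid does not exceed that cluster's boundary (the
boundary itself counts as inside, since the region is described as
bounded by B); instances vote by majority, and the mean membership of
the closest cluster is the soft score feeding ROC construction.

A genetic algorithm with the same operator suite tunes the weights and
the per-cluster thresholds on a validation set containing both classes,
maximising 0.5·accuracy − 0.5·(mean threshold extension) by default; the
σ genes live in [0, 1] and are scaled by the mean pairwise weighted
distance among targets so thresholds remain comparable across weight
candidates. When the per-view column blocks are supplied, one weight
gene is evolved per block and broadcast across its columns — this keeps
the search space independent of the number of prototypes, which at desk
scale is the difference between a recoverable and a hopeless search. The
clustering restarts are re-seeded identically for every candidate so
that individuals are compared under the same initialisations.

## Synthetic data

Two generators define the study conditions.

**Chains.** A self-avoiding-biased random walk with a fixed 3.8 Å step
(the backbone CA spacing, just below the 4 Å contact bound, so
sequence-adjacent residues never form contacts), an excluded-volume
radius of 4.0 Å enforced by rejection against all earlier residues, and
a weak centripetal bias that folds the walk into a compact globule.
Chains of length ≥ 30 yield connected contact networks in ≥ 90% of
seeds (a seeded regression property, not a biological claim). Fixtures
are written as minimal poly-glycine PDB text with optional resolution
and EC header records, round-tripping coordinates at the format's
3-decimal precision.

**Planted multi-view data.** Every view has the same anatomy, chosen to
mirror what real descriptor vectors look like: a low-variance signal
subspace (2 dimensions, unit noise sd) plus higher-variance distractor
components (4 dimensions, sd 2.5) further multiplied by a per-pattern
log-normal scale factor (σ_log = 1), emulating the heavy-tailed,
pattern-scale heterogeneity of real graph descriptors (energies, sizes
and Betti counts vary over orders of magnitude across proteins). Only in
the informative views are the signal components' class means separated —
by effect_size · noise_sd in Euclidean norm, default 5σ. Defaults: two
classes, 250 patterns per class.

The distractor design is load-bearing and worth stating plainly. If the
non-informative views were featureless iid noise, the kernel weights β
would be structurally unidentifiable: the SVM dual constraint Σαy = 0
makes near-constant kernels (small γ) contribute exactly zero to every
decision, and near-identity kernels (large γ) act only as benign ridge
regularisation, so the search can neutralise any noise view through γ
alone and the mass of β carries no information. Measured on such data,
the correlation between the planted view's weight and fitness is ≈ 0.
With heavy-tailed distractors inside every view, no single kernel width
flattens any view, weight placed on a non-informative view always costs
validation informedness, and β becomes the operative lever. The same
heterogeneity caps the achievable informedness below 1 (the informative
view's own distractors blur its distances), which is precisely the
regime in which weight recovery is observable: selection pressure on β
is proportional to one minus the achievable ceiling, because a margin
classifier is indifferent to diluted kernels as long as validation
performance saturates. Passing recovery tests on this generator
therefore demonstrates that the system identifies informative
representations when representations genuinely differ in usefulness;
they do not show that β would concentrate on a problem easy enough for
every kernel mixture to solve, nor do the fixtures mimic real
secondary-structure statistics.

## Problem sizes and numerical choices

Tests and the acceptance script run the evolution at population 20 for
15 generations over 5 seeded runs on the 500-pattern planted dataset
with a 60/20/20 stratified split (per-class proportions preserved within
one pattern; per-classifier splits are re-drawn after one-vs-all
recoding with seeds derived from a master seed). These sizes were chosen
so the full suite completes comfortably on a single CPU while leaving the
recovery signal measurable. The β simplex tolerance is 10⁻¹²; kernel PSD
tolerance 10⁻⁸; GF(2) ranks are exact; ROC ties are handled by the
rank-averaging (Mann–Whitney) convention; metric denominators of zero
raise typed errors rather than returning silent zeros.

## Known limitations

- Per-run argmax(β) recovery and near-ceiling test informedness trade
  off against each other (see above); run-averaged β is the more stable
  knowledge-discovery readout and is what `knowledge_reports` returns.
- The one-class baseline's σ genes are searched jointly with the
  weights; at large k the σ part of the genome is high-dimensional and
  only weakly optimised within small generation budgets.
- The clique-complex homology is dense GF(2) elimination — adequate for
  contact networks (≤ 1500 nodes, dimension ≤ 2), not for large
  complexes or higher dimensions.
- PDB parsing handles the fixed-column dialect via Bio.PDB; mmCIF and
  insertion-code subtleties beyond first-occurrence policy are out of
  scope, as is any network retrieval.
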