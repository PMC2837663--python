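# Methods

This note documents the generative model, its parameters and defaults, the
numerical choices, and the limits of what the simulation (and its tests)
can show.

## Model trees

Trees are grown under a Yule pure-birth process conditioned on exactly *n*
tips: starting from a root with two lineages, each of *k* extant lineages
splits at total rate *k* (waiting times Exp(*k*)), a uniformly chosen
lineage splitting at each event; after the *n*-th lineage appears the
process runs one further Exp(*n*) interval. All node times are then rescaled
so every root-to-leaf path equals the target height (default 1.0 expected
substitutions/site). The result is exactly ultrametric, fully binary, with
strictly positive edge lengths.

Clock deviation multiplies each edge length by a factor evolving as a
random walk in preorder: the root carries factor 1.0, and each daughter
edge's factor is its parent edge's factor plus a N(0, σ) increment
(default σ = 0.05), clamped into [0.05, 8]. Clamping is applied at every
step and the walk continues from the clamped value, so the constraint
holds on every edge, not just at the end. Preorder is the only traversal
consistent with propagation "from parent branch to daughter branches".
Topology and leaf labels are untouched; the realized factors and raw
increments are attached to nodes for diagnostics.

## Gene birth and loss

Gene presence is modelled with a binary site evolving down the tree. On
each branch an event fires with probability 1 − e^(−λ·b_norm). Branch
lengths are normalized by the total tree length (b_norm = b / Σb), which
makes the process independent of tree height; the intensity λ
(`lambda_norm`) then equals the expected number of events per whole-tree
pass. Its default is 1.0 — the value is a free parameter of the design
(no canonical value exists), chosen so that birth points spread over the
tree rather than saturating near the root, and it is exposed in
`DecayParams` and recorded in run logs. Births and losses use the same
decay process by default; the loss intensity can be overridden
independently.

The birth scan starts at the root: the branches leaving the current node
are tested, and if any fires the scan stops; otherwise it recurses into
all children and keeps the earliest reported event (smallest distance from
the root), breaking exact ties uniformly. A pass with no event anywhere is
repeated. The node at the top of the firing branch becomes the birth node
by default (`birth_anchor="parent"`, matching the loss rule's opposite
convention of assigning losses to the node *below* the branch); the child
anchor is available as a configuration flag. Losses are then sampled below
the birth node with the same per-branch rule; a loss on a branch removes
the child and its entire subtree, so the surviving node set is connected by
construction. Draws in which no leaf survives are rejected and resampled —
a gene must be observable in at least one taxon. Genes surviving in a
single leaf are kept in the manifest but carry no alignment (they cannot
inform any tree).

Universal genes are born at the root and never lost. They default to the
slow rate class; the all-scaffold study design also uses medium-rate
universal genes (50 slow + 50 medium in a pool of 100), so the rate class
is an explicit argument rather than an invariant.

## Sequence evolution

Each gene evolves independently down its presence subtree under GTR+Γ+I.
The GTR generator is built from the six exchangeabilities (order AC, AG,
AT, CG, CT, GT with GT = 1 the reference — the standard PAUP*/Seq-Gen
upper-triangle layout) and the stationary frequencies, normalized to one
expected substitution per unit branch length at stationarity. The three
built-in parameter sets (Angiosperm, Nematode, rbcL) are stored exactly as
published; their printed frequencies sum to 0.999999 in two cases and are
renormalized internally (a 10⁻⁶ effect).

Per site: with probability p_inv the site is invariable — its state is
drawn once at the root and copied down the whole subtree; otherwise its
rate is drawn from Gamma(α, mean 1), continuously by default. A
discrete-category option (mean-of-quantile-bin category rates, any k) is
provided but off by default; with the data simulated here the two are
statistically indistinguishable at gene length 500. Branch lengths are
multiplied by the gene's rate-class factor (fast 2.0, medium 1.0,
slow 0.1). Transition matrices exp(Qt) are computed by symmetrized
eigendecomposition (Q is reversible), vectorized over sites, with tiny
negative round-off clipped and rows renormalized. Sequences are gapless
and aligned by construction; no indel process is modelled.

## Dataset assembly

Clades are selected by the same branch-selection scan used for gene
births; the child node of the selected branch is the clade root.
Selection is rejection-sampled per clade independently until the size
bounds are met (defaults per tree size: 100 → 5 clades of ≥ 20 taxa,
500 → 15 of ≥ 30, 1000 → 25 in [30, 500]), with a 10,000-attempt cap that
fails loudly on infeasible bounds. Distinctness means distinct root nodes;
nested clades are allowed. For each clade the three non-universal genes
covering the most clade taxa are chosen (ties uniformly at random), taxa
are restricted to those carrying all three, and datasets retaining fewer
than 10 taxa are discarded (logged).

Scaffold datasets include each taxon independently with probability *p*
(the scaffold factor, studied at 0.2/0.5/0.75/1.0) and concatenate 1, 2 or
4 universal genes; empty draws are resampled. The supermatrix superimposes
every dataset's alignments: one column block per distinct gene, the block
filled for the union of taxa over the datasets using that gene and `?`
elsewhere, blocks ordered universal-first then by gene id. Because all
copies of a gene come from the single simulated alignment, superimposition
cannot conflict; the builder still verifies dataset rows against the
per-gene alignments to guard hand-edited inputs.

A usability check flags source-dataset sets with too little taxon overlap
for any super-method: the dataset graph (edge when two datasets share ≥ 3
taxa) must be connected and its component must span ≥ 95% of sampled taxa.
The thresholds formalize an informal criterion and are configurable; the
check logs rather than deletes.

## MRP encoding and exact search

Source trees are treated as unrooted. Each internal edge contributes one
character: 1 for taxa on the side away from the tree's lexicographically
smallest taxon, 0 for the other side, `?` for taxa absent from that tree
(orientation is cosmetic — parsimony scores are orientation-invariant —
but fixed for reproducibility). Pendant edges are parsimony-uninformative
and skipped by default; `include_pendant` restores the literal
one-character-per-branch behavior. Weighted MRP takes each character's
weight from its edge's support value (Newick internal-node labels) and
refuses trees with missing supports. Matrices are written as NEXUS
(datatype=standard, symbols="01", missing=?) with a PAUP* assumptions
block carrying the weight vector, plus a TSV sidecar of weights and
per-character provenance.

Parsimony lengths are computed by Hartigan's generalization of the Fitch
algorithm, vectorized over characters, exact for arbitrary node degrees
and missing data. Exhaustive search enumerates all unrooted binary
topologies by leaf insertion, capped at 9 taxa (135,135 topologies); it
exists to validate MRP behavior at small sizes, not to replace heuristic
searches. Strict and majority (> 50%) consensus trees are built from split
counts; majority splits are pairwise compatible, so the consensus is
assembled by nesting splits in decreasing size.

## Evaluation

Trees are compared as sets of unrooted non-trivial bipartitions. FN = |model
splits missing from the estimate| / (n − 3); FP = |estimated splits not in
the model| / (estimate's internal-edge count); average topological error is
their mean, provably equal to normalized Robinson–Foulds distance for
binary pairs (and verified against an independent implementation in the
tests). Degenerate cases: a star estimate has FP = 0 by convention (it
asserts nothing false; the formula is 0/0), logged; a non-binary reference
uses its actual internal-edge count instead of n − 3, logged; the FN
denominator stays n − 3 regardless of the estimate's resolution.
Per-condition summaries report the mean and standard error
(sample SD / √replicates; SE = 0 for a single replicate, logged).

## Reproducibility

Every stage seeds a fresh generator with
SHA-256(master_seed | stage_name | replicate_index) mod 2³¹, so replicates
are bit-identical given the configuration and independent across stages
and indices. Run logs record per-stage events (discards, resamples,
overlap checks).

## What the simulation does and does not show

The generator reproduces the *structure* of multi-marker studies: clade-
concentrated taxon sampling, connected gene footprints, heterogeneous
substitution models, rate-class mixture, and block-structured missing
data. It does not model indels/alignment error, gene-tree discordance
(all genes evolve on the species tree), paralogy or horizontal transfer,
sequencing error, or within-class rate variation among lineages beyond the
clock deviation. Passing tests therefore certify the simulator's fidelity
to its own model and the exactness of the encoders/metrics — not that any
tree-estimation method will behave on real data as it does on these
matrices. Because the decay intensity λ is a design parameter, absolute
missing-data percentages are tunable rather than canonical; comparisons
across scaffold factors and dataset designs are the intended use.

Problem sizes used in the test and acceptance suites — one replicate per
tree-size preset, 200,000-site model-fidelity simulations, 100,000-draw
birth/loss checks against exhaustive enumeration, exhaustive searches to
8 taxa — were chosen as the smallest scales at which each statistical
check has the stated power (3 SE bounds throughout).
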