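# Methods

`chloroscape` quantifies how individual plastid protein-coding genes
(PCGs) agree or conflict with a species tree, how fast they evolve, and
how informative they are — and ties those quantities together in a single
per-gene profile. This note documents the models, estimators, defaults
and numerical choices, and what the synthetic benchmark does and does not
establish about real data.

## Gene-tree discordance in Robinson–Foulds tree space (GD)

All gene trees and the species tree(s) are first pruned to their common
taxon set; trees with fewer than four tips of their own (heavily
incomplete loci) are dropped beforehand and reported, because keeping
them would only shrink the common set for everyone else. Pairwise
unnormalized Robinson–Foulds (RF) distances — the symmetric difference of
non-trivial bipartition sets on the unrooted forms — feed a classical
PCoA: eigendecomposition of `B = -1/2 J D∘D J` with `J` the centering
matrix. Coordinates are kept only for positive eigenvalues, scaled by
`sqrt(λ)`; negative eigenvalues (RF is non-Euclidean) are reported
uncorrected, and variance explained is relative to the positive-part
total. No Cailliez/Lingoes correction is applied: GD uses only axes 1–2
and the corrections change the absolute scale unpredictably.

GD for a gene is its Euclidean distance to the coalescent species tree
in axes 1 and 2. Two deterministic conventions make output reproducible:
eigenvector signs are fixed (largest-magnitude loading positive), and
items with bitwise-identical distance-matrix rows are forced to coincide
in the embedding — so a gene tree topologically identical to the species
tree gets GD exactly 0, not 1e-16. Whether RF is normalized before
ordination is a config switch (`rf_normalized`, default off); GD is
scale-covariant either way.

## Partitioned coalescence support (PCS)

The optimality criterion is the summary-coalescent quartet score: a
gene's fit to a topology is the number of four-taxon subsets resolved
identically in both trees, computed on their shared taxa only and left as
an unnormalized integer count. Quartet resolutions are read off the
four-point condition on topological (edge-count) distances, vectorized
over all C(n,4) subsets; this brute-force route is exact and entirely
adequate at plastome scale (C(26,4) = 14 950). PCS therefore depends on
topology only, never on branch lengths.

For each internal branch (clade) of the species tree the candidate
alternatives are, by default, the two nearest-neighbour-interchange
resolutions around that branch; an explicit list of alternative species
trees (e.g. a concatenation ML tree) can be supplied instead, in which
case an alternative challenges exactly the clades it lacks. The best
alternative per clade is the candidate with the highest total fit summed
over genes; `PCS(g, c) = fit_g(species tree) − fit_g(best alternative)`.
A gene's single PCS value aggregates per-clade values by summation by
default; a focal-clade mode is exposed because the field also reports
PCS against one contentious branch, and output labels which aggregation
was used. Sign classification is strict: zero means exactly 0.

## Substitution rates (NG86 counting)

dN and dS are estimated by Nei–Gojobori (1986) counting with
Jukes–Cantor correction, not by ML codon-model fitting: the downstream
analyses need relative rates and a purifying-selection signal, and a
counting estimator is deterministic and checkable against exhaustive
enumeration. Site counts per codon sum the synonymous/nonsynonymous
fractions of the nine single-nucleotide changes, excluding changes that
create stop codons (so a codon contributes `3 − k/3` sites with `k` stop
neighbours). Multi-difference codons average over all orderings of
single-step pathways, excluding pathways through stops; in the rare case
every pathway is blocked, all pathways are used with stop intermediates
scored as nonsynonymous. `d = −3/4 ln(1 − 4p/3)` corrects each
proportion; `p ≥ 3/4` leaves that rate missing rather than infinite.
Codons containing gaps, ambiguity codes or stops in either sequence of a
pair are skipped pairwise, mirroring `cleandata`-style handling. The
universal genetic code is assumed throughout (plastid PCGs use it).

A unit's (gene, functional group, or LSC/SSC/IR region) rates are means
over all sequence pairs, with missing pairwise values excluded per rate;
group and region units are built by codon-respecting concatenation in
which taxa missing a gene contribute gap codons. ω is reported missing —
not 0, not ∞ — whenever dS is 0 or saturated. Calibration: on neutral
(ω = 1) simulations the mean estimate across 20 seeds falls within
[0.8, 1.25]; on ω = 0.2 within [0.1, 0.3] (see the acceptance suite).

## Variation and phylogenetic informativeness

S counts columns with ≥ 2 distinct bases among A/C/G/T (gaps and
ambiguity codes are ignored per column, so a column varying only by a
gap is not segregating). π is the mean over unordered pairs of per-site
differences with pairwise deletion (complete deletion is available as a
config choice). PV = S/L. Parsimony-informative columns need ≥ 2 states
each in ≥ 2 sequences.

Per-site rates for informativeness profiling are per-column JC69 ML
rates on a fixed relative-time ultrametric tree (root depth 1): the
likelihood uses Felsenstein pruning with the closed-form JC transition
probability, vectorized across columns, and a vectorized golden-section
search on λ ∈ [0, λ_max] (default λ_max = 20 per unit relative time,
absolute tolerance 1e-6). Invariant columns are assigned λ = 0 directly.
The clock tree is produced by mean-path-length smoothing: each internal
node's age is the mean path length to its descendant tips, clamped so a
parent is never younger than a child, scaled to root age 1; unrooted
inputs are midpoint-rooted first. This replaces external clock-ML
programs; it is deterministic and adequate for relative-time profiling.

Informativeness follows Townsend's quartet formula
`ρ(t; λ) = 16 λ² t e^(−4λt)`, summed over sites and profiled on a grid
over (0, 1] (default 100 points). A single-site profile peaks at
`t* = 1/(4λ)`. Because one "net PI" number per gene is ambiguous
(maximum? integral? fixed time?), the profile itself is emitted along
with its maximum and argmax; ranking uses the maximum by default. Note
that net PI scales with gene length, so cross-gene comparisons of
informativeness *per site* should divide by L.

## Correlation panels

Twelve Pearson correlations — {GD, π, PV, PI} × {dN, dS, ω} — are
computed with pairwise deletion of missing genes; p-values are two-sided
from the Student-t reference distribution with n − 2 df, reported raw
with conventional stars (a Holm step-down option exists but is off by
default, matching the field's raw-p convention). Genes share a genome,
so these correlations are descriptive, not phylogenetically independent
contrasts; that caveat applies equally to the analyses the package
emulates.

## The synthetic benchmark

The generator builds a Gentianeae-like study: 26 taxa, the 76-gene
plastome template (real gene names, typical angiosperm CDS lengths from
90 bp to 6.9 kb, Table-2-style functional groups, canonical LSC/SSC/IR
regions), with:

- a Yule species tree (T1..Tn) rescaled to 30 coalescent units of
  height. A plastome is uniparentally inherited and effectively one
  linked locus, so deep coalescence is rare; long coalescent branches
  give mild topological discordance among true gene trees, and most
  observed gene-tree scatter comes from per-gene information content —
  as in real plastome data sets, where coalescent and concatenation
  species trees typically coincide;
- standard multispecies-coalescent gene trees (one haploid sample per
  species; within a branch k lineages coalesce at rate k(k−1)/2). The
  simulator is calibrated against the closed form
  `P(concordance) = 1 − (2/3)e^(−T)` for a 3-taxon tree;
- GY94 (M0) codon simulation over the 61 sense codons with F3×4
  frequencies from AT-rich position-specific base frequencies, κ = 2,
  and per-gene rate multipliers `r_g` = group base rate × region
  multiplier × lognormal noise (σ = 0.5). Group base rates encode the
  field's observed syndrome (photosynthesis genes slow; ribosomal
  protein and RNA-polymerase genes fast; "other genes" fastest) and the
  inverted repeat is slowed 0.3× (copy-correction). Branch lengths are
  converted at 0.0012 substitutions/site per coalescent unit, calibrated
  so per-gene π spans roughly 0.008–0.09 — the range reported for real
  plastome PCG sets. Transition probabilities come from one symmetrized
  eigendecomposition per gene, so no waiting-time simulation is needed;
  a two-taxon run is checked against the brute-force `expm(Qt)` oracle;
- ω_g coupled to `r_g` (`ω = 0.15 r` with 0.15 lognormal noise, clipped
  to [0.02, 0.9]): fast groups also tolerate more amino-acid change.
  This plants purifying selection everywhere plus the rate/variation/ω
  correlation structure the pipeline is meant to recover;
- gene loss: all 11 NDH genes removed from one clade of 4–7 taxa
  (ndh-like clade loss) and `rpl33` from two further random taxa
  (sporadic single-gene loss). Loss events are recorded in the truth
  object; genes left with < 4 taxa are flagged unusable.

GD's anti-correlation with rates is planted at the construction level:
gene trees are estimated (JC69 + neighbor joining) from the simulated
alignments, so low-signal genes (short length × low rate) yield noisy
topologies far from the species tree while high-signal genes recover
theirs — the same mechanism believed to drive the empirical pattern.

What the benchmark does **not** emulate: indel evolution and alignment
error, among-gene linkage beyond the shared species tree, recombination
or introgression, base-composition heterogeneity among lineages, and ML
gene-tree inference (NJ is the stand-in). Passing tests therefore show
the pipeline's statistics behave correctly under a clean, plastome-like
generating process — not that any particular empirical data set will
show the same effect sizes.

## Determinism and numerical choices

Every stochastic stage derives its own sub-seed from the single run seed
by hashing the stage name (`sha256(f"{seed}:{name}") mod 2^31`), so
stages are independently reproducible and identical configurations give
byte-identical TSV outputs. NJ breaks Q-matrix ties at the lowest
(row, column) pair; JC distances are capped at d_max = 5 substitutions/
site so saturated pairs stay finite without dominating joins; NJ's
negative branch-length estimates are clamped to 0. Newick output uses
shortest round-trip float formatting, preserving lengths exactly.
Partition tables use 1-based inclusive coordinates.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks run exhaustively at n = 5 (all 15 topologies)
and on 200 random 8-tip pairs; MSC calibration uses 10 000 replicates
per branch length; ω recovery uses 20 seeds × (20 taxa, 300 codons);
the end-to-end planted-structure check runs the full default benchmark
(26 taxa, 76 genes) across 20 seeds. Smaller configurations (8–16 taxa,
6–40 genes) are used where a property does not depend on the full size.
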