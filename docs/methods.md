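# Methods

## Triplet discordance model

For three ingroup taxa with species topology ((A,B),C) and an outgroup used
only for rooting, each locus is reduced to a rooted triplet: the ingroup
cherry and the internal branch length *t* between the first and second
coalescence. Gene trees are pruned to the four labels (branch lengths along
removed paths are summed), the quartet's single internal edge is read off,
and the cherry is the side not containing the outgroup. Multifurcating or
zero-length cherries are recorded as unresolved; they enter no fit and are
tallied separately.

Under the multispecies coalescent, a discordant topology's internal
branches are exponential with mean one coalescent unit. Introgression adds
a cohort whose branches are delayed by the time between the species split
and the gene-flow event, modelled as a shifted exponential with the same
rate. The two fitted models per topology are

- ILS-only (one parameter): f(t) = (1/λ) e^(−t/λ), with MLE λ̂ = mean(t),
- mixture (three parameters): f(t) = π (1/λ) e^(−t/λ)
  + (1−π)(1/λ) e^(−(t−C)/λ)·1[t ≥ C],

and the decision uses ΔBIC = BIC2Dist − BIC1Dist with BIC = k ln n − 2 lnL:
ΔBIC > 10 → ILS only; ΔBIC < −10 → mixture (introgression); otherwise
indistinguishable. A topology classified as mixture contributes π̂ × count
ILS loci to the triplet's ILS estimate, all other topologies contribute
their full count; only topologies discordant with the species tree can set
the introgression flag, because the species topology's branches are
intrinsically delayed by the species-tree internal branch and always prefer
a shifted component.

Loci with t = 0 are kept in topology tallies but excluded from fitting (the
shifted component's support boundary makes the density ill-behaved there);
their count is reported.

### Fitting the mixture

π and λ have closed-form EM updates (π ← mean responsibility,
λ ← mean(t) − C·mean(r₂)). C is updated once per EM iteration by a
golden-section search on the log-likelihood slice lnL(C | π, λ) over
[0, max t], accepted only if it does not decrease the observed-data
likelihood, so the iteration trace is monotone non-decreasing. The search
starts from C = 0, where the mixture collapses to the exponential and
lnL2 = lnL1 exactly — this guarantees the nesting inequality lnL2 ≥ lnL1.

The golden-section step assumes the slice is unimodal. That assumption is a
deliberate regularizer: the mixture likelihood is discontinuous in C at
every data point, and its global maxima on unstructured (pure-exponential)
data place the support boundary inside the data bulk, harvesting several
log-likelihood units from sampling noise — the classic shift-mixture
pathology. An exhaustive profile of C (grid over data quantiles plus local
refinement) reliably finds those spurious optima and would call genuinely
ILS-only data "indistinguishable" most of the time; the conservative path
keeps null gains small while still locking onto a genuinely shifted cohort,
whose likelihood gain is one to two orders of magnitude larger. For the
same reason the default is a single deterministic start (π₀ = 0.5,
λ₀ = mean); best-of-N restarts (available via `restarts`) systematically
re-find the pathological optima on null data and are only useful when a
genuine fit is suspected of being a local optimum. Convergence is declared
when the per-iteration likelihood gain drops below `tol` (default 1e-8,
`max_iter` 500); non-convergence warns and returns the best fit so far.

Measured operating characteristics at n = 500 loci per topology, 50 seeds:
pure-exponential data → ils_only in ~74–82% (the remainder
indistinguishable, never mixture); shifted data (π = 0.5, C = 3λ) →
mixture in 100%. On planted mixtures (π = 0.3, λ = 1, C = 2, n = 2000) the
EM recovers π with mean absolute error ≈ 0.01. The fit is exactly
scale-equivariant: scaling all t by c scales λ̂ and Ĉ by c and leaves π̂ and
the classification unchanged, so substitutions/site and coalescent units
are interchangeable.

Per-topology minimum for fitting: 10 loci with t > 0; smaller topologies
carry ILS weight 1.0 with a logged caveat. Percentages are reported to two
decimals; the species-topology share also as a rounded integer.

## Synthetic data

The simulators define the package's test conditions; their defaults are
chosen to be realistic for a plant phylogenomics setting, not calibrated to
any particular species (the real coalescent parameters of the study system
are unknown).

**Triplet gene trees.** Per locus, the sister pair coalesces within the
species-tree internal branch T2 with probability 1 − e^(−T2) (waiting time
Exp(1) truncated at T2); otherwise all three lineages enter the ancestral
population, where the first coalescence is Exp(rate 3) over a uniformly
random pair and the second Exp(1). With probability γ the recipient lineage
follows the donor's history (the donor–recipient pair becomes the locally
sister pair) — a locus-level pulse, the simplest mechanism producing the
delayed cohort the mixture assumes. The internal branch is the time between
the two coalescences; trees are emitted as Newick with branch lengths
scaled by `subst_scale` (coalescent units → substitutions/site), the
outgroup attached `t_root` above the root coalescence, and the sister-pair
species divergence fixed at 1.0 coalescent unit before present (cosmetic:
it cancels from every internal branch). Ground-truth observations carry t
in coalescent units. Closed-form check: the concordant-topology probability
is 1 − (2/3)e^(−T2). Not modelled: sequence-level noise (trees are exact),
within-locus recombination, demographic change.

**Branch-length mixtures.** Direct draws from π·Exp(λ) + (1−π)·(C + Exp(λ))
for estimator-recovery experiments.

**Orthogroup matrices.** Category counts are apportioned exactly
(largest-remainder) from the requested weights; presence counts are drawn
uniformly within each category's band and copy numbers uniformly in
[1, max_copies]. Recovery of planted fractions is therefore exact, which
tests the classifier's binning, not sampling noise.

**SV tables.** Planted deletions appear (with optional start jitter) in
every "present" genome and nowhere else; background SVs of all seven types
are placed uniformly at least 1 kb away from planted intervals, so at full
reciprocal overlap the candidate filter's answer is the planted list by
construction.

**LTR pairs.** Two copies of a random ancestral sequence evolve
independently for `true_time` years under a two-rate (K80) process with
total rate μ per site per year and transition:transversion rate ratio
α/(2β) (default 2.0; 0.5 makes all three substitution directions
equiprobable), using the exact K80 transition probabilities rather than
event-by-event simulation. The K2P estimate of the pair divergence then
recovers 2μ·true_time in expectation.

What passing these tests shows — and does not show — about real data: the
pipeline's statistics are correct under their own generative assumptions;
real alignments add alignment error, rate variation, gene-tree estimation
error and recombination, none of which the generators emulate.

## Alignment windows

Windows of `window_size` (default 1000 bp) start at column 0 with stride
`window_size + gap_between` (default gap 20 kb, to reduce the chance of a
window spanning a recombination breakpoint); terminal partial windows are
dropped. Soft-masked (lowercase) bases are uppercased on input. A site is
parsimony-informative when at least two distinct unambiguous bases each
occur in at least two taxa (gaps and ambiguity codes never count as
states); windows with fewer than `min_informative` (default 10) such sites
are removed — the boundary is keep-at-exactly-10. Where the windows start
relative to a chromosome and how partial terminal windows were handled are
not uniquely determined conventions; the choices here (start at 0, drop
partials) are fixed and documented rather than configurable.

The per-window neighbour-joining tree is a deliberately simple stand-in so
the pipeline runs self-contained: pairwise K2P distances with pairwise
deletion of gapped/ambiguous columns, `skbio.tree.nj` with negative branch
lengths clamped to zero, taxa sorted for deterministic tie-breaking. Real
analyses should supply externally estimated (e.g. maximum-likelihood) gene
trees; tree inference quality is out of scope.

## Pan-genome families

Presence is count ≥ 1; paralog counts are kept only for gene-count
reporting. With G genomes: core = present in all G; private = present in
exactly 1; softcore = presence ≥ ceil(softcore_fraction × G) but < G
(default fraction 0.90 — at G = 13 the softcore band is exactly presence
12, so core + softcore reproduces a "present in more than 11 genomes" bin);
dispensable = the rest. Private takes precedence over softcore in the
degenerate small-G case where the bands would otherwise touch. Saturation
curves add genomes in `n_permutations` (default 100) random orders; pan
(union) counts are non-decreasing and core (intersection) counts
non-increasing within every single permutation, and that per-permutation
monotonicity is asserted in tests, not just on averages.

## Structural variants

Assemblytics-style BED tables are parsed with type names normalized to the
seven canonical forms; coordinates are 0-based half-open throughout (GFF3's
1-based closed intervals are converted on read). Cross-genome equivalence
of two SVs of the same type on the same reference uses reciprocal overlap:
the shared interval must cover at least `min_reciprocal_overlap` (default
0.5) of both records; r = 1.0 gives exact-coordinate matching. Insertions
occupy a 1-bp anchor on the reference, so they match by breakpoint distance
≤ (1 − r) × min(size_a, size_b) instead.

Candidate deletions are single-linkage clusters (union-find over the match
relation) of present-group deletions; a cluster qualifies only if every
present-group genome contributes a record ("occurring in" all of them) and
no absent-group deletion matches any member. The representative interval is
the union of the members, and the result is invariant to genome order
within groups. Planted deletions jittered by at most (1 − r) × size are
still recovered. Proximal genes are those whose span lies within
`max_distance` (default 2000 bp, inclusive) of the candidate interval,
distance 0 when overlapping, strand ignored.

## LTR insertion dating

K2P distance with pairwise deletion: with transition fraction P and
transversion fraction Q over comparable sites,
K = −½ ln((1 − 2P − Q)·√(1 − 2Q)); a non-positive log argument raises a
saturation flag and excludes the element from profiles (never silently
dropped from per-element tables). Insertion age is T = K/(2μ). μ is a
required argument everywhere — there is no defensible universal default;
the examples use 1e-8 substitutions/site/year as a documented illustration.
Age profiles are Gaussian KDEs (`scipy.stats.gaussian_kde`; `bandwidth`
forwarded as `bw_method`) evaluated on a grid 25% beyond the data range,
with modes reported as local maxima ordered by density; close cohorts merge
under the default (Scott) bandwidth, so resolving known multimodality needs
a smaller explicit bandwidth. A superfamily with a single distinct age
degenerates to a spike at that age.

## Problem sizes

The validation experiments use 50 000 simulated loci for the coalescent
closed-form check, 30 seeds × 2000 draws for mixture-weight recovery,
2 × 50 datasets × 500 loci for the ΔBIC operating characteristics, 100
random matrices plus one 20 000-family planted matrix for the pan-genome
oracle, 6 genomes with 5 planted deletions for the SV filter, and 30 seeds
of 5-kb LTR pairs for age recovery — sizes at which Monte-Carlo error is
well below the assertion tolerances while the whole suite stays fast.

## Known limitations

- The ΔBIC rule's null specificity is bounded by the shift-mixture
  pathology described above: a minority of genuinely ILS-only topologies
  land in the indistinguishable band (they are never called mixture, so
  introgression false positives remain rare).
- The simulator's introgression pulse swaps lineage history at the species
  divergence; it does not model varying pulse times, and C in the fitted
  mixture is therefore interpreted qualitatively.
- K2P dating ignores rate variation among sites and elements; ages are only
  as good as the supplied μ.
- The NJ stand-in is not a substitute for likelihood-based gene trees in
  real analyses.
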