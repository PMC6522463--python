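# Methods

This note records the scientific conventions the package implements, the
default parameter values and why they were chosen, and the limits of the
simulator used for validation.

## Candidate evaluation

A *candidate species* is a labelled group of specimens in a
`SpeciesHypothesis`.  Each candidate is evaluated against a *comparator*:
the sister candidate read off the combined-data tree when the candidate
is monophyletic there and its sister clade maps cleanly onto one other
label, else the nearest candidate by total mean cross-pair SNP distance.
The five criteria, their verdicts (`pass` / `fail` / `not_assessable`)
and defaults:

- **monophyly** (`support_threshold = 0.95`).  The candidate must be a
  clade, with node support at or above the threshold, in the
  combined-data tree *and* in at least one single-locus tree; when the
  comparator has two or more specimens, its monophyly is required in the
  same trees (reciprocity).  A clade whose subtending node carries no
  support value counts as resolved — absence of annotation is not
  treated as absence of support, since topology-only trees (e.g. the
  built-in neighbour-joining concatenation tree) would otherwise veto
  every candidate.  Support values in Newick input may be posterior
  probabilities in [0, 1] or percentages in (1, 100]; percentages are
  divided by 100, and anything outside [0, 100] is an error rather than
  a silent clamp.
- **genealogical concordance**.  The candidate fails if any single-locus
  tree contains a *supported* split incompatible with the candidate
  being exclusive: a split such that both of its sides intersect both
  the candidate and its complement.  Unsupported structure never
  contradicts — poorly resolved gene trees are uninformative, not
  counter-evidence.  Note the asymmetry with monophyly: certifying
  exclusivity tolerates missing supports, while refuting it requires
  explicit support, so both criteria err on the side of the data that is
  actually annotated.
- **distinctness** (`min_snp_per_locus = 3`).  The minimum cross-pair
  SNP distance between candidate and comparator must be at least three
  ("more than two SNPs") at *every* locus that contains members of both
  groups.  Distances are counted over columns where both sequences carry
  unambiguous bases; pairs with zero such overlap are excluded from the
  statistics and reported, not counted as zero distance.
- **minimal sampling** (`n_min = 3`).  Fewer than three specimens leave
  within-group variation unassessable; singletons and doubletons fail
  this criterion but, deliberately, are never merged away on its account
  alone — undersampling is a reason to collect more material, not to
  lump.
- **polygenic differentiation** (`min_coverage_fraction = 1.0`).  The
  candidate must share at least one synapomorphy with respect to the
  comparator at a strict majority of the highly variable loci (default
  ITS, EF-1α, RPB1, RPB2; LSU is too conserved to demand diagnosis
  from).  A *synapomorphy* is an alignment column at which every covered
  candidate member carries one unambiguous base and every covered
  comparator member carries a different one, with at least
  `min_coverage_fraction` of each group covering the column.  The
  default requires full coverage; relax it (e.g. to 0.5) for panels with
  partial, fungarium-grade sequences.

Ambiguity codes (IUPAC) and gaps are *missing data* by default: they
never create variation, never count toward distances and never qualify
as synapomorphic states.  An optional `ambiguity="intersect"` mode
scores two IUPAC codes as different only when their base sets are
disjoint (R vs A matches; R vs C differs), for panels rich in
heterozygous positions.

## Merge recommendation

Failing candidates are processed by ascending total minimum distance to
their comparator (lexicographic tie-break).  A merge partner is taken
from the labels appearing in contradiction witnesses (most frequent
first), else from a comparator with which the candidate shares zero
synapomorphies; the partner must itself be failing, so a well-supported
species is never absorbed into a failing neighbour.  One merge is
applied per round, everything is re-evaluated, and the loop stops when
no candidate fails, no partner exists, or after (number of labels − 1)
merges — the maximum possible for any sequence of lumpings.  The report
lists the merged original labels and the criteria evidence for the final
candidate set.

## Single-locus determination (barcoding)

Diagnostic sites between two labels are exactly the synapomorphic
columns of the reference panel; an optional wider panel flags a site as
unstable when any of its sequences carrying one of the two labels
violates the diagnostic state.  A query — pre-aligned to panel
coordinates, possibly truncated — is assigned a label only if every
diagnostic site it covers with an unambiguous base votes for the same
label (unanimity, not majority: a single conflicting site may signal
introgression and warrants caution).  Otherwise it is `UNDETERMINED`
with a reason: `no_coverage`, `ambiguous_base` or `conflicting_sites`.

## The simulator

Validation data come from a hand-written multispecies coalescent:
within each species-tree branch the `k` lineages present coalesce at
rate `k(k−1)/2` per coalescent unit, survivors are passed to the parent
population, and everything merges above the root.  Sequences evolve
from a uniform random root under finite-sites Jukes–Cantor with
per-branch substitution probability `p = 0.75·(1 − exp(−4/3·(θ/2)·b))`,
so that the expected pairwise within-species difference per site equals
θ; an infinite-sites mode gives every mutation a fresh column and
errors out rather than silently recycling columns.  Default loci mimic
the relative variability of the five-locus panel (ITS most variable,
LSU least).  Branch lengths are in coalescent units throughout; the
simulator does not model recombination within loci, selection, gene
flow after divergence, rate variation among sites, or alignment error.
Uncertainty-free "true" gene trees carry support 1.0; the combined-data
tree is neighbour joining on summed per-locus SNP distances and carries
no supports.

Determinism: every random stream is derived from a single seed via
`numpy.random.default_rng([seed, stream])`, with fixed stream indices
per locus for tree, alignment and truncation draws, so datasets are
bit-reproducible across runs and platforms.

## Validation choices

The test suite checks the column, distance and split logic against
deliberately naive re-implementations (per-column set logic; split
enumeration by graph edge removal) on hundreds of random alignments and
trees, and calibrates the simulator against closed-form coalescent
expectations: mean pair coalescence time of 1.0 coalescent unit, and
Watterson's `S/(L·a_{n−1})` recovering θ.  Problem sizes (alignments up
to 8×50 for oracle checks, 2000/200 simulation replicates) keep the
whole suite under a minute on one CPU while leaving Monte-Carlo noise
several standard errors inside the asserted tolerances (5% for the
TMRCA mean, 15% for Watterson recovery).

## Limitations

- The concatenation tree is topology-only; for real studies supply a
  Bayesian or likelihood combined-data tree with supports.
- Sister identification from the combined tree requires the sister
  clade to map onto exactly one candidate label; otherwise the nearest
  candidate by distance is used, which can differ from the true sister
  under heavy incomplete lineage sorting.
- The criteria assume pre-aligned, per-locus FASTA with consistent
  specimen identifiers across loci; alignment itself is out of scope.
- Verdicts are per-candidate relative to one comparator; a candidate
  distinct from its sister but identical to a distant label would need
  a second pass with a revised hypothesis to be caught.
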