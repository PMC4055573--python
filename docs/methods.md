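# Methods

## The model

`phylohmm` scans a multi-genome alignment with a hidden Markov model
whose hidden states are pairs *(parental class, rooted gene-tree
topology)*.  The parental classes are the trees displayed by a
phylogenetic network relating the sampled species — one class for
vertical descent, one (or more) for introgressive descent — supplied by
the user as a `ParentalForest`: an ordered list of rooted trees with
branch lengths in coalescent units (a unit is the time in which one
pair of lineages in a population coalesces; 2N generations for haploid
lineages) plus an allele-to-species map and the set of class indices
flagged introgressed.

Within a class, the relative plausibility of each gene-tree topology is
its exact probability under the multispecies coalescent given that
class's parental tree.  These probabilities are computed by
enumerating coalescent histories: every assignment of gene-tree
coalescences to species-tree branches consistent with both the species
ancestry of the alleles and the gene-tree partial order contributes a
product over branches of `g_uv(t) * w / d`, where `g_uv(t)` is Tavaré's
probability that `u` lineages leave `v` after duration `t`, `d` counts
the possible coalescence sequences and `w` the orderings consistent
with the topology (a hook-length count over the in-branch event
forest).  The enumeration is exact, covers multiple alleles per
species and unsampled species, handles zero-length branches (the
star-tree limit returns exactly uniform topology probabilities), and is
capped at 6 alleles.  For three alleles the implementation reproduces
the classic closed form — each incongruent topology has probability
`exp(-t)/3` — to 1e-9, and it is cross-checked against coalescent
simulation (msprime) in the test suite.

Transitions couple this coalescent structure with three scalar
parameters: γ (probability of switching parental class between adjacent
sites, split uniformly when there are more than two classes), s1
(genealogy-switch factor out of a state congruent with its parental
tree) and s2 (out of an incongruent state).  Rows are completed by a
non-negative diagonal remainder, so the matrix is exactly
row-stochastic for any valid parameters; the start state's outgoing
distribution is the normalised gene-tree probability over all states.
The paper trail for one ambiguity: the published description defines
switch factors only for congruent→incongruent and
incongruent→congruent moves; this implementation applies s2 to *all*
moves out of an incongruent genealogy, which reproduces both published
definitions with two parameters.

Emissions are pruning-algorithm likelihoods of alignment columns under
a GTR model whose rate matrix is normalised to mean rate 1, so
gene-tree branch lengths are identifiable as expected substitutions per
site.  `N`, gaps and IUPAC ambiguity codes are marginalised (an
all-missing column has likelihood exactly 1).  Distinct alignment
columns are collapsed to patterns once; forward, backward (Rabiner
scaling) and Viterbi (log space, ties to the lowest state index) run as
numba-compiled kernels over the pattern indices.

## Branch-length sharing between states

Because GTR is reversible, a rooted genealogy's likelihood depends only
on its unrooted topology, so states whose genealogies differ only in
root placement are emission-equivalent and share one branch-length
block.  Three sharing policies are supported:

* `share="unrooted"` (default): one block per unrooted topology across
  the whole model — 3 blocks for the 31-state two-species scan model.
* `share="unrooted_class"`: one block per (parental class, unrooted
  topology) — 6 blocks for the same model.  **The scan pipeline uses
  this.**  With a two-species network both parental trees are
  topologically identical, so fully shared blocks make vertical-descent
  and introgressed states emission-identical and leave class
  discrimination to the transition weights alone; measured on simulated
  data this collapses detection almost completely.  Per-class blocks
  let the introgressed class fit the short donor–recipient distances
  that are its actual signature.
* `share="rooted"`: one block per rooted topology.  Needed for the
  three-taxon model, where *all* rooted genealogies reduce to the
  single unrooted 3-leaf topology: under any reversible model fully
  shared blocks make every genealogy state emission-identical and the
  likelihood exactly flat in γ/s1/s2.  The transition-parameter
  recovery experiment therefore generates and fits with rooted blocks.

## Fitting

All free scalars — γ/s1/s2, five GTR exchangeabilities (GT fixed at 1),
three stick-breaking frequency coordinates, parental branch lengths
(only edges that can influence topology probabilities: internal edges
plus leaf edges of species with ≥ 2 sampled alleles), and the
branch-length blocks — are optimised by coordinate ascent, each scalar
with Brent's bounded method on its profile log-likelihood.  Bounds:
probabilities [1e-6, 1−1e-6] (optimised on a log10 scale, since the ML
class-switch probability is often 1e-4 or smaller and a linear-scale
bounded search cannot resolve it), substitution-unit lengths
[1e-6, 10], coalescent-unit lengths [1e-3, 20].  Sweep order: HMM
parameters, GTR, parental lengths, blocks.  Convergence: round
improvement < 1e-6 log-units (default) or `max_rounds`.  Restarts draw
starting scalars uniformly over the (transformed) bounds from seeds
derived from the single run seed; restart 0 keeps the supplied model.
Moving a transition scalar never recomputes emissions; moving one
block's length recomputes only that block's pattern likelihoods.  An
alignment that carries no information (e.g. all missing) is detected by
probing each profile at its bounds and reported as `flat`.

The scan treats the parental trees as **fixed** by default.  With
topologically identical parental classes the introgressed class is
distinguished only by its divergence time, and profiling that time on
introgression-free data drifts it to the background value (the merged
model gains about log 2 by not committing to a class), after which the
class posterior is uninformative at 1/2.  Freeing the parental group is
still possible (`FitConfig.free_groups`), but it is not part of the
default protocol; this identifiability limit is intrinsic to the
model, not to the optimiser.

Initialisation for scans: GTR starts at the empirical base composition
with unit exchangeabilities; background-class blocks from three-/
four-point distance formulas on Jukes–Cantor-corrected pairwise
distances; introgressed-class blocks from the network hypothesis
itself — a clock rate ν estimated as (mean cross-species
distance)/(2·t_background) converts the two parental divergence times
into expected edge lengths, and each mixed-topology block is committed
to one recipient allele playing the migrant (its edge and its in-split
donor partner short at ν·t_intro, the other recipient allele long at
2ν·t_bg).  This is purely a starting point for the ascent, but it
matters: it makes migrant segments of either phase prefer some
introgressed-class state from the first iteration.

## The synthetic-data generator

The simulator draws from a structured coalescent with two in-group
populations A and B (two haploid samples each; optional single
outgroup), isolation after their split, and unidirectional migration
from B into A (forward in time; implemented backwards as A-lineage
jumps into B) at scaled rate m during a window
[t_mig_start, t_mig_end].  Defaults are anchored on consensus rodent
estimates: in-group divergence 1.5 Mya at 2 generations/year with
Ne = 50,000 gives, in units of 2N generations, t_split_ab = 30 and
t_split_outgroup = 60; θ = 4Nμ = 4.5e-4 per bp (the commonly cited
4.5e-9 substitutions/site/year, ≈ 1.35% in-group divergence);
recombination ρ = 5.6e-4 breakpoints per bp (0.56 cM/Mb), i.e. ≈ 57
segments per 100 kb; sequence length 100 kb; migration windows
(0, 0.25) and (0, 0.5) and rates m ∈ {0, 0.5, 2.0} per lineage per
unit, chosen so the low setting introgresses roughly a fifth of sites
and the high setting about half.

Recombination uses sequentially independent segments: Poisson
breakpoints, one independent genealogy per segment.  This ignores the
correlation between neighbouring genealogies of a true ancestral
recombination graph — adjacent segments in real data share most of
their coalescent history, so real tracts are smoother than simulated
ones — and the generator has no selection, growth or gene conversion.
An ms-format tree reader (`[length]newick` lines) is provided so an
external simulator's output can be substituted.  Sequence evolution is
Jukes–Cantor with branch lengths (θ/2) × coalescent time.

Each segment carries an exact truth label: *migration evidence* is a
clade of exactly one A sample plus ≥ 1 B samples whose coalescence time
lies strictly inside the migration window.  Such a clade cannot arise
under isolation (soundness: at m = 0 the label is identically false),
and migrant lineages that coalesce only after the window closes are not
counted, so the labelled site fraction is a conservative lower bound on
the migrant-affected fraction.  Passing the grid comparison therefore
shows the scan detects at least the unambiguously-migrant sites and
stays silent on the control — it does not certify calibration of the
posterior on real, ARG-correlated, selected or mis-specified data.

## Validation experiments and problem sizes

* **Migration grid** (`pipeline.migration_experiment`): rates
  {0, 0.5, 2.0}, window (0, 0.25), 20 replicates × 100 kb per rate.
  Per replicate the model is initialised as above and fitted with a
  two-phase scaled-down protocol: one coordinate sweep over the
  introgressed-class blocks, then two sweeps over γ/s1/s2; GTR and
  background blocks stay at their data-driven initial values (the data
  are Jukes–Cantor, which the initialisation already matches).
  Reported per replicate: % sites with introgression posterior > 0.9,
  the truth-bound %, and the region calls.
* **GTR recovery** (`pipeline.gtr_recovery_experiment`): full fits
  (γ/s1/s2 + all GTR parameters + all blocks, two rounds) on
  Jukes–Cantor replicates; recovered stationary frequencies are within
  ±0.003 of 0.25 at 100 kb.
* **Transition-parameter recovery**
  (`pipeline.transition_recovery_experiment`): alignments of 10⁴ sites
  sampled from a known 7-state model (γ = 0.05, s1 = 0.1, s2 = 0.3,
  rooted-share blocks with cherry/far-leaf lengths 0.05/0.20 and
  internal 0.15 substitutions/site); γ, s1, s2 re-fitted with the
  structural parameters held at truth, 3 restarts.  γ and s1 recover
  with median absolute errors well under 0.05; s2's profile is nearly
  flat over ±0.2 at this alignment length and emission contrast, so
  its median error sits at ≈ 0.057 — a sampling-variance limit of the
  design (the hill-climb itself is consistent: restart final
  likelihoods agree to ≪ 0.1 units).

## Numerical choices

* Forward/backward: per-column scaling in linear space; forward and
  independently-scaled backward totals agree to 1e-8 and are checked.
* Viterbi ties break to the lowest state index.
* Topology probabilities must sum to 1 within 1e-9 over the enumerated
  set; a NaN anywhere raises immediately with the offending class.
* `expm` of the GTR rate matrix via the symmetric similarity transform
  (exact reversibility, no Padé iteration), clipped at 0 and
  row-renormalised to absorb roundoff.
* Model JSON serialisation round-trips bit-exactly (same log-likelihood
  to the last ulp), because block structure is rebuilt deterministically
  and floats pass through `repr`.
* Region calling: maximal runs with posterior strictly above the
  threshold (default 0.9), runs separated by ≤ `merge_gap` sites merged,
  runs shorter than `min_sites` (default 2) dropped; coordinates are
  0-based half-open, genomic when the alignment carries positions
  (1-based in the haplotype TSV dialect, converted on input).

## Known limitations

* Gene-tree probabilities on MUL-trees (needed for networks that cannot
  be decomposed into parental trees, e.g. multiple reticulations with
  multiple sampled alleles tracing different parents) are not computed;
  `network_to_multree` provides the conversion and full allele-mapping
  enumeration for inspection and export only.
* Topologies (parental and gene trees) are fixed inputs; only branch
  lengths are estimated.  Network topology search is out of scope.
* Enumeration-based coalescent probabilities are limited to 6 alleles.
* No rate variation across sites (GTR only, no +Γ), no amino-acid
  models.
* The truth-label comparison is only as strong as the generator's
  assumptions (independent segments, neutral evolution, known network).
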