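# Methods

## Experimental model

A mutation-accumulation (MA) experiment minimises selection by forcing each
of `L` independent lineages through repeated single-colony bottlenecks.
Between consecutive bottlenecks a colony grows from one cell to its final
size, contributing `N = log₂(final cells)` generations; after `T`
bottlenecks a lineage has accumulated mutations over `N·T` generations.
The pooled rate estimator is `μ = m/(L·N·T)` mutations per genome per
generation; dividing by the sequenced genome size `G` gives the
per-nucleotide rate, and `μ′ = m/(L·D)` expresses the rate per genome per
day (`D` total days), which distinguishes replication-coupled from
clock-like mutagenesis when the two environments divide at different
speeds.

The packaged study designs are: aerobic `L=24, N=25, T=180, D=180`;
anaerobic `L=24, N=24, T=144, D=432` (anaerobic bottlenecks every three
days). The default sequenced genome size, 4.50 Mb, is back-derived from
the published per-genome/per-nucleotide rate pairs; it is a configuration
constant, not a measurement made here.

Because every bottleneck passes through a single cell, the number of
mutations a lineage fixes per bottleneck is very nearly Poisson; the MA
simulator therefore draws per-lineage, per-class counts from
`Poisson(rate·N·T)` without simulating within-colony genealogy. This is
the one deliberate simplification of the generator's growth model.

## Uncertainty and comparisons

Each lineage yields its own rate (zero-mutation lineages contribute zeros);
the SEM across the `L` per-lineage rates uses the sample standard deviation
(n−1). Environment contrasts use the Mann-Whitney U test on the
per-lineage vectors, reporting U for the first sample and a two-sided p:
exact enumeration when both samples have ≤8 observations and no ties,
otherwise the tie-corrected normal approximation.

## Spectrum and positional tests

Substitutions are recorded on the conventional top strand and collapsed
into six strand-symmetric pair classes. The chromosome's two replichores
are the arcs ori→ter (clockwise) and ter→ori; on the clockwise replichore
the top strand templates lagging-strand synthesis, on the counter-clockwise
replichore the leading strand. The strand-bias test therefore classifies
each substitution by its pair class and literal top-strand focal base,
splits the counts by replichore, and compares them with a 1-df Pearson
chi-square against an expectation proportional either to replichore
lengths (default, matching the published construction) or to per-replichore
focal-base counts (`mode="composition"`, which corrects for compositional
skew between the arms; the two coincide for a compositionally uniform
genome). Macrodomain tests compare observed placement against
length-proportional expectations with df = #macrodomains − 1. No
continuity correction is applied anywhere, and p-values are unadjusted, in
both cases following the original analysis.

All coordinates are 1-based with intervals closed on the left, open on the
right; arcs wrap modularly around the circular chromosome, and a boundary
position belongs to the interval starting at it.

The packaged REL4536-like geometry reproduces the published replichore arc
lengths (2.06 Mb clockwise, 2.54 Mb counter-clockwise on a 4.6 Mb circle)
but places the origin at coordinate 1 and uses synthetic macrodomain
boundaries, because the strain's exact coordinates are not published. Any
analysis of a real genome should supply its own geometry file.

## Selection diagnostics

The neutral dN/dS expectation enumerates, for every sense codon weighted by
its genome-wide usage, the nine single-nucleotide neighbours, weighting
each transition `2R` and each transversion `1` (each codon position offers
one transition and two transversions, so the implied event-level
transition:transversion ratio equals the observed `R`); stop-gaining
changes count as nonsynonymous and stop codons are excluded from usage.
For glycine-only usage (GGG) this gives exactly 2.0 at every `R`, a useful
analytic anchor.

Two caveats. First, the packaged codon-usage table is a synthetic
stand-in assembled from published E. coli genomic usage frequencies rather
than counted from the study strain's annotation; `codon_usage_from_annotation`
rebuilds the table from any annotated genome. Second, this construction
does **not** reproduce the published expectations of 3.10 (R=2.08) and
3.05 (R=1.09): it yields ≈2.4 and ≈2.8, and is monotonically *decreasing*
in `R`, whereas the published pair increases with `R`. Under the standard
genetic code transitions are more often synonymous than transversions, so
*any* fixed transition/transversion weighting decreases with `R`; the
published construction therefore cannot be a pure ts/tv-conditioned
weighting of this kind, and its exact form is not recoverable from the
published description. The discrepancy is reported rather than tuned away;
an exploratory `weighting="uniform"` mode (ignore `R`) is provided for
sensitivity analysis and gives ≈3.25 with the packaged usage.

The coding/non-coding placement test splits observed substitutions
coding:noncoding and compares against the genome's protein-coding to
non-coding ratio (`ratio : 1`) with a 1-df chi-square. "Coding" means
annotated CDS only. The published genome-wide ratio 7.83 can be supplied
directly when no annotation is at hand.

## Fluctuation assays

The Luria-Delbrück pmf is computed with the Ma-Sandri-Sarkar recursion
`p₀ = e^(−m)`, `p_r = (m/r)·Σ_{i<r} p_i/(r−i+1)`. The likelihood of a
counts vector is maximised over `ln m ∈ [ln 10⁻⁴, ln 10²]` by
golden-section search (tolerance 10⁻⁶); counts at or above a cap (default
150) are pooled into a single tail category with the complementary tail
probability, which keeps jackpot cultures from dominating runtime without
discarding them. All-zero counts give the boundary estimate `m̂ = 0`; an
experiment whose counts all sit at the cap is flagged unreliable.

The default 95% interval is the log-normal approximation used by the
FALCOR lineage of tools, `exp(ln m̂ ± 1.96·σ)` with
`σ = 1.225·m̂^(−0.315)/√C` for `C` cultures; a profile-likelihood interval
is available as an alternative. In seeded coverage simulations at `m=2`,
`C=48` the log-normal interval is mildly conservative (~96–97% empirical
coverage).

Rate conversions assume perfect plating, no phenotypic lag and neutral
mutants: per-locus rate `m̂/N_final`, per-nucleotide after dividing by the
number of resistance-conferring sites (default 20), per-genome after
multiplying by genome size. `N_final` is user-supplied.

### LD simulator

Cultures grow from `n0` to `n_final` cells (`n_final − n0` divisions).
Mutational events per culture are Poisson with mean `μ·(n_final − n0)`;
divisions occur at population sizes uniform on `(n0, n_final)`
(asynchronous growth), and a clone born at population size `n` expands
deterministically to `⌊n_final/n⌋` cells. In the `n_final ≫ n0` limit
this yields the classic clone-size law `P(size=k) = 1/(k(k+1))` and hence
the MSS pmf itself. Synchronous generation-by-generation doubling was
rejected as a growth model because it quantises clone sizes to powers of
two and produces a mutant-count distribution measurably different from the
Luria-Delbrück distribution the estimator assumes.

## Synthetic data: what it does and does not emulate

The MA generator reproduces the statistical structure the analyses consume:
Poisson class counts at the study's rates (defaults encode the published
class totals — 124/158 mutations, ts/tv 2.08/1.09, 33/65 SVs, 17/20
indels — under the study designs), substitutions placed on focal-base
eligible sites with per-class clockwise:counter-clockwise odds, SVs placed
with macrodomain weights (threefold Ter enrichment by default) and
mediated by IS elements drawn proportional to copy number × activity
(IS150 tenfold more active anaerobically; IS2/IS30/IS600/IS911 silent),
and indels with a 51.4% slippage fraction. The strand-bias odds apply to
both orientations of a pair class jointly, so simulated bias is symmetric
in the focal base. The generator does not emulate local sequence-context
rate variation, insertion-site hotspots, mutator phenotypes, or
correlations between lineages — so passing recovery tests demonstrates
estimator correctness under the stated model, not robustness to those
real-data features. IS copy numbers in the default table are synthetic,
keeping only the published ordering (IS1 most abundant, >4× IS150).

Generated genomes (toy and full-size) are uniform random sequence with
tiled CDS steering toward a target coding fraction; codon usage and
composition are realistic only in aggregate.

## Problem sizes and numerical choices

Simulation-backed checks use a 200 kb random genome with uneven
replichores (rates are genome-size-free, so this loses nothing), 500
replicates for type-I calibration and MSS-MLE recovery, 10⁴ cultures for
pmf agreement, and 25 replicates for the strand-bias power check at a
configured effect of 3:1 odds on ~60 substitutions. Chi-square tests
refuse non-positive expected counts; ratio estimators signal
zero-denominator cases distinctly (infinite ts/tv, undefined dN/dS) rather
than returning sentinel values. All generators are pure functions of
(configuration, seed), and reports are byte-stable across reruns.
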