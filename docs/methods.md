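# Methods

This note documents the models, defaults and numerical choices behind each
stage of the toolkit, what the synthetic generators do and do not emulate,
and the known limitations.

## Coordinates and formats

All intervals inside the package are 0-based half-open on the forward
strand. 1-based inclusive coordinates exist only at the GFF3 and CX-report
file boundary, where a single conversion pair (`gff_to_internal` /
`internal_to_gff`) is applied; the pair is an involution and is tested as
one. Readers are strict: a malformed row raises an error carrying the file
path and line number, never a silent skip. CX rows with zero coverage are
retained (they complete the genome-wide cytosine census) but excluded from
all level and calling computations. Cytosine records on the two strands
are kept separate; symmetric-CG collapsing is deliberately not performed,
so CG statistics are per-strand.

When a gene has several transcripts, the representative transcript is the
one with the largest spliced (summed-exon) length, with ties broken by
transcript id; "longest" by genomic span was the alternative reading, but
spliced length is what downstream exonic statistics actually consume.

## LTR insertion-time dating

Model: the two LTRs of an intact element are identical at insertion and
subsequently accumulate substitutions independently and neutrally. The
pairwise distance is the Kimura two-parameter estimator

K = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

with P and Q the transition and transversion proportions over compared
columns. Age is T = K/2r with r defaulting to 2.2×10⁻⁹
substitutions·site⁻¹·yr⁻¹, the rate conventionally applied across
gymnosperms; r is configurable per run.

Numerical choices:

* Columns containing a gap or an N in either row are removed by pairwise
  deletion before computing P and Q. Whether to trim alignments further is
  left to the caller; the estimator sees whatever alignment it is given.
* When the log argument is non-positive (saturation, roughly K ≳ 1) a
  typed `SaturationError` is raised; `date_elements` reports such elements
  separately with undefined age instead of clamping, and logs their count.
* Pairwise alignment uses a global aligner with linear gap costs
  (match 1, mismatch −1, gap −2 by default); the score is checked against
  an exhaustive alignment enumeration on short sequences in the tests.
* The solo:intact ratio is plain division of externally supplied counts
  (solo-LTR calling rules vary between annotation pipelines, so which
  annotations count as "solo" is taken as input).

The generator (`simulate_ltr_pairs`) evolves each LTR copy site-by-site
with a Poisson(r·T) number of hits per site and a transition bias
(default 2/3), allowing multiple hits per site. This matters: a
proportion-only simulator would never exercise the multiple-hit correction
that distinguishes K2P from raw divergence. Recovery holds within 10% of
truth for cohorts of 200 two-kilobase elements at 1, 10 and 25 Myr.

## Ks mixtures and WGD detection

A whole-genome duplication appears as a synchronous hump in the paralog Ks
distribution. The model is a k-component univariate Gaussian mixture over
Ks values restricted to a fit range, default (0.05, 5.0): the lower bound
excludes allelic and very recent duplicates, the upper bound saturated
pairs. Values outside the range are discarded rather than handled with a
truncated-likelihood EM — a deliberate approximation that is adequate for
locating the density summit, the quantity of interest; mixture weights
near the range edges are correspondingly mildly biased.

The EM iteration is written in full so that its defining invariant — the
log-likelihood never decreases — is asserted on every iteration (a
decrease beyond 1e-9 raises). Defaults: 10 restarts (the first from the
plain data-quantile grid, the rest jittered), convergence at Δlog-L <
1e-8, standard-deviation floor 1e-3. Component count can be selected by
BIC over k = 1..k_max with ties resolved toward the smaller k. The summit
is the argmax of the fitted density on a 0.01-spaced grid; a summit on the
search-range boundary triggers a warning. scikit-learn's GaussianMixture
is used in the test suite as an independent cross-check of the fitted
means, never as the implementation.

## Bisulfite methylome statistics

Conversion rate: the lambda spike-in is fully unmethylated, so the rate is
estimated as (converted observations)/(all observations) pooled over
lambda cytosines. Its complement is the null success probability of the
site caller.

Site calling: for each covered cytosine, a one-sided upper-tail binomial
test of count_m successes in count_total trials against p₀ = 1 − rate.
The upper tail is the only direction under which "methylated" is the
alternative hypothesis. FDR control is Benjamini–Hochberg applied within
each context class (CG/CHG/CHH null burdens differ by an order of
magnitude); a site is called at q < 0.05. The default coverage floor for
site-level statistics is 4 reads; low-coverage sites still contribute to
pooled levels.

Levels: every aggregate level is count-pooled, Σ mC / Σ(mC + umC) — never
a mean of per-site ratios. Consequence (tested as an exact identity): the
global level equals the coverage-weighted mean of bin levels. Empty bins
are reported missing, not zero.

Metaprofiles: upstream flank, spliced exonic axis, spliced intronic axis
and downstream flank are each divided into fixed numbers of bins
(defaults 10/20/20/10, flank 2 kb), strand-aware so that "upstream" is
always 5′ of the gene; counts are pooled across genes per bin per context.
Gene-body-methylation analysis ranks genes by mean TPM (stable ties by
gene id), splits them into 20 equal-size groups, and reports each group's
median TPM and pooled exonic level per context.

Demethylation valleys: a covered site qualifies when its per-site level is
below the 5% threshold. Qualifying sites are chained while (a) the gap to
the previous qualifying site is ≤ 2 kb and (b) the growing region — over
*all* covered sites it spans — keeps every per-context pooled level below
the threshold. Enforcing (b) online, rather than only on the final region,
is what keeps a valley from leaking into high-methylation background
through isolated noisy sites, and is necessary because in a genome whose
CHH background (~4%) sits below the 5% threshold, CHH sites alone carry no
valley signal. Closed regions are kept at span ≥ 1 kb and ≥ 10 covered
sites. The "every context below threshold" reading (rather than "at least
one") matches the biology of a valley; an `any` mode is exposed for the
alternative reading. Boundaries are resolved to the outermost qualifying
sites, so detected valleys can overshoot a planted valley by a few hundred
base pairs per edge before condition (b) halts growth; planted-valley
recovery at default parameters runs at per-region Jaccard ≈ 0.86–0.96.
Common DMVs across samples are the base-pair intersection of each sample's
merged intervals, with pieces < 1 kb dropped. Differential-methylation
(DMR) testing with proper dispersion modelling is out of scope and should
be delegated to a dedicated package.

## HGT screen

Per query and per database partition (out-group: archaea/bacteria/fungi;
mid-group: non-gymnosperm plants; in-group: gymnosperms), hits surviving
the e-value cutoff (default 1e-5) are reduced to one best hit per species
(ties: lower e-value, then lexicographic subject id), capped at the top
100 by bitscore, and averaged into the ABV. A query is a candidate when it
has at least `min_out_hits` (default 5 — single-hit ABVs are noise;
no floor is inherent to the rule itself) kept out-group hits and its
out-group ABV exceeds its mid-group ABV. A missing mid-group passes the
comparison vacuously but is flagged `mid_absent` (a classic transfer
signature, but also the signature of contamination); in-group-only queries
are `no_signal`. The screen is order-invariant and its filter is verified
against brute-force subset enumeration in the tests. Phylogenetic
confirmation of candidates is an external follow-up by design.

## Assembly QC

N50 is the largest length L such that contigs ≥ L sum to at least half the
assembly; ties resolve to the largest qualifying contig length. Printed
statistics are rounded half-up to the conventional precision (one decimal
for folds and percentages, three for base accuracy). The k-mer genome-size
estimator divides the k-mer observations above the error cutoff by the
homozygous-peak depth; the cutoff defaults to the histogram's first local
minimum, and a histogram with no rise after the error spike is rejected.
Telomere scanning counts non-overlapping TTTAGGG copies in the terminal
10 kb (reverse complement at the 5′ end) and flags ends with ≥ 10 copies;
window and copy thresholds are decisions, not field constants, and are
configurable. Centromere summaries aggregate externally produced
tandem-repeat annotations by monomer period and report the modal period
(ties flagged) and its per-chromosome presence.

## Synthetic data: what it does and does not show

The generators emulate the *statistical structure* each stage consumes:
divergence accumulation on LTR pairs, binomial read sampling over
Poisson coverage with planted valleys and a lambda track, Gaussian
bitscore contrasts, mixture-distributed Ks, and literal planted sequence
features. Defaults reflect the study conditions of a large gymnosperm
seed genome: CG/CHG/CHH levels 0.83/0.69/0.04, mean depth 20×,
non-conversion 0.005, substitution rate 2.2×10⁻⁹, Ks components at
0.3 and 1.4, telomere motif TTTAGGG, 101-bp centromeric monomer. The
lambda spike-in fraction is a free parameter (no field constant exists).
Sites are placed uniformly at random (~50 bp mean spacing), so the
generators do not reproduce CpG clustering, chromatin-scale
autocorrelation of methylation, indel evolution, read-level error
profiles, mappability structure, or contamination. Passing tests
therefore demonstrate correctness of the estimators under their stated
sampling models, not robustness to every artefact of real libraries.

Problem sizes in the test and acceptance runs (200×2-kb LTR cohorts,
2,000 Ks pairs, 10⁴–10⁵ cytosines, 30-query HGT tables) are chosen so the
statistical criteria are comfortably inside their Monte-Carlo envelopes
while the whole suite stays quick on a laptop; all are parameters, and
scale linearly.

## Known limitations

* Truncation-by-discarding biases Ks mixture weights near range edges.
* Per-strand CG levels differ from symmetric-CG-merged levels when
  coverage is strand-unbalanced.
* DMV boundaries overshoot by up to a few hundred bp per edge (above).
* The binomial caller assumes independent reads; overdispersion from
  PCR duplicates would inflate calls and should be handled upstream.
* `fold_change` and `ddct_relative_expression` are descriptive; no
  inference is attached.
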