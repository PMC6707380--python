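# Methods

## The discovery model

`cnvreg` treats CNVR discovery as three deterministic set operations on
interval call sets, followed by descriptive and validation statistics.

**Consensus filtering.** Two callers with orthogonal detection signals
observe each genome: a primary breakpoint-sensitive caller and a
supporting read-depth caller. A primary call `A` survives iff there is
a *single* support call `B` from the same sample with
`|A∩B| / |A| ≥ s` (default `s = 0.10`). The comparison is inclusive
(≥): a fraction of exactly 0.10 retains the call. The fraction is
one-way by design — it asks how much of the primary call is
corroborated, not the converse. Support is evaluated per single call,
not against the union of support coverage, and cross-sample support is
never allowed (both callers observed the same individual; pooling
individuals would conflate genotypes). Loss/gain type agreement between
the callers is *not* required by default, because read-depth and
breakpoint callers frequently disagree on type at the boundaries of
complex events; a `match_type` flag enforces agreement for sensitivity
analysis.

**Within-genome merge.** Before cross-sample merging, each sample's
retained calls of the same type that overlap by ≥ 1 bp are replaced by
their union. Different types never merge — a deletion and a duplication
at one locus in one genome are distinct events. The merged call's copy
number is the length-weighted mean of its members' estimates when all
report one, otherwise absent.

**Cross-sample merging.** Two calls are linked when their reciprocal
overlap `min(|A∩B|/|A|, |A∩B|/|B|) ≥ r` (default `r = 0.50`). CNVRs are
the *connected components* of this graph; a region spans
`[min start, max end)` of its component and can therefore grow by
chaining: if A links B and B links C, all three merge even though A and
C alone may fall below the threshold. Component semantics was chosen
over the stricter "every pair must qualify" (clique) reading because it
is order-independent, matches the intuition of a region growing from
`a` to `d` as new overlapping calls accrue, and is what interval-merge
implementations in this field almost universally do. A `clique` flag
implements the stricter greedy variant (calls processed in coordinate
order, joining a region only if they qualify against every member) for
sensitivity analysis; it always yields at least as many regions.
Merging ignores call type — regions carrying both losses and gains in
different individuals are typed `mixed`, which is how such catalogues
report them. Regions shorter than 200 bp are removed after merging
(strictly-less-than: a 200 bp region survives, consistent with
catalogues whose minimum reported size is just above the cutoff).
Region ids are `CNVR<rank>` in (chromosome, start) order, so a given
input always produces identical ids.

All coordinates are 0-based half-open everywhere (BED dialect); GFF3
input is shifted on read. Touching intervals share 0 bp and never merge
or count as overlapping. Strand is ignored: CNVs are unstranded.

## Trio validation

For a parent–child pair, the transmission rate is
`|CNVRs(parent) ∩ CNVRs(child)| / |CNVRs(parent)|`; for a trio, the
inheritance rate is `|CNVRs(child) ∩ (CNVRs(sire) ∪ CNVRs(dam))| /
|CNVRs(child)|`. "Called in" a sample means the sample is a carrier
member of the population-level CNVR — validation is of the regions, not
the raw calls — with a loose mode (`raw_calls=`) that instead accepts
any ≥ 1 bp overlap of the sample's raw calls with the region span.
Means across trios are unweighted (each trio counts once); trios with
an empty denominator yield NaN, are excluded from the means, and are
warned about. The error-rate estimate `1 − mean inheritance` assumes
de-novo and somatic copy-number events are negligible relative to
calling error; the report carries that assumption explicitly
(`assumes_negligible_de_novo_and_somatic`). Under that assumption false
positives in the child and false negatives in the parents both depress
inheritance, which is what makes the complement an error-rate proxy.

## Annotation, comparison, enrichment

Feature overlap uses the CNVR union span (the catalogue overlays
regions, not member calls, on annotation) and counts from 1 shared base
(configurable). Breed-specific regions are those whose carrier set maps
to a single breed; single-carrier regions are breed-specific by
construction, so the summary reports their fraction. Cross-catalogue
comparison counts this catalogue's regions touched (≥ 1 bp) by any
region of an external set and reports `100·n/total` half-up rounded to
2 decimals.

QTL enrichment builds, per trait, the 2×2 table (trait's QTL
overlapped, trait's QTL not overlapped, other traits' QTL overlapped,
other traits' QTL not overlapped), tested with two-sided Fisher's exact
(scipy; the two-sided rule sums hypergeometric mass of tables no more
probable than the observed one — the test suite checks this against an
independent exhaustive enumeration for every table with margins ≤ 15).
QTL *records* are counted, not unique trait intervals. The BH family is
all traits with ≥ 1 overlapped QTL in the run; traits with no overlap
cannot be discoveries and are excluded, which also keeps the family
comparable across runs. The trait-vs-rest construction is the minimal
table consistent with asking "are this trait's QTL unusually often hit
by CNVRs?"; a CNVR-level alternative (regions as sampling units) is
deliberately not implemented. Odds ratios are `(a·d)/(b·c)`, infinite
when `b·c = 0` with signal, NaN for the empty diagonal. The binomial
mode is the standard term-overrepresentation test: `p0 = |term| /
|universe|`, one-sided upper tail at `n = |study|`; the universe is
caller-supplied so either a whole-genome or annotated-only reference
can be used. BH adjustment is the classic step-up (statsmodels),
cross-checked in tests against hand-derived values.

## Summary statistics

The per-chromosome table reports length, region count, unique covered
bases (interval union, double-counting removed) and the coverage ratio;
chromosomes with zero regions are included. The genome-wide "mean
chromosome coverage" is the *unweighted* mean of per-chromosome ratios
(this is the convention under which the published table this package
reproduces yields its printed mean), while the genome fraction is total
unique coverage over total placed-chromosome length — unplaced
scaffolds are simply absent from the genome metadata. Percentages are
printed at 2 decimals, half-up; raw proportions stay in machine output.
Pearson correlations use scipy and are NaN on zero variance.

## The synthetic generator

The generator emulates the target study design, not sequence data: a
multi-breed herd observed by two imperfect callers.

*Pedigree.* Defaults: 12 purebred sires (two breeds, alternating), 36
composite dams, 12 children each from a distinct sire×dam pair — 60
samples, 12 trios, mirroring a herd with a dozen sequenced trios at a
size where every experiment runs in seconds. Per-sample mean coverage
is log-normal (median 12×, σ = 0.45) clipped to [1×, 31×], spanning the
low-to-high coverage mix such cohorts actually have.

*Truth loci.* 300 (default) mutually disjoint intervals (≥ 2 kb apart,
so distinct loci can never merge downstream and parameter-recovery
claims are exact), lengths log-normal with median 2.9 kb — matching the
size scale reported for sequence-based CNVR catalogues — 5% gains / 95%
losses (read-depth discovery is strongly deletion-biased). Each locus
gets an independent per-breed allele frequency from Beta(0.6, 2.4)
(mean 0.2, mass near zero: most CNVs are rare, some common).

*Genotypes.* Founders draw each allele Bernoulli(breed frequency);
children inherit one allele per parental slot. X and Y follow ploidy by
sex (a son's X comes from the dam only; male X losses emit copy number
0), so sex-chromosome handling is exercised by construction. Every
non-founder allele traces to a parent allele — the Mendelian audit in
the tests checks exactly this — which makes "inheritance rate = 1.0
under noiseless calling" a theorem about the generator, not an
empirical observation.

*Caller noise.* Three independent mechanisms per caller: boundary
jitter (Gaussian, default σ = 100 bp); false negatives with probability
`fn_max / (1 + exp((cov − 10)/4))` — a logistic in coverage calibrated
so a < 5× genome misses roughly twice as many events as a 20× genome;
false positives Poisson per megabase at random positions. `noiseless()`
switches all three off. `drop_calls` and `inject_false_positive_cnvrs`
graft extra error of a known size onto a call set or catalogue, which
is how the validation experiments dial in, e.g., exactly 20% child
false-positive calls (for a child with k genuine regions,
`round(k·p/(1−p))` spurious singletons are added, making false calls a
fraction p of its total and the expected inheritance 1 − p).

*What it does not emulate.* Read-level artefacts (GC bias, mappability,
segmental duplications), overlapping/nested true loci, correlated
errors between callers, de-novo events, and realistic linkage between
loci (loci segregate independently). Passing tests therefore
demonstrate the pipeline's arithmetic and its behaviour under
controlled error models — not calling performance on real sequence
data.

## Problem sizes and numerics

Default experiments use a 20 Mb three-chromosome genome (two autosomes
plus X) and 300 loci; the parameter-recovery experiment uses 70 Mb and
1,000 loci, where binomial noise on the injected-FP inheritance mean is
well under ±0.03. The null enrichment control averages 200 replicates
of a 40-trait random-overlap track. Threshold comparisons are exact
rational arithmetic wherever possible (integer overlaps divided once);
the inclusive ≥ at the support threshold is deliberate and logged in
every pipeline report. Degenerate inputs fail loudly: invalid
coordinates, zero-length queries, empty universes, all-zero 2×2 margins
and unknown chromosomes/samples raise with context rather than
propagating NaN.

## Known limitations

- Within-sample merging uses ≥ 1 bp union; if the upstream convention
  was itself reciprocal, catalogues with heavily fragmented calls may
  differ.
- `trio_report` treats carriers at region level; raw-call semantics are
  available but not the default, and the two can differ when a sample's
  call was filtered out before merging.
- The clique merge mode is greedy in coordinate order, one of several
  defensible maximal-clique decompositions.
- Rehydrating CNVRs from BED (`read_cnvrs_bed`/CLI) loses member-call
  detail; downstream statistics that need members (e.g. length-weighted
  copy number) are only available in-process.
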