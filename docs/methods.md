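# Methods

This note documents the models, parameter choices and numerical
conventions behind `circkit`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinates and junction identity

All internal coordinates are 0-based half-open `[start, end)`. BED input
is native; GTF (1-based closed) is converted at the boundary, so a GTF
exon `start=101, end=150` becomes `[100, 150)`. A junction is identified
by `chrom:start|end:strand` with `start < end` always; back-splice
orientation is carried by the category and the calling-stage orientation
test, never by swapping coordinates. Interval overlap is half-open
everywhere: a feature beginning exactly at a query's `end` does not
overlap it.

## Back-splice calling

A chimeric read record has two aligned segments in read order. The
orientation test accepts a record as a back-splice candidate iff both
segments share chromosome and strand and the first segment aligns
genomically downstream of the second (plus strand; mirrored on minus).
Colinear two-segment alignments — ordinary linear splice junctions — fail
this test, and it is deliberately the *only* discriminator: no sequence
motifs, no realignment. Inter-chromosomal and strand-discordant chimeras
(fusion candidates, not circles) are dropped, as are unstranded records
(the orientation test needs a strand; the number dropped is logged).

Annotation against the gene model assigns `exonic_circRNA` when both
boundaries coincide with exon borders of a single transcript, `ciRNA`
when the interval is contained in one intron, and `low_confidence`
otherwise (retained or dropped according to the low-confidence mode).
Tie-breaking when several transcripts match is deterministic: exonic
beats intronic; among exonic matches the transcript spanning the fewest
exons wins, then the lexicographically smallest transcript id.

Read support counts distinct `read_id`s per sample, so paired-end mates
sharing an id count once — fragments, not reads. Whether the upstream
tooling the field uses counts fragments or mates is not something this
package takes a position on; fragment counting is our convention and is
stated here rather than asserted as anyone else's behavior. Junctions
with fewer than 2 unique reads summed over samples are not "expressed"
and are removed (threshold configurable, monotone by construction).

## Quantification and the RNase-R filter

Circular abundance is RPM = count / library size × 10⁶; linear gene
abundance is FPKM = count / (length/10³) / (library size/10⁶). The
circular-to-linear ratio is `circ / (circ + linear_summary)` where
`linear_summary` is by default the arithmetic mean of the linear read
counts at the two back-splice boundaries ("surrounding" the site admits
several aggregations; `max` and `sum` are selectable). The ratio is 0
when only linear reads exist and reported missing when both are zero.

The RNase-R filter validates a junction iff at least one treated/untreated
pair shows (a) ≥ 20 unique treated reads and (b) treated abundance ≥ 2×
untreated abundance. The fold is computed on RPM by default because
treated and untreated libraries differ strongly in composition after
linear RNA digestion, so raw-count folds would be library-size
confounded; a raw-count mode exists. A pseudocount of one read is added
to the untreated count before normalization as a division-by-zero guard —
this makes the filter slightly conservative for circles absent from the
untreated library. Both thresholds are configurable and the validated set
is monotone non-increasing in each.

## Cell-type specificity

The expression profile of transcript *c* is built from per-class *mean*
RPM over the samples of the analysis subset (default: healthy controls
only, to avoid disease-state confounding): add 1 to each class mean and
normalize to sum 1. The +1 shift regularizes all-zero transcripts to the
uniform profile and bounds how extreme a profile can be at low abundance —
at a class mean of 10 RPM against zeros elsewhere the profile entry is
10/14 ≈ 0.71, not 1.0.

S_{c,i} = 1 − JSD(p_c, q̂ᵢ) with JSD the Jensen–Shannon *distance*
(square root of the divergence) using base-2 entropies, so JSD and S are
bounded in [0, 1] and JSD is a metric. With the divergence instead of the
distance the 0.5 threshold would mean something different (divergence
0.5 ≈ distance 0.71). 0·log 0 ≡ 0. Numerical guards: profile sums checked
to 1e-9; negative divergences from roundoff clipped at 0.

A transcript is specific to class *i* when S_{c,i} ≥ 0.5 and its class-*i*
mean RPM strictly exceeds mean + 1 s.d. of its expression pooled across
all samples of the analysis subset. Pooling across samples (rather than
across class means) is the default "overall expression"; the alternative
is available. Both the 5-way cell-class scheme (DA, TCPY, MCPY, PBMC, FB)
and the grouped 3-way scheme (DA, PY = TCPY+MCPY, NN = PBMC+FB) are
implemented; class order is fixed because it indexes the unit vectors.

For circular-vs-linear comparisons each transcript contributes its
best-class score, paired by host locus, with a two-sided Mann–Whitney
test; a restriction to loci hosting a single circRNA is available.

## Differential expression

Junction counts are aggregated to host genes by summation (junctions
without a host are excluded and counted in the log). Size factors are
median-of-ratios over genes positive in every sample, rescaled to
geometric mean 1, with a total-count fallback (warned) when no such gene
exists. Each gene is fit with an NB GLM: log link, NB2 variance
var = μ + αμ², log size-factor offset, design = intercept + condition +
sex + standardized age/PMI/RIN (standardization is for numerical
conditioning only; the condition coefficient is unaffected). Rank
deficiency is reported naming the collinear columns.

Dispersion is estimated per gene by maximizing the Cox–Reid adjusted
profile likelihood (the 0.5·logdet(XᵀWX) penalty) over log α, seeded by
the method-of-moments estimate and floored at 1e-8; the GLM is refit and
the dispersion re-estimated until the estimate stabilizes (at most two
passes; a method-of-moments value that beats the search optimum is kept).
Plain per-gene ML is biased low with six coefficients at n = 40, which
anticonservatively shrinks Wald standard errors; the CR adjustment is the
standard correction in this framework. For the same reason the Wald
statistic is referred to a t distribution with residual degrees of
freedom rather than the normal — with a per-gene plug-in dispersion and
no cross-gene shrinkage the normal reference is measurably
anticonservative at n = 40 (type-I ≈ 0.06–0.08 vs ≈ 0.05 with the t).
This framework intentionally omits dispersion shrinkage across genes,
fold-change shrinkage and independent filtering, so its p-values are not
numerically interchangeable with shrinkage-based packages; the claim
surface is the covariate-adjusted per-gene Wald test.

IRLS convergence: statsmodels GLM with tol 1e-8, 100 iterations;
non-convergent genes are flagged, not dropped. Genes with all-zero counts
are skipped; genes with mean count < 1 are flagged low-confidence.
P-values are BH-adjusted across tested genes.

Stage association fits the same model with an ordinal-numeric stage
(0, 1, 2, 3, 4) as a single slope plus the standard covariates, requiring
≥ 3 distinct stages; nominal p ≤ 0.05 is flagged "suggestive". Treating
the stage as ordinal-numeric (rather than factor contrasts or a
correlation test) is an interpretation choice, stated here.

## Enrichment

One-sided over-representation p is the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), computed after intersecting query and
set with the universe (so universe restriction provably leaves p
unchanged). The universe is the supplied gene model's genes and N is
recorded in the output. Odds ratios use a Haldane 0.5 correction when any
2×2 cell is zero. Disease scans flag p < α / #sets (Bonferroni over
unique sets); GO-style scans use BH. A two-sided option exists for parity
with two-sided Fisher conventions. Gene–disease tables are filtered at
GDA score > 0.1 (strict). GO-term slimming/redundancy reduction is out of
scope — results are plain sorted tables.

SNP proximity counts a SNP when its distance to the nearest junction
interval is ≤ the window (closed comparison; 0 inside the interval),
reported to the nearest percent.

## Genomic features

Flanking introns of an exonic circle are the introns immediately
adjacent, in transcript orientation, to the first and last circularized
exons (upstream is genomically right on the minus strand); circles
touching terminal exons have a missing flank on that side. Control exons
are a seeded uniform sample of internal exons not overlapping any
circularized exon — size-matched only, not length- or GC-matched, which
is a stated limitation. Overlap counts use the raw feature intervals;
covered fractions merge features first, so merging never changes a
fraction but can only reduce a count. Overlap is strand-agnostic by
default (eCLIP and repeat strand semantics vary), with a stranded option.

Group contrasts use a two-sided Mann–Whitney U: full enumeration of the
permutation distribution when both groups have ≤ 8 observations
(two-sided p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1), otherwise the
tie-corrected normal approximation with continuity correction.

## The synthetic-data generator

`simulate` produces every input with planted truth. What it emulates:
negative-binomial junction counts (NB2, var = m + αm², matching the GLM),
per-sample library-size variation, five cell classes, planted cell-type-
specific junctions (target-class mean multiplied by a fold), planted
condition effects on host genes, RNase-R circular enrichment and linear
depletion around observed means, back-splice-ordered chimeric records
with colinear decoys, host genes with longer flanking introns, and one
disease set drawn preferentially from specific-circle host genes at a
chosen sampling odds ratio. Determinism: every stage derives its stream
from (seed, stage id), so identical configurations give byte-identical
outputs and stages are order-independent.

Key defaults and why: NB dispersion 0.1 (typical for bulk RNA-seq count
models at moderate depth); baseline 10 RPM so that junctions sit
comfortably above the expressed threshold; specificity fold 10, RNase
circular fold 10 / linear fold 0.1, and |log2FC| 1.5 on 5% of genes as
the planted-effect regime the recovery studies quantify; 20 samples per
cell class; six RNase pairs; 50% colinear decoy records; hosts get 3×
longer introns; library sizes 1–2 million mapped reads, a desk-scale
choice — deeper libraries would only rescale raw counts, all RPM-based
targets are depth-invariant by construction.

What it does **not** emulate, hence what passing tests do not show about
real data: no sequence-level reads (no mappability, GC or fragment-length
bias), no multi-mapping ambiguity, no cross-junction count correlation
beyond host-gene sharing, no batch or outlier structure, circular–linear
coupling off by default (an optional coupling parameter exists; observed
coupling in real data is weak), covariates generated null rather than
confounded, and decoys limited to colinear splices of the same
transcript — the only error mode the orientation test is defined against.
Recovery at fold 10 says the pipeline is correct and well-calibrated, not
that real circRNAs are this separable.

## Evaluation scales

The recovery studies run at: 1,000 junctions / 20 samples per class
(specificity, and its fold-1 null), 500 junctions / 6 pairs (RNase), 300
junctions with 50% decoys (calling exactness), 2,000 genes / 20+20
samples (NB type-I and power), 100 replicate worlds (enrichment ranking),
and 500 genes / 2,000 junctions / 60 samples for the end-to-end run.
These sizes make the binomial noise on each reported rate small relative
to its acceptance margin while keeping the full suite around a minute.

## Known limitations

- The NB framework reports per-gene plug-in-dispersion Wald t-tests; at
  very small n or very low counts, shrinkage-based methods will be more
  powerful and better calibrated.
- `low_confidence` calling recognizes junctions only via the supplied
  model's exon borders and introns; unannotated gene structures yield
  `low_confidence` calls, not novel-exon reconstruction.
- Control exon sampling is not covariate-matched.
- The GTF reader handles the Ensembl exon dialect (gene_id/transcript_id
  attributes); it is not a general GFF3 parser.
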