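# circkit

Circular RNAs (circRNAs) are covalently closed transcripts produced by
back-splicing: a downstream splice donor joins an upstream splice
acceptor, so a read crossing the junction aligns chimerically in
reversed genomic order. Because they lack free ends, circRNAs resist the
3'→5' exoribonuclease RNase R, which degrades linear RNA — the basis of
the standard experimental validation filter. `circkit` is a tested,
reusable pipeline for circRNA catalogs from bulk or sorted-cell total
RNA-seq: back-splice junction calling and annotation, RNase-R validation,
RPM quantification, Jensen–Shannon cell-type specificity scoring,
circular-to-linear ratios, gene-level negative-binomial differential
expression, gene-set/disease enrichment, and genomic-feature contrasts.
It is aimed at transcriptomics analysts who have chimeric junction reads
(or junction count matrices) and want the downstream statistics with
planted-truth tests behind every stage.

## The statistics at the core

**Junction calling.** A two-segment chimeric read is a back-splice
candidate iff both segments share chromosome and strand and the segment
first along the read aligns genomically downstream of the second (plus
strand; mirrored on minus). Junctions with both boundaries on annotated
exon borders of one transcript are `exonic_circRNA`; junctions inside a
single intron are `ciRNA`; anything else is `low_confidence`. Junctions
with ≥ 2 unique back-spliced reads over all samples are "expressed"
candidates; abundance is RPM = back-spliced reads / library size × 10⁶.

**RNase-R validation.** A junction is validated iff, in at least one
treated/untreated library pair, the treated sample has ≥ 20 unique reads
and ≥ 2-fold RPM enrichment over the untreated sample (pseudocount of one
read on the untreated member).

**Cell-type specificity.** For transcript *c* with expression profile
*p_c* (per-class mean RPM + 1, normalized to a density over the cell
classes) and unit vector *q̂ᵢ* of perfect expression in class *i*,

    S_{c,i} = 1 − JSD(p_c, q̂ᵢ),

where JSD is the Jensen–Shannon distance (square root of the JS
divergence, base-2 entropies, so S ∈ [0, 1]). A transcript is specific to
class *i* when S_{c,i} ≥ 0.5 **and** its class-*i* mean exceeds the
mean + 1 s.d. of its expression over all samples in the analysis subset.

**Differential expression.** Junction counts are summed per host gene
and each gene is fit with an NB GLM (log link, var = μ + αμ², median-of-
ratios size-factor offset) adjusting for sex, age, post-mortem interval
and RIN; the condition coefficient is tested with a two-sided Wald test
(t reference with residual df), BH-adjusted across genes.

**Enrichment.** One-sided Fisher's exact (hypergeometric upper tail) on
the 2×2 table (k, n−k, K−k, N−K−n+k) of query genes vs a gene set within
universe N; Bonferroni threshold α / #sets for disease scans (e.g.
0.05 / 4,638 ≈ 1.08 × 10⁻⁵), BH FDR for GO-style scans.

Every stage is exercised end-to-end on synthetic data with planted ground
truth (`circkit.simulate`), so sensitivity/precision of the whole chain
is measured, not assumed.

## Worked example

```python
from circkit.simulate import (SimulationConfig, simulate_gene_models,
                              simulate_counts, simulate_rnase_pairs)
from circkit.quantify import rpm_normalize, rnase_validate
from circkit.specificity import CellTypeScheme, score_matrix

config = SimulationConfig(seed=7, n_genes=100, n_junctions=400, condition_split=0.0)
models, hosts = simulate_gene_models(config)
counts, linear, design, truth = simulate_counts(models, config, hosts)

pairs, circ_keys, decoy_keys = simulate_rnase_pairs(counts, linear, config, design)
validated = rnase_validate(counts.index, pairs)

rpm = rpm_normalize(counts, design)
scheme = CellTypeScheme.from_design(design)
result = score_matrix(rpm, scheme)
specific = result.specific.any(axis=1)

print(f"junctions simulated:   {len(counts)}")
print(f"RNase-R validated:     {int(validated.sum())} ({100 * validated.mean():.1f}%)")
print(f"cell-type specific:    {int(specific.sum())} (planted: {len(truth.specific_junctions)})")
print(result.table.loc[specific].head(3).round(3).to_string())
```

prints

```
junctions simulated:   400
RNase-R validated:     400 (100.0%)
cell-type specific:    100 (planted: 100)
                        S_DA  S_TCPY  S_MCPY  S_PBMC   S_FB best_class  specific_any specific_class
junction
chrS2:635828|635975:+  0.567   0.108   0.107   0.111  0.118         DA          True             DA
chrS4:129223|133469:+  0.103   0.107   0.123   0.570  0.106       PBMC          True           PBMC
chrS4:129223|131194:+  0.101   0.096   0.088   0.603  0.109       PBMC          True           PBMC
```

All 400 simulated circles pass the RNase-R filter (the generator plants a
10× circular enrichment), and the specificity caller recovers exactly the
100 planted cell-type-specific junctions: each has S ≥ 0.5 toward its
planted class (here ≈ 0.57–0.60) and near-uniform low scores elsewhere
(a fully uniform profile gives S ≈ 0.219 toward every class).

The same stages are available from the shell:

```sh
circkit simulate --seed 7 --out sim/
circkit call --records sim/chimeric_records.tsv --gtf sim/genes.gtf --out called.tsv
circkit quantify --counts called.tsv --design sim/design.tsv --out rpm.tsv
circkit specificity --matrix rpm.tsv --design sim/design.tsv --out specific.tsv
```

## Layout

- `circkit.io` — GTF/BED12 gene models, junction count TSVs, GMT and
  gene–disease tables, chimeric-record TSVs, BED output
- `circkit.simulate` — synthetic data with planted ground truth
- `circkit.calling` — back-splice detection, annotation, read filters
- `circkit.quantify` — RPM/FPKM, circular-to-linear ratio, RNase-R filter
- `circkit.specificity` — JSD specificity scores and classification
- `circkit.diffexp` — gene aggregation, size factors, NB-GLM Wald tests
- `circkit.enrichment` — Fisher enrichment, disease/GO scans, hit rates
- `circkit.features` — flanking introns, interval overlap, rank-sum tests
- `circkit.evaluation` — planted-truth recovery studies
- `docs/methods.md` — models, assumptions, parameter choices, limitations
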