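"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a laser-capture
total-RNA circRNA study: negative-binomial back-splice junction counts
per sample across five cell classes (DA, TCPY, MCPY, PBMC, FB),
library-size variation, planted cell-type-specific circRNAs, planted
condition effects on host genes, RNase-R circular enrichment / linear
depletion, weak (by default absent) circular–linear abundance coupling,
chimeric read records in back-splice order with colinear decoys, and a
planted enriched disease gene set.

Counts are drawn as NB(mean m, dispersion alpha) with the NB2 variance
var = m + alpha * m^2, matching the GLM used downstream; the NB mean for
a junction in a sample is its target RPM x library_size / 1e6.

Identical configurations (including the seed) give byte-identical
outputs. Each stage derives its random stream from (seed, stage id), so
generating stages in a different order does not change any one output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ChimericReadRecord,
    Gene,
    GeneModel,
    GeneSetCollection,
    Segment,
    Transcript,
    junction_key,
)
from .quantify import RNasePair

# stage ids for per-stage random streams
_STAGE_MODELS, _STAGE_COUNTS, _STAGE_RNASE, _STAGE_READS, _STAGE_SETS = range(5)

CIRNA_CATEGORY = "ciRNA"
EXONIC_CATEGORY = "exonic_circRNA"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults encode the planted-effect regime the recovery analyses are
    run at: fold-10 cell-type specificity, fold-10 RNase circular
    enrichment with 10-fold linear depletion, log2FC 1.5 condition
    effects, NB dispersion 0.1, and 20 samples per cell class.
    """

    seed: int = 0
    n_genes: int = 200
    exons_per_gene_range: tuple[int, int] = (4, 10)
    n_junctions: int = 1000
    samples_per_cell_type: dict = field(
        default_factory=lambda: {"DA": 20, "TCPY": 20, "MCPY": 20, "PBMC": 20, "FB": 20}
    )
    nb_dispersion: float = 0.1
    baseline_mean_rpm: float = 10.0
    baseline_linear_rpm: float = 50.0
    specificity_fold: float = 10.0
    frac_specific: float = 0.05
    frac_cirna: float = 0.1
    rnase_circ_fold: float = 10.0
    rnase_linear_fold: float = 0.1
    n_rnase_pairs: int = 6
    de_fold: float = float(2.0**1.5)
    frac_de: float = 0.05
    condition_split: float = 0.5
    contrast_condition: str = "ILB"
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    decoy_frac: float = 0.5
    host_intron_fold: float = 3.0
    frac_hosts: float = 0.5
    exon_len_log_mean: float = float(np.log(150.0))
    exon_len_log_sd: float = 0.6
    intron_len_log_mean: float = float(np.log(1500.0))
    intron_len_log_sd: float = 1.0
    chrom_length: int | None = None
    n_chroms: int = 4
    n_gene_sets: int = 50
    gene_set_size: int = 50
    planted_set_odds: float = 8.0
    enriched_cell_type: str | None = "DA"
    coupling: float = 0.0

    def __post_init__(self) -> None:
        for name in ("specificity_fold", "rnase_circ_fold", "rnase_linear_fold", "de_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frac_specific", "frac_de", "frac_cirna", "decoy_frac",
                     "condition_split", "frac_hosts", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_specific * len(self.samples_per_cell_type) > 1.0:
            raise ValueError("frac_specific too large for the number of cell classes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    specific_junctions: dict[str, str] = field(default_factory=dict)  # key -> cell type
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2 fold
    enriched_sets: list[str] = field(default_factory=list)
    junction_host: dict[str, str] = field(default_factory=dict)
    junction_category: dict[str, str] = field(default_factory=dict)
    junction_exon_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    host_flagged_genes: set[str] = field(default_factory=set)


def nb_draw(rng: np.random.Generator, mean, alpha: float):
    """NB2 draws: var = mean + alpha * mean^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def simulate_gene_models(config: SimulationConfig) -> tuple[GeneModel, set[str]]:
    """Multi-exon single-transcript genes on both strands.

    Exon and intron lengths are log-normal; a seeded subset of genes
    (``frac_hosts``) is flagged as future circRNA hosts and receives
    ``host_intron_fold``-times longer introns, so the flanking-intron
    contrast is recoverable downstream. Returns the model and the set of
    host-flagged gene ids (also recorded in SyntheticTruth).
    """
    rng = config.rng(_STAGE_MODELS)
    lo, hi = config.exons_per_gene_range
    if lo < 2 or hi < lo:
        raise ValueError("exons_per_gene_range must be (lo, hi) with 2 <= lo <= hi")
    n_hosts = int(round(config.frac_hosts * config.n_genes))
    host_idx = set(rng.permutation(config.n_genes)[:n_hosts].tolist())

    model = GeneModel()
    hosts: set[str] = set()
    cursors = {f"chrS{i + 1}": 10_000 for i in range(config.n_chroms)}
    width = len(str(config.n_genes))
    for gi in range(config.n_genes):
        chrom = f"chrS{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = np.maximum(
            rng.lognormal(config.exon_len_log_mean, config.exon_len_log_sd, n_exons), 30
        ).astype(int)
        intron_lens = np.maximum(
            rng.lognormal(config.intron_len_log_mean, config.intron_len_log_sd, n_exons - 1),
            80,
        ).astype(int)
        is_host = gi in host_idx
        if is_host:
            intron_lens = (intron_lens * config.host_intron_fold).astype(int)
        pos = cursors[chrom]
        exons = []
        for ei in range(n_exons):
            exons.append((pos, pos + int(exon_lens[ei])))
            pos += int(exon_lens[ei])
            if ei < n_exons - 1:
                pos += int(intron_lens[ei])
        if config.chrom_length is not None and pos > config.chrom_length:
            raise ValueError(
                f"gene {gi} exceeds chrom_length {config.chrom_length} at {pos}"
            )
        cursors[chrom] = pos + 10_000
        gid = f"G{gi + 1:0{width}d}"
        gene = Gene(gene_id=gid, gene_name=gid, chrom=chrom, strand=strand)
        gene.transcripts[f"{gid}.t1"] = Transcript(
            transcript_id=f"{gid}.t1", exons=exons
        )
        model.genes[gid] = gene
        if is_host:
            hosts.add(gid)
    return model, hosts


# ---------------------------------------------------------------------------
# count matrices + design
# ---------------------------------------------------------------------------


def _make_design(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cell_type in sorted(config.samples_per_cell_type):
        n = config.samples_per_cell_type[cell_type]
        n_alt = int(round(config.condition_split * n))
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{cell_type}_{i + 1:02d}",
                    "cell_type": cell_type,
                    "condition": config.contrast_condition if i >= n - n_alt else "HC",
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "age": float(np.round(rng.normal(75.0, 8.0), 1)),
                    "PMI": float(np.round(rng.uniform(2.0, 30.0), 1)),
                    "RIN": float(np.round(rng.uniform(6.0, 9.5), 1)),
                    "library_size": int(
                        rng.integers(config.library_size_range[0],
                                     config.library_size_range[1] + 1)
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _place_junctions(
    models: GeneModel, hosts: set[str], config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], SyntheticTruth]:
    truth = SyntheticTruth(host_flagged_genes=set(hosts))
    host_list = sorted(hosts) if hosts else sorted(models.genes)
    keys: list[str] = []
    used = set()
    attempts = 0
    while len(keys) < config.n_junctions:
        attempts += 1
        if attempts > 50 * config.n_junctions:
            raise ValueError("could not place the requested number of junctions")
        gid = host_list[int(rng.integers(len(host_list)))]
        gene = models.genes[gid]
        tx = next(iter(gene.transcripts.values()))
        n_exons = len(tx.exons)
        if rng.random() < config.frac_cirna and n_exons >= 2:
            introns = tx.introns
            intron = introns[int(rng.integers(len(introns)))]
            ilen = intron[1] - intron[0]
            if ilen < 60:
                continue
            start = intron[0] + int(rng.integers(1, max(ilen // 4, 2)))
            end = intron[1] - int(rng.integers(1, max(ilen // 4, 2)))
            if end - start < 30:
                continue
            category = CIRNA_CATEGORY
            span = None
        else:
            first = int(rng.integers(0, n_exons))
            last = int(rng.integers(first, min(first + 4, n_exons)))
            start, end = tx.exons[first][0], tx.exons[last][1]
            category = EXONIC_CATEGORY
            span = (first, last)
        key = junction_key(gene.chrom, start, end, gene.strand)
        if key in used:
            continue
        used.add(key)
        keys.append(key)
        truth.junction_host[key] = gid
        truth.junction_category[key] = category
        if span is not None:
            truth.junction_exon_span[key] = span
    return keys, truth


def simulate_counts(
    models: GeneModel,
    config: SimulationConfig,
    hosts: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Junction counts, linear gene counts, sample design and truth.

    Junction counts are NB draws around ``baseline_mean_rpm``; planted
    specific junctions have their mean multiplied by ``specificity_fold``
    in their target cell class only; planted DE genes have all their
    junctions' means multiplied by ``de_fold`` (random sign on the log2
    scale) in contrast-condition samples. Linear gene counts are drawn
    independently of the circular counts unless ``coupling`` > 0.
    """
    if len(models) == 0:
        raise ValueError("empty gene model")
    rng = config.rng(_STAGE_COUNTS)
    design = _make_design(config, rng)
    if hosts is None:
        hosts = set(models.genes)
    keys, truth = _place_junctions(models, hosts, config, rng)

    cell_types = sorted(config.samples_per_cell_type)
    n_spec = int(round(config.frac_specific * len(keys)))
    order = rng.permutation(len(keys))
    cursor = 0
    for cell_type in cell_types:
        for idx in order[cursor : cursor + n_spec]:
            truth.specific_junctions[keys[idx]] = cell_type
        cursor += n_spec

    host_genes_with_junction = sorted({truth.junction_host[k] for k in keys})
    n_de = int(round(config.frac_de * len(host_genes_with_junction)))
    if n_de > 0 and config.condition_split > 0:
        de_idx = rng.permutation(len(host_genes_with_junction))[:n_de]
        log2f = float(np.log2(config.de_fold))
        for i in de_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.de_genes[host_genes_with_junction[i]] = sign * log2f

    libs = design["library_size"].to_numpy(dtype=float)
    ct = design["cell_type"].to_numpy()
    is_alt = (design["condition"] == config.contrast_condition).to_numpy()

    mean_rpm = np.full((len(keys), len(design)), float(config.baseline_mean_rpm))
    for ji, key in enumerate(keys):
        spec_ct = truth.specific_junctions.get(key)
        if spec_ct is not None:
            mean_rpm[ji, ct == spec_ct] *= config.specificity_fold
        lf = truth.de_genes.get(truth.junction_host[key])
        if lf is not None:
            mean_rpm[ji, is_alt] *= 2.0**lf
    means = mean_rpm * libs / 1e6
    counts = nb_draw(rng, means, config.nb_dispersion)
    junction_counts = pd.DataFrame(
        counts, index=pd.Index(keys, name="junction"), columns=design.index
    )

    genes = sorted(models.genes)
    linear_mean_rpm = np.full((len(genes), len(design)), float(config.baseline_linear_rpm))
    if config.coupling > 0:
        circ_by_gene = (
            junction_counts.groupby(pd.Series(truth.junction_host)).sum()
            .reindex(genes).fillna(0.0).to_numpy()
        )
        rel = circ_by_gene / np.maximum(circ_by_gene.mean(axis=1, keepdims=True), 1e-9)
        linear_mean_rpm = linear_mean_rpm * (
            1.0 - config.coupling + config.coupling * rel
        )
    linear_counts = pd.DataFrame(
        nb_draw(rng, linear_mean_rpm * libs / 1e6, config.nb_dispersion),
        index=pd.Index(genes, name="gene_id"),
        columns=design.index,
    )
    return junction_counts, linear_counts, design, truth


def simulate_gene_count_matrix(
    config: SimulationConfig, n_genes: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Gene-level NB count matrix with planted condition effects.

    A direct generator for differential-expression studies: one row per
    gene, NB(baseline RPM x library/1e6, nb_dispersion) counts, and
    ``frac_de`` of genes multiplied by ``de_fold`` (random sign on the
    log2 scale) in contrast-condition samples. Returns (counts, design,
    planted log2 folds by gene).
    """
    rng = config.rng(_STAGE_COUNTS)
    design = _make_design(config, rng)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    n_de = int(round(config.frac_de * n_genes))
    de_genes: dict[str, float] = {}
    if n_de > 0 and config.condition_split > 0:
        log2f = float(np.log2(config.de_fold))
        for i in rng.permutation(n_genes)[:n_de]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            de_genes[genes[i]] = sign * log2f
    libs = design["library_size"].to_numpy(dtype=float)
    is_alt = (design["condition"] == config.contrast_condition).to_numpy()
    mean_rpm = np.full((n_genes, len(design)), float(config.baseline_mean_rpm))
    for gi, gene in enumerate(genes):
        if gene in de_genes:
            mean_rpm[gi, is_alt] *= 2.0 ** de_genes[gene]
    counts = pd.DataFrame(
        nb_draw(rng, mean_rpm * libs / 1e6, config.nb_dispersion),
        index=pd.Index(genes, name="gene_id"),
        columns=design.index,
    )
    return counts, design, de_genes


# ---------------------------------------------------------------------------
# RNase-R pairs
# ---------------------------------------------------------------------------


def simulate_rnase_pairs(
    junction_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    config: SimulationConfig,
    design: pd.DataFrame | None = None,
) -> tuple[list[RNasePair], pd.Index, pd.Index]:
    """Paired treated/untreated junction counts.

    Circular junctions keep their observed mean RPM in the untreated
    member and are enriched ``rnase_circ_fold``-fold by treatment; the
    linear rows act as decoy junctions depleted to ``rnase_linear_fold``.
    Returns (pairs, circular keys, linear decoy keys).
    """
    if config.rnase_circ_fold < 1 or config.rnase_linear_fold > 1:
        raise ValueError("expected rnase_circ_fold >= 1 and rnase_linear_fold <= 1")
    rng = config.rng(_STAGE_RNASE)
    if design is not None:
        libs = design.loc[junction_counts.columns, "library_size"].to_numpy(float)
    else:
        libs = np.full(junction_counts.shape[1], float(np.mean(config.library_size_range)))
    circ_rpm = (junction_counts.to_numpy(float) / libs * 1e6).mean(axis=1)
    lin_rpm = (linear_counts.to_numpy(float) / libs * 1e6).mean(axis=1)

    circ_keys = junction_counts.index
    decoy_keys = pd.Index([f"linear:{g}" for g in linear_counts.index])
    universe = circ_keys.append(decoy_keys)
    untreated_rpm = np.concatenate([circ_rpm, lin_rpm])
    treated_rpm = np.concatenate(
        [circ_rpm * config.rnase_circ_fold, lin_rpm * config.rnase_linear_fold]
    )
    pairs = []
    lo, hi = config.library_size_range
    for pi in range(config.n_rnase_pairs):
        lib_t = float(rng.integers(lo, hi + 1))
        lib_u = float(rng.integers(lo, hi + 1))
        treated = nb_draw(rng, treated_rpm * lib_t / 1e6, config.nb_dispersion)
        untreated = nb_draw(rng, untreated_rpm * lib_u / 1e6, config.nb_dispersion)
        pairs.append(
            RNasePair(
                pair_id=f"pair_{pi + 1}",
                treated=pd.Series(treated, index=universe),
                untreated=pd.Series(untreated, index=universe),
                treated_library_size=lib_t,
                untreated_library_size=lib_u,
            )
        )
    return pairs, circ_keys, decoy_keys


# ---------------------------------------------------------------------------
# chimeric read records
# ---------------------------------------------------------------------------


def _segments_for_junction(
    key: str, truth: SyntheticTruth, models: GeneModel, seg_len: int = 30
) -> tuple[Segment, Segment, str]:
    from .io import parse_junction_key

    chrom, start, end, strand = parse_junction_key(key)
    gid = truth.junction_host.get(key)
    if gid is None or gid not in models.genes:
        raise ValueError(f"junction {key} has no host transcript")
    # cap segment length at half the junction span so the two anchor
    # segments never overlap even for single-exon circles
    L = max(min(seg_len, (end - start) // 2), 1)
    span = truth.junction_exon_span.get(key)
    if span is not None:
        tx = next(iter(models.genes[gid].transcripts.values()))
        left_exon = tx.exons[span[0]]
        right_exon = tx.exons[span[1]]
        l1 = min(L, left_exon[1] - left_exon[0])
        l2 = min(L, right_exon[1] - right_exon[0])
        left = Segment(chrom, strand, start, start + l1)
        right = Segment(chrom, strand, end - l2, end)
    else:  # intronic circle: segments hug the circle boundaries
        left = Segment(chrom, strand, start, start + L)
        right = Segment(chrom, strand, end - L, end)
    # back-splicing order: the segment first along the read is the one the
    # read exits the circle through — genomically downstream on '+',
    # upstream on '-'
    if strand == "+":
        return right, left, chrom
    return left, right, chrom


def simulate_chimeric_records(
    junction_counts: pd.DataFrame,
    models: GeneModel,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> list[ChimericReadRecord]:
    """One back-splice-ordered record per counted read, plus colinear decoys.

    Decoys are colinear splices of the same transcripts (fraction
    ``decoy_frac`` of the true record count); they fail the orientation
    test and must be rejected by the calling stage.
    """
    rng = config.rng(_STAGE_READS)
    records: list[ChimericReadRecord] = []
    samples = list(junction_counts.columns)
    mat = junction_counts.to_numpy()
    for ji, key in enumerate(junction_counts.index):
        seg1, seg2, _ = _segments_for_junction(key, truth, models)
        for si, sample in enumerate(samples):
            for ri in range(int(mat[ji, si])):
                records.append(
                    ChimericReadRecord(
                        read_id=f"{key}|{sample}|r{ri}",
                        sample_id=sample,
                        segment1=seg1,
                        segment2=seg2,
                    )
                )
    n_decoys = int(round(config.decoy_frac * len(records)))
    host_list = sorted({g for g in truth.junction_host.values()})
    for di in range(n_decoys):
        gid = host_list[int(rng.integers(len(host_list)))]
        gene = models.genes[gid]
        tx = next(iter(gene.transcripts.values()))
        if len(tx.exons) < 2:
            continue
        i = int(rng.integers(0, len(tx.exons) - 1))
        j = int(rng.integers(i + 1, len(tx.exons)))
        up, down = tx.exons[i], tx.exons[j]
        seg_up = Segment(gene.chrom, gene.strand, max(up[1] - 30, up[0]), up[1])
        seg_down = Segment(gene.chrom, gene.strand, down[0], min(down[0] + 30, down[1]))
        # colinear order along the read: 5' exon first in transcript sense
        if gene.strand == "+":
            seg1, seg2 = seg_up, seg_down
        else:
            seg1, seg2 = seg_down, seg_up
        sample = samples[int(rng.integers(len(samples)))]
        records.append(
            ChimericReadRecord(
                read_id=f"decoy|{di}",
                sample_id=sample,
                segment1=seg1,
                segment2=seg2,
            )
        )
    return records


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    models: GeneModel,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> GeneSetCollection:
    """Random gene sets plus (optionally) one planted enriched disease set.

    The planted set draws its members preferentially from circRNA host
    genes of ``enriched_cell_type`` so that its sampling odds ratio
    against the rest of the universe equals ``planted_set_odds``; all
    other sets are uniform draws. The planted set name is recorded in
    ``truth.enriched_sets``.
    """
    if config.gene_set_size <= 0:
        raise ValueError("gene_set_size must be positive")
    rng = config.rng(_STAGE_SETS)
    universe = sorted(models.genes)
    coll = GeneSetCollection()
    n_random = config.n_gene_sets

    if config.enriched_cell_type is not None:
        hosts = sorted(
            {
                truth.junction_host[k]
                for k, c in truth.specific_junctions.items()
                if c == config.enriched_cell_type
            }
        )
        non_hosts = [g for g in universe if g not in set(hosts)]
        if hosts and non_hosts:
            h, nh = len(hosts), len(non_hosts)
            odds_pool = config.planted_set_odds * h / nh
            pi = odds_pool / (1.0 + odds_pool)
            n_from_hosts = min(int(round(pi * config.gene_set_size)), h)
            n_from_rest = min(config.gene_set_size - n_from_hosts, nh)
            chosen = [hosts[i] for i in rng.choice(h, n_from_hosts, replace=False)]
            chosen += [non_hosts[i] for i in rng.choice(nh, n_from_rest, replace=False)]
            name = "planted_disease"
            coll.sets[name] = set(chosen)
            coll.descriptions[name] = "planted enriched set"
            truth.enriched_sets = [name]
            n_random -= 1

    for si in range(n_random):
        members = rng.choice(len(universe), min(config.gene_set_size, len(universe)),
                             replace=False)
        name = f"set_{si + 1:03d}"
        coll.sets[name] = {universe[i] for i in members}
        coll.descriptions[name] = "random set"
    return coll
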