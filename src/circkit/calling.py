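"""Back-splice junction calling from chimeric read alignments.

A back-splice joins a downstream splice donor to an upstream splice
acceptor, so a chimerically aligned read crosses the junction in
"back-splicing order": on the plus strand the segment that comes first
along the read aligns genomically *downstream* of the second segment
(mirrored on the minus strand). Colinear two-segment alignments are
ordinary linear splices and are rejected by this orientation test, which
is the sole discriminator used here.

Junction categories follow exon-border annotation: ``exonic_circRNA`` when
both boundaries coincide with annotated exon borders of one transcript,
``ciRNA`` when the interval lies inside a single annotated intron, and
``low_confidence`` otherwise (kept only when low-confidence mode is on).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io import ChimericReadRecord, GeneModel, junction_key

logger = logging.getLogger(__name__)

EXONIC = "exonic_circRNA"
CIRNA = "ciRNA"
LOW_CONFIDENCE = "low_confidence"


@dataclass
class BackspliceJunction:
    """One back-splice event with per-sample unique read counts.

    ``start`` is the genomic 5' boundary of the circle (the acceptor on the
    plus strand) and ``end`` the genomic 3' boundary; start < end always.
    """

    chrom: str
    strand: str
    start: int
    end: int
    category: str = LOW_CONFIDENCE
    host_gene: str | None = None
    exon_span: tuple[int, int] | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"junction requires start < end, got [{self.start},{self.end})")

    @property
    def key(self) -> str:
        return junction_key(self.chrom, self.start, self.end, self.strand)

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


def detect_backsplice(record: ChimericReadRecord) -> BackspliceJunction | None:
    """Orientation test on a two-segment chimeric alignment.

    Returns a junction candidate only when both segments share chromosome
    and strand and are in back-splicing order; otherwise None (colinear
    splices and inter-chromosomal fusions are not circles).
    """
    s1, s2 = record.segment1, record.segment2
    if s1.chrom != s2.chrom:
        logger.debug("inter-chromosomal chimera %s skipped", record.read_id)
        return None
    if s1.strand != s2.strand or s1.strand not in "+-":
        return None
    if s1.strand == "+":
        backspliced = s1.start >= s2.end
    else:
        backspliced = s1.end <= s2.start
    if not backspliced:
        return None
    start = min(s1.start, s2.start)
    end = max(s1.end, s2.end)
    return BackspliceJunction(chrom=s1.chrom, strand=s1.strand, start=start, end=end)


class ModelIndex:
    """Per-(chrom, strand) transcript index with exon-border lookups."""

    def __init__(self, models: GeneModel):
        self._by_loc: dict[tuple[str, str], list] = defaultdict(list)
        for gene, tx in models.transcripts():
            starts = {e[0]: i for i, e in enumerate(tx.exons)}
            ends = {e[1]: i for i, e in enumerate(tx.exons)}
            self._by_loc[(gene.chrom, gene.strand)].append(
                (tx.start, tx.end, tx.transcript_id, gene.gene_id, starts, ends, tx.introns)
            )

    def overlapping(self, chrom: str, strand: str, start: int, end: int):
        for tx_start, tx_end, tid, gid, starts, ends, introns in self._by_loc.get(
            (chrom, strand), ()
        ):
            if end > tx_start and start < tx_end:
                yield tid, gid, starts, ends, introns


def annotate_junction(
    candidate: BackspliceJunction, models: GeneModel | ModelIndex
) -> BackspliceJunction:
    """Assign category, host gene and exon span against the gene model.

    Tie-breaking when several transcripts match: exonic beats intronic;
    among exonic matches the transcript spanning the fewest exons wins,
    then the lexicographically smallest transcript_id.
    """
    index = models if isinstance(models, ModelIndex) else ModelIndex(models)
    exonic_matches = []  # (n_spanned, transcript_id, gene_id, span)
    intronic_matches = []  # (transcript_id, gene_id)
    for tid, gid, starts, ends, introns in index.overlapping(
        candidate.chrom, candidate.strand, candidate.start, candidate.end
    ):
        if candidate.start in starts and candidate.end in ends:
            first, last = starts[candidate.start], ends[candidate.end]
            if first <= last:
                exonic_matches.append((last - first + 1, tid, gid, (first, last)))
                continue
        for intron in introns:
            if intron[0] <= candidate.start and candidate.end <= intron[1]:
                intronic_matches.append((tid, gid))
                break
    if exonic_matches:
        _, _tid, gid, span = min(exonic_matches)
        candidate.category = EXONIC
        candidate.host_gene = gid
        candidate.exon_span = span
    elif intronic_matches:
        _tid, gid = min(intronic_matches)
        candidate.category = CIRNA
        candidate.host_gene = gid
        candidate.exon_span = None
    else:
        candidate.category = LOW_CONFIDENCE
        candidate.host_gene = None
        candidate.exon_span = None
    return candidate


def count_unique_reads(
    records: dict[str, list[ChimericReadRecord]]
) -> dict[str, int]:
    """Distinct read_ids per sample; paired mates sharing a read_id count once."""
    return {
        sample: len({r.read_id for r in recs}) for sample, recs in records.items()
    }


def filter_candidates(
    junctions: list[BackspliceJunction], min_total_reads: int = 2
) -> list[BackspliceJunction]:
    """Keep junctions with at least ``min_total_reads`` unique back-spliced
    reads summed over all samples (the "being expressed" candidate filter)."""
    if min_total_reads < 1:
        raise ValueError("min_total_reads must be >= 1")
    return [j for j in junctions if j.total_reads >= min_total_reads]


def call_junctions(
    records: list[ChimericReadRecord],
    models: GeneModel,
    min_total_reads: int = 2,
    low_confidence: bool = True,
) -> list[BackspliceJunction]:
    """Full calling pass: detect, deduplicate, count, annotate, filter.

    With ``low_confidence=False``, junctions whose boundaries do not match
    annotated exon borders (and are not intron-contained) are dropped.
    """
    grouped: dict[tuple, dict[str, list[ChimericReadRecord]]] = defaultdict(
        lambda: defaultdict(list)
    )
    n_dropped_unstranded = 0
    for record in records:
        if record.segment1.strand not in "+-" or record.segment2.strand not in "+-":
            n_dropped_unstranded += 1
            continue
        cand = detect_backsplice(record)
        if cand is None:
            continue
        grouped[(cand.chrom, cand.start, cand.end, cand.strand)][record.sample_id].append(record)
    if n_dropped_unstranded:
        logger.info("dropped %d unstranded chimeric records", n_dropped_unstranded)

    index = ModelIndex(models)
    junctions = []
    for (chrom, start, end, strand), by_sample in grouped.items():
        j = BackspliceJunction(chrom=chrom, strand=strand, start=start, end=end)
        j.counts = count_unique_reads(by_sample)
        annotate_junction(j, index)
        junctions.append(j)
    if not low_confidence:
        junctions = [j for j in junctions if j.category != LOW_CONFIDENCE]
    junctions = filter_candidates(junctions, min_total_reads)
    junctions.sort(key=lambda j: (j.chrom, j.start, j.end, j.strand))
    return junctions


def junctions_to_counts(junctions: list[BackspliceJunction], samples: list[str]):
    """Junction × sample count matrix (pandas DataFrame) from called junctions."""
    import pandas as pd

    data = {
        j.key: [int(j.counts.get(s, 0)) for s in samples] for j in junctions
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(samples)).rename_axis("junction")
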