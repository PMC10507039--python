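"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based, half-open ``[start, end)`` internally.
GTF input (1-based, closed) is converted at the boundary; BED is native.
A back-splice junction is identified by the key ``chrom:start|end:strand``
with ``start < end`` always — the back-splice orientation is encoded in the
junction's category, not by swapping coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("DA", "TCPY", "MCPY", "PBMC", "FB")
CONDITIONS = ("HC", "ILB", "PD", "AD")

DESIGN_COLUMNS = ("cell_type", "condition", "sex", "age", "PMI", "RIN", "library_size")


class FormatError(ValueError):
    """Raised when an input file violates its schema."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise FormatError(
                    f"transcript {self.transcript_id}: exon [{start},{end}) is empty"
                )
            if start < prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: dict[str, Transcript] = field(default_factory=dict)


@dataclass
class GeneModel:
    """A collection of genes with their transcript/exon structure."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def transcripts(self):
        for gene in self:
            for tx in gene.transcripts.values():
                yield gene, tx


def _parse_gtf_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for token in attr_field.strip().rstrip(";").split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            key, value = token.split(" ", 1)
        except ValueError:
            raise FormatError(f"GTF line {lineno}: malformed attribute {token!r}")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path: Path) -> GeneModel:
    model = GeneModel()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates")
            if strand not in "+-":
                raise FormatError(f"GTF line {lineno}: invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(attr, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(
                    f"GTF line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            gene = model.genes.setdefault(
                gid,
                Gene(
                    gene_id=gid,
                    gene_name=attrs.get("gene_name", gid),
                    chrom=chrom,
                    strand=strand,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                ),
            )
            if gene.chrom != chrom or gene.strand != strand:
                raise FormatError(
                    f"GTF line {lineno}: gene {gid} spans multiple chrom/strand"
                )
            tx = gene.transcripts.setdefault(tid, Transcript(transcript_id=tid))
            # GTF is 1-based closed; internal is 0-based half-open
            tx.exons.append((start_i - 1, end_i))
    for gene, tx in model.transcripts():
        if not tx.exons:
            raise FormatError(f"transcript {tx.transcript_id} has zero exons")
        tx.__post_init__()  # re-sort and re-validate after appends
    if not model.genes:
        logger.warning("gene model file %s contained no exon records", path)
    return model


def _read_bed12(path: Path) -> GeneModel:
    model = GeneModel()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"BED12 line {lineno}: expected 12 fields, got {len(fields)}"
                )
            chrom, chrom_start, _end, name, _score, strand = fields[:6]
            try:
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
                starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
                cs = int(chrom_start)
            except ValueError:
                raise FormatError(f"BED12 line {lineno}: non-integer block fields")
            if block_count == 0:
                raise FormatError(f"BED12 line {lineno}: transcript with zero exons")
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"BED12 line {lineno}: blockCount does not match blockSizes/blockStarts"
                )
            exons = [(cs + s, cs + s + z) for s, z in zip(starts, sizes)]
            # name convention: gene_id|transcript_id, else name doubles as both
            gid, _, tid = name.partition("|")
            tid = tid or f"{gid}.t1"
            gene = model.genes.setdefault(
                gid, Gene(gene_id=gid, gene_name=gid, chrom=chrom, strand=strand)
            )
            gene.transcripts[tid] = Transcript(transcript_id=tid, exons=exons)
    if not model.genes:
        logger.warning("gene model file %s contained no records", path)
    return model


def read_gene_model(path: str | Path) -> GeneModel:
    """Read gene models from GTF (Ensembl dialect) or BED12.

    Coordinates are converted to 0-based half-open; exons are sorted by
    start within each transcript.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _read_bed12(path)
    return _read_gtf(path)


def write_gtf(model: GeneModel, path: str | Path) -> None:
    """Write exon records in Ensembl GTF dialect (1-based closed)."""
    with open(path, "w") as fh:
        for gene in sorted(model, key=lambda g: (g.chrom, min(t.start for t in g.transcripts.values()), g.gene_id)):
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tid}"; '
                        f'gene_name "{gene.gene_name}"; gene_biotype "{gene.biotype}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tcirckit\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# junction count matrices
# ---------------------------------------------------------------------------


def junction_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}|{end}:{strand}"


def parse_junction_key(key: str) -> tuple[str, int, int, str]:
    chrom, span, strand = key.rsplit(":", 2)
    start, end = span.split("|")
    return chrom, int(start), int(end), strand


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    """Read a junction × sample count matrix.

    The TSV carries columns chrom, start, end, strand and one integer
    column per sample. Returns a DataFrame indexed by the junction key
    ``chrom:start|end:strand``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = ["chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"junction count table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise FormatError("junction count table has no sample columns")
    counts = df[sample_cols]
    if not all(np.issubdtype(d, np.integer) for d in counts.dtypes):
        bad = [c for c in sample_cols if not np.issubdtype(counts[c].dtype, np.integer)]
        raise FormatError(f"non-integer counts in columns: {bad}")
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative counts in junction table")
    keys = [
        junction_key(r.chrom, r.start, r.end, r.strand)
        for r in df.itertuples(index=False)
    ]
    dup = pd.Index(keys).duplicated()
    if dup.any():
        raise FormatError(
            f"duplicate junction keys: {sorted(set(np.asarray(keys)[dup]))[:5]}"
        )
    out = counts.copy()
    out.index = pd.Index(keys, name="junction")
    return out


def write_junction_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_junction_counts` (bit-exact round-trip)."""
    rows = [parse_junction_key(k) for k in counts.index]
    head = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    body = counts.reset_index(drop=True)
    pd.concat([head, body], axis=1).to_csv(path, sep="\t", index=False)


def check_samples_against_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = sorted(set(counts.columns) - set(design.index))
    if missing:
        raise FormatError(f"samples absent from design table: {missing}")


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (sample_id + covariates)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError("design table requires a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design table")
    df = df.set_index("sample_id")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing columns: {missing}")
    if (df["library_size"] <= 0).any():
        raise FormatError("library_size must be positive")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chimeric read records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"empty aligned segment [{self.start},{self.end})")


@dataclass(frozen=True)
class ChimericReadRecord:
    """A read aligned in two segments; segment1 comes first along the read."""

    read_id: str
    sample_id: str
    segment1: Segment
    segment2: Segment


_CHIMERIC_COLUMNS = [
    "read_id", "sample_id",
    "chrom1", "strand1", "start1", "end1",
    "chrom2", "strand2", "start2", "end2",
]


def read_chimeric_records(path: str | Path) -> list[ChimericReadRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    missing = [c for c in _CHIMERIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"chimeric record table missing columns: {missing}")
    return [
        ChimericReadRecord(
            read_id=str(r.read_id),
            sample_id=str(r.sample_id),
            segment1=Segment(r.chrom1, r.strand1, int(r.start1), int(r.end1)),
            segment2=Segment(r.chrom2, r.strand2, int(r.start2), int(r.end2)),
        )
        for r in df.itertuples(index=False)
    ]


def write_chimeric_records(records, path: str | Path) -> None:
    rows = [
        (r.read_id, r.sample_id,
         r.segment1.chrom, r.segment1.strand, r.segment1.start, r.segment1.end,
         r.segment2.chrom, r.segment2.strand, r.segment2.start, r.segment2.end)
        for r in records
    ]
    pd.DataFrame(rows, columns=_CHIMERIC_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-style or disease), optionally GDA-scored.

    Gene symbols are matched case-sensitively; duplicates within a set are
    collapsed.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected name, description and >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            if name in coll.sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            coll.sets[name] = set(genes)
            coll.descriptions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.sets:
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{genes}\n")


def read_gene_disease_table(path: str | Path, min_gda: float = 0.1) -> GeneSetCollection:
    """Read a gene–disease association table and group genes by disease.

    Rows with GDA score <= ``min_gda`` are excluded (strict inequality:
    associations with score > threshold are retained).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("disease", "gene", "gda_score"):
        if col not in df.columns:
            raise FormatError(f"gene–disease table missing column {col!r}")
    scores = pd.to_numeric(df["gda_score"], errors="coerce")
    if scores.isna().any():
        bad = df.loc[scores.isna(), "gda_score"].iloc[0]
        raise FormatError(f"non-numeric gda_score value {bad!r}")
    kept = df[scores > min_gda]
    coll = GeneSetCollection()
    for disease, group in kept.groupby("disease", sort=True):
        coll.sets[str(disease)] = set(group["gene"].astype(str))
        coll.descriptions[str(disease)] = ""
    return coll


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------


def write_junction_bed(junctions, path: str | Path) -> None:
    """Write annotated junctions as BED6.

    Score column is the total unique back-spliced read count; name is
    ``host_gene:category``.
    """
    junctions = list(junctions)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for j in junctions:
            host = j.host_gene or "NA"
            total = int(sum(j.counts.values()))
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{host}:{j.category}\t{total}\t{j.strand}\n")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ interval file into a DataFrame (chrom, start, end[, ...])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno}: fewer than 3 fields")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]),
                     fields[3] if len(fields) > 3 else ".",
                     fields[5] if len(fields) > 5 else ".")
                )
            except ValueError:
                raise FormatError(f"BED line {lineno}: non-integer coordinates")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
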