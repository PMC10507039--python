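"""Abundance normalization and the RNase-R validation filter.

Circular RNA abundance is expressed as RPM — back-spliced reads per
million mapped reads. Linear gene abundance is FPKM. The RNase-R filter
validates a junction when, in at least one treated/untreated library
pair, the treated sample shows >= ``min_treated_reads`` unique reads and
at least ``min_fold`` enrichment over the untreated sample. RNase R is a
3'->5' exoribonuclease that digests linear RNA but not covalently closed
circles, so true circles are enriched by treatment while linear species
are depleted.

Enrichment folds are computed on RPM by default (treated and untreated
libraries differ strongly in composition, so raw-count folds would be
library-size confounded), with a pseudocount of one read added to the
untreated count before normalization as a division-by-zero guard. A
raw-count mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import BackspliceJunction, CIRNA, EXONIC


def rpm_normalize(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """counts / library_size * 1e6, per sample column."""
    missing = [s for s in counts.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples without library size in design: {missing}")
    libs = design.loc[counts.columns, "library_size"].astype(float)
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("library sizes must be positive and non-missing")
    return counts / libs * 1e6


def fpkm_normalize(
    counts: pd.DataFrame, lengths: pd.Series, design: pd.DataFrame
) -> pd.DataFrame:
    """counts / (length/1e3) / (library_size/1e6), per gene row and sample column."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    libs = design.loc[counts.columns, "library_size"].astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


@dataclass
class CircLinearRatio:
    junction: str
    circ_reads: float
    linear_acceptor: float
    linear_donor: float
    ratio: float | None  # None when circ and both linear counts are 0


def circ_linear_ratio(
    junction: str,
    circ: float,
    linear_acceptor: float,
    linear_donor: float,
    linear_summary: str = "mean",
) -> CircLinearRatio:
    """Circularization ratio: circ / (circ + linear reads around the site).

    The linear summary over the two back-splice boundaries is their
    arithmetic mean by default (``max`` and ``sum`` also supported).
    Undefined (ratio None) when the circle and both boundaries have zero
    reads.
    """
    if min(circ, linear_acceptor, linear_donor) < 0:
        raise ValueError("read counts must be non-negative")
    if linear_summary == "mean":
        lin = (linear_acceptor + linear_donor) / 2.0
    elif linear_summary == "max":
        lin = max(linear_acceptor, linear_donor)
    elif linear_summary == "sum":
        lin = linear_acceptor + linear_donor
    else:
        raise ValueError(f"unknown linear_summary {linear_summary!r}")
    ratio = None if circ == 0 and lin == 0 else circ / (circ + lin)
    return CircLinearRatio(junction, circ, linear_acceptor, linear_donor, ratio)


@dataclass
class RNasePair:
    """One paired RNase-R treated / untreated (mock) library."""

    pair_id: str
    treated: pd.Series  # junction -> unique read count
    untreated: pd.Series
    treated_library_size: float
    untreated_library_size: float

    def __post_init__(self) -> None:
        if not self.treated.index.equals(self.untreated.index):
            self.untreated = self.untreated.reindex(self.treated.index)
            if self.untreated.isna().any():
                raise ValueError(
                    f"pair {self.pair_id}: treated/untreated junction universes differ"
                )


def rnase_validate(
    junctions: list[str] | pd.Index,
    pairs: list[RNasePair],
    min_treated_reads: int = 20,
    min_fold: float = 2.0,
    use_rpm: bool = True,
) -> pd.Series:
    """Validated flag per junction under the RNase-R enrichment criterion.

    A junction is validated iff in at least one pair the treated count is
    >= ``min_treated_reads`` AND treated abundance >= ``min_fold`` x
    untreated abundance. Abundances are RPM with a +1 read pseudocount on
    the untreated member (``use_rpm=False`` compares raw counts, same
    pseudocount).
    """
    if min_treated_reads <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    if not pairs:
        raise ValueError("at least one RNase pair is required")
    junctions = pd.Index(junctions)
    validated = pd.Series(False, index=junctions)
    for pair in pairs:
        t = pair.treated.reindex(junctions, fill_value=0).astype(float)
        u = pair.untreated.reindex(junctions, fill_value=0).astype(float)
        if use_rpm:
            t_ab = t / pair.treated_library_size * 1e6
            u_ab = (u + 1.0) / pair.untreated_library_size * 1e6
        else:
            t_ab = t
            u_ab = u + 1.0
        ok = (t >= min_treated_reads) & (t_ab >= min_fold * u_ab)
        validated |= ok
    return validated


def summarize_catalog(
    junctions: list[BackspliceJunction],
    validated: pd.Series,
    max_hist_reads: int = 50,
) -> dict:
    """Catalog summary: per-category counts and validation rates, the
    circRNAs-per-host-gene distribution, the read-support histogram, and
    the correlation between circRNAs per gene and host exon count."""
    rows = [
        (j.key, j.category, j.host_gene, j.total_reads,
         (j.exon_span[1] - j.exon_span[0] + 1) if j.exon_span else np.nan)
        for j in junctions
    ]
    df = pd.DataFrame(rows, columns=["junction", "category", "host_gene", "total_reads", "n_exons"])
    df["validated"] = validated.reindex(df["junction"]).fillna(False).to_numpy()

    per_cat = (
        df.groupby("category")
        .agg(candidates=("junction", "size"), validated=("validated", "sum"))
        .assign(rate_pct=lambda d: (100.0 * d["validated"] / d["candidates"]).round(1))
    )

    per_gene = df.dropna(subset=["host_gene"]).groupby("host_gene").size()
    hist = (
        df["total_reads"].clip(upper=max_hist_reads).value_counts().sort_index()
    )

    # circRNAs per gene vs number of annotated exons spanned (proxy for
    # host exon count among observed circles)
    exon_max = df.dropna(subset=["host_gene"]).groupby("host_gene")["n_exons"].max()
    common = per_gene.index.intersection(exon_max.dropna().index)
    if len(common) >= 3 and per_gene.loc[common].nunique() > 1 and exon_max.loc[common].nunique() > 1:
        rho, rho_p = stats.spearmanr(per_gene.loc[common], exon_max.loc[common])
    else:
        rho, rho_p = np.nan, np.nan

    return {
        "per_category": per_cat,
        "circ_per_gene": per_gene,
        "read_support_hist": hist,
        "exon_count_correlation": {"spearman_rho": rho, "p": rho_p},
        "n_candidates": len(df),
        "n_validated": int(df["validated"].sum()),
    }


def validation_rate_pct(n_validated: int, n_candidates: int) -> float:
    """Percentage of candidates passing validation (unrounded; e.g.
    10,845 of 22,593 exonic candidates -> 48.0018...)."""
    if n_candidates <= 0:
        raise ValueError("candidate count must be positive")
    if n_validated < 0 or n_validated > n_candidates:
        raise ValueError("validated count must be in [0, candidates]")
    return 100.0 * n_validated / n_candidates
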