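"""Genomic characteristics of circularized exons vs control exons.

Circularized exons are contrasted with a seeded uniform sample of
non-circularized internal exons on exon length, flanking intron length,
repeat content, and RBP (eCLIP-style) peak overlap. Group differences are
tested with a two-sided Mann–Whitney rank-sum test: exact enumeration of
the U distribution when both groups have at most 8 observations, a
tie-corrected normal approximation (with continuity correction)
otherwise.

Interval overlap follows the half-open convention everywhere: a feature
abutting a query at its end coordinate does not overlap. Counts refer to
individual feature intervals; covered fractions merge the features first,
so overlapping features are not double-counted.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

from .calling import BackspliceJunction, EXONIC
from .io import GeneModel


# ---------------------------------------------------------------------------
# flanking introns
# ---------------------------------------------------------------------------


def extract_flanks(
    junction: BackspliceJunction, models: GeneModel
) -> dict[str, tuple[int, int] | None]:
    """Flanking intron intervals of an exonic circRNA.

    Upstream/downstream follow the transcript orientation (on the minus
    strand the upstream flank is genomically to the right). A missing
    flank (circle starting at the first or ending at the last exon)
    is returned as None.
    """
    if junction.category != EXONIC or junction.host_gene is None:
        raise ValueError("flanks are defined only for annotated exonic circRNAs")
    gene = models.genes[junction.host_gene]
    matches = []
    for tid in sorted(gene.transcripts):
        tx = gene.transcripts[tid]
        starts = {e[0]: i for i, e in enumerate(tx.exons)}
        ends = {e[1]: i for i, e in enumerate(tx.exons)}
        if junction.start in starts and junction.end in ends:
            f, l = starts[junction.start], ends[junction.end]
            if f <= l:
                matches.append((l - f + 1, tid, tx, f, l))
    if not matches:
        raise ValueError(f"junction {junction.key} has no exon-border match in host")
    _, _, tx, first, last = min(matches, key=lambda m: (m[0], m[1]))
    left = (tx.exons[first - 1][1], tx.exons[first][0]) if first > 0 else None
    right = (
        (tx.exons[last][1], tx.exons[last + 1][0])
        if last < len(tx.exons) - 1
        else None
    )
    if junction.strand == "+":
        return {"upstream": left, "downstream": right}
    return {"upstream": right, "downstream": left}


def sample_control_exons(
    models: GeneModel,
    circularized: set[tuple[str, int, int]],
    n: int,
    seed: int,
) -> list[tuple[str, int, int]]:
    """Seeded uniform sample of n internal exons not overlapping any
    circularized exon (the background group for the contrasts)."""
    circ_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in circularized:
        circ_by_chrom.setdefault(chrom, []).append((s, e))
    trees = {
        chrom: IntervalTree.from_tuples(iv) for chrom, iv in circ_by_chrom.items()
    }
    eligible = []
    seen = set()
    for gene, tx in models.transcripts():
        for s, e in tx.exons[1:-1]:
            key = (gene.chrom, s, e)
            if key in seen or key in circularized:
                continue
            tree = trees.get(gene.chrom)
            if tree is not None and tree.overlap(s, e):
                continue
            seen.add(key)
            eligible.append(key)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible control exons for a sample of {n}"
        )
    eligible.sort()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------


class FeatureIndex:
    """Per-chromosome interval index over a feature BED (repeats, peaks)."""

    def __init__(self, features: pd.DataFrame, stranded: bool = False):
        self.stranded = stranded
        self._trees: dict = {}
        self._merged: dict = {}
        group_cols = ["chrom", "strand"] if stranded else ["chrom"]
        for key, grp in features.groupby(group_cols):
            key = key if stranded else key[0]
            ivs = grp[["start", "end"]].to_numpy()
            self._trees[key] = IntervalTree.from_tuples(map(tuple, ivs))
            order = np.argsort(ivs[:, 0], kind="mergesort")
            starts, ends = ivs[order, 0], ivs[order, 1]
            m_starts, m_ends = [], []
            for s, e in zip(starts, ends):
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            self._merged[key] = (np.asarray(m_starts), np.asarray(m_ends))

    def _key(self, chrom: str, strand: str):
        return (chrom, strand) if self.stranded else chrom

    def count(self, chrom: str, start: int, end: int, strand: str = ".") -> int:
        tree = self._trees.get(self._key(chrom, strand))
        return len(tree.overlap(start, end)) if tree is not None else 0

    def covered_fraction(
        self, chrom: str, start: int, end: int, strand: str = "."
    ) -> float:
        merged = self._merged.get(self._key(chrom, strand))
        if merged is None or end <= start:
            return 0.0
        m_starts, m_ends = merged
        lo = np.clip(m_starts, start, end)
        hi = np.clip(m_ends, start, end)
        return float(np.maximum(hi - lo, 0).sum() / (end - start))


def overlap_stats(
    intervals: pd.DataFrame, features: pd.DataFrame, stranded: bool = False
) -> pd.DataFrame:
    """Per-interval feature overlap count and covered fraction.

    ``intervals`` and ``features`` need columns chrom, start, end (and
    strand when ``stranded``). Counts use the raw feature intervals;
    fractions use the merged features.
    """
    index = FeatureIndex(features, stranded=stranded)
    counts, fractions = [], []
    for row in intervals.itertuples(index=False):
        strand = getattr(row, "strand", ".")
        counts.append(index.count(row.chrom, row.start, row.end, strand))
        fractions.append(index.covered_fraction(row.chrom, row.start, row.end, strand))
    out = intervals.copy()
    out["overlap_count"] = counts
    out["covered_fraction"] = fractions
    return out


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------


def _rank_with_ties(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(x, y, exact_max_n: int = 8) -> dict:
    """Two-sided Mann–Whitney U test.

    Exact p by full enumeration of the permutation distribution of U when
    both groups have at most ``exact_max_n`` observations; otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns U (for the first group), p, and the group medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rank_with_ties(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 <= exact_max_n and n2 <= exact_max_n:
        us = []
        idx = range(n1 + n2)
        for comb in combinations(idx, n1):
            r = ranks[list(comb)].sum()
            us.append(r - n1 * (n1 + 1) / 2.0)
        us = np.asarray(us)
        total = len(us)
        p = 2.0 * min(
            (us <= u1 + 1e-9).sum() / total, (us >= u1 - 1e-9).sum() / total
        )
        p = min(p, 1.0)
        method = "exact"
    else:
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            z = max(abs(u1 - mean_u) - 0.5, 0.0) / np.sqrt(var_u)
            p = float(2.0 * norm.sf(z))
        method = "asymptotic"
    return {
        "U": u1,
        "p": float(p),
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
        "method": method,
    }


def compare_groups(
    circ_values, control_values, variable: str = ""
) -> dict:
    """Two-sided rank-sum contrast between circularized and control exons
    on one variable (length, flank length, repeat fraction, peak count)."""
    res = mann_whitney(circ_values, control_values)
    res["variable"] = variable
    return res


def exon_feature_table(
    junctions: list[BackspliceJunction],
    models: GeneModel,
    repeats: pd.DataFrame | None = None,
    peaks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-circularized-exon feature record: exon length, flanking intron
    lengths, repeat overlap, peak overlap (for exonic junctions)."""
    rows = []
    for j in junctions:
        if j.category != EXONIC:
            continue
        flanks = extract_flanks(j, models)
        up, down = flanks["upstream"], flanks["downstream"]
        rows.append(
            {
                "junction": j.key,
                "chrom": j.chrom,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "length": j.end - j.start,
                "upstream_flank_len": (up[1] - up[0]) if up else np.nan,
                "downstream_flank_len": (down[1] - down[0]) if down else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for name, feats in (("repeat", repeats), ("peak", peaks)):
        if feats is not None:
            stats = overlap_stats(df[["chrom", "start", "end"]], feats)
            df[f"{name}_count"] = stats["overlap_count"].to_numpy()
            df[f"{name}_fraction"] = stats["covered_fraction"].to_numpy()
    return df
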