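"""Jensen–Shannon cell-type specificity scoring.

For each transcript c the expression profile p_c over cell classes is the
per-class mean RPM, shifted by +1 and normalized to a probability vector.
The specificity score toward class i is

    S_{c,i} = 1 - JSD(p_c, q_i)

where q_i is the unit vector of perfect expression in class i (e.g.
[1, 0, 0, 0, 0]) and JSD is the Jensen–Shannon *distance*: the square
root of the Jensen–Shannon divergence with base-2 entropies, so that
JSD and S both live in [0, 1].

A transcript is called specific to class i when S_{c,i} >= 0.5 and its
mean expression in that class exceeds the mean + one standard deviation
of its overall expression across all samples of the analysis subset
(by default the healthy-control samples only, to avoid confounding by
disease state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FIVE_WAY = ("DA", "TCPY", "MCPY", "PBMC", "FB")
THREE_WAY_MAP = {"DA": "DA", "TCPY": "PY", "MCPY": "PY", "PBMC": "NN", "FB": "NN"}
THREE_WAY = ("DA", "PY", "NN")


@dataclass
class CellTypeScheme:
    """Ordered cell classes and the sample -> class mapping.

    The class order is fixed: it defines the index i of the unit vector
    q_i that each per-class score is computed against.
    """

    classes: tuple[str, ...]
    sample_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set(self.sample_class.values())
        empty = [c for c in self.classes if c not in seen]
        if empty:
            raise ValueError(f"cell classes without samples: {empty}")
        unknown = seen - set(self.classes)
        if unknown:
            raise ValueError(f"samples mapped to unknown classes: {sorted(unknown)}")

    @classmethod
    def from_design(
        cls, design: pd.DataFrame, scheme: str = "5way", controls_only: bool = True
    ) -> "CellTypeScheme":
        sub = design[design["condition"] == "HC"] if controls_only else design
        if scheme == "5way":
            classes, mapping = FIVE_WAY, {c: c for c in FIVE_WAY}
        elif scheme == "3way":
            classes, mapping = THREE_WAY, THREE_WAY_MAP
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        sample_class = {s: mapping[ct] for s, ct in sub["cell_type"].items()}
        return cls(classes=classes, sample_class=sample_class)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_class)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd(p, q) -> float:
    """Jensen–Shannon distance (base-2 entropies, 0*log0 = 0).

    JSD(p, q) = sqrt( H(m) - [H(p) + H(q)] / 2 ),  m = (p + q) / 2.
    Bounded in [0, 1]; a metric on probability vectors.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors differ in length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    if not (np.isclose(p.sum(), 1.0, atol=1e-9) and np.isclose(q.sum(), 1.0, atol=1e-9)):
        raise ValueError("probability vectors must sum to 1")
    m = (p + q) / 2.0
    divergence = _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2.0
    return float(np.sqrt(max(divergence, 0.0)))


def class_mean_profile(
    matrix: pd.DataFrame, scheme: CellTypeScheme
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Per-transcript expression profiles over cell classes.

    Returns (p_c profiles, per-class mean RPM, overall mean, overall s.d.)
    with profiles normalized densities of (mean RPM + 1). Only samples in
    the scheme's analysis subset are used; overall mean/s.d. pool all of
    those samples.
    """
    samples = [s for s in scheme.samples if s in matrix.columns]
    absent = set(scheme.samples) - set(samples)
    if absent:
        raise ValueError(f"scheme samples missing from matrix: {sorted(absent)[:5]}")
    sub = matrix[samples]
    groups = pd.Series({s: scheme.sample_class[s] for s in samples})
    class_means = sub.T.groupby(groups).mean().T[list(scheme.classes)]
    shifted = class_means + 1.0
    profiles = shifted.div(shifted.sum(axis=1), axis=0)
    overall_mean = sub.mean(axis=1)
    overall_sd = sub.std(axis=1, ddof=1)
    return profiles, class_means, overall_mean, overall_sd


def specificity_scores(profiles: pd.DataFrame) -> pd.DataFrame:
    """S_{c,i} = 1 - JSD(p_c, q_i) for every transcript and class.

    Vectorized over transcripts: against a unit vector q_i, H(q)=0 and
    H(m) decomposes entry-wise with m = (p + q_i)/2.
    """
    p = profiles.to_numpy(dtype=float)
    n, k = p.shape
    mask = p > 0
    h_p = -(np.where(mask, p * np.log2(np.where(mask, p, 1.0)), 0.0)).sum(axis=1)
    scores = np.empty((n, k))
    for i in range(k):
        m = p / 2.0
        mi = (p[:, i] + 1.0) / 2.0
        mm = m.copy()
        mm[:, i] = mi
        msk = mm > 0
        h_m = -(np.where(msk, mm * np.log2(np.where(msk, mm, 1.0)), 0.0)).sum(axis=1)
        div = h_m - h_p / 2.0
        scores[:, i] = 1.0 - np.sqrt(np.clip(div, 0.0, None))
    return pd.DataFrame(scores, index=profiles.index, columns=profiles.columns)


def classify_specific(
    scores: pd.DataFrame,
    class_means: pd.DataFrame,
    overall_mean: pd.Series,
    overall_sd: pd.Series,
    threshold_s: float = 0.5,
) -> pd.DataFrame:
    """Per-class specific flag: S >= threshold and class mean RPM strictly
    greater than overall mean + 1 s.d. of expression across samples."""
    gate = class_means.gt(overall_mean + overall_sd, axis=0)
    return scores.ge(threshold_s) & gate


@dataclass
class SpecificityResult:
    scores: pd.DataFrame  # transcript x class S values
    class_means: pd.DataFrame
    specific: pd.DataFrame  # boolean flags
    best_class: pd.Series

    @property
    def table(self) -> pd.DataFrame:
        out = self.scores.add_prefix("S_")
        out["best_class"] = self.best_class
        out["specific_any"] = self.specific.any(axis=1)
        out["specific_class"] = self.specific.idxmax(axis=1).where(
            self.specific.any(axis=1)
        )
        return out


def score_matrix(
    matrix: pd.DataFrame, scheme: CellTypeScheme, threshold_s: float = 0.5
) -> SpecificityResult:
    """Full specificity pass over an RPM (or FPKM) matrix."""
    profiles, class_means, mean, sd = class_mean_profile(matrix, scheme)
    scores = specificity_scores(profiles)
    flags = classify_specific(scores, class_means, mean, sd, threshold_s)
    best = scores.idxmax(axis=1)
    return SpecificityResult(scores, class_means, flags, best)


def zscore_matrix(class_means: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores of per-class means, for heatmap-style export."""
    mu = class_means.mean(axis=1)
    sd = class_means.std(axis=1, ddof=1).replace(0.0, np.nan)
    return class_means.sub(mu, axis=0).div(sd, axis=0)


def compare_circ_vs_linear(
    circ: SpecificityResult,
    linear: SpecificityResult,
    locus_map: pd.Series,
    single_circ_only: bool = False,
) -> dict:
    """Paired per-locus comparison of circular vs linear specificity.

    ``locus_map`` maps circular transcript id -> host locus (the linear
    result is indexed by locus). Each transcript contributes its best-class
    score. Returns the paired table, the Mann–Whitney two-sided p and the
    median difference; optionally restricted to loci hosting one circRNA.
    """
    locus_map = locus_map.reindex(circ.scores.index).dropna()
    if single_circ_only:
        counts = locus_map.value_counts()
        locus_map = locus_map[locus_map.map(counts).eq(1)]
    rows = []
    best_circ = circ.scores.max(axis=1)
    best_lin = linear.scores.max(axis=1)
    for transcript, locus in locus_map.items():
        if locus in best_lin.index:
            rows.append((transcript, locus, best_circ[transcript], best_lin[locus]))
    if not rows:
        raise ValueError("no loci with both a circular and a linear transcript")
    table = pd.DataFrame(rows, columns=["transcript", "locus", "S_circ", "S_linear"])
    if np.allclose(table["S_circ"], table["S_linear"]):
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(
            table["S_circ"], table["S_linear"], alternative="two-sided"
        )
    return {
        "table": table,
        "p": float(p),
        "median_diff": float((table["S_circ"] - table["S_linear"]).median()),
    }
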