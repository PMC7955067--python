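"""Skewness-weighted Pearson similarity and cell-line identity recall.

The primary instrument for judging a batch correction: after integration,
a screen of cell line X from one institute should be more similar to the
screen of X from the other institute than to any other screen. Similarity is
a weighted Pearson correlation whose per-gene weights are the absolute mean
skewness of the gene's dependency signal across the overlapping cell lines
-- upweighting selective dependencies, which carry cell-line identity, and
downweighting flat or unselective profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ScreenMatrix, ScreenMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "RecallCurve",
    "skewness_weights",
    "weighted_pearson",
    "wpearson_matrix",
    "identity_recall_curve",
]


@dataclass
class WeightVector:
    """Per-gene non-negative weights, aligned to a gene list."""

    weights: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.gene_ids):
            raise ValueError("weight length does not match gene list")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not (self.weights > 0).any():
            raise ValueError("weights must not be all zero")

    def for_genes(self, genes: list[str]) -> np.ndarray:
        s = pd.Series(self.weights, index=self.gene_ids)
        return s.reindex(genes).fillna(0.0).to_numpy()


@dataclass
class RecallCurve:
    """Proportion of queries whose counterpart lies within the k-neighborhood."""

    k: np.ndarray
    proportion: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.proportion) < 0):
            raise ValueError("recall curve must be non-decreasing")

    @property
    def nauc(self) -> float:
        return float(np.mean(self.proportion))

    def at(self, k: int) -> float:
        return float(self.proportion[int(k) - 1])


def skewness_weights(a: ScreenMatrix, b: ScreenMatrix, overlap_screens_a=None,
                     overlap_screens_b=None) -> WeightVector:
    """w_g = |(skew_a(g) + skew_b(g)) / 2| across overlap screens.

    Skewness is the adjusted Fisher-Pearson moment coefficient (small-sample
    corrected). Genes with zero variance in a dataset contribute skewness 0
    there, and a gene flat in both datasets gets weight 0 (logged).
    """
    if overlap_screens_a is not None:
        a = a.subset_screens(list(overlap_screens_a))
    if overlap_screens_b is not None:
        b = b.subset_screens(list(overlap_screens_b))
    if a.gene_ids != b.gene_ids:
        raise ValueError("matrices must share an identical gene list")

    def _skew(m: ScreenMatrix) -> np.ndarray:
        vals = np.where(m.missing_mask, np.nan, m.values)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = stats.skew(vals, axis=1, bias=False, nan_policy="omit")
        return np.nan_to_num(np.asarray(s, dtype=float))

    w = np.abs((_skew(a) + _skew(b)) / 2.0)
    n_zero = int((w == 0).sum())
    if n_zero:
        logger.info("%d genes received zero skewness weight", n_zero)
    return WeightVector(w, list(a.gene_ids))


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation over pairwise-complete entries.

    Uniform weights reduce to the plain Pearson correlation. Zero weighted
    variance in either vector yields NaN (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (w > 0)
    x, y, w = x[ok], y[ok], w[ok]
    if w.sum() == 0 or x.size < 2:
        logger.info("weighted Pearson undefined: no usable entries")
        return float("nan")
    wn = w / w.sum()
    mx, my = wn @ x, wn @ y
    cov = wn @ ((x - mx) * (y - my))
    vx = wn @ ((x - mx) ** 2)
    vy = wn @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        logger.info("weighted Pearson undefined: zero weighted variance")
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def wpearson_matrix(m: ScreenMatrix, w: WeightVector) -> pd.DataFrame:
    """All-pairs weighted Pearson between screens (missing entries are
    imputed at the per-gene weighted mean before the product)."""
    weights = w.for_genes(m.gene_ids)
    wn = weights / weights.sum()
    X = np.where(m.missing_mask, np.nan, m.values)
    gene_mean = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), gene_mean[:, None], X)
    mu = wn @ X
    Xc = (X - mu) * np.sqrt(wn)[:, None]
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms[norms == 0] = np.nan
    corr = (Xc.T @ Xc) / np.outer(norms, norms)
    return pd.DataFrame(corr, index=m.screen_ids, columns=m.screen_ids)


def identity_recall_curve(
    corrected: ScreenMatrix,
    meta: ScreenMetadata,
    w: WeightVector,
    k_max: int | None = None,
) -> RecallCurve:
    """Recall of cell-line identity across institutes.

    For each overlap screen, all other screens of the union are ranked by
    weighted Pearson (descending; ties broken by screen id for determinism)
    and the rank of the same-cell-line screen from the other batch is found.
    Each cell line keeps the minimum of its two directional ranks;
    ``curve(k)`` is the fraction of overlap cell lines with min-rank <= k.
    nAUC is the mean of the curve over k = 1..K (K = all candidates by
    default). Cell lines without a counterpart are excluded (logged).
    """
    meta = meta.for_screens(corrected.screen_ids)
    line_of = meta.cell_line_of()
    batch_of = meta.batch_of()
    pairs: dict[str, list[str]] = {}
    for sid in corrected.screen_ids:
        pairs.setdefault(line_of[sid], []).append(sid)
    dup_lines = {
        l: sorted(s)
        for l, s in pairs.items()
        if len(s) == 2 and len({batch_of[x] for x in s}) == 2
    }
    skipped = [l for l, s in pairs.items() if len(s) != 2 or l not in dup_lines]
    if skipped:
        logger.info("excluded %d cell lines without a cross-batch counterpart", len(skipped))
    if not dup_lines:
        raise ValueError("no overlap cell lines with one screen in each batch")

    corr = wpearson_matrix(corrected, w)
    screen_ids = np.array(corrected.screen_ids)
    n = len(screen_ids)
    K = n - 1 if k_max is None else int(k_max)

    def rank_of(query: str, target: str) -> int:
        c = corr.loc[query].drop(query)
        order = sorted(c.index, key=lambda s: (-c[s], s))
        return order.index(target) + 1

    min_ranks = []
    for _line, (s1, s2) in sorted(dup_lines.items()):
        min_ranks.append(min(rank_of(s1, s2), rank_of(s2, s1)))
    min_ranks = np.asarray(min_ranks)
    ks = np.arange(1, K + 1)
    proportion = np.array([(min_ranks <= k).mean() for k in ks])
    return RecallCurve(ks, proportion)
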