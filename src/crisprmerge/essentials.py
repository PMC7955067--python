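"""Common-essential gene identification.

Three layers: per-screen binary depletion calls from a precision curve over
prior-known essential/non-essential controls (5% FDR rank threshold); the
90th-percentile method, which asks whether a gene still ranks among the most
depleted in its 90th-percentile least dependent cell line and separates the
resulting rank distribution with a two-component Gaussian mixture; and an
ADaM-style consensus that picks, per tissue, the number of dependent cell
lines maximizing the gap between true-positive rate and the permutation-null
expected rate. Genes found by both routes form tier 1, by exactly one tier 2.
The same 90th-percentile machinery applied to basal expression yields
never-expressed negative controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .data import ScreenMatrix, ScreenMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "DepletionCalls",
    "MixtureFit",
    "CommonEssentialSet",
    "binary_depletion_calls",
    "depletion_call_matrix",
    "percentile90_common_essentials",
    "adam_consensus",
    "assign_tiers",
    "never_expressed_genes",
]


@dataclass
class DepletionCalls:
    """Binary genes x screens call matrix with per-screen thresholds."""

    calls: pd.DataFrame  # bool
    k_star: pd.Series  # per screen, NaN when the precision bar is never met
    f_star: pd.Series
    fdr: float = 0.05


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    crossover: float
    converged: bool


@dataclass
class CommonEssentialSet:
    genes: set
    provenance: dict = field(default_factory=dict)  # gene -> {percentile90, adam, both}

    def tier(self, gene: str) -> int:
        return 1 if self.provenance.get(gene) == "both" else 2

    @property
    def tier1(self) -> set:
        return {g for g, p in self.provenance.items() if p == "both"}

    @property
    def tier2(self) -> set:
        return {g for g, p in self.provenance.items() if p != "both"}


def binary_depletion_calls(
    scores: pd.Series, essentials, non_essentials, fdr: float = 0.05
) -> tuple[pd.Series, float, float]:
    """Depletion calls for one screen from the control precision curve.

    Genes are ranked by score increasing (most depleted first). At each rank
    position k, ``PPV(k) = |P(k) & E| / |P(k)|`` where ``P(k)`` holds the
    controls (E u N) ranked <= k. ``k*`` is the largest k with
    ``PPV(k) >= 1 - fdr``; ``F*`` is the score at rank k*; every gene with
    score < F* is called depleted. If the precision bar is never met there
    are no calls and ``k*``/``F*`` are NaN (logged).
    """
    scores = scores.dropna().sort_values(kind="mergesort")
    e_set = set(essentials) & set(scores.index)
    n_set = set(non_essentials) & set(scores.index)
    if not e_set or not n_set:
        raise ValueError("both control sets must have scored genes in the screen")
    is_ctrl = scores.index.isin(e_set | n_set)
    is_e = scores.index.isin(e_set)
    n_ctrl = np.cumsum(is_ctrl)
    n_e = np.cumsum(is_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(n_ctrl > 0, n_e / np.maximum(n_ctrl, 1), np.nan)
    ok = np.where(np.nan_to_num(ppv) >= 1 - fdr)[0]
    if ok.size == 0:
        logger.info("precision never reaches %.2f; zero calls", 1 - fdr)
        return pd.Series(False, index=scores.index), float("nan"), float("nan")
    k_star = int(ok[-1] + 1)
    f_star = float(scores.iloc[k_star - 1])
    calls = scores < f_star
    return calls, k_star, f_star


def depletion_call_matrix(
    m: ScreenMatrix, essentials, non_essentials, fdr: float = 0.05
) -> DepletionCalls:
    """Per-screen binary depletion calls for every screen of a matrix."""
    df = m.to_frame()
    calls = pd.DataFrame(False, index=df.index, columns=df.columns)
    k_star, f_star = {}, {}
    for s in df.columns:
        c, k, f = binary_depletion_calls(df[s], essentials, non_essentials, fdr)
        calls.loc[c.index, s] = c
        k_star[s], f_star[s] = k, f
    return DepletionCalls(calls, pd.Series(k_star), pd.Series(f_star), fdr)


def _percentile90_ranks(df: pd.DataFrame, min_screens: int) -> pd.Series:
    """For each gene: its depletion rank within its 90th-percentile least
    dependent screen (screens ordered most -> least dependent, boundary at
    position ceil(0.9 n), 1-based; within-screen ranks ascending by score)."""
    X = df.to_numpy(dtype=float)
    n_g, n_s = X.shape
    if n_s < min_screens:
        raise ValueError(f"need >= {min_screens} screens, got {n_s}")
    if n_g < 2:
        raise ValueError("need >= 2 genes")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)  # ascending, average ties
    boundary = int(np.ceil(0.9 * n_s)) - 1
    order = np.argsort(X, axis=1, kind="mergesort")
    boundary_screen = order[:, boundary]
    gene_rank = ranks[np.arange(n_g), boundary_screen]
    return pd.Series(gene_rank, index=df.index)


_SD_FLOOR = 0.5  # ranks are integers; prevents component collapse


def _em_two_normals(
    x: np.ndarray, q_split: float, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Two-component normal EM on 1-D data, initialized by partitioning at a
    quantile and taking each side's moments (so a small depleted minority can
    seed its own basin of attraction)."""
    cut = np.quantile(x, q_split)
    lower = x <= cut
    if not lower.any() or lower.all():
        lower = x <= np.median(x)
    if not lower.any() or lower.all():
        lower = np.zeros_like(x, dtype=bool)
        lower[np.argmin(x)] = True
    m = np.array([x[lower].mean(), x[~lower].mean()])
    w = np.array([max(lower.mean(), 1e-3), max(1 - lower.mean(), 1e-3)])
    w /= w.sum()
    s = np.maximum([x[lower].std(), x[~lower].std()], _SD_FLOOR)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_p = np.log(w)[:, None] + stats.norm.logpdf(x[None, :], m[:, None], s[:, None])
        log_tot = np.logaddexp(log_p[0], log_p[1])
        ll = float(log_tot.sum())
        resp = np.exp(log_p - log_tot)
        nk = resp.sum(axis=1)
        if (nk < 1e-8).any():
            break
        w = nk / x.size
        m = (resp @ x) / nk
        s = np.sqrt((resp @ (x[None, :] - m[:, None]).T ** 2).diagonal() / nk)
        s = np.maximum(s, _SD_FLOOR)
        if abs(ll - ll_old) < tol * max(abs(ll_old), 1.0):
            converged = True
            break
        ll_old = ll
    order = np.argsort(m)
    return m[order], s[order], w[order], ll, converged


def _fit_rank_mixture(ranks: np.ndarray) -> MixtureFit:
    """Two-normal mixture over boundary ranks.

    EM is run from several quantile-pair initializations; among converged
    fits the one with the largest component separation (Ashman's D) is kept,
    so the lower component captures the depleted minority rather than an
    arbitrary split of the bulk.
    """
    if np.ptp(ranks) == 0:
        return MixtureFit(np.array([float(ranks[0])] * 2), np.zeros(2),
                          np.array([0.5, 0.5]), float("nan"), False)
    quantile_inits = [0.05, 0.10, 0.25, 0.50, 0.90]
    candidates = []
    for q_split in quantile_inits:
        m, s, w, ll, conv = _em_two_normals(ranks.astype(float), q_split)
        if conv and m[1] - m[0] > _SD_FLOOR and min(w) > 1e-4:
            d = (m[1] - m[0]) / np.sqrt((s[0] ** 2 + s[1] ** 2) / 2)
            candidates.append((d, m, s, w))
    if not candidates:
        return MixtureFit(np.full(2, np.nan), np.full(2, np.nan),
                          np.full(2, np.nan), float("nan"), False)
    _, means, sds, weights = max(candidates, key=lambda c: c[0])
    crossover = _density_crossover(means, sds, weights)
    return MixtureFit(means, sds, weights, crossover, np.isfinite(crossover))


def _density_crossover(means, sds, weights) -> float:
    """Rank at which the two weighted component densities are equal,
    searched between the two means."""
    m1, m2 = means
    if not np.isfinite([m1, m2]).all() or m2 - m1 < 1e-9 or min(sds) <= 0:
        return float("nan")

    def diff(x):
        return (np.log(weights[0]) + stats.norm.logpdf(x, m1, sds[0])) - (
            np.log(weights[1]) + stats.norm.logpdf(x, m2, sds[1])
        )

    lo, hi = m1, m2
    if diff(lo) * diff(hi) > 0:
        grid = np.linspace(lo, hi, 2001)
        return float(grid[np.argmin(np.abs(diff(grid)))])
    return float(optimize.brentq(diff, lo, hi, xtol=1e-6))


def percentile90_common_essentials(
    corrected: ScreenMatrix | pd.DataFrame, min_screens: int = 20
) -> tuple[set, MixtureFit, pd.Series]:
    """Common essentials by the 90th-percentile rank-mixture method.

    Returns the gene set (ranks strictly below the mixture crossover), the
    mixture fit, and the per-gene boundary ranks. A degenerate fit (no
    convergence or no crossover) yields an empty set with
    ``converged=False``.
    """
    df = corrected.to_frame() if isinstance(corrected, ScreenMatrix) else corrected
    ranks = _percentile90_ranks(df, min_screens)
    fit = _fit_rank_mixture(ranks.to_numpy())
    if not fit.converged:
        logger.warning("rank mixture did not converge; returning empty set")
        return set(), fit, ranks
    genes = set(ranks.index[ranks.to_numpy() < fit.crossover])
    return genes, fit, ranks


def never_expressed_genes(
    expression: pd.DataFrame, min_lines: int = 2
) -> tuple[set, MixtureFit]:
    """Genes with no basal expression anywhere, via the 90th-percentile
    machinery on the expression matrix.

    With expression as the score, the boundary cell line is the gene's
    90th-percentile *most expressed* line and low within-line ranks mean low
    expression, so genes below the mixture crossover are those still lowly
    expressed even in their near-top expression line.
    """
    if expression.size == 0:
        raise ValueError("empty expression matrix")
    genes, fit, _ranks = percentile90_common_essentials(expression, min_screens=min_lines)
    return genes, fit


def adam_consensus(
    calls: DepletionCalls | pd.DataFrame,
    meta: ScreenMetadata | pd.Series,
    reference_essentials,
    n_permutations: int = 1000,
    seed: int = 0,
    min_lines: int = 3,
) -> tuple[set, dict]:
    """ADaM-style consensus common essentials.

    Per tissue, the threshold ``n*`` (number of dependent cell lines needed
    to call a gene essential in that tissue) maximizes
    ``TPR(n) - expected_rate(n)``, with TPR computed on the reference
    essentials and the expected rate from column-wise permutations of the
    call matrix. The pan-cancer set repeats the selection over the
    genes x tissues membership matrix. Tissues with fewer than ``min_lines``
    cell lines are skipped (logged).
    """
    rng = np.random.default_rng(seed)
    M = calls.calls if isinstance(calls, DepletionCalls) else calls
    M = M.astype(int)
    if isinstance(meta, ScreenMetadata):
        key = "screen_id" if set(M.columns) <= set(meta.table["screen_id"]) else "cell_line_id"
        lineage = meta.table.drop_duplicates(key).set_index(key)["lineage"]
    else:
        lineage = meta
    lineage = lineage.reindex(M.columns)
    e_ref = set(reference_essentials) & set(M.index)
    if not e_ref:
        raise ValueError("no reference essentials present in the call matrix")

    def select_threshold(mat: np.ndarray) -> tuple[int, np.ndarray]:
        n_g, n_c = mat.shape
        row = mat.sum(axis=1)
        e_mask = np.isin(np.arange(n_g), e_idx)
        thresholds = np.arange(1, n_c + 1)
        tpr = np.array([(row[e_mask] >= n).mean() for n in thresholds])
        exceed = np.zeros(n_c)
        for _ in range(n_permutations):
            perm_rows = rng.permuted(mat, axis=0).sum(axis=1)
            counts = np.bincount(perm_rows, minlength=n_c + 1)
            ge = np.cumsum(counts[::-1])[::-1]  # ge[n] = #genes with rowsum >= n
            exceed += ge[1:] / n_g
        expected = exceed / n_permutations
        score = tpr - expected
        n_star = int(thresholds[np.argmax(score)])
        return n_star, row

    gene_index = {g: i for i, g in enumerate(M.index)}
    e_idx = np.array([gene_index[g] for g in sorted(e_ref)])

    tissue_sets = {}
    info = {}
    for tissue in sorted(lineage.dropna().unique()):
        cols = [c for c in M.columns if lineage[c] == tissue]
        if len(cols) < min_lines:
            logger.info("tissue %s skipped (%d lines < %d)", tissue, len(cols), min_lines)
            continue
        n_star, row = select_threshold(M[cols].to_numpy())
        tissue_sets[tissue] = set(M.index[row >= n_star])
        info[tissue] = {"n_star": n_star, "n_lines": len(cols)}
    if not tissue_sets:
        raise ValueError("no tissue had enough cell lines")
    if len(tissue_sets) == 1:
        (only,) = tissue_sets.values()
        return only, info
    membership = pd.DataFrame(
        {t: M.index.isin(s).astype(int) for t, s in tissue_sets.items()}, index=M.index
    )
    n_star, row = select_threshold(membership.to_numpy())
    info["pan_cancer"] = {"n_star": n_star, "n_tissues": membership.shape[1]}
    return set(M.index[row >= n_star]), info


def assign_tiers(p90: set, adam: set) -> CommonEssentialSet:
    """Tier 1 = found by both methods; tier 2 = by exactly one."""
    provenance = {}
    for g in p90 | adam:
        if g in p90 and g in adam:
            provenance[g] = "both"
        elif g in p90:
            provenance[g] = "percentile90"
        else:
            provenance[g] = "adam"
    return CommonEssentialSet(set(provenance), provenance)
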