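"""Use-case metrics for comparing integrated dependency datasets.

Covers: separation of prior-known essential/non-essential controls (NNMD),
false-positive and empirical-FDR checks against unexpressed genes, lineage
clustering agreement (AMI), cancer-subtype rank recall, selective-dependency
detection (NormLRT via skew-t vs normal likelihoods), biomarker association
testing, oncogene-addiction recovery (ROC AUC), and recovery of known
related gene pairs against mean-matched null pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .data import ReferenceSets, ScreenMatrix, ScreenMetadata
from .similarity import RecallCurve

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "NormLRTResult",
    "AMIResult",
    "GenePairRecovery",
    "BenchmarkReport",
    "nnmd",
    "unexpressed_fpr",
    "empirical_fdr_recall",
    "lineage_ami",
    "subtype_rank_recall",
    "normlrt",
    "biomarker_associations",
    "oncogene_benchmark",
    "gene_pair_recovery",
]


# ---------------------------------------------------------------------------
# control separation and expression-based false positives


def nnmd(scores: pd.Series, essentials, non_essentials) -> float:
    """Null-normalized mean difference of one screen.

    ``(mean(E) - mean(N)) / sd(N)`` over non-missing scores; more negative
    means better separation of essential from non-essential controls.
    """
    scores = scores.dropna()
    e = scores[scores.index.isin(set(essentials))]
    n = scores[scores.index.isin(set(non_essentials))]
    if len(e) < 2 or len(n) < 2:
        raise ValueError("need >=2 scored genes from each control set")
    sd = n.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null: sd of non-essential scores is zero")
    return float((e.mean() - n.mean()) / sd)


def unexpressed_fpr(scores: pd.Series, unexpressed, frac: float = 0.15) -> float:
    """Fraction of unexpressed genes falling in the most-depleted ``frac``
    of the screen (rank-based); the expected rate for a random screen is
    ``frac`` itself."""
    scores = scores.dropna()
    unexpr = [g for g in unexpressed if g in scores.index]
    if not unexpr:
        raise ValueError("no unexpressed genes scored in this screen")
    k = int(np.floor(frac * len(scores)))
    depleted = set(scores.nsmallest(k).index)
    return float(np.mean([g in depleted for g in unexpr]))


def empirical_fdr_recall(
    scores: pd.Series, unexpressed, essentials, fdr: float = 0.10
) -> float:
    """Recall of reference essentials at an empirical FDR threshold.

    Unexpressed genes provide the null: the per-gene empirical p-value is
    ``(1 + #{null scores <= score}) / (1 + #null)`` (add-one corrected),
    Benjamini-Hochberg adjusted across all genes.
    """
    scores = scores.dropna()
    null = scores[scores.index.isin(set(unexpressed))].to_numpy()
    if null.size < 50:
        raise ValueError(f"unexpressed null too small ({null.size} < 50)")
    null = np.sort(null)
    p = (1 + np.searchsorted(null, scores.to_numpy(), side="right")) / (1 + null.size)
    q = multipletests(p, method="fdr_bh")[1]
    qs = pd.Series(q, index=scores.index)
    e = [g for g in essentials if g in qs.index]
    if not e:
        raise ValueError("no reference essentials scored in this screen")
    return float((qs[e] <= fdr).mean())


# ---------------------------------------------------------------------------
# clustering and subtype structure


@dataclass
class AMIResult:
    values: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def lineage_ami(
    corrected: ScreenMatrix,
    meta: ScreenMetadata,
    n_genes: int = 500,
    n_runs: int = 100,
    seed: int = 0,
) -> AMIResult:
    """Adjusted mutual information between k-means clusters of screens (on
    the top-variance gene subspace) and tissue lineage labels, over
    ``n_runs`` k-means++ restarts with run-indexed seeds."""
    meta = meta.for_screens(corrected.screen_ids)
    labels = meta.lineage_of()[corrected.screen_ids].to_numpy()
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need >=2 lineages")
    if k > corrected.n_screens:
        raise ValueError("more lineages than screens")
    X = np.where(corrected.missing_mask, np.nan, corrected.values)
    gene_mean = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), gene_mean[:, None], X)
    var = X.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_genes, corrected.n_genes)]
    pts = X[top].T
    amis = np.empty(n_runs)
    for r in range(n_runs):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed + r)
        amis[r] = adjusted_mutual_info_score(labels, km.fit_predict(pts))
    t, p = stats.ttest_1samp(amis, 0.0)
    return AMIResult(amis, float(t), float(p))


def subtype_rank_recall(corrected: ScreenMatrix, meta: ScreenMetadata) -> RecallCurve:
    """Within one tissue: for each query screen, the rank (by plain Pearson)
    of the nearest screen sharing its cancer subtype.

    Queries whose subtype has no second member are excluded (logged); fewer
    than two multi-member subtypes is an error.
    """
    meta = meta.for_screens(corrected.screen_ids)
    subtype = meta.table.set_index("screen_id")["subtype"]
    counts = subtype.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 subtypes with >=2 members each")
    X = np.where(corrected.missing_mask, np.nan, corrected.values)
    gene_mean = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), gene_mean[:, None], X)
    corr = pd.DataFrame(
        np.corrcoef(X.T), index=corrected.screen_ids, columns=corrected.screen_ids
    )
    n = corrected.n_screens
    ranks = []
    for q in corrected.screen_ids:
        mates = [s for s in corrected.screen_ids if s != q and subtype[s] == subtype[q]]
        if not mates:
            logger.info("query %s excluded: singleton subtype %s", q, subtype[q])
            continue
        c = corr.loc[q].drop(q)
        order = sorted(c.index, key=lambda s: (-c[s], s))
        ranks.append(min(order.index(m) for m in mates) + 1)
    ks = np.arange(1, n)
    prop = np.array([(np.asarray(ranks) <= k).mean() for k in ks])
    return RecallCurve(ks, prop)


# ---------------------------------------------------------------------------
# selective dependencies: skew-t vs normal likelihood ratio


@dataclass
class NormLRTResult:
    gene: str | None
    ll_normal: float
    ll_skewt: float
    value: float  # 2 * (ll_skewt - ll_normal)
    df: float | None
    df_source: str  # "fitted" | "fixed" | "normal-limit"
    failed: bool = False


_FALLBACK_DF = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
_NU_MAX = 1e6


def _skewt_nll(params, x, fixed_nu=None):
    if fixed_nu is None:
        xi, log_omega, alpha, log_nu = params
        nu = np.exp(log_nu)
    else:
        xi, log_omega, alpha = params
        nu = fixed_nu
    omega = np.exp(log_omega)
    if not np.isfinite(omega) or omega <= 0 or nu < 0.5 or nu > _NU_MAX:
        return np.inf
    z = (x - xi) / omega
    lp = (
        np.log(2.0)
        - log_omega
        + stats.t.logpdf(z, nu)
        + stats.t.logcdf(alpha * z * np.sqrt((nu + 1.0) / (nu + z**2)), nu + 1.0)
    )
    val = -np.sum(lp)
    return val if np.isfinite(val) else np.inf


def normlrt(profile, gene: str | None = None, min_n: int = 30) -> NormLRTResult:
    """Departure-from-normality statistic for one gene's dependency profile.

    Twice the log-likelihood gain of a maximum-likelihood Azzalini skew-t
    (location, scale, slant, df) over a normal fit. If the free skew-t fit
    fails, the df is fixed at 2, 5, 10, 25, 50, 100 in order and the best
    converged fit is kept; the normal limit (slant 0, df -> inf) is always a
    candidate, so the statistic is non-negative up to optimizer tolerance.
    """
    x = pd.Series(profile).dropna().to_numpy(dtype=float)
    if x.size < min_n:
        raise ValueError(f"need >={min_n} non-missing values, got {x.size}")
    mu, sd = x.mean(), x.std(ddof=0)
    if sd == 0:
        return NormLRTResult(gene, np.nan, np.nan, np.nan, None, "degenerate", True)
    ll_norm = float(np.sum(stats.norm.logpdf(x, mu, sd)))

    candidates: list[tuple[float, float, str]] = []
    # normal-limit candidate guarantees nesting
    ll_limit = -_skewt_nll([mu, np.log(sd), 0.0], x, fixed_nu=_NU_MAX)
    candidates.append((ll_limit, _NU_MAX, "normal-limit"))

    g1 = float(stats.skew(x))
    start = [mu, np.log(sd), np.sign(g1) * 1.0 if g1 else 0.5, np.log(10.0)]
    try:
        res = optimize.minimize(
            _skewt_nll, start, args=(x,), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if np.isfinite(res.fun):
            candidates.append((-res.fun, float(np.exp(res.x[3])), "fitted"))
    except Exception:  # pragma: no cover - optimizer pathologies
        pass
    if not any(src == "fitted" for _, _, src in candidates):
        for nu in _FALLBACK_DF:
            try:
                res = optimize.minimize(
                    _skewt_nll, start[:3], args=(x, nu), method="Nelder-Mead",
                    options={"maxiter": 1000},
                )
                if np.isfinite(res.fun):
                    candidates.append((-res.fun, nu, "fixed"))
            except Exception:  # pragma: no cover
                continue
    ll_st, df, src = max(candidates, key=lambda c: c[0])
    return NormLRTResult(gene, ll_norm, float(ll_st), float(2 * (ll_st - ll_norm)), df, src)


# ---------------------------------------------------------------------------
# biomarker associations


@dataclass
class AssociationResult:
    tissue: str
    cfe: str
    gene: str
    n_carriers: int
    n_noncarriers: int
    t_statistic: float
    p_value: float
    fdr: float
    delta_fc: float  # Cohen's delta


def _cohens_delta(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = a.size, b.size
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def biomarker_associations(
    corrected: ScreenMatrix,
    meta: ScreenMetadata,
    refs: ReferenceSets,
    sgd_lrt_min: float = 200.0,
    fdr: float = 0.05,
    min_group: int = 3,
    sgd_genes=None,
) -> list[AssociationResult]:
    """Tissue-restricted differential-dependency tests.

    For each (tissue, CFE, selective gene) with at least ``min_group``
    carriers and non-carriers, an equal-variance two-sided t-test compares
    carrier vs non-carrier dependency scores; BH correction is applied
    globally across all tests. Selective genes (SGDs) are those with
    NormLRT > ``sgd_lrt_min`` unless an explicit ``sgd_genes`` list is given.
    The matrix columns must be cell lines (post duplicate resolution).
    """
    if refs.cfe_matrix is None:
        raise ValueError("reference CFE matrix required")
    df = corrected.to_frame()
    line_lineage = (
        meta.table.drop_duplicates("cell_line_id").set_index("cell_line_id")["lineage"]
    )
    if sgd_genes is None:
        sgd_genes = []
        for g in corrected.gene_ids:
            try:
                r = normlrt(df.loc[g], gene=g)
            except ValueError:
                continue
            if not r.failed and r.value > sgd_lrt_min:
                sgd_genes.append(g)
    sgd_genes = [g for g in sgd_genes if g in set(corrected.gene_ids)]
    if not sgd_genes:
        logger.warning("no selective gene dependencies to test")
        return []

    lines = [l for l in df.columns if l in refs.cfe_matrix.index and l in line_lineage.index]
    results = []
    for tissue in sorted(line_lineage.loc[lines].unique()):
        t_lines = [l for l in lines if line_lineage[l] == tissue]
        for cfe in refs.cfe_matrix.columns:
            scope = refs.cfe_tissue.get(cfe)
            if scope is not None and scope != tissue:
                continue
            status = refs.cfe_matrix.loc[t_lines, cfe]
            carriers = [l for l in t_lines if status[l] == 1]
            others = [l for l in t_lines if status[l] == 0]
            if len(carriers) < min_group or len(others) < min_group:
                continue
            for g in sgd_genes:
                a = df.loc[g, carriers].dropna().to_numpy()
                b = df.loc[g, others].dropna().to_numpy()
                if a.size < min_group or b.size < min_group:
                    continue
                t, p = stats.ttest_ind(a, b, equal_var=True)
                results.append(
                    AssociationResult(
                        tissue, cfe, g, a.size, b.size, float(t), float(p),
                        np.nan, _cohens_delta(a, b),
                    )
                )
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.fdr = float(qv)
    return results


def associations_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# oncogene addiction


def oncogene_benchmark(
    corrected: ScreenMatrix,
    oncogene_positives: dict,
    common_essential_cutoff: float = -0.5,
) -> tuple[dict, float]:
    """Recovery of gain-of-function oncogene addictions.

    Oncogenes whose mean score is below ``common_essential_cutoff`` are
    dropped (they behave as common essentials, not selective addictions).
    Returns per-oncogene NNMD (positives as the depleted group; needs >=2
    positives) and the pooled ROC AUC over all (gene, line) pairs with
    positives expected more negative.
    """
    df = corrected.to_frame()
    scores, labels = [], []
    per_gene_nnmd: dict[str, float] = {}
    for gene, pos_lines in sorted(oncogene_positives.items()):
        if gene not in df.index:
            continue
        row = df.loc[gene].dropna()
        if row.mean() < common_essential_cutoff:
            logger.info("oncogene %s dropped: mean score %.3f", gene, row.mean())
            continue
        pos = [l for l in pos_lines if l in row.index]
        if not pos:
            continue
        neg = [l for l in row.index if l not in set(pos)]
        scores.extend(-row[pos + neg].to_numpy())
        labels.extend([1] * len(pos) + [0] * len(neg))
        if len(pos) >= 2 and len(neg) >= 2:
            per_gene_nnmd[gene] = float(
                (row[pos].mean() - row[neg].mean()) / row[neg].std(ddof=1)
            )
    if not any(labels):
        logger.warning("no oncogene positives after filtering")
        return {}, float("nan")
    auc = float(roc_auc_score(labels, scores)) if 0 < sum(labels) < len(labels) else float("nan")
    return per_gene_nnmd, auc


# ---------------------------------------------------------------------------
# related gene pairs


@dataclass
class GenePairRecovery:
    n_tested: int
    n_recovered: int
    ci_low: float
    ci_high: float
    p_values: np.ndarray


def gene_pair_recovery(
    corrected: ScreenMatrix,
    related_pairs,
    n_bins: int = 20,
    fdr: float = 0.10,
    n_bootstrap: int = 100,
    seed: int = 0,
    min_pairs: int = 100,
) -> GenePairRecovery:
    """Recovery of known related gene pairs against mean-matched nulls.

    For each known pair the absolute Pearson correlation of the two genes'
    dependency profiles is compared with a null built by replacing the
    partner with a random gene from the same mean-score bin (20 equal-width
    bins; related genes excluded). Empirical add-one p-values are BH
    corrected; the count of pairs at FDR <= ``fdr`` is reported with a 95%
    bootstrap CI over pair resampling.
    """
    rng = np.random.default_rng(seed)
    df = corrected.to_frame()
    genes = set(df.index)
    pairs = [tuple(p) for p in related_pairs if p[0] in genes and p[1] in genes]
    if len(pairs) < min_pairs:
        raise ValueError(f"need >={min_pairs} related pairs with both genes present")
    partners: dict[str, set] = {}
    for g1, g2 in pairs:
        partners.setdefault(g1, set()).add(g2)
        partners.setdefault(g2, set()).add(g1)

    means = df.mean(axis=1)
    edges = np.linspace(means.min(), means.max(), n_bins + 1)
    bin_of = np.clip(np.digitize(means.to_numpy(), edges[1:-1]), 0, n_bins - 1)
    bins = pd.Series(bin_of, index=means.index)
    members = {b: list(idx) for b, idx in means.groupby(bins).groups.items()}

    X = df.to_numpy()
    gi = {g: i for i, g in enumerate(df.index)}

    def corr(g1, g2):
        a, b = X[gi[g1]], X[gi[g2]]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return 0.0
        return abs(float(np.corrcoef(a[ok], b[ok])[0, 1]))

    def null_partner(query, partner):
        b = bins[partner]
        cand = [g for g in members.get(b, []) if g != query and g not in partners.get(query, set())]
        step = 1
        while not cand and step < n_bins:
            for nb in (b - step, b + step):
                cand.extend(
                    g for g in members.get(nb, [])
                    if g != query and g not in partners.get(query, set())
                )
            if cand:
                logger.info("empty bin %s; used nearest non-empty bin", b)
            step += 1
        return cand[rng.integers(len(cand))]

    obs = np.array([corr(q, p) for q, p in pairs])
    null = np.sort([corr(q, null_partner(q, p)) for q, p in pairs])
    p_emp = (1 + null.size - np.searchsorted(null, obs, side="left")) / (1 + null.size)
    q = multipletests(p_emp, method="fdr_bh")[1]
    n_rec = int((q <= fdr).sum())

    boots = []
    for _ in range(max(n_bootstrap, 1)):
        idx = rng.integers(len(pairs), size=len(pairs))
        qb = multipletests(p_emp[idx], method="fdr_bh")[1]
        boots.append(int((qb <= fdr).sum()))
    if n_bootstrap <= 1:
        lo = hi = float(n_rec)
    else:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return GenePairRecovery(len(pairs), n_rec, float(lo), float(hi), p_emp)


# ---------------------------------------------------------------------------
# report container


@dataclass
class BenchmarkReport:
    """Structured results of the use-case metrics for one integrated dataset."""

    label: str
    metrics: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def add(self, name: str, value) -> None:
        self.metrics[name] = value

    def mark_failed(self, name: str, reason: str) -> None:
        self.metrics[name] = {"failed": True, "reason": reason}
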