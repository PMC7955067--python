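"""Empirical-Bayes batch correction and the four integration pipelines.

The correction follows the location/scale empirical-Bayes model of Johnson
et al. (ComBat): scores are standardized per gene with pooled mean/variance,
per-batch per-gene location and scale estimates are shrunk toward parametric
priors (normal on locations, inverse-gamma on scales; hyperparameters by
method of moments; iterative posterior solution), and screens are shifted
and scaled gene-wise. The model is fitted only on cell lines screened by
both institutes and then applied to *all* screens, so screens unique to one
institute are corrected by extension. Optional follow-ups are a second
quantile normalization and removal of the first one or two principal
components of the joint dataset. Finally each overlapping cell line's two
corrected screens are resolved into one profile: concordant pairs are
averaged, divergent pairs keep the higher-quality screen (more negative
NNMD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import nnmd
from .data import AlignedCohort, ReferenceSets, ScreenMatrix, ScreenMetadata, align_datasets
from .preprocess import quantile_normalize_screens, spline_quality_adjust
from .similarity import WeightVector, skewness_weights, wpearson_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "BatchModel",
    "PCRemovalModel",
    "IntegrationResult",
    "PIPELINES",
    "combat_fit",
    "combat_apply",
    "remove_principal_components",
    "resolve_overlap_duplicates",
    "run_pipeline",
]

#: pipeline label -> (second quantile normalization?, number of PCs removed)
PIPELINES = {
    "combat": (False, 0),
    "combat_qn": (True, 0),
    "combat_qn_pc1": (True, 1),
    "combat_qn_pc1-2": (True, 2),
}


@dataclass
class BatchModel:
    """Frozen correction parameters, fitted on overlap screens.

    ``alpha``/``sigma`` are the pooled per-gene mean and sd; ``gamma_star``
    and ``delta2_star`` are the (optionally EB-shrunk) per-batch location and
    squared-scale adjustments in standardized units.
    """

    genes: list[str]
    batches: list[str]
    alpha: np.ndarray
    sigma: np.ndarray
    gamma_star: pd.DataFrame  # batches x genes
    delta2_star: pd.DataFrame  # batches x genes, > 0
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    priors: dict  # per batch: gamma_bar, tau2, lam, theta
    parametric_eb: bool
    excluded_genes: list = field(default_factory=list)


@dataclass
class PCRemovalModel:
    centers: np.ndarray
    loadings: np.ndarray  # c x genes, orthonormal
    n_removed: int
    variance_explained: np.ndarray


@dataclass
class DuplicateResolution:
    cell_line: str
    screens: tuple
    distance: float
    action: str  # "averaged" | "selected-by-quality"
    kept: tuple
    quality_nnmd: dict


@dataclass
class IntegrationResult:
    """One integrated dataset: the per-cell-line corrected matrix plus the
    full audit trail of how it was produced."""

    matrix: ScreenMatrix  # one column per cell line
    pipeline: str
    divergence_threshold: float
    resolutions: list
    screen_level: ScreenMatrix | None = None  # corrected union, one column per screen
    batch_model: BatchModel | None = None
    pc_model: PCRemovalModel | None = None
    weights: WeightVector | None = None
    meta: ScreenMetadata | None = None


def combat_fit(
    overlap: ScreenMatrix,
    meta: ScreenMetadata,
    parametric_eb: bool = True,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> BatchModel:
    """Estimate batch-correction parameters on the overlap screens.

    No covariates enter the design (batch only). Screens containing missing
    values are excluded from estimation (logged); genes with zero pooled
    variance are excluded and logged. With ``parametric_eb=False`` the
    returned adjustments are the unshrunk per-batch estimates.
    """
    meta = meta.for_screens(overlap.screen_ids)
    has_missing = overlap.missing_mask.any(axis=0)
    if has_missing.any():
        drop = [overlap.screen_ids[j] for j in np.where(has_missing)[0]]
        logger.info("excluding %d screens with missing values from fit", len(drop))
        keep = [s for s in overlap.screen_ids if s not in set(drop)]
        overlap = overlap.subset_screens(keep)
        meta = meta.for_screens(keep)
    batch = meta.batch_of()[overlap.screen_ids].to_numpy()
    batches = sorted(set(batch))
    if len(batches) < 2:
        raise ValueError("need >=2 batches to estimate batch effects")
    counts = {b: int((batch == b).sum()) for b in batches}
    small = [b for b, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"batches with <2 screens: {small}")

    X = overlap.values
    n_total = X.shape[1]
    masks = {b: batch == b for b in batches}
    batch_means = np.stack([X[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([counts[b] / n_total for b in batches])
    alpha = weights @ batch_means
    resid = X - batch_means.T @ np.array([masks[b] for b in batches], dtype=float)
    var_pooled = (resid**2).mean(axis=1)

    ok = var_pooled > 0
    excluded = [overlap.gene_ids[i] for i in np.where(~ok)[0]]
    if excluded:
        logger.info("excluding %d zero-variance genes from batch model", len(excluded))
    genes = [g for g, keep in zip(overlap.gene_ids, ok) if keep]
    X, alpha, var_pooled = X[ok], alpha[ok], var_pooled[ok]
    sigma = np.sqrt(var_pooled)
    Z = (X - alpha[:, None]) / sigma[:, None]

    gamma_hat = {}
    delta2_hat = {}
    gamma_star = {}
    delta2_star = {}
    priors = {}
    for b in batches:
        Zb = Z[:, masks[b]]
        n_b = counts[b]
        g_hat = Zb.mean(axis=1)
        d2_hat = Zb.var(axis=1, ddof=1)
        gamma_hat[b] = g_hat
        delta2_hat[b] = d2_hat
        if not parametric_eb:
            gamma_star[b] = g_hat
            delta2_star[b] = np.maximum(d2_hat, np.finfo(float).tiny)
            priors[b] = {}
            continue
        gamma_bar = g_hat.mean()
        tau2 = g_hat.var(ddof=1)
        m = d2_hat.mean()
        s2 = d2_hat.var(ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        priors[b] = {"gamma_bar": gamma_bar, "tau2": tau2, "lambda": lam, "theta": theta}
        g_old = g_hat.copy()
        d_old = d2_hat.copy()
        for _ in range(max_iter):
            g_new = (tau2 * n_b * g_hat + d_old * gamma_bar) / (tau2 * n_b + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * sum2) / (n_b / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[b] = g_old
        delta2_star[b] = np.maximum(d_old, np.finfo(float).tiny)

    return BatchModel(
        genes=genes,
        batches=batches,
        alpha=alpha,
        sigma=sigma,
        gamma_star=pd.DataFrame(gamma_star, index=genes).T,
        delta2_star=pd.DataFrame(delta2_star, index=genes).T,
        gamma_hat=pd.DataFrame(gamma_hat, index=genes).T,
        delta2_hat=pd.DataFrame(delta2_hat, index=genes).T,
        priors=priors,
        parametric_eb=parametric_eb,
        excluded_genes=excluded,
    )


def combat_apply(model: BatchModel, m: ScreenMatrix, meta: ScreenMetadata) -> ScreenMatrix:
    """Shift and scale every screen gene-wise with the frozen batch vectors.

    ``Y* = sigma_g * (Z - gamma*_ig) / delta*_ig + alpha_g`` with
    ``Z = (Y - alpha_g) / sigma_g``. Screens outside the fitting set are
    corrected by extension; unknown batch labels are an error; genes absent
    from the model pass through unchanged (warned); masked entries stay
    masked.
    """
    meta = meta.for_screens(m.screen_ids)
    batch = meta.batch_of()[m.screen_ids]
    unknown = sorted(set(batch) - set(model.batches))
    if unknown:
        raise ValueError(f"batch labels not in model: {unknown}")
    gene_pos = {g: i for i, g in enumerate(model.genes)}
    rows = [i for i, g in enumerate(m.gene_ids) if g in gene_pos]
    absent = m.n_genes - len(rows)
    if absent:
        logger.warning("%d genes absent from batch model left unchanged", absent)
    model_rows = [gene_pos[m.gene_ids[i]] for i in rows]
    out = m.values.copy()
    alpha = model.alpha[model_rows]
    sigma = model.sigma[model_rows]
    for b in model.batches:
        cols = np.where(batch.to_numpy() == b)[0]
        if cols.size == 0:
            continue
        g_star = model.gamma_star.loc[b].to_numpy()[model_rows]
        d_star = np.sqrt(model.delta2_star.loc[b].to_numpy()[model_rows])
        sub = out[np.ix_(rows, cols)]
        Z = (sub - alpha[:, None]) / sigma[:, None]
        out[np.ix_(rows, cols)] = sigma[:, None] * (Z - g_star[:, None]) / d_star[:, None] + alpha[:, None]
    return ScreenMatrix(out, list(m.gene_ids), list(m.screen_ids), m.missing_mask.copy())


def remove_principal_components(
    m: ScreenMatrix, c: int
) -> tuple[ScreenMatrix, PCRemovalModel]:
    """Remove the first ``c`` principal components of the joint dataset.

    Screens are observations and genes features; missing entries are
    mean-imputed per gene for the decomposition and re-masked afterwards.
    ``c = 0`` is the identity.
    """
    if c not in (0, 1, 2):
        raise ValueError("c must be 0, 1 or 2")
    if c == 0:
        return m.copy(), PCRemovalModel(
            np.zeros(m.n_genes), np.zeros((0, m.n_genes)), 0, np.array([])
        )
    if m.n_screens < c + 1:
        raise ValueError(f"need at least {c + 1} screens to remove {c} components")
    X = np.where(m.missing_mask, np.nan, m.values)
    gene_mean = np.nanmean(X, axis=1)
    gene_mean = np.where(np.isfinite(gene_mean), gene_mean, 0.0)
    X = np.where(np.isnan(X), gene_mean[:, None], X)
    centers = X.mean(axis=1)
    D = (X - centers[:, None]).T  # screens x genes
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    if c > S.size:
        raise ValueError("fewer available components than requested")
    loadings = Vt[:c]
    scores = U[:, :c] * S[:c]
    D_clean = D - scores @ loadings
    var_explained = (S[:c] ** 2) / (S**2).sum()
    out = D_clean.T + centers[:, None]
    return (
        ScreenMatrix(out, list(m.gene_ids), list(m.screen_ids), m.missing_mask.copy()),
        PCRemovalModel(centers, loadings, c, var_explained),
    )


def _duplicate_pairs(meta: ScreenMetadata, screen_ids: list[str]) -> dict:
    sub = meta.for_screens(screen_ids).table
    pairs = {}
    for line, grp in sub.groupby("cell_line_id"):
        if len(grp) == 2 and grp["batch"].nunique() == 2:
            pairs[line] = tuple(sorted(grp["screen_id"]))
    return pairs


def resolve_overlap_duplicates(
    corrected: ScreenMatrix,
    meta: ScreenMetadata,
    weights: WeightVector,
    refs: ReferenceSets | None = None,
    quality_nnmd: pd.Series | None = None,
    pipeline: str = "custom",
) -> IntegrationResult:
    """Collapse each overlapping cell line's two screens into one profile.

    The distance between a duplicate pair is 1 - weighted Pearson. The
    divergence threshold is the 95th percentile of distances among pairs
    that are mutual first neighbors (each screen's most-correlated screen is
    its counterpart). Pairs below the threshold are averaged gene-wise;
    divergent pairs keep the screen with the better (more negative) quality
    NNMD, taken from ``quality_nnmd`` if given, else computed from the
    reference essential/non-essential sets.
    """
    meta_all = meta.for_screens(corrected.screen_ids)
    pairs = _duplicate_pairs(meta_all, corrected.screen_ids)
    if not pairs:
        raise ValueError("no overlap cell lines with exactly one screen per batch")
    corr = wpearson_matrix(corrected, weights)

    def first_neighbor(s: str) -> str:
        c = corr.loc[s].drop(s)
        return min(c.index, key=lambda t: (-c[t], t))

    dist = {l: 1.0 - corr.loc[s1, s2] for l, (s1, s2) in pairs.items()}
    mutual = [
        l
        for l, (s1, s2) in pairs.items()
        if first_neighbor(s1) == s2 and first_neighbor(s2) == s1
    ]
    if mutual:
        threshold = float(np.percentile([dist[l] for l in mutual], 95))
    else:
        logger.warning("no mutual-first-neighbor pairs; threshold from all pairs")
        threshold = float(np.percentile(list(dist.values()), 95))

    def screen_nnmd(s: str) -> float:
        if quality_nnmd is not None and s in quality_nnmd.index and pd.notna(quality_nnmd[s]):
            return float(quality_nnmd[s])
        if refs is None or not refs.essentials or not refs.non_essentials:
            raise ValueError(
                f"divergent pair needs a quality NNMD for screen {s}; "
                "supply quality_nnmd or reference gene sets"
            )
        col = corrected.to_frame()[s]
        return nnmd(col, refs.essentials, refs.non_essentials)

    df = corrected.to_frame()
    line_of = meta_all.cell_line_of()
    columns = {}
    resolutions = []
    for s in corrected.screen_ids:
        line = line_of[s]
        if line not in pairs:
            columns[line] = df[s]
    for line, (s1, s2) in sorted(pairs.items()):
        d = dist[line]
        if d <= threshold:
            columns[line] = df[[s1, s2]].mean(axis=1)  # NaN only if both missing
            resolutions.append(
                DuplicateResolution(line, (s1, s2), float(d), "averaged", (s1, s2), {})
            )
        else:
            q = {s1: screen_nnmd(s1), s2: screen_nnmd(s2)}
            kept = s1 if q[s1] <= q[s2] else s2
            columns[line] = df[kept]
            resolutions.append(
                DuplicateResolution(line, (s1, s2), float(d), "selected-by-quality", (kept,), q)
            )
    out = pd.DataFrame(columns).sort_index(axis=1)
    return IntegrationResult(
        matrix=ScreenMatrix.from_frame(out),
        pipeline=pipeline,
        divergence_threshold=threshold,
        resolutions=resolutions,
        screen_level=corrected,
        weights=weights,
        meta=meta_all,
    )


def _concat(a: ScreenMatrix, b: ScreenMatrix) -> ScreenMatrix:
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene lists differ")
    return ScreenMatrix(
        np.hstack([a.values, b.values]),
        list(a.gene_ids),
        list(a.screen_ids) + list(b.screen_ids),
        np.hstack([a.missing_mask, b.missing_mask]),
    )


def run_pipeline(
    a: ScreenMatrix,
    a_meta: ScreenMetadata,
    b: ScreenMatrix,
    b_meta: ScreenMetadata,
    pipeline: str = "combat_qn_pc1",
    refs: ReferenceSets | None = None,
    spline_df: int = 5,
    skip_quality_spline: bool = False,
    parametric_eb: bool = True,
) -> IntegrationResult:
    """Execute one full integration pipeline on two institute datasets.

    Stages: per-institute quantile normalization and screen-quality spline
    adjustment; ComBat fitted on overlap screens and applied to the union;
    optionally a second quantile normalization and removal of the first one
    or two principal components (per the pipeline label); finally duplicate
    resolution to one profile per cell line.
    """
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; choose from {sorted(PIPELINES)}")
    second_qn, n_pcs = PIPELINES[pipeline]
    cohort: AlignedCohort = align_datasets(a, a_meta, b, b_meta)
    if not cohort.overlap_cell_lines:
        raise ValueError(
            "no overlapping cell lines: batch effects cannot be estimated; "
            "screen a shared subset first (see the downsampling analysis for sizes)"
        )
    qa = quantile_normalize_screens(cohort.a)
    qb = quantile_normalize_screens(cohort.b)
    if not skip_quality_spline:
        qa, _ = spline_quality_adjust(qa, df=spline_df)
        qb, _ = spline_quality_adjust(qb, df=spline_df)

    line_of = cohort.meta.cell_line_of()
    overlap_set = set(cohort.overlap_cell_lines)
    ov_a = [s for s in qa.screen_ids if line_of[s] in overlap_set]
    ov_b = [s for s in qb.screen_ids if line_of[s] in overlap_set]
    weights = skewness_weights(qa, qb, ov_a, ov_b)

    union = _concat(qa, qb)
    overlap_m = union.subset_screens(ov_a + ov_b)
    model = combat_fit(overlap_m, cohort.meta, parametric_eb=parametric_eb)
    corrected = combat_apply(model, union, cohort.meta)
    if second_qn:
        corrected = quantile_normalize_screens(corrected)
    pc_model = None
    if n_pcs:
        corrected, pc_model = remove_principal_components(corrected, n_pcs)
    result = resolve_overlap_duplicates(
        corrected, cohort.meta, weights, refs=refs, pipeline=pipeline
    )
    result.batch_model = model
    result.pc_model = pc_model
    return result
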