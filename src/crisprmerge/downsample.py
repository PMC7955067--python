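"""How many overlapping cell lines does batch correction need?

Repeatedly subsample the overlap roster (lineage-proportional selection
probabilities), refit the batch model on each subsample, apply it to every
screen, and compare the resulting profiles with those corrected using the
full overlap: per-screen Pearson correlation measures convergence toward the
full correction, and the average silhouette width (ASW) with the institute
of origin as the cluster label measures residual batch structure (near 0
means batch effects are gone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .data import ScreenMatrix, ScreenMetadata, align_datasets
from .integrate import combat_apply, combat_fit
from .preprocess import quantile_normalize_screens, spline_quality_adjust

logger = logging.getLogger(__name__)

__all__ = ["DownsampleResult", "downsample_correction_analysis", "average_silhouette_width"]


@dataclass
class DownsampleResult:
    """Long-format correlations plus per-replicate ASW and rosters."""

    correlations: pd.DataFrame  # columns: fraction, rep, screen, correlation
    asw: pd.DataFrame  # columns: fraction, rep, asw (overlap screens, batch labels)
    rosters: dict = field(default_factory=dict)  # (fraction, rep) -> list of cell lines
    baseline: pd.DataFrame | None = None  # no-correction per-screen correlation

    def median_correlation(self, fraction: float) -> float:
        sub = self.correlations[self.correlations["fraction"] == fraction]
        return float(sub["correlation"].median())


def average_silhouette_width(m: ScreenMatrix, labels) -> float:
    """Mean silhouette of screens under the given labels (Euclidean over all
    genes, missing entries mean-imputed per gene)."""
    labels = np.asarray(pd.Series(labels))
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need >=2 labels")
    if (counts < 2).any():
        raise ValueError(f"singleton labels: {list(values[counts < 2])}")
    X = np.where(m.missing_mask, np.nan, m.values)
    gene_mean = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), gene_mean[:, None], X)
    return float(silhouette_score(X.T, labels, metric="euclidean"))


def downsample_correction_analysis(
    a: ScreenMatrix,
    a_meta: ScreenMetadata,
    b: ScreenMatrix,
    b_meta: ScreenMetadata,
    fractions=(0.05, 0.1, 0.25, 0.5, 0.75, 0.9),
    n_reps: int = 50,
    seed: int = 0,
    lineage_filter: str | None = None,
    compute_asw: bool = True,
    spline_df: int = 5,
) -> DownsampleResult:
    """Correlation-to-full-correction curves over overlap subsample sizes.

    ``fractions`` may also contain absolute sizes (> 1). Subsamples are drawn
    without replacement with per-line probability proportional to the line's
    lineage share of the overlap. A draw collapsing below two lines is
    redrawn (logged). The no-correction baseline is recorded separately.
    """
    rng = np.random.default_rng(seed)
    cohort = align_datasets(a, a_meta, b, b_meta)
    qa = quantile_normalize_screens(cohort.a)
    qb = quantile_normalize_screens(cohort.b)
    qa, _ = spline_quality_adjust(qa, df=spline_df)
    qb, _ = spline_quality_adjust(qb, df=spline_df)
    union = ScreenMatrix(
        np.hstack([qa.values, qb.values]),
        list(qa.gene_ids),
        list(qa.screen_ids) + list(qb.screen_ids),
        np.hstack([qa.missing_mask, qb.missing_mask]),
    )
    meta = cohort.meta
    line_of = meta.cell_line_of()
    lineage_of_line = (
        meta.table.drop_duplicates("cell_line_id").set_index("cell_line_id")["lineage"]
    )
    overlap = list(cohort.overlap_cell_lines)
    if lineage_filter is not None:
        overlap = [l for l in overlap if lineage_of_line[l] == lineage_filter]
    if len(overlap) < 2:
        raise ValueError("need at least 2 overlap cell lines")
    screens_of = {
        l: [s for s in union.screen_ids if line_of[s] == l] for l in overlap
    }
    overlap_screens = [s for l in overlap for s in screens_of[l]]

    # lineage-proportional selection probabilities
    shares = lineage_of_line[overlap].value_counts(normalize=True)
    probs = np.array([shares[lineage_of_line[l]] for l in overlap])
    probs = probs / probs.sum()

    full_model = combat_fit(union.subset_screens(overlap_screens), meta)
    reference = combat_apply(full_model, union, meta)
    ref_vals = reference.values

    def per_screen_corr(vals: np.ndarray) -> pd.Series:
        out = {}
        for j, s in enumerate(union.screen_ids):
            x, y = vals[:, j], ref_vals[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            out[s] = float(np.corrcoef(x[ok], y[ok])[0, 1])
        return pd.Series(out)

    baseline = (
        per_screen_corr(union.values)
        .rename("correlation")
        .rename_axis("screen")
        .reset_index()
    )

    rows, asw_rows, rosters = [], [], {}
    batch_of = meta.batch_of()
    ov_batch_labels = batch_of[overlap_screens].to_numpy()
    for frac in fractions:
        size = int(round(frac * len(overlap))) if frac <= 1 else int(frac)
        size = max(size, 2)
        for rep in range(n_reps):
            for _attempt in range(100):
                chosen = list(rng.choice(overlap, size=size, replace=False, p=probs))
                sub_screens = [s for l in chosen for s in screens_of[l]]
                sub_batches = set(batch_of[sub_screens])
                if len(sub_batches) == 2:
                    break
                logger.info("subsample collapsed to one batch; redrawing")
            rosters[(frac, rep)] = chosen
            model = combat_fit(union.subset_screens(sub_screens), meta)
            corrected = combat_apply(model, union, meta)
            corr = per_screen_corr(corrected.values)
            for s, c in corr.items():
                rows.append({"fraction": frac, "rep": rep, "screen": s, "correlation": c})
            if compute_asw:
                ov = corrected.subset_screens(overlap_screens)
                asw_rows.append(
                    {
                        "fraction": frac,
                        "rep": rep,
                        "asw": average_silhouette_width(ov, ov_batch_labels),
                    }
                )
    return DownsampleResult(
        correlations=pd.DataFrame(rows),
        asw=pd.DataFrame(asw_rows, columns=["fraction", "rep", "asw"]),
        rosters=rosters,
        baseline=baseline,
    )
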