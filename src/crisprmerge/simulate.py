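"""Synthetic two-institute dependency cohorts with known ground truth.

The generator emulates the structure that cross-institute integration has to
contend with: a common biological signal (common-essential genes centred near
a score of -1, non-essentials near 0, lineage/subtype-specific dependencies,
biomarker-linked selective dependencies), overlaid with institute batch
effects of three kinds -- per-gene location shifts, per-gene scale changes on
the noise term (the location/scale model empirical-Bayes correction assumes),
and one shared low-rank (rank-1) component whose within-batch variation is
*not* expressible as per-gene location/scale, giving principal-component
removal a distinct signal to take out. Screen quality enters as a
multiplicative phenotype-intensity factor per screen.

All draws flow from a single seed; each operation derives its own stream from
``(seed, stage)`` so the three public operations are individually
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ReferenceSets, ScreenMatrix, ScreenMetadata

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dual_screens",
    "simulate_expression",
    "simulate_cfe_and_oncogenes",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror a scaled-down two-institute design: 1000 genes, 168
    overlapping cell lines spread over 16 lineages, per-gene batch shift sd
    0.3, batch scale sd 0.1 and iid noise sd 0.2 (score units are log
    fold-changes, where prior-known essentials sit near -1).

    ``selective_dependency_specs`` lists planted biomarker dependencies as
    ``(gene, cfe_id, tissue, delta)`` where ``delta`` is the effect size in
    Cohen's-delta units (carrier screens are shifted by ``-delta * noise_sd``).
    """

    n_genes: int = 1000
    n_screens_a: int = 200
    n_screens_b: int = 250
    n_overlap: int = 168
    n_lineages: int = 16
    subtypes_per_lineage: int = 2
    frac_essential: float = 0.10
    frac_never_expressed: float = 0.05
    selective_dependency_specs: tuple = ()
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    shared_component_sd: float = 0.3
    quality_sd: float = 0.1
    noise_sd: float = 0.2
    n_lineage_markers: int = 3
    lineage_marker_effect: float = -0.8
    n_subtype_markers: int = 2
    subtype_marker_effect: float = -0.8
    frac_selective: float = 0.20
    selective_line_frac: tuple = (0.02, 0.25)
    selective_effect: tuple = (-1.2, -0.4)
    n_related_pairs: int = 0
    related_pair_loading: float = 0.4
    n_background_cfes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_essential, self.frac_never_expressed):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for n in (self.n_genes, self.n_screens_a, self.n_screens_b, self.n_lineages):
            if n <= 0:
                raise ValueError("counts must be positive")
        if self.n_overlap > min(self.n_screens_a, self.n_screens_b):
            raise ValueError("n_overlap exceeds a batch size")


@dataclass
class GroundTruth:
    """Planted parameters recorded for recovery checks."""

    essential_genes: set
    non_essential_genes: set
    never_expressed_genes: set
    base_scores: pd.Series
    batch_shift: pd.DataFrame  # batches x genes, additive
    batch_scale: pd.DataFrame  # batches x genes, multiplies the noise sd
    shared_gene_loading: pd.Series
    shared_screen_score: pd.Series
    quality: pd.Series  # per screen
    lineage: pd.Series  # per cell line
    subtype: pd.Series  # per cell line
    lineage_markers: dict = field(default_factory=dict)
    subtype_markers: dict = field(default_factory=dict)
    selective_dependencies: dict = field(default_factory=dict)  # gene -> (effect, lines)
    biomarkers: list = field(default_factory=list)  # (gene, cfe, tissue, delta, carriers)
    related_pairs: list = field(default_factory=list)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.lineage.index)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _line_names(n: int) -> list[str]:
    return [f"CL{i:04d}" for i in range(n)]


def simulate_dual_screens(
    cfg: SimulationConfig,
) -> tuple[ScreenMatrix, ScreenMatrix, ScreenMetadata, ReferenceSets, GroundTruth]:
    """Generate matched institute-A and institute-B dependency datasets.

    Per-screen scores are
    ``q_j * (base_g + effects_gl) + gamma_ig + s * u_g * m_j + delta_ig * eps``
    with quality multiplier ``q_j``, per-batch per-gene shift ``gamma`` and
    noise scale ``delta``, shared rank-1 component ``u_g m_j`` of magnitude
    ``s`` and iid noise ``eps ~ N(0, noise_sd)``. Overlapping cell lines are
    screened once in each batch with independent noise.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = _gene_names(cfg.n_genes)
    n_unique = cfg.n_screens_a + cfg.n_screens_b - cfg.n_overlap
    lines = _line_names(n_unique)

    # gene classes
    n_ess = round(cfg.frac_essential * cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    essential = {genes[i] for i in perm[:n_ess]}
    non_essential = {g for g in genes if g not in essential}
    n_nev = round(cfg.frac_never_expressed * cfg.n_genes)
    nev_pool = [genes[i] for i in perm[n_ess:]]
    never_expressed = set(nev_pool[:n_nev])

    base = pd.Series(0.0, index=genes)
    ess_idx = sorted(essential)
    base[ess_idx] = rng.normal(-1.0, 0.15, size=len(ess_idx))
    non_idx = sorted(non_essential)
    # non-essential knockouts have near-zero true fitness effect
    base[non_idx] = rng.normal(0.0, 0.05, size=len(non_idx))

    # lineage / subtype assignment over unique cell lines
    props = rng.dirichlet(np.full(cfg.n_lineages, 4.0))
    lineage_labels = [f"tissue{i:02d}" for i in range(cfg.n_lineages)]
    assignment = rng.choice(cfg.n_lineages, size=n_unique, p=props)
    # guarantee each lineage is represented
    for i in range(cfg.n_lineages):
        if not (assignment == i).any():
            assignment[rng.integers(n_unique)] = i
    lineage = pd.Series([lineage_labels[i] for i in assignment], index=lines)
    subtype = pd.Series(
        [
            f"{lineage[l]}_s{rng.integers(cfg.subtypes_per_lineage)}"
            for l in lines
        ],
        index=lines,
    )

    # marker genes: extra depletion in lines of one lineage / subtype
    marker_pool = [g for g in nev_pool[n_nev:]]
    rng.shuffle(marker_pool)
    pool_iter = iter(marker_pool)
    lineage_markers = {
        lab: [next(pool_iter) for _ in range(cfg.n_lineage_markers)]
        for lab in lineage_labels
    }
    subtype_markers = {
        sub: [next(pool_iter) for _ in range(cfg.n_subtype_markers)]
        for sub in sorted(subtype.unique())
    }

    # functionally related pairs share a per-line latent factor
    related_pairs = []
    pair_loading = {}
    for _ in range(cfg.n_related_pairs):
        g1, g2 = next(pool_iter), next(pool_iter)
        related_pairs.append((g1, g2))
        pair_loading[(g1, g2)] = cfg.related_pair_loading

    # sparse per-line selective dependencies: each cell line's combination of
    # private dependencies is its identity fingerprint across institutes
    n_sel = round(cfg.frac_selective * cfg.n_genes)
    selective_genes = [next(pool_iter) for _ in range(min(n_sel, len(marker_pool) - 1))]
    selective_map: dict[str, tuple] = {}
    for g in selective_genes:
        frac_dep = rng.uniform(*cfg.selective_line_frac)
        n_dep = max(1, round(frac_dep * n_unique))
        dep_lines = rng.choice(n_unique, size=n_dep, replace=False)
        effect = rng.uniform(*cfg.selective_effect)
        selective_map[g] = (effect, {lines[i] for i in dep_lines})

    # biomarker specs: carriers drawn from the spec's tissue
    biomarkers = []
    for gene, cfe, tissue, delta in cfg.selective_dependency_specs:
        if tissue not in lineage_labels:
            raise ValueError(f"selective dependency references unknown lineage {tissue!r}")
        members = [l for l in lines if lineage[l] == tissue]
        n_car = len(members) // 2
        if n_car < 3 or len(members) - n_car < 3:
            raise ValueError(
                f"tissue {tissue!r} too small ({len(members)} lines) for >=3 "
                "carriers and >=3 non-carriers"
            )
        carriers = set(rng.choice(members, size=n_car, replace=False))
        biomarkers.append((gene, cfe, tissue, float(delta), carriers))

    # per-line effect matrix (genes x lines)
    effects = pd.DataFrame(0.0, index=genes, columns=lines)
    for lab, mk in lineage_markers.items():
        cols = lineage.index[lineage == lab]
        effects.loc[mk, cols] += cfg.lineage_marker_effect
    for sub, mk in subtype_markers.items():
        cols = subtype.index[subtype == sub]
        effects.loc[mk, cols] += cfg.subtype_marker_effect
    for g, (effect, dep_lines) in selective_map.items():
        effects.loc[g, sorted(dep_lines)] += effect
    for (g1, g2), load in pair_loading.items():
        factor = rng.normal(0.0, 1.0, size=n_unique)
        effects.loc[g1] += load * factor
        effects.loc[g2] += load * factor
    for gene, _cfe, _tissue, delta, carriers in biomarkers:
        effects.loc[gene, sorted(carriers)] += -delta * cfg.noise_sd

    # rosters: overlap lines screened in both batches
    order = rng.permutation(n_unique)
    overlap_lines = [lines[i] for i in order[: cfg.n_overlap]]
    a_only = [lines[i] for i in order[cfg.n_overlap : cfg.n_screens_a]]
    b_only = [lines[i] for i in order[cfg.n_screens_a :]]
    lines_a = sorted(overlap_lines + a_only)
    lines_b = sorted(overlap_lines + b_only)

    batches = ["broad", "sanger"]
    # batch effects are relative distortions between institutes: the
    # common-mode component is unidentifiable (it is part of the consensus
    # signal), so planted shifts/scales are mean-zero across batches while
    # keeping the stated per-batch marginal sd
    raw_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(2, cfg.n_genes))
    raw_shift = (raw_shift - raw_shift.mean(axis=0)) * np.sqrt(2.0)
    gamma = pd.DataFrame(raw_shift, index=batches, columns=genes)
    raw_logscale = rng.normal(0.0, cfg.batch_scale_sd, size=(2, cfg.n_genes))
    raw_logscale = (raw_logscale - raw_logscale.mean(axis=0)) * np.sqrt(2.0)
    delta_scale = pd.DataFrame(np.exp(raw_logscale), index=batches, columns=genes)
    u = pd.Series(rng.normal(0.0, 1.0, size=cfg.n_genes), index=genes)

    def make_batch(batch: str, batch_lines: list[str], m_mean: float):
        screens = [f"{l}_{batch}" for l in batch_lines]
        q = rng.normal(1.0, cfg.quality_sd, size=len(screens)).clip(0.2, None)
        m_j = rng.normal(m_mean, 0.3, size=len(screens))
        signal = base.to_numpy()[:, None] + effects[batch_lines].to_numpy()
        eps = rng.normal(0.0, cfg.noise_sd, size=signal.shape)
        vals = (
            q[None, :] * signal
            + gamma.loc[batch].to_numpy()[:, None]
            + cfg.shared_component_sd * u.to_numpy()[:, None] * m_j[None, :]
            + delta_scale.loc[batch].to_numpy()[:, None] * eps
        )
        mat = ScreenMatrix(vals, genes, screens)
        meta = pd.DataFrame(
            {
                "screen_id": screens,
                "cell_line_id": batch_lines,
                "batch": batch,
                "lineage": [lineage[l] for l in batch_lines],
                "subtype": [subtype[l] for l in batch_lines],
            }
        )
        return mat, meta, q, m_j

    mat_a, meta_a, q_a, m_a = make_batch("broad", lines_a, +0.5)
    mat_b, meta_b, q_b, m_b = make_batch("sanger", lines_b, -0.5)
    meta = ScreenMetadata(pd.concat([meta_a, meta_b], ignore_index=True))
    quality = pd.Series(
        np.concatenate([q_a, q_b]), index=list(mat_a.screen_ids) + list(mat_b.screen_ids)
    )
    m_all = pd.Series(
        np.concatenate([m_a, m_b]), index=list(mat_a.screen_ids) + list(mat_b.screen_ids)
    )

    gt = GroundTruth(
        essential_genes=essential,
        non_essential_genes=non_essential,
        never_expressed_genes=never_expressed,
        base_scores=base,
        batch_shift=gamma,
        batch_scale=delta_scale,
        shared_gene_loading=u,
        shared_screen_score=m_all,
        quality=quality,
        lineage=lineage,
        subtype=subtype,
        lineage_markers=lineage_markers,
        subtype_markers=subtype_markers,
        selective_dependencies=selective_map,
        biomarkers=biomarkers,
        related_pairs=related_pairs,
    )

    used = {g for mk in lineage_markers.values() for g in mk}
    used |= {g for mk in subtype_markers.values() for g in mk}
    used |= {g for pair in related_pairs for g in pair}
    used |= set(selective_map)
    n_pool = sorted(non_essential - never_expressed - used)
    refs = ReferenceSets(
        essentials=set(essential),
        non_essentials=set(
            rng.choice(n_pool, size=min(2 * max(len(essential), 1), len(n_pool)), replace=False)
        ),
        related_pairs=list(related_pairs),
    )
    refs.expression = simulate_expression(gt, cfg)
    cfe_matrix, cfe_tissue, onco = simulate_cfe_and_oncogenes(gt, cfg)
    refs.cfe_matrix = cfe_matrix
    refs.cfe_tissue = cfe_tissue
    refs.oncogene_positives = onco
    return mat_a, mat_b, meta, refs, gt


def simulate_expression(gt: GroundTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Basal expression, log2(TPM+1), genes x cell lines.

    Never-expressed genes stay below 0.01 in every line; every other gene is
    expressed (>= 0.01) in well over 10% of lines (each gene draws its
    expressed fraction from U(0.6, 1)).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    genes = list(gt.base_scores.index)
    lines = gt.cell_lines
    n_l = len(lines)
    expr = np.empty((len(genes), n_l))
    nev = gt.never_expressed_genes
    for i, g in enumerate(genes):
        if g in nev:
            expr[i] = rng.uniform(0.0, 0.009, size=n_l)
        else:
            frac = rng.uniform(0.6, 1.0)
            on = rng.random(n_l) < frac
            if not on.any():
                on[rng.integers(n_l)] = True
            mu = rng.uniform(2.0, 8.0)
            vals = rng.normal(mu, 1.0, size=n_l).clip(0.02, None)
            # low but detectable trace expression in "off" lines keeps the
            # never-expressed class cleanly separable, as in bulk RNA-seq
            expr[i] = np.where(on, vals, rng.uniform(0.01, 0.5, size=n_l))
    return pd.DataFrame(expr, index=genes, columns=lines)


def simulate_cfe_and_oncogenes(
    gt: GroundTruth, cfg: SimulationConfig
) -> tuple[pd.DataFrame, dict, dict]:
    """Binary CFE matrix (cell lines x CFEs), per-CFE tissue scope, and
    oncogene gain-of-function positives.

    Planted biomarker CFEs mark exactly the carrier lines chosen when the
    score effects were planted; background CFEs are random binary features.
    Oncogenes are the planted selective-dependency genes, with their carrier
    lines as gain-of-function positives.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    lines = gt.cell_lines
    cols = {}
    cfe_tissue = {}
    for gene, cfe, tissue, _delta, carriers in gt.biomarkers:
        cols[cfe] = [1 if l in carriers else 0 for l in lines]
        cfe_tissue[cfe] = tissue
    for i in range(cfg.n_background_cfes):
        name = f"bgCFE{i:03d}"
        p = rng.uniform(0.1, 0.5)
        cols[name] = (rng.random(len(lines)) < p).astype(int)
        cfe_tissue[name] = None
    cfe_matrix = pd.DataFrame(cols, index=lines)
    onco = {
        gene: set(carriers) for gene, _cfe, _tissue, _delta, carriers in gt.biomarkers
    }
    return cfe_matrix, cfe_tissue, onco
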