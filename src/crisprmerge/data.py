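"""Core data containers and I/O for gene-level dependency screens.

The universal currency of the pipeline is a genes x screens matrix of
dependency scores (log fold-change-like; negative values indicate loss of
fitness on knockout), accompanied by per-screen metadata (cell line,
institute/batch, lineage, subtype) and reference sets (prior essential /
non-essential genes, basal expression, cancer functional events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenMatrix",
    "ScreenMetadata",
    "ReferenceSets",
    "AlignedCohort",
    "read_screen_matrix",
    "write_screen_matrix",
    "read_screen_metadata",
    "harmonize_gene_symbols",
    "align_datasets",
]

METADATA_COLUMNS = ["screen_id", "cell_line_id", "batch", "lineage", "subtype"]


@dataclass
class ScreenMatrix:
    """Genes x screens matrix of dependency scores with an explicit missing mask.

    Canonical orientation is genes in rows. Missing entries are carried in
    ``missing_mask`` (True = missing), never as sentinel numbers; ``values``
    must be finite wherever the mask is False.
    """

    values: np.ndarray
    gene_ids: list[str]
    screen_ids: list[str]
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.screen_ids = [str(s) for s in self.screen_ids]
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_g, n_s = self.values.shape
        if len(self.gene_ids) != n_g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_g} rows")
        if len(self.screen_ids) != n_s:
            raise ValueError(f"{len(self.screen_ids)} screen ids for {n_s} columns")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        for name, ids in (("gene", self.gene_ids), ("screen", self.screen_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {name} ids: {sorted(dups)}")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite values outside the missing mask")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_screens(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view (genes x screens) with NaN at masked entries."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.screen_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenMatrix":
        vals = df.to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        vals = np.where(mask, 0.0, vals)
        return cls(vals, list(df.index), list(df.columns), mask)

    def subset_genes(self, genes: list[str]) -> "ScreenMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ScreenMatrix(
            self.values[rows], list(genes), list(self.screen_ids), self.missing_mask[rows]
        )

    def subset_screens(self, screens: list[str]) -> "ScreenMatrix":
        idx = {s: i for i, s in enumerate(self.screen_ids)}
        cols = [idx[s] for s in screens]
        return ScreenMatrix(
            self.values[:, cols], list(self.gene_ids), list(screens), self.missing_mask[:, cols]
        )

    def copy(self) -> "ScreenMatrix":
        return ScreenMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.screen_ids),
            self.missing_mask.copy(),
        )


@dataclass
class ScreenMetadata:
    """Per-screen annotations: cell line, batch (institute), lineage, subtype.

    Backed by a DataFrame with columns ``screen_id, cell_line_id, batch,
    lineage, subtype`` (subtype nullable) and an optional ``quality_nnmd``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if "subtype" not in df.columns:
            df = df.assign(subtype=pd.NA)
        dups = _duplicates(list(df["screen_id"]))
        if dups:
            raise ValueError(f"duplicate screen ids in metadata: {sorted(dups)}")
        self.table = df.reset_index(drop=True)

    def for_screens(self, screen_ids: list[str]) -> "ScreenMetadata":
        sub = self.table[self.table["screen_id"].isin(set(screen_ids))]
        found = set(sub["screen_id"])
        lost = [s for s in screen_ids if s not in found]
        if lost:
            raise KeyError(f"screens without metadata: {lost[:5]}")
        order = {s: i for i, s in enumerate(screen_ids)}
        sub = sub.sort_values("screen_id", key=lambda s: s.map(order))
        return ScreenMetadata(sub.reset_index(drop=True))

    def batch_of(self) -> pd.Series:
        return self.table.set_index("screen_id")["batch"]

    def cell_line_of(self) -> pd.Series:
        return self.table.set_index("screen_id")["cell_line_id"]

    def lineage_of(self) -> pd.Series:
        return self.table.set_index("screen_id")["lineage"]

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch"].unique())

    def concat(self, other: "ScreenMetadata") -> "ScreenMetadata":
        return ScreenMetadata(pd.concat([self.table, other.table], ignore_index=True))

    def per_cell_line(self) -> "ScreenMetadata":
        """Metadata keyed by cell line (for matrices whose columns are cell
        lines after duplicate resolution)."""
        t = self.table.drop_duplicates("cell_line_id").copy()
        t["screen_id"] = t["cell_line_id"]
        return ScreenMetadata(t)


@dataclass
class ReferenceSets:
    """Prior knowledge used by benchmarking and essential-gene calling.

    ``essentials`` and ``non_essentials`` are disjoint gene sets; ``expression``
    is a genes x cell-lines matrix of log2(TPM+1); ``cfe_matrix`` is a binary
    cell-lines x CFEs matrix with per-CFE tissue scope in ``cfe_tissue``;
    ``oncogene_positives`` maps oncogene -> cell lines carrying a
    gain-of-function alteration; ``related_pairs`` lists known related genes.
    """

    essentials: set = field(default_factory=set)
    non_essentials: set = field(default_factory=set)
    expression: pd.DataFrame | None = None
    cfe_matrix: pd.DataFrame | None = None
    cfe_tissue: dict = field(default_factory=dict)
    oncogene_positives: dict = field(default_factory=dict)
    related_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = self.essentials & self.non_essentials
        if overlap:
            raise ValueError(f"genes in both E and N: {sorted(overlap)[:5]}")
        if self.expression is not None and (self.expression.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        if self.cfe_matrix is not None:
            vals = self.cfe_matrix.to_numpy()
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("cfe_matrix entries must be 0/1")


@dataclass
class AlignedCohort:
    """Two datasets restricted to shared genes, plus roster bookkeeping."""

    a: ScreenMatrix
    b: ScreenMatrix
    meta: ScreenMetadata
    genes: list[str]
    overlap_cell_lines: list[str]
    union_cell_lines: list[str]

    @property
    def n_unique_cell_lines(self) -> int:
        return len(self.union_cell_lines)


def _duplicates(ids: list[str]) -> set:
    seen: set = set()
    dup: set = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_screen_matrix(path, dialect: str = "genes-in-rows") -> ScreenMatrix:
    """Read a delimited dependency matrix (one id header row, one id column).

    ``dialect`` declares the file orientation; the result is always
    genes-in-rows. Empty cells become masked entries. Duplicate ids or a
    non-numeric body cell are hard errors.
    """
    if dialect not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown dialect: {dialect}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if dialect == "genes-in-columns":
        df = df.T
    for name, ids in (("gene", list(df.index)), ("screen", list(df.columns))):
        dups = _duplicates([str(x) for x in ids])
        if dups:
            raise ValueError(f"duplicate {name} ids in {path}: {sorted(dups)}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    nonempty = df.notna() & df.apply(lambda c: c.astype(str).str.strip() != "")
    bad = coerced.isna() & nonempty
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, screen {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    # astype goes through Python float() and is correctly rounded, unlike
    # the to_numeric fast path
    return ScreenMatrix.from_frame(df.astype(float))


def write_screen_matrix(m: ScreenMatrix, path) -> None:
    """Write genes-in-rows delimited text; masked entries become empty cells.

    Uses repr-precision floats so a read/write cycle is lossless.
    """
    df = m.to_frame()
    df.to_csv(
        path,
        sep=_sep_for(path),
        index_label="gene",
        na_rep="",
        float_format=lambda v: repr(float(v)),
    )


def read_screen_metadata(path) -> ScreenMetadata:
    return ScreenMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_screen_metadata(meta: ScreenMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def harmonize_gene_symbols(m: ScreenMatrix, alias_map: dict) -> ScreenMatrix:
    """Map gene symbols through a user-supplied alias table (old -> current).

    Unmapped symbols pass through unchanged. When two rows collapse to the
    same current symbol, the row with fewer missing entries is kept (ties by
    first occurrence) and the drop is logged; >10% row loss logs a warning.
    """
    new_ids = [alias_map.get(g, g) for g in m.gene_ids]
    n_missing = m.missing_mask.sum(axis=1)
    keep: dict[str, int] = {}
    dropped = []
    for i, sym in enumerate(new_ids):
        if sym not in keep:
            keep[sym] = i
        elif n_missing[i] < n_missing[keep[sym]]:
            dropped.append(keep[sym])
            keep[sym] = i
        else:
            dropped.append(i)
    if dropped:
        logger.info(
            "symbol harmonization dropped %d duplicated rows: %s",
            len(dropped),
            [m.gene_ids[i] for i in dropped[:10]],
        )
        if len(dropped) > 0.10 * m.n_genes:
            logger.warning(
                "symbol harmonization collapsed >10%% of rows (%d of %d)",
                len(dropped),
                m.n_genes,
            )
    rows = sorted(keep.values())
    return ScreenMatrix(
        m.values[rows],
        [new_ids[i] for i in rows],
        list(m.screen_ids),
        m.missing_mask[rows],
    )


def align_datasets(
    a: ScreenMatrix,
    a_meta: ScreenMetadata,
    b: ScreenMatrix,
    b_meta: ScreenMetadata,
) -> AlignedCohort:
    """Restrict two harmonized datasets to shared genes and build rosters.

    The union roster counts each cell line once per institute screen; the
    overlap roster holds cell lines with exactly one screen in each batch, so
    ``|union lines| = |A lines| + |B lines| - |overlap|`` (inclusion-exclusion).
    A cell line with more than one screen in a single batch must be collapsed
    upstream and is a hard error here.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between datasets")
    a_meta = a_meta.for_screens(a.screen_ids)
    b_meta = b_meta.for_screens(b.screen_ids)
    for name, meta in (("a", a_meta), ("b", b_meta)):
        counts = meta.table.groupby("cell_line_id")["screen_id"].count()
        multi = counts[counts > 1]
        if len(multi):
            raise ValueError(
                f"dataset {name} has cell lines with >1 screen: {list(multi.index)[:5]}"
            )
    lines_a = set(a_meta.table["cell_line_id"])
    lines_b = set(b_meta.table["cell_line_id"])
    overlap = sorted(lines_a & lines_b)
    union = sorted(lines_a | lines_b)
    return AlignedCohort(
        a=a.subset_genes(shared),
        b=b.subset_genes(shared),
        meta=a_meta.concat(b_meta),
        genes=shared,
        overlap_cell_lines=overlap,
        union_cell_lines=union,
    )
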