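"""Fold-change expression tables: enrichment selection, Venn intersection,
outlier miRNA detection, correlation and hierarchical clustering.

Fold changes follow the signed convention used on expression arrays
comparing two compartments: a positive value x means x-fold higher in
the exosome than in the parent cell, a negative value x means |x|-fold
higher in the cell.  A ratio and its reciprocal are therefore encoded
by sign and no value lies strictly inside (-1, 1).  Tables of raw
ratios can be imported with ``assume_ratios=True``, which converts
r < 1 to -1/r.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class SelectionConfig:
    """Thresholds for calling a transcript enriched.

    fc_min: minimum signed fold change (inclusive; printed fold changes
    are rounded, so a table entry equal to the threshold passes).
    z_cut: z-score cutoff applied within a cell line's distribution
    when mode='fc_and_z'.
    """

    fc_min: float = 2.0
    z_cut: float = 3.0

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.z_cut <= 0:
            raise ValueError("z_cut must be > 0")


class ExpressionTable:
    """Signed fold changes, features x cell lines.

    Parameters
    ----------
    frame:
        DataFrame indexed by feature id with one column per cell line.
    kind:
        'lncRNA' or 'miRNA'.
    assume_ratios:
        If True, values are raw ratios and values in (0, 1) are
        converted to the signed encoding (-1/r).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        kind: Literal["lncRNA", "miRNA"] = "lncRNA",
        assume_ratios: bool = False,
    ) -> None:
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        values = frame.astype(float)
        if assume_ratios:
            if (values.to_numpy() <= 0).any():
                raise ValueError("raw ratios must be positive")
            arr = values.to_numpy()
            arr = np.where(arr < 1.0, -1.0 / arr, arr)
            values = pd.DataFrame(arr, index=values.index, columns=values.columns)
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("fold changes must be finite")
        if (np.abs(arr) < 1.0).any():
            raise ValueError(
                "signed fold-change encoding admits no values in (-1, 1); "
                "use assume_ratios=True for raw ratio tables"
            )
        self.frame = values
        self.kind = kind

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        kind: Literal["lncRNA", "miRNA"] = "lncRNA",
        assume_ratios: bool = False,
    ) -> "ExpressionTable":
        """Load a TSV/CSV with a header row of cell lines, first column ids."""
        sep = "," if str(path).endswith(".csv") else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        # drop annotation columns (e.g. lncRNA type) that are not numeric
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        keep = [c for c in frame.columns if numeric[c].notna().all()]
        return cls(numeric[keep], kind=kind, assume_ratios=assume_ratios)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    def line_values(self, line: str) -> pd.Series:
        if line not in self.frame.columns:
            raise KeyError(f"unknown cell line: {line!r}")
        return self.frame[line]

    def signed_log10(self) -> pd.DataFrame:
        """sign(v) * log10(|v|) per entry; the scale used for miRNA work."""
        arr = self.frame.to_numpy()
        return pd.DataFrame(
            np.sign(arr) * np.log10(np.abs(arr)),
            index=self.frame.index,
            columns=self.frame.columns,
        )


def zscores(values: Sequence[float]) -> np.ndarray:
    """Standard z-score transform using the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return (arr - arr.mean()) / sd


def select_enriched(
    table: ExpressionTable,
    line: str,
    cfg: SelectionConfig | None = None,
    mode: Literal["fc_only", "fc_and_z"] = "fc_only",
    direction: Literal["up", "down"] = "up",
) -> set[str]:
    """Features passing the fold-change (and optionally z-score) filter.

    'up' selects value >= fc_min (exosome-enriched); 'down' selects
    value <= -fc_min (cell-enriched).  In mode 'fc_and_z' the feature's
    z-score within the given line's distribution must also reach z_cut.
    """
    cfg = cfg or SelectionConfig()
    vals = table.line_values(line)
    if direction == "up":
        mask = vals >= cfg.fc_min
    else:
        mask = vals <= -cfg.fc_min
    if mode == "fc_and_z":
        z = pd.Series(zscores(vals.to_numpy()), index=vals.index)
        mask &= (z >= cfg.z_cut) if direction == "up" else (z <= -cfg.z_cut)
    return set(vals.index[mask])


def intersect_enriched(
    per_line_sets: Mapping[str, set[str]],
) -> tuple[set[str], dict[tuple[str, ...], int]]:
    """Intersection of per-cell-line selections plus all Venn region sizes.

    Returns the common set and a mapping from each non-empty membership
    pattern (tuple of line labels the region belongs to) to its size.
    """
    if len(per_line_sets) < 2:
        raise ValueError("need at least two sets to intersect")
    lines = list(per_line_sets)
    universe = set().union(*per_line_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for pattern in product([True, False], repeat=len(lines)):
        if not any(pattern):
            continue
        inside = [ln for ln, p in zip(lines, pattern) if p]
        outside = [ln for ln, p in zip(lines, pattern) if not p]
        region = set(universe)
        for ln in inside:
            region &= per_line_sets[ln]
        for ln in outside:
            region -= per_line_sets[ln]
        regions[tuple(inside)] = len(region)
    common = set.intersection(*(set(s) for s in per_line_sets.values()))
    return common, regions


def select_outlier_mirnas(
    table: ExpressionTable,
    line: str,
    whisker: float = 1.5,
) -> set[str]:
    """Over-expressed miRNAs by the Tukey boxplot rule on log10 fold change.

    A miRNA is flagged when its signed log10 fold change strictly
    exceeds Q3 + whisker * IQR of the line's distribution (linear-
    interpolation quartiles).  whisker=1.5 flags 'outliers'; pass 3.0
    for the 'extreme' fence.
    """
    if table.kind != "miRNA":
        raise ValueError("outlier selection applies to miRNA tables")
    vals = table.signed_log10()[_check_line(table, line)]
    if len(vals) < 4:
        raise ValueError("too few values for quartiles")
    q1, q3 = np.percentile(vals.to_numpy(), [25, 75])
    fence = q3 + whisker * (q3 - q1)
    return set(vals.index[vals > fence])


def _check_line(table: ExpressionTable, line: str) -> str:
    if line not in table.frame.columns:
        raise KeyError(f"unknown cell line: {line!r}")
    return line


def pearson_cell_vs_exosome(
    cell_values: Sequence[float], exosome_values: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between cellular and exosomal
    log10 fold-change profiles over matched features."""
    x = np.asarray(cell_values, float)
    y = np.asarray(exosome_values, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def hcl_cluster(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    method: Literal["average", "single", "complete"] = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) with Euclidean distance.

    Mirrors the standard expression-heatmap workflow: samples are
    clustered on their feature profiles; average linkage by default.
    The dendrogram is returned with a newick serialisation whose branch
    lengths are merge heights.
    """
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float).T  # rows become samples
        labels = labels or list(matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float).T
        labels = list(labels) if labels is not None else [
            f"S{i}" for i in range(data.shape[0])
        ]
    if np.isnan(data).any():
        raise ValueError("matrix contains NaN")
    if data.shape[0] < 2:
        raise ValueError("need at least two samples")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method=method)
    tree = hierarchy.to_tree(Z)
    leaf_idx = hierarchy.leaves_list(Z)
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(Z, list(labels), [labels[i] for i in leaf_idx], newick)


def _to_newick(node, labels: Sequence[str], parent_height: float | None = None) -> str:
    length = "" if parent_height is None else f":{parent_height - node.dist:.6g}"
    if node.is_leaf():
        return f"{labels[node.id]}{length}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}){length}"
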