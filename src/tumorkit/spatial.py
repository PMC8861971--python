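"""Spatial single-cell statistics for multiplexed tissue imaging.

Single-cell feature tables (centroids in micrometers, per-marker mean
intensities) from multiplex immunohistochemistry or cyclic
immunofluorescence are normalized per image, routed through a hierarchical
gating tree into phenotype populations, and summarized as composition
percentages and densities. A binary extracellular-matrix (ECM) mask — e.g.
thresholded collagen I staining — serves as the reference for
distance-to-matrix analysis: each cell's distance to the nearest mask
pixel is measured, cells are grouped into 0-25/25-50/50-75 um bins, and
marker intensity across bins is compared by one-way ANOVA with Bonferroni
correction over the tests in the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "ECMMask",
    "GateNode",
    "DistanceBinResult",
    "DEFAULT_BIN_EDGES",
    "normalize_intensities",
    "parse_gating_tree",
    "apply_gating_tree",
    "population_counts",
    "composition_metrics",
    "distance_to_mask",
    "bin_and_test",
    "distance_bin_analysis",
]

DEFAULT_BIN_EDGES = (0.0, 25.0, 50.0, 75.0)
X_COL, Y_COL = "x_um", "y_um"


@dataclass(frozen=True)
class ECMMask:
    """Binary raster of positive ECM staining.

    Pixel (0, 0) is top-left; x runs rightward along columns and y downward
    along rows. ``pixel_size`` is um per pixel.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("mask must be a nonempty 2-D raster")
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))


@dataclass(frozen=True)
class GateNode:
    """One split of a hierarchical gating tree.

    Cells with normalized ``marker`` intensity >= ``threshold`` follow the
    ``above`` branch (boundary inclusive), the rest follow ``below``. A
    branch is either another GateNode or a leaf population label.
    """

    marker: str
    threshold: float
    above: "GateNode | str"
    below: "GateNode | str"
    name: str | None = None


@dataclass(frozen=True)
class DistanceBinResult:
    marker: str
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    bin_means: tuple[float, ...]
    f_stat: float
    p_value: float
    p_adjusted: float
    significant: bool
    testable: bool


# ---------------------------------------------------------------------------
# normalization and gating
# ---------------------------------------------------------------------------

def normalize_intensities(
    cells: pd.DataFrame,
    markers: Sequence[str],
    image_col: str | None = None,
) -> pd.DataFrame:
    """Rescale marker intensities to [0, 1] by the per-image maximum.

    Each marker column is divided by its maximum within each image (whole
    table when ``image_col`` is None). An all-zero marker is left at 0 with
    a warning.
    """
    out = cells.copy()
    groups = [(None, out)] if image_col is None else out.groupby(image_col)
    for key, sub in groups:
        for m in markers:
            mx = sub[m].max()
            if mx > 0:
                out.loc[sub.index, m] = sub[m] / mx
            else:
                warnings.warn(
                    f"marker {m!r} all zero in image {key!r}; left unscaled",
                    stacklevel=2,
                )
    return out


def parse_gating_tree(spec: Mapping | str) -> "GateNode | str":
    """Build a gating tree from a nested mapping (e.g. loaded YAML).

    Each node mapping carries ``marker``, ``threshold``, ``above`` and
    ``below``; branches are nested mappings or leaf label strings.
    """
    if isinstance(spec, str):
        return spec
    for key in ("marker", "threshold", "above", "below"):
        if key not in spec:
            raise ValueError(f"gating node missing {key!r}: {dict(spec)!r}")
    return GateNode(
        marker=str(spec["marker"]),
        threshold=float(spec["threshold"]),
        above=parse_gating_tree(spec["above"]),
        below=parse_gating_tree(spec["below"]),
        name=spec.get("name"),
    )


def _node_name(node: GateNode, depth: int) -> str:
    return node.name or f"{node.marker}@{node.threshold:g}"


def apply_gating_tree(cells: pd.DataFrame, tree: "GateNode | str") -> pd.Series:
    """Route every cell to exactly one leaf population label."""
    labels = pd.Series("", index=cells.index, dtype=object, name="population")

    def route(idx: pd.Index, node: "GateNode | str"):
        if isinstance(node, str):
            labels.loc[idx] = node
            return
        if node.marker not in cells.columns:
            raise KeyError(
                f"gating node {_node_name(node, 0)!r} references missing marker "
                f"{node.marker!r}"
            )
        vals = cells.loc[idx, node.marker]
        above = idx[(vals >= node.threshold).to_numpy()]
        below = idx.difference(above)
        route(above, node.above)
        route(below, node.below)

    route(cells.index, tree)
    return labels


def population_counts(cells: pd.DataFrame, tree: "GateNode | str") -> pd.DataFrame:
    """Counts of cells reaching every node (internal and leaf) of the tree.

    Returns a DataFrame with columns (population, parent, count, is_leaf);
    the root row has parent "" and counts all cells. Internal-node counts
    equal the sum of their children by construction.
    """
    rows: list[dict] = []

    def walk(idx: pd.Index, node: "GateNode | str", parent: str):
        if isinstance(node, str):
            rows.append(
                {"population": node, "parent": parent, "count": len(idx), "is_leaf": True}
            )
            return
        if node.marker not in cells.columns:
            raise KeyError(f"gating tree references missing marker {node.marker!r}")
        name = _node_name(node, 0)
        rows.append(
            {"population": name, "parent": parent, "count": len(idx), "is_leaf": False}
        )
        vals = cells.loc[idx, node.marker]
        above = idx[(vals >= node.threshold).to_numpy()]
        below = idx.difference(above)
        walk(above, node.above, name)
        walk(below, node.below, name)

    rows.append(
        {"population": "total", "parent": "", "count": len(cells), "is_leaf": False}
    )
    walk(cells.index, tree, "total")
    return pd.DataFrame(rows)


def composition_metrics(
    cells: pd.DataFrame,
    tree: "GateNode | str",
    tissue_area_mm2: float,
) -> pd.DataFrame:
    """Population composition percentages and densities.

    Cells from multiple regions of interest should be pooled (counts and
    areas summed) before calling, so percentages reflect the whole tissue.
    Per population: percent of total nucleated cells, percent of the parent
    population (NaN when the parent is empty), and cells per mm^2 of tissue
    analyzed. A zero-cell table yields a zeroed report with a warning.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    counts = population_counts(cells, tree)
    total = int(counts.loc[counts["population"] == "total", "count"].iloc[0])
    if total == 0:
        warnings.warn("no cells in table; composition report is zeroed", stacklevel=2)
    by_name = counts.set_index("population")["count"]
    out = counts.copy()
    out["percent_of_total"] = 100.0 * out["count"] / total if total else 0.0
    parent_counts = out["parent"].map(by_name)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["percent_of_parent"] = np.where(
            parent_counts.to_numpy() > 0,
            100.0 * out["count"].to_numpy() / parent_counts.to_numpy(),
            np.nan,
        )
    out["density_per_mm2"] = out["count"] / tissue_area_mm2
    return out


# ---------------------------------------------------------------------------
# distance to ECM and binned intensity testing
# ---------------------------------------------------------------------------

def distance_to_mask(cells: pd.DataFrame, mask: ECMMask) -> np.ndarray:
    """Distance (um) from each cell centroid to the nearest positive mask pixel.

    Distances are Euclidean to positive pixel centers; a centroid lying on
    a positive pixel is inside the matrix and gets distance 0. Sub-pixel
    mask geometry is ignored, bounding the error by pixel_size/sqrt(2).
    """
    if not mask.data.any():
        raise ValueError("ECM mask has no positive pixels")
    ps = mask.pixel_size
    rows, cols = np.nonzero(mask.data)
    centers = np.column_stack(((cols + 0.5) * ps, (rows + 0.5) * ps))
    pts = cells[[X_COL, Y_COL]].to_numpy(dtype=float)
    dist, _ = cKDTree(centers).query(pts)
    ci = np.floor(pts[:, 0] / ps).astype(int)
    ri = np.floor(pts[:, 1] / ps).astype(int)
    inbounds = (
        (ri >= 0) & (ri < mask.data.shape[0]) & (ci >= 0) & (ci < mask.data.shape[1])
    )
    inside = np.zeros(len(pts), dtype=bool)
    inside[inbounds] = mask.data[ri[inbounds], ci[inbounds]]
    dist[inside] = 0.0
    return dist


def bin_and_test(
    intensities: np.ndarray | pd.Series,
    distances: np.ndarray,
    *,
    marker: str = "",
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    n_tests: int = 1,
    alpha: float = 0.001,
) -> DistanceBinResult:
    """One-way ANOVA of marker intensity across distance-to-ECM bins.

    Cells fall into half-open bins [0,25), [25,50), [50,75) um by default;
    cells beyond the last edge are excluded. The ANOVA p-value is
    Bonferroni-adjusted by ``n_tests`` (the number of marker x sample tests
    in the invocation) and capped at 1; significance requires adjusted
    p < ``alpha``. With fewer than two bins holding at least two cells the
    result is marked untestable.
    """
    x = np.asarray(intensities, dtype=float)
    d = np.asarray(distances, dtype=float)
    if x.shape != d.shape:
        raise ValueError("intensities and distances must align")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    edges = list(bin_edges)
    groups, counts, means = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        g = x[sel]
        counts.append(int(sel.sum()))
        means.append(float(g.mean()) if len(g) else float("nan"))
        if len(g) >= 2:
            groups.append(g)
    if len(groups) < 2:
        return DistanceBinResult(
            marker=marker,
            bin_edges=tuple(edges),
            bin_counts=tuple(counts),
            bin_means=tuple(means),
            f_stat=float("nan"),
            p_value=float("nan"),
            p_adjusted=float("nan"),
            significant=False,
            testable=False,
        )
    f, p = stats.f_oneway(*groups)
    p_adj = min(float(p) * n_tests, 1.0)
    return DistanceBinResult(
        marker=marker,
        bin_edges=tuple(edges),
        bin_counts=tuple(counts),
        bin_means=tuple(means),
        f_stat=float(f),
        p_value=float(p),
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        testable=True,
    )


def distance_bin_analysis(
    cells: pd.DataFrame,
    distances: np.ndarray,
    markers: Sequence[str],
    *,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    alpha: float = 0.001,
) -> list[DistanceBinResult]:
    """Run the binned ANOVA per marker with a shared Bonferroni family.

    The correction family is all tests in this invocation (one per marker
    here; callers testing several samples should concatenate first).
    """
    n_tests = len(markers)
    return [
        bin_and_test(
            cells[m],
            distances,
            marker=m,
            bin_edges=bin_edges,
            n_tests=n_tests,
            alpha=alpha,
        )
        for m in markers
    ]
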