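"""Regulon-based transcriptional-regulator activity scoring.

A regulon is a transcriptional regulator together with the signed set of
genes whose expression it controls, taken from a literature-derived
network restricted to expression-control edges. Regulator activity in one
sample is inferred from positional shifts of the regulon's targets within
a rank-sorted gene signature (the sample's per-gene deviation from the
cohort median): an active regulator pushes its positively controlled
targets up and its repressed targets down.

Three complementary enrichment components are computed per regulator and
combined:

* **local delta concordance** — Spearman concordance between edge-weight
  magnitude and the directional rank of each target within the regulon,
  evaluated separately for positive and negative edges and averaged, so a
  regulon dominated by one edge sign still contributes;
* **local enrichment** — weighted median of directional quantile positions
  of the targets within the regulon-restricted ranking, with each target's
  quantile weighted by its edge-weight magnitude;
* **global enrichment** — median directional quantile of the targets within
  the full ranked feature space.

Each component is centered so the no-activity expectation is 0 and scaled
to [-1, 1]; the integrated score is the mean of median/MAD-standardized
components across regulators. Edge weights combine an F-test for linear
dependency with the Spearman rank correlation of each regulator-target
pair as w = rho * (1 - p_F), which is sign-preserving and monotone in both
evidence sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulonNetwork",
    "parse_sif",
    "build_regulon_network",
    "expand_secondary",
    "assign_edge_weights",
    "compute_signature",
    "local_delta_concordance",
    "local_enrichment",
    "global_enrichment",
    "score_regulators",
    "integrate_scores",
    "activity_delta",
]

EXPRESSION_RELATION = "controls-expression-of"
COMPONENT_COLUMNS = ("local_delta_concordance", "local_enrichment", "global_enrichment")


@dataclass(frozen=True)
class RegulonNetwork:
    """Signed regulator->target expression-control edges.

    ``edges`` has columns (regulator, target, sign) with sign in {+1, -1}.
    """

    edges: pd.DataFrame

    def __post_init__(self):
        req = {"regulator", "target", "sign"}
        if not req <= set(self.edges.columns):
            raise ValueError(f"network edges need columns {sorted(req)}")
        if len(self.edges) == 0:
            raise ValueError("empty regulon network")
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-loops are not expression-control edges")
        if not self.edges["sign"].isin([1, -1]).all():
            raise ValueError("edge signs must be +1 or -1")
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            raise ValueError(
                "a regulator's positive and negative target sets must be disjoint "
                "(duplicate regulator-target pairs found)"
            )

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def targets_of(self, regulator: str) -> pd.DataFrame:
        return self.edges.loc[self.edges["regulator"] == regulator]


def parse_sif(lines: Iterable[str]) -> pd.DataFrame:
    """Parse SIF text into (source, relation, target[, sign]) rows.

    Whitespace-delimited, three required columns plus an optional numeric
    sign column. Malformed lines raise with their 1-based line number.
    """
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(
                f"SIF parse error at line {lineno}: expected 3 or 4 columns, "
                f"got {len(parts)}: {line!r}"
            )
        sign = None
        if len(parts) == 4:
            try:
                sign = int(float(parts[3]))
            except ValueError as exc:
                raise ValueError(
                    f"SIF parse error at line {lineno}: bad sign {parts[3]!r}"
                ) from exc
            if sign not in (1, -1):
                raise ValueError(
                    f"SIF parse error at line {lineno}: sign must be +1/-1, got {sign}"
                )
        rows.append((parts[0], parts[1], parts[2], sign))
    return pd.DataFrame(rows, columns=["source", "relation", "target", "sign"])


def build_regulon_network(
    sif: pd.DataFrame, expressed_genes: Iterable[str]
) -> RegulonNetwork:
    """Restrict a SIF table to expression-control edges over measured genes.

    Keeps only ``controls-expression-of`` edges whose regulator and target
    both appear in ``expressed_genes``. Edges without a sign annotation
    default to +1 (activation), with a logged warning.
    """
    expressed = set(expressed_genes)
    sub = sif.loc[sif["relation"] == EXPRESSION_RELATION].copy()
    sub = sub.loc[sub["source"].isin(expressed) & sub["target"].isin(expressed)]
    if len(sub) == 0:
        raise ValueError(
            "no expression-control edges remain after restricting to measured genes"
        )
    if sub["sign"].isna().any():
        warnings.warn(
            f"{int(sub['sign'].isna().sum())} edge(s) lack a sign; defaulting to +1",
            stacklevel=2,
        )
    sub["sign"] = pd.to_numeric(sub["sign"]).fillna(1)
    edges = sub.rename(columns={"source": "regulator"})[["regulator", "target", "sign"]]
    edges["sign"] = edges["sign"].astype(int)
    edges = edges.drop_duplicates(subset=["regulator", "target"]).reset_index(drop=True)
    return RegulonNetwork(edges=edges)


def expand_secondary(network: RegulonNetwork) -> RegulonNetwork:
    """Add secondary (two-step) regulatory interactions as direct edges.

    For edges R->X and X->T, a composite edge R->T with the sign product is
    added unless a direct R->T edge already exists. Composites whose sign
    is ambiguous (reachable with both signs) are dropped. Depth is limited
    to two steps.
    """
    edges = network.edges
    direct = {(r, t) for r, t in zip(edges["regulator"], edges["target"])}
    by_reg: dict[str, list[tuple[str, int]]] = {}
    for r, t, s in edges.itertuples(index=False):
        by_reg.setdefault(r, []).append((t, s))
    composite: dict[tuple[str, str], set[int]] = {}
    for r, mids in by_reg.items():
        for x, s1 in mids:
            for t, s2 in by_reg.get(x, []):
                if t == r or (r, t) in direct:
                    continue
                composite.setdefault((r, t), set()).add(s1 * s2)
    rows = [
        {"regulator": r, "target": t, "sign": next(iter(signs))}
        for (r, t), signs in composite.items()
        if len(signs) == 1
    ]
    if not rows:
        return network
    out = pd.concat([edges, pd.DataFrame(rows)], ignore_index=True)
    return RegulonNetwork(edges=out)


# ---------------------------------------------------------------------------
# edge weights
# ---------------------------------------------------------------------------

def assign_edge_weights(network: RegulonNetwork, expression: pd.DataFrame) -> pd.DataFrame:
    """Weight each regulator-target edge from the expression matrix.

    Per edge: rho is the Spearman correlation between regulator and target
    expression across samples; the F statistic comes from the univariate
    linear regression of target on regulator (F = t^2 on the slope); the
    combined weight is rho * (1 - p_F). Constant regulator or target
    vectors leave the statistics undefined and the weight 0. Edges whose
    regulator or target is missing from the matrix are dropped with a
    warning.

    Expression is genes x samples; at least 4 samples are required.
    """
    n = expression.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples to define Spearman/F statistics")
    genes = set(expression.index)
    edges = network.edges
    present = edges["regulator"].isin(genes) & edges["target"].isin(genes)
    if not present.all():
        warnings.warn(
            f"{int((~present).sum())} edge(s) with genes absent from the "
            "expression matrix were dropped",
            stacklevel=2,
        )
    edges = edges.loc[present].reset_index(drop=True)
    if len(edges) == 0:
        raise ValueError("no edges left after matching the expression matrix")

    x = expression.to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(xc, axis=1)
    rnorm = np.linalg.norm(rc, axis=1)
    pos = {g: i for i, g in enumerate(expression.index)}

    ri = edges["regulator"].map(pos).to_numpy()
    ti = edges["target"].map(pos).to_numpy()
    denom_p = xnorm[ri] * xnorm[ti]
    denom_s = rnorm[ri] * rnorm[ti]
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.einsum("ij,ij->i", xc[ri], xc[ti]) / denom_p
        rho = np.einsum("ij,ij->i", rc[ri], rc[ti]) / denom_s
    defined = (denom_p > 0) & (denom_s > 0)
    pearson = np.where(defined, np.clip(pearson, -1.0, 1.0), np.nan)
    rho = np.where(defined, np.clip(rho, -1.0, 1.0), np.nan)
    r2 = pearson**2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(r2 < 1.0, r2 * (n - 2) / (1.0 - r2), np.inf)
    p_f = stats.f.sf(f_stat, 1, n - 2)
    p_f = np.where(np.isinf(f_stat), 0.0, p_f)
    weight = np.where(defined, np.nan_to_num(rho) * (1.0 - np.nan_to_num(p_f, nan=1.0)), 0.0)

    out = edges.copy()
    out["rho"] = np.where(defined, rho, 0.0)
    out["f_stat"] = np.where(defined, f_stat, 0.0)
    out["p_f"] = np.where(defined, p_f, 1.0)
    out["weight"] = weight
    return out


# ---------------------------------------------------------------------------
# signatures and enrichment components
# ---------------------------------------------------------------------------

def compute_signature(expression: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Per-gene deviation of one sample from the cohort median, rank-sorted.

    score_g = expr_g(sample) - median_g over all cohort samples; ranks run
    1..m in descending score order with ties averaged.
    """
    if sample_id not in expression.columns:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 cohort samples for a median reference")
    score = expression[sample_id] - expression.median(axis=1)
    rank = score.rank(ascending=False, method="average")
    out = pd.DataFrame({"score": score, "rank": rank})
    out.index.name = "gene"
    return out


def _winsorized_ascending_ranks(scores: np.ndarray) -> np.ndarray:
    """Ranks (ascending, ties averaged) after 3-MAD winsorization.

    The robust quantile transform clips scores at median +/- 3 scaled MADs
    before ranking, so extreme outliers tie at the clip boundary instead of
    stretching the tail.
    """
    med = np.median(scores)
    mad = stats.median_abs_deviation(scores, scale="normal")
    if mad > 0:
        scores = np.clip(scores, med - 3 * mad, med + 3 * mad)
    return stats.rankdata(scores)


def _directional_quantiles(scores: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Quantile position of each target, oriented by edge sign.

    Ascending rank r over the given scores maps to q = r/(m+1); a positive
    edge supports activity when its target is highly expressed (q near 1),
    a negative edge when its target is repressed (1-q near 1).
    """
    m = len(scores)
    r = _winsorized_ascending_ranks(scores)
    q = r / (m + 1.0)
    return np.where(signs > 0, q, 1.0 - q)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    if np.all(weights <= 0):
        weights = np.ones_like(values)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half))
    idx = min(idx, len(v) - 1)
    if idx + 1 < len(v) and np.isclose(cum[idx], half):
        # mass splits exactly at this value: take the midpoint, so the
        # equal-weight case reduces to the ordinary sample median
        return float(0.5 * (v[idx] + v[idx + 1]))
    return float(v[idx])


def _regulon_frame(weights: pd.DataFrame, signature: pd.DataFrame, regulator: str):
    sub = weights.loc[weights["regulator"] == regulator]
    sub = sub.loc[sub["target"].isin(signature.index)]
    if len(sub) == 0:
        return None
    scores = signature.loc[sub["target"], "score"].to_numpy(dtype=float)
    return sub, scores


def local_delta_concordance(
    weights: pd.DataFrame, signature: pd.DataFrame, regulator: str
) -> float:
    """Concordance of edge-weight magnitude with directional target rank.

    Within the regulon, positive-edge targets are ranked from lowest to
    highest signature score and negative-edge targets in the reverse
    direction; the component is the Spearman correlation between |weight|
    and that directional rank, computed per edge-sign group and averaged
    over the groups that have at least two informative edges. Returns NaN
    when no group is scorable.
    """
    frame = _regulon_frame(weights, signature, regulator)
    if frame is None:
        return float("nan")
    sub, scores = frame
    vals = []
    for sign in (1, -1):
        grp = sub["sign"].to_numpy() == sign
        if grp.sum() < 2:
            continue
        s = scores[grp] if sign == 1 else -scores[grp]
        w = np.abs(sub["weight"].to_numpy()[grp])
        if np.ptp(s) == 0 or np.ptp(w) == 0:
            continue
        rho = stats.spearmanr(w, stats.rankdata(s)).statistic
        if np.isfinite(rho):
            vals.append(rho)
    return float(np.mean(vals)) if vals else float("nan")


def local_enrichment(
    weights: pd.DataFrame, signature: pd.DataFrame, regulator: str
) -> float:
    """Weight-integrated directional enrichment in the local feature space.

    The local ranked signature is the signature restricted to the genes the
    weighted network covers (every target of any edge); the regulon's
    targets are robust-quantile-transformed within that local ranking,
    oriented by edge sign, and summarized by the |weight|-weighted median
    quantile, centered and scaled to [-1, 1]. A fully activated regulon
    whose targets sit at the consistent extremes of the local ranking
    approaches +1, a repressed one -1, uniform spread ~0.
    """
    frame = _regulon_frame(weights, signature, regulator)
    if frame is None:
        return float("nan")
    sub, _ = frame
    local_genes = signature.index.intersection(pd.unique(weights["target"]))
    local_scores = signature.loc[local_genes, "score"].to_numpy(dtype=float)
    local_q = pd.Series(
        _winsorized_ascending_ranks(local_scores) / (len(local_scores) + 1.0),
        index=local_genes,
    )
    q = local_q.loc[sub["target"]].to_numpy()
    q = np.where(sub["sign"].to_numpy() > 0, q, 1.0 - q)
    med = _weighted_median(q, np.abs(sub["weight"].to_numpy(dtype=float)))
    return float((med - 0.5) * 2.0)


def global_enrichment(
    weights: pd.DataFrame, signature: pd.DataFrame, regulator: str
) -> float:
    """Directional enrichment of the regulon within the full feature space.

    All genes are robust-quantile-transformed by signature score; the
    component is the median directional quantile of the regulon's targets,
    centered and scaled to [-1, 1].
    """
    frame = _regulon_frame(weights, signature, regulator)
    if frame is None:
        return float("nan")
    sub, _ = frame
    all_scores = signature["score"].to_numpy(dtype=float)
    m = len(all_scores)
    global_q = pd.Series(
        _winsorized_ascending_ranks(all_scores) / (m + 1.0), index=signature.index
    )
    q = global_q.loc[sub["target"]].to_numpy()
    q = np.where(sub["sign"].to_numpy() > 0, q, 1.0 - q)
    return float((np.median(q) - 0.5) * 2.0)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_scores(components: pd.DataFrame) -> pd.DataFrame:
    """Standardize the three components across regulators and average them.

    Each component column is centered by its median and scaled by its
    normal-consistent MAD across regulators (a zero MAD yields zeros); the
    integrated score is the mean of the available standardized components,
    and regulators are ranked by it in descending order.
    """
    if len(components) == 0:
        raise ValueError("no regulators to integrate")
    std = pd.DataFrame(index=components.index)
    for col in COMPONENT_COLUMNS:
        if col not in components.columns:
            continue
        x = components[col]
        med = x.median()
        mad = stats.median_abs_deviation(x.dropna(), scale="normal") if x.notna().any() else 0.0
        std[col] = (x - med) / mad if mad > 0 else 0.0 * x
    out = components.copy()
    out["integrated"] = std.mean(axis=1, skipna=True)
    out = out.sort_values("integrated", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_regulators(
    network: RegulonNetwork,
    expression: pd.DataFrame,
    sample_id: str,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full regulator-activity scoring of one sample.

    Computes edge weights (unless supplied), the median-reference gene
    signature of ``sample_id``, the three enrichment components per
    regulator, and the integrated score. Regulators with no component
    defined are dropped.
    """
    if weights is None:
        weights = assign_edge_weights(network, expression)
    signature = compute_signature(expression, sample_id)
    rows = {}
    for reg in network.regulators:
        rows[reg] = {
            "local_delta_concordance": local_delta_concordance(weights, signature, reg),
            "local_enrichment": local_enrichment(weights, signature, reg),
            "global_enrichment": global_enrichment(weights, signature, reg),
        }
    comp = pd.DataFrame.from_dict(rows, orient="index")
    comp.index.name = "regulator"
    comp = comp.dropna(how="all")
    if len(comp) == 0:
        raise ValueError("no regulator has a defined component")
    return integrate_scores(comp)


def activity_delta(scores_t1: pd.DataFrame, scores_t2: pd.DataFrame) -> pd.DataFrame:
    """Per-regulator change in integrated activity between two timepoints.

    Reports difference (t2 - t1) and ratio (t2 / t1, NaN at zero
    denominator), ranked by absolute difference.
    """
    shared = scores_t1.index.intersection(scores_t2.index)
    if len(shared) == 0:
        raise ValueError("regulator sets are disjoint")
    a = scores_t1.loc[shared, "integrated"]
    b = scores_t2.loc[shared, "integrated"]
    out = pd.DataFrame(
        {
            "integrated_t1": a,
            "integrated_t2": b,
            "difference": b - a,
            "ratio": b / a.replace(0.0, np.nan),
        }
    )
    out.index.name = "regulator"
    return out.sort_values("difference", key=lambda s: s.abs(), ascending=False)
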