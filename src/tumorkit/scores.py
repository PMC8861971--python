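"""Closed-form scoring utilities.

Reverse-phase protein array (RPPA) pathway scores, cohort z-scores against
the median, PAM50 intrinsic-subtype assignment by Spearman correlation to
published centroids, tumor mutational burden (TMB), and neoepitope
filtering/intersection over MHC binding affinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayDefinition",
    "Pam50Result",
    "PAM50_SUBTYPES",
    "pathway_score",
    "cohort_zscore",
    "pam50_assign",
    "tmb",
    "filter_neoepitopes",
    "shared_neoepitopes",
]

#: fixed subtype order; also the deterministic tie-break priority
PAM50_SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")


@dataclass(frozen=True)
class PathwayDefinition:
    """Signed protein predictor lists defining one pathway score."""

    name: str
    positive_predictors: tuple[str, ...]
    negative_predictors: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "positive_predictors", tuple(self.positive_predictors))
        object.__setattr__(self, "negative_predictors", tuple(self.negative_predictors))
        pos, neg = set(self.positive_predictors), set(self.negative_predictors)
        if pos & neg:
            raise ValueError(f"predictors on both sides: {sorted(pos & neg)}")
        if not pos | neg:
            raise ValueError("pathway needs at least one predictor")


@dataclass(frozen=True)
class Pam50Result:
    subtype: str
    correlations: pd.Series
    negative_best: bool  # best correlation is negative: assignment is weak


def pathway_score(
    sample_values: Mapping[str, float] | pd.Series, definition: PathwayDefinition
) -> float:
    """RPPA pathway score: (sum positives - sum negatives) / n predictors.

    Predictors missing from the sample are excluded with a warning and the
    denominator shrinks accordingly; a pathway with no usable predictor is
    an error.
    """
    values = pd.Series(sample_values)
    pos = [p for p in definition.positive_predictors if p in values.index]
    neg = [p for p in definition.negative_predictors if p in values.index]
    missing = (set(definition.positive_predictors) | set(definition.negative_predictors)) - set(
        values.index
    )
    if missing:
        warnings.warn(
            f"pathway {definition.name!r}: predictors missing from sample, "
            f"excluded: {sorted(missing)}",
            stacklevel=2,
        )
    n_used = len(pos) + len(neg)
    if n_used == 0:
        raise ValueError(f"pathway {definition.name!r}: no usable predictors")
    total = float(values[pos].sum() - values[neg].sum())
    return total / n_used


def cohort_zscore(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Median-centered z-scores per protein across a cohort.

    z = (x - cohort median) / cohort SD, row-wise over a proteins x samples
    matrix. Proteins with zero SD get z = 0 and a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for cohort z-scoring")
    med = matrix.median(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) have zero SD; z set to 0", stacklevel=2
        )
        sd = sd.replace(0.0, np.nan)
    z = matrix.sub(med, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def pam50_assign(
    sample_expr: pd.Series,
    centroids: pd.DataFrame,
    background_cohort: pd.DataFrame,
) -> Pam50Result:
    """Assign a PAM50 intrinsic subtype by Spearman correlation to centroids.

    The query sample is appended to the background cohort (e.g. 20 ER+ and
    20 ER- tumors), the combined matrix is mean-centered per gene, and the
    centered query profile is Spearman-correlated with each subtype
    centroid over the shared gene set. The subtype with the highest
    correlation wins; exact ties resolve by the fixed subtype order. A
    best correlation that is negative is flagged rather than suppressed.
    """
    if background_cohort.shape[1] < 1:
        raise ValueError("background cohort must contain at least one sample")
    genes = centroids.index.intersection(sample_expr.index).intersection(
        background_cohort.index
    )
    if len(genes) < 10:
        raise ValueError(
            f"only {len(genes)} genes overlap the centroid table; need >= 10"
        )
    combined = background_cohort.loc[genes].copy()
    combined["_query_"] = sample_expr.loc[genes]
    centered = combined.sub(combined.mean(axis=1), axis=0)
    query = centered["_query_"]
    cors = {}
    for subtype in centroids.columns:
        cors[subtype] = float(stats.spearmanr(query, centroids.loc[genes, subtype]).statistic)
    cor_series = pd.Series(cors)
    order = [s for s in PAM50_SUBTYPES if s in cor_series.index] + [
        s for s in cor_series.index if s not in PAM50_SUBTYPES
    ]
    cor_series = cor_series[order]
    best = cor_series.idxmax()  # first occurrence wins ties -> fixed order
    return Pam50Result(
        subtype=str(best), correlations=cor_series, negative_best=cor_series[best] < 0
    )


def tmb(n_nonsynonymous: int, target_size_mb: float) -> float:
    """Tumor mutational burden: nonsynonymous mutations per targeted megabase."""
    if target_size_mb <= 0:
        raise ValueError("target region size must be positive")
    if n_nonsynonymous < 0:
        raise ValueError("mutation count must be >= 0")
    return n_nonsynonymous / target_size_mb


def filter_neoepitopes(records: pd.DataFrame, threshold_nm: float = 500.0) -> pd.DataFrame:
    """Keep neoepitopes binding at least one allele below the affinity cutoff.

    ``records`` is long-form with columns (peptide, allele, affinity_nm)
    plus any extra annotation; a peptide is retained iff its minimum
    affinity across alleles is strictly below ``threshold_nm``. All rows of
    retained peptides pass through.
    """
    req = {"peptide", "affinity_nm"}
    if not req <= set(records.columns):
        raise ValueError(f"neoepitope table needs columns {sorted(req)}")
    if len(records) == 0:
        return records
    if (records["affinity_nm"] <= 0).any():
        raise ValueError("binding affinities must be positive (nM)")
    best = records.groupby("peptide")["affinity_nm"].min()
    keep = set(best.index[best < threshold_nm])
    return records.loc[records["peptide"].isin(keep)]


def shared_neoepitopes(records: pd.DataFrame, sample_set: Sequence[str]) -> pd.DataFrame:
    """Neoepitopes present in every sample of ``sample_set``.

    Presence is encoded by boolean ``present_<sample>`` columns (or bare
    sample-named columns); a peptide is shared when some row marks it
    present in each sample. Returns all rows for the shared peptides.
    """
    if len(records) == 0:
        return records
    cols = []
    for s in sample_set:
        for cand in (f"present_{s}", s):
            if cand in records.columns:
                cols.append(cand)
                break
        else:
            raise ValueError(f"no presence column for sample {s!r}")
    presence = records.groupby("peptide")[cols].any()
    shared = set(presence.index[presence.all(axis=1)])
    return records.loc[records["peptide"].isin(shared)]
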