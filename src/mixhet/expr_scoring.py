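"""Single-sample gene-set scoring, centroid subtyping, regulon activity, DE filtering.

The single-sample enrichment score is a rank-weighted area statistic: genes
are ranked by decreasing expression (rank r = 1..G, ties broken by gene id),
each in-set gene at rank r carries weight (G - r + 1)**alpha, and the score is
the summed gap between the normalized in-set and out-of-set cumulative walks,

    score = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{set genes at rank <= i} w_r / sum_{all set genes} w_r,
    P_out(i) = #{non-set genes at rank <= i} / (G - m).

Positive scores mean the set is concentrated at the top of the ranking.
``alpha`` defaults to 0.25; at alpha = 0 the score depends on ranks only and
is invariant under any strictly monotone transform of the values.

Nearest-centroid subtype assignment uses correlation-based distance
(1 - Pearson r) against per-subtype mean profiles built from the top genes of
a shrunken one-vs-rest t statistic. Regulon activity is the two-tailed score:
enrichment of the positive targets minus enrichment of the negative targets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "EnrichmentScore",
    "CentroidSet",
    "Regulon",
    "ssgsea_score",
    "ssgsea_matrix",
    "build_centroids",
    "classify_nearest_centroid",
    "regulon_activity",
    "de_filter",
]


@dataclass(frozen=True)
class EnrichmentScore:
    value: float
    gene_set: str
    sample_id: str
    alpha: float


@dataclass(frozen=True)
class CentroidSet:
    """Per-subtype centroids over a shared gene panel.

    ``centroids`` is a panel-genes x subtypes DataFrame; ``selected`` records
    the per-class top genes that formed the panel (their union).
    """

    centroids: pd.DataFrame
    selected: dict[str, tuple[str, ...]]

    @property
    def panel(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def labels(self) -> list[str]:
        return list(self.centroids.columns)


@dataclass(frozen=True)
class Regulon:
    """A regulator's induced (positive) and repressed (negative) target sets."""

    regulator: str
    positive_targets: GeneSet
    negative_targets: GeneSet

    def __post_init__(self) -> None:
        if set(self.positive_targets.genes) & set(self.negative_targets.genes):
            raise ValueError(
                f"regulon {self.regulator}: positive and negative targets overlap"
            )


def _as_series(sample_values: Mapping[str, float] | pd.Series) -> pd.Series:
    s = sample_values if isinstance(sample_values, pd.Series) else pd.Series(sample_values)
    if s.index.has_duplicates:
        raise ValueError("tied gene ids in expression profile")
    return s.astype(float)


def ssgsea_score(
    sample_values: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    alpha: float = 0.25,
    sample_id: str = "",
) -> EnrichmentScore:
    """Rank-weighted single-sample enrichment score of one gene set."""
    s = _as_series(sample_values)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    genes = np.array(order)
    G = genes.size
    in_set = np.isin(genes, list(gene_set.genes))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError(f"empty effective set: no member of {gene_set.name!r} in profile")
    ranks = np.arange(1, G + 1)
    weights = (G - ranks + 1).astype(float) ** alpha
    denom_in = weights[in_set].sum()
    incr_in = np.where(in_set, weights / denom_in, 0.0)
    if G > m:
        incr_out = np.where(in_set, 0.0, 1.0 / (G - m))
    else:
        incr_out = np.zeros(G)
    running = np.cumsum(incr_in) - np.cumsum(incr_out)
    return EnrichmentScore(
        value=float(running.sum()),
        gene_set=gene_set.name,
        sample_id=sample_id,
        alpha=alpha,
    )


def ssgsea_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    collection: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Enrichment score for every (set, sample); sets x samples DataFrame.

    Sets with no member in the matrix are dropped with a warning. With
    ``normalize`` every score is divided by the global max - min; when raw
    scores span zero this bounds them in [-1, 1].
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    usable: list[GeneSet] = []
    for gs in collection:
        if any(g in data.index for g in gs.genes):
            usable.append(gs)
        else:
            warnings.warn(f"dropping gene set {gs.name!r}: no overlap with matrix",
                          stacklevel=2)
    if not usable:
        raise ValueError("no gene set overlaps the expression matrix")
    out = pd.DataFrame(
        index=[gs.name for gs in usable], columns=data.columns, dtype=float
    )
    for sample in data.columns:
        profile = data[sample]
        for gs in usable:
            out.loc[gs.name, sample] = ssgsea_score(
                profile, gs, alpha=alpha, sample_id=sample
            ).value
    if normalize:
        span = out.values.max() - out.values.min()
        if span > 0:
            out = out / span
    return out


def build_centroids(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    genes_per_class: int = 500,
) -> CentroidSet:
    """Per-class centroids from the top genes of a shrunken one-vs-rest t.

    For each class, genes are ranked by |t_g| with
    t_g = (mean_in - mean_out) / (pooled SD + s0) and s0 the median pooled SD
    across genes; the top ``genes_per_class`` per class are pooled into the
    panel, and each centroid is the within-class mean over that panel.
    Ties in |t_g| break lexicographically on gene id.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    lab = pd.Series(labels).reindex(data.columns)
    if lab.isna().any():
        raise ValueError("every sample needs a class label")
    classes = sorted(lab.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if genes_per_class <= 0:
        raise ValueError("genes_per_class must be positive")
    if genes_per_class > data.shape[0]:
        raise ValueError("genes_per_class exceeds gene count")
    counts = lab.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"class {small.index[0]!r} has fewer than 2 samples")

    values = data.to_numpy(dtype=float)
    genes = np.array(data.index)
    selected: dict[str, tuple[str, ...]] = {}
    for cls in classes:
        in_mask = (lab == cls).to_numpy()
        x_in = values[:, in_mask]
        x_out = values[:, ~in_mask]
        n_in, n_out = x_in.shape[1], x_out.shape[1]
        mean_diff = x_in.mean(axis=1) - x_out.mean(axis=1)
        var_in = x_in.var(axis=1, ddof=1)
        var_out = x_out.var(axis=1, ddof=1) if n_out >= 2 else np.zeros_like(var_in)
        dof = n_in + n_out - 2
        pooled_sd = np.sqrt(((n_in - 1) * var_in + max(n_out - 1, 0) * var_out) / dof)
        s0 = float(np.median(pooled_sd))
        denom = pooled_sd + s0
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, mean_diff / denom, 0.0)
        order = sorted(range(len(genes)), key=lambda i: (-abs(t[i]), genes[i]))
        selected[str(cls)] = tuple(genes[i] for i in order[:genes_per_class])

    panel = sorted(set().union(*selected.values()))
    centroids = pd.DataFrame(index=panel, columns=[str(c) for c in classes], dtype=float)
    sub = data.loc[panel]
    for cls in classes:
        centroids[str(cls)] = sub.loc[:, (lab == cls).to_numpy()].mean(axis=1)
    return CentroidSet(centroids=centroids, selected=selected)


def classify_nearest_centroid(
    sample: Mapping[str, float] | pd.Series,
    centroids: CentroidSet,
) -> tuple[str, dict[str, float]]:
    """Assign a sample to the subtype with minimal 1 - Pearson correlation.

    The sample is silently intersected with the centroid panel (errors only
    below 2 shared genes); labels tie-break lexicographically. Distances for
    every subtype are returned for audit.
    """
    s = _as_series(sample)
    shared = [g for g in centroids.panel if g in s.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 panel genes present in sample")
    x = s[shared].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("degenerate profile: zero variance over centroid panel")
    distances: dict[str, float] = {}
    for label in centroids.labels:
        c = centroids.centroids.loc[shared, label].to_numpy(dtype=float)
        if np.std(c) == 0:
            distances[label] = 1.0  # uncorrelated convention for flat centroid
            continue
        r = float(np.corrcoef(x, c)[0, 1])
        distances[label] = 1.0 - r
    best = min(distances, key=lambda lbl: (distances[lbl], lbl))
    return best, distances


def regulon_activity(
    sample_values: Mapping[str, float] | pd.Series,
    regulon: Regulon,
    alpha: float = 0.25,
) -> float:
    """Two-tailed regulon activity: score(positive) - score(negative).

    Positive activity means the induced targets sit higher in the ranking
    than the repressed targets; samples split into positive / negative
    activity groups by the sign.
    """
    pos = ssgsea_score(sample_values, regulon.positive_targets, alpha=alpha)
    neg = ssgsea_score(sample_values, regulon.negative_targets, alpha=alpha)
    return pos.value - neg.value


def de_filter(
    de_table: pd.DataFrame,
    log2fc_cut: float = 1.0,
    fdr_cut: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Threshold a differential-expression table into up/down gene lists.

    Cuts are strict: up requires log2fc > cut, down log2fc < -cut, both with
    fdr < fdr_cut, so a gene at exactly the fold-change boundary is excluded.
    """
    for col in ("gene", "log2fc", "fdr"):
        if col not in de_table.columns:
            raise ValueError(f"DE table is missing column {col!r}")
    fc = de_table["log2fc"].astype(float)
    fdr = de_table["fdr"].astype(float)
    up = de_table.loc[(fc > log2fc_cut) & (fdr < fdr_cut), "gene"].tolist()
    down = de_table.loc[(fc < -log2fc_cut) & (fdr < fdr_cut), "gene"].tolist()
    return up, down
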