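"""Regulatory-region annotation and factor/mark overlap classification.

Window rules (strand-oriented, applied to the peak anchor = summit if present,
else the interval midpoint):

* promoter   — anchor within TSS +/- 2,000 bp of any gene;
* enhancer   — anchor within the span from 50,000 bp upstream of the TSS to
  5,000 bp downstream of the TES (for - strand genes "upstream" extends to
  higher coordinates);
* intergenic — everything else.

The promoter window lies inside the enhancer span, so promoter takes
precedence; the three categories partition any peak set. Factor/mark overlap
is measured edge-to-edge: a histone-mark region counts as "overlapping" when
any factor peak lies within ``max_gap_bp`` (gap 0 for touching or overlapping
intervals); unmatched marks are mark_only, unmatched factor peaks factor_only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel, Peak, index_by_chrom

__all__ = [
    "AnnotatedPeak",
    "OverlapClass",
    "annotate_interval",
    "annotate_peaks",
    "classify_overlap",
    "filter_near_tss",
    "kmeans_cluster_signal",
]

PROMOTER_BP = 2_000
UPSTREAM_BP = 50_000
DOWNSTREAM_BP = 5_000


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its regulatory category and nearest qualifying gene.

    ``distance_to_tss`` is signed in gene orientation (negative = upstream of
    the TSS); it is None exactly when the category is intergenic.
    """

    peak: Peak
    category: str
    assigned_gene: str | None
    distance_to_tss: int | None

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.assigned_gene is None):
            raise ValueError("intergenic iff no assigned gene")


@dataclass(frozen=True)
class OverlapClass:
    region_id: str
    cls: str  # factor_only | mark_only | overlapping


def _gene_windows(gene: GeneModel, promoter_bp: int, upstream_bp: int,
                  downstream_bp: int) -> tuple[int, int, int]:
    """(tss0, span_lo, span_hi): 0-based TSS and genomic enhancer span bounds."""
    tss0 = gene.tss - 1
    tes0 = gene.tes - 1
    if gene.strand == "+":
        span_lo, span_hi = tss0 - upstream_bp, tes0 + downstream_bp
    else:
        span_lo, span_hi = tes0 - downstream_bp, tss0 + upstream_bp
    return tss0, span_lo, span_hi


def annotate_interval(
    peak: Peak,
    gene_models: Sequence[GeneModel] | dict[str, list[GeneModel]],
    promoter_bp: int = PROMOTER_BP,
    upstream_bp: int = UPSTREAM_BP,
    downstream_bp: int = DOWNSTREAM_BP,
) -> AnnotatedPeak:
    """Annotate one peak as promoter / enhancer / intergenic.

    The assigned gene is the nearest-TSS gene among those qualifying at the
    awarded category (lexicographic gene-id tie-break). Peaks on chromosomes
    absent from the gene models are labeled intergenic with a warning.
    """
    index = gene_models if isinstance(gene_models, dict) else index_by_chrom(gene_models)
    genes = index.get(peak.chrom)
    if not genes:
        warnings.warn(
            f"peak chromosome {peak.chrom!r} absent from gene models; "
            "labeling intergenic",
            stacklevel=2,
        )
        return AnnotatedPeak(peak=peak, category="intergenic",
                             assigned_gene=None, distance_to_tss=None)
    pos = peak.midpoint
    promoter_hits: list[tuple[int, str, int]] = []  # (|d|, gene_id, signed d)
    enhancer_hits: list[tuple[int, str, int]] = []
    for gene in genes:
        tss0, span_lo, span_hi = _gene_windows(gene, promoter_bp, upstream_bp,
                                               downstream_bp)
        signed = pos - tss0 if gene.strand == "+" else tss0 - pos
        if abs(pos - tss0) <= promoter_bp:
            promoter_hits.append((abs(pos - tss0), gene.gene_id, signed))
        elif span_lo <= pos <= span_hi:
            enhancer_hits.append((abs(pos - tss0), gene.gene_id, signed))
    hits, category = (
        (promoter_hits, "promoter") if promoter_hits
        else (enhancer_hits, "enhancer") if enhancer_hits
        else ([], "intergenic")
    )
    if not hits:
        return AnnotatedPeak(peak=peak, category="intergenic",
                             assigned_gene=None, distance_to_tss=None)
    _, gene_id, signed = min(hits)
    return AnnotatedPeak(peak=peak, category=category,
                         assigned_gene=gene_id, distance_to_tss=signed)


def annotate_peaks(
    peaks: Iterable[Peak],
    gene_models: Sequence[GeneModel] | dict[str, list[GeneModel]],
    **window_kwargs,
) -> list[AnnotatedPeak]:
    index = gene_models if isinstance(gene_models, dict) else index_by_chrom(gene_models)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        return [annotate_interval(p, index, **window_kwargs) for p in peaks]


def classify_overlap(
    factor_peaks: Sequence[Peak],
    mark_regions: Sequence[Peak],
    max_gap_bp: int = 5_000,
) -> tuple[list[OverlapClass], dict[str, float]]:
    """Classify factor-binding peaks and mark regions by mutual proximity.

    Returns one record per merged region — an "overlapping" record per mark
    with a factor peak within ``max_gap_bp``, plus mark_only and factor_only
    records for the unmatched remainder — and the class proportions over the
    union count (they sum to 1).
    """
    if len(factor_peaks) == 0 and len(mark_regions) == 0:
        raise ValueError("both interval sets are empty")
    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(factor_peaks):
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, i)
    matched_factors: set[int] = set()
    records: list[OverlapClass] = []
    n_overlap = n_mark_only = 0
    for j, m in enumerate(mark_regions):
        tree = trees.get(m.chrom)
        # gap <= max_gap with edge-to-edge gaps; +/-1 converts the closed
        # condition into intervaltree's half-open overlap query
        hits = (tree.overlap(m.start - max_gap_bp - 1, m.end + max_gap_bp + 1)
                if tree else set())
        if hits:
            n_overlap += 1
            records.append(OverlapClass(region_id=f"mark:{j}", cls="overlapping"))
            matched_factors.update(iv.data for iv in hits)
        else:
            n_mark_only += 1
            records.append(OverlapClass(region_id=f"mark:{j}", cls="mark_only"))
    n_factor_only = 0
    for i in range(len(factor_peaks)):
        if i not in matched_factors:
            n_factor_only += 1
            records.append(OverlapClass(region_id=f"factor:{i}", cls="factor_only"))
    total = n_factor_only + n_mark_only + n_overlap
    proportions = {
        "factor_only": n_factor_only / total,
        "mark_only": n_mark_only / total,
        "overlapping": n_overlap / total,
    }
    return records, proportions


def filter_near_tss(
    regions: Sequence[Peak],
    gene_models: Sequence[GeneModel] | dict[str, list[GeneModel]],
    max_dist_bp: int = 10_000,
) -> list[Peak]:
    """Keep regions whose anchor lies within ``max_dist_bp`` of any TSS (unsigned)."""
    index = gene_models if isinstance(gene_models, dict) else index_by_chrom(gene_models)
    tss_by_chrom = {
        chrom: np.sort(np.array([g.tss - 1 for g in genes]))
        for chrom, genes in index.items()
    }
    kept = []
    for region in regions:
        tss = tss_by_chrom.get(region.chrom)
        if tss is None or tss.size == 0:
            continue
        pos = region.midpoint
        i = int(np.searchsorted(tss, pos))
        d = min(
            abs(pos - tss[i - 1]) if i > 0 else np.inf,
            abs(tss[i] - pos) if i < tss.size else np.inf,
        )
        if d <= max_dist_bp:
            kept.append(region)
    return kept


def kmeans_cluster_signal(
    signal_matrix: np.ndarray,
    k: int = 2,
    seed: int | None = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """Cluster region signal profiles with k-means (Lloyd + k-means++).

    Rows are regions, columns signal bins. The best of ``n_restarts``
    initializations (lowest within-cluster sum of squares) is kept, and
    labels are renumbered 1..k by decreasing cluster mean signal, so cluster
    1 always carries the highest signal. Deterministic under a fixed seed.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(signal_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("signal_matrix must be 2-D (regions x bins)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal_matrix must be finite")
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] < k:
        raise ValueError(f"fewer rows ({x.shape[0]}) than clusters ({k})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    raw = km.fit_predict(x)
    means = np.array([x[raw == c].mean() if (raw == c).any() else -np.inf
                      for c in range(k)])
    order = np.argsort(-means)  # cluster with highest mean first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]
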