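"""Seed-controlled generators for every input class the pipeline consumes.

Each generator is a bit-exact function of its configuration and seed and
returns the planted ground truth alongside the data, so every analysis stage
can be tested for recovery without any external download.

The paired-mutation generator is the generative twin of the clonality
likelihood: informative loci are drawn without replacement with weights
proportional to p_j * (2 - p_j) — the probability that at least one of two
independent tumors mutates locus j — and each selected locus is assigned
shared / private-A / private-B with the mixture probabilities
(xi + (1 - xi) q_sh, (1 - xi) q_a, (1 - xi) q_b). A separate null-pair
generator redraws per-tumor locus sets exactly the way the test's Monte-Carlo
null does (weighted without replacement, weights p_j), which keeps observed
and simulated likelihood-ratio statistics exchangeable in type-I studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clonality import ReferenceFrequencies
from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    Mutation,
    PatientPair,
    Peak,
    RegionProfile,
)

__all__ = [
    "PairSimConfig",
    "ExprSimConfig",
    "simulate_reference_frequencies",
    "simulate_pair",
    "simulate_null_pair",
    "simulate_expression",
    "simulate_regulatory_landscape",
]

_P_FLOOR = 1e-6
_P_CEIL = 0.5


@dataclass(frozen=True)
class PairSimConfig:
    """Conditions for one simulated tumor pair over a reference universe."""

    xi_true: float = 0.5
    n_events: int = 100
    universe_size: int = 10_000
    beta_a: float = 0.5
    beta_b: float = 50.0
    hotspot_fraction: float = 0.0
    hotspot_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi_true < 1.0:
            raise ValueError("xi_true must lie in [0, 1)")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.universe_size < self.n_events:
            raise ValueError("universe_size must be >= n_events")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class ExprSimConfig:
    """Conditions for a subtype-structured expression matrix.

    Defaults emulate a strongly subtype-separated cohort: 4 subtypes of 20
    samples, 50 signature genes each over a 2,000-gene background, a +3
    log-scale signature shift, and Gaussian noise of sd 0.5.
    """

    n_genes: int = 2_000
    n_samples: int = 80
    n_subtypes: int = 4
    signature_size: int = 50
    effect_shift: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes * self.signature_size > self.n_genes:
            raise ValueError("signatures exceed gene count")
        if self.n_subtypes < 2 or self.n_samples < 2 * self.n_subtypes:
            raise ValueError("need >= 2 subtypes with >= 2 samples each")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _locus_key(j: int) -> str:
    return f"{j % 22 + 1}:{j + 1}:A:C"


def _locus_mutation(key: str, gene: str = "", effect: str = "nonsynonymous") -> Mutation:
    chrom, pos, ref, alt = key.split(":")
    return Mutation(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                    gene=gene or f"G{pos}", effect=effect)


def simulate_reference_frequencies(
    universe_size: int = 10_000,
    beta_a: float = 0.5,
    beta_b: float = 50.0,
    hotspot_fraction: float = 0.0,
    hotspot_factor: float = 1.0,
    n_ref: int = 400,
    pseudocount: float = 0.5,
    seed: int | None = 0,
) -> ReferenceFrequencies:
    """Reference marginal frequencies drawn i.i.d. from a Beta model.

    The default Beta(0.5, 50), clipped to (1e-6, 0.5], mimics a long-tailed
    somatic hotspot spectrum without extreme frequencies. With a hotspot
    mixture, a fraction of loci has its frequency multiplied by
    ``hotspot_factor`` before clipping.
    """
    if universe_size < 2:
        raise ValueError("universe_size must be >= 2")
    if beta_a <= 0 or beta_b <= 0:
        raise ValueError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    p = rng.beta(beta_a, beta_b, size=universe_size)
    if hotspot_fraction > 0:
        n_hot = int(round(hotspot_fraction * universe_size))
        hot = rng.choice(universe_size, size=n_hot, replace=False)
        p[hot] *= hotspot_factor
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    keys = tuple(_locus_key(j) for j in range(universe_size))
    return ReferenceFrequencies(locus_keys=keys, probs=p, n_ref=n_ref,
                                pseudocount=pseudocount)


def _weighted_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    keys = rng.exponential(size=weights.size) / weights
    if k >= weights.size:
        return np.argsort(keys)[:k]
    return np.argpartition(keys, k)[:k]


def _profiles_from_keys(
    patient_id: str, keys_a: Sequence[str], keys_b: Sequence[str],
    covered_mb: float = 30.0,
) -> PatientPair:
    prof_a = RegionProfile(
        patient_id=patient_id, region_label="UC",
        mutations=tuple(_locus_mutation(k) for k in keys_a),
        covered_mb=covered_mb,
    )
    prof_b = RegionProfile(
        patient_id=patient_id, region_label="SqD",
        mutations=tuple(_locus_mutation(k) for k in keys_b),
        covered_mb=covered_mb,
    )
    return PatientPair(profile_a=prof_a, profile_b=prof_b)


def simulate_pair(
    ref: ReferenceFrequencies,
    xi_true: float,
    n_events: int,
    seed: int | None = 0,
    patient_id: str = "SIM",
    covered_mb: float = 30.0,
) -> tuple[PatientPair, dict[str, str]]:
    """Simulate one tumor pair under the conditional clonality model.

    Returns the pair and the per-locus ground-truth labels
    ({locus key: "shared" | "private_a" | "private_b"}).
    """
    if not 0.0 <= xi_true < 1.0:
        raise ValueError("xi_true must lie in [0, 1)")
    if n_events > len(ref):
        raise ValueError("n_events exceeds the reference universe")
    rng = np.random.default_rng(seed)
    p = ref.probs
    weights = p * (2.0 - p)
    chosen = _weighted_without_replacement(rng, weights, n_events)
    p_sel = p[chosen]
    q_sh = p_sel / (2.0 - p_sel)
    p_shared = xi_true + (1.0 - xi_true) * q_sh
    p_priv_a = (1.0 - xi_true) * (1.0 - p_sel) / (2.0 - p_sel)
    u = rng.random(n_events)
    labels = np.where(
        u < p_shared, "shared",
        np.where(u < p_shared + p_priv_a, "private_a", "private_b"),
    )
    keys = [ref.locus_keys[j] for j in chosen]
    truth = dict(zip(keys, labels.tolist()))
    keys_a = [k for k, lab in truth.items() if lab in ("shared", "private_a")]
    keys_b = [k for k, lab in truth.items() if lab in ("shared", "private_b")]
    pair = _profiles_from_keys(patient_id, keys_a, keys_b, covered_mb)
    return pair, truth


def simulate_null_pair(
    ref: ReferenceFrequencies,
    n_a: int,
    n_b: int,
    seed: int | None = 0,
    patient_id: str = "NULL",
    covered_mb: float = 30.0,
) -> PatientPair:
    """Two independent tumors with fixed per-region mutation counts.

    Each region's loci are a weighted sample without replacement (weights
    p_j) from the reference universe — the same conditional draw the
    clonality test's Monte-Carlo null performs.
    """
    if max(n_a, n_b) > len(ref):
        raise ValueError("per-region count exceeds the reference universe")
    rng = np.random.default_rng(seed)
    idx_a = _weighted_without_replacement(rng, ref.probs, n_a)
    idx_b = _weighted_without_replacement(rng, ref.probs, n_b)
    keys_a = [ref.locus_keys[j] for j in idx_a]
    keys_b = [ref.locus_keys[j] for j in idx_b]
    return _profiles_from_keys(patient_id, keys_a, keys_b, covered_mb)


def simulate_expression(
    config: ExprSimConfig | None = None,
) -> tuple[ExpressionMatrix, pd.Series, list[GeneSet]]:
    """Subtype-structured expression matrix with known labels and signatures.

    Baseline log-scale expression per gene ~ N(8, 1); each subtype's
    (disjoint) signature genes are shifted by ``effect_shift`` in that
    subtype's samples; Gaussian noise of sd ``noise_sd`` is added and values
    are floored at zero. Returns (matrix, truth labels, signature GeneSets).
    """
    cfg = config or ExprSimConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    subtype_of = pd.Series(
        [f"SUB{i % cfg.n_subtypes + 1}" for i in range(cfg.n_samples)],
        index=samples, name="subtype",
    )
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)
    values = np.tile(baseline[:, None], (1, cfg.n_samples))
    signatures: list[GeneSet] = []
    for s in range(cfg.n_subtypes):
        label = f"SUB{s + 1}"
        sig_idx = np.arange(s * cfg.signature_size, (s + 1) * cfg.signature_size)
        col_mask = (subtype_of == label).to_numpy()
        values[np.ix_(sig_idx, col_mask)] += cfg.effect_shift
        signatures.append(
            GeneSet(name=f"{label}_signature",
                    genes=tuple(genes[i] for i in sig_idx))
        )
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, log_scale=True), subtype_of, signatures


def simulate_regulatory_landscape(
    n_genes: int = 800,
    genome_length: int = 150_000_000,
    class_fractions: tuple[float, float, float] = (0.55, 0.29, 0.16),
    seed: int | None = 0,
    n_regions: int = 1_000,
    annotation_fractions: tuple[float, float, float] = (0.08, 0.64, 0.28),
    gene_length: int = 20_000,
) -> tuple[list[GeneModel], list[Peak], list[Peak], dict]:
    """Plant a factor/mark landscape with known overlap and annotation classes.

    ``class_fractions`` = (factor_only, mark_only, overlapping) and
    ``annotation_fractions`` = (promoter, enhancer, intergenic) for the factor
    peaks; defaults mirror a transcription-factor / H3K27ac integration with
    a mostly-enhancer binding profile. One region anchor is placed per genome
    tile, tiles are wide enough that neighbouring regions and gene windows
    cannot interact, and the returned truth dict records every planted label.
    """
    if abs(sum(class_fractions) - 1.0) > 1e-9:
        raise ValueError("class_fractions must sum to 1")
    if abs(sum(annotation_fractions) - 1.0) > 1e-9:
        raise ValueError("annotation_fractions must sum to 1")
    tile = genome_length // n_regions
    if tile < 140_000:
        raise ValueError("genome too small for the requested region count")
    n_prom = int(round(annotation_fractions[0] * n_regions))
    n_enh = int(round(annotation_fractions[1] * n_regions))
    n_genic = n_prom + n_enh
    if n_genes < n_genic:
        raise ValueError("not enough genes for the requested genic regions")
    if n_genes > n_regions:
        raise ValueError("n_genes cannot exceed the number of tiles")
    n_factor_only = int(round(class_fractions[0] * n_regions))
    n_mark_only = int(round(class_fractions[1] * n_regions))

    rng = np.random.default_rng(seed)
    chrom = "1"
    genes: list[GeneModel] = []
    anchors = np.empty(n_regions, dtype=int)
    categories = np.empty(n_regions, dtype=object)
    jitter = rng.integers(0, 5_000, size=n_regions)
    for i in range(n_regions):
        s = i * tile + int(jitter[i])
        if i < n_genes:
            tss = s + 60_000
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                genes.append(GeneModel(gene_id=f"g{i:05d}", chrom=chrom,
                                       strand="+", tss=tss,
                                       tes=tss + gene_length))
            else:
                # keep the TSS at the same coordinate; body extends leftward
                genes.append(GeneModel(gene_id=f"g{i:05d}", chrom=chrom,
                                       strand="-", tss=tss,
                                       tes=tss - gene_length))
        if i < n_prom:
            anchors[i] = s + 60_000 - 1 + int(rng.integers(-1_500, 1_501))
            categories[i] = "promoter"
        elif i < n_genic:
            tss0 = s + 60_000 - 1
            offset = int(rng.integers(5_000, 15_001))
            anchors[i] = tss0 + offset if genes[i].strand == "+" else tss0 - offset
            categories[i] = "enhancer"
        else:
            anchors[i] = s + tile - 12_000
            categories[i] = "intergenic"

    overlap_truth = np.empty(n_regions, dtype=object)
    overlap_truth[:n_factor_only] = "factor_only"
    overlap_truth[n_factor_only:n_factor_only + n_mark_only] = "mark_only"
    overlap_truth[n_factor_only + n_mark_only:] = "overlapping"
    rng.shuffle(overlap_truth)

    factor_peaks: list[Peak] = []
    mark_regions: list[Peak] = []
    factor_categories: list[str] = []
    for i in range(n_regions):
        a = int(anchors[i])
        cls = overlap_truth[i]
        if cls == "factor_only":
            factor_peaks.append(Peak(chrom=chrom, start=a - 150, end=a + 150))
            factor_categories.append(categories[i])
        elif cls == "mark_only":
            mark_regions.append(Peak(chrom=chrom, start=a - 500, end=a + 500))
        else:  # overlapping: factor at the anchor, mark within the gap limit
            factor_peaks.append(Peak(chrom=chrom, start=a - 150, end=a + 150))
            factor_categories.append(categories[i])
            gap = int(rng.integers(0, 4_001))
            mark_regions.append(
                Peak(chrom=chrom, start=a + 150 + gap, end=a + 150 + gap + 1_000)
            )
    truth = {
        "overlap_class": list(overlap_truth),
        "anchor_category": list(categories),
        "factor_category": factor_categories,
        "class_fractions": {
            "factor_only": n_factor_only / n_regions,
            "mark_only": n_mark_only / n_regions,
            "overlapping": (n_regions - n_factor_only - n_mark_only) / n_regions,
        },
    }
    return genes, factor_peaks, mark_regions, truth
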