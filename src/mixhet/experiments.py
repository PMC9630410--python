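"""Multi-replicate studies shared by the test suite, the acceptance script and
the analysis drivers.

Every study takes an integer seed, spawns independent child streams from it
(via :class:`numpy.random.SeedSequence`), and returns plain dictionaries of
summary numbers, so identical seeds give identical results wherever a study
is invoked from.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from . import clonality, expr_scoring, phylo, regulatory, synthetic_data
from .oracles import per_base_annotation_reference, ssgsea_running_sum_reference
from .io_formats import GeneModel, GeneSet, Peak

__all__ = [
    "type_i_error_study",
    "xi_recovery_study",
    "power_study",
    "phylogeny_identity_study",
    "ssgsea_oracle_study",
    "annotation_oracle_study",
    "overlap_recovery_study",
    "subtype_recovery_study",
    "kmeans_separation_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def type_i_error_study(
    seed: int,
    n_pairs: int = 500,
    n_per_region: int = 100,
    universe_size: int = 10_000,
    n_sims: int = 499,
    alpha: float = 0.05,
) -> dict:
    """Empirical rejection rate of the clonality test on independent tumors.

    Null pairs carry ``n_per_region`` mutations per region, drawn with the
    same per-tumor weighted sampler the Monte-Carlo null uses, over a
    Beta(0.5, 50) frequency universe.
    """
    ref = synthetic_data.simulate_reference_frequencies(
        universe_size=universe_size, seed=seed
    )
    seeds = _child_seeds(seed, 2 * n_pairs)
    n_reject = 0
    for i in range(n_pairs):
        pair = synthetic_data.simulate_null_pair(
            ref, n_per_region, n_per_region, seed=seeds[2 * i]
        )
        res = clonality.clonality_test(pair, ref, n_sims=n_sims,
                                       seed=seeds[2 * i + 1])
        if res.p_value <= alpha:
            n_reject += 1
    return {"rejection_rate": n_reject / n_pairs, "n_pairs": n_pairs,
            "alpha": alpha, "n_sims": n_sims}


def xi_recovery_study(
    seed: int,
    xi_values: Sequence[float] = (0.2, 0.5, 0.8),
    n_events: int = 200,
    n_reps: int = 200,
    universe_size: int = 10_000,
) -> dict:
    """Mean maximum-likelihood estimate of the clonality parameter per true xi."""
    ref = synthetic_data.simulate_reference_frequencies(
        universe_size=universe_size, seed=seed
    )
    seeds = _child_seeds(seed, len(xi_values) * n_reps)
    means = {}
    k = 0
    for xi in xi_values:
        estimates = np.empty(n_reps)
        for r in range(n_reps):
            pair, _ = synthetic_data.simulate_pair(ref, xi, n_events,
                                                   seed=seeds[k])
            part = phylo.partition_mutations(pair)
            estimates[r], _ = clonality.fit_xi(part, ref)
            k += 1
        means[xi] = float(estimates.mean())
    return {"mean_xi_hat": means, "n_events": n_events, "n_reps": n_reps}


def power_study(
    seed: int,
    xi_values: Sequence[float] = (0.2, 0.5, 0.8),
    n_events: int = 4,
    n_reps: int = 200,
    n_sims: int = 199,
    universe_size: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """Empirical power of the clonality test per true xi.

    Run in a deliberately low-information regime (few events per pair):
    with hundreds of rare-locus events the test rejects essentially always at
    any xi > 0, which would flatten the power curve at 1.
    """
    ref = synthetic_data.simulate_reference_frequencies(
        universe_size=universe_size, seed=seed
    )
    seeds = _child_seeds(seed, 2 * len(xi_values) * n_reps)
    power = {}
    k = 0
    for xi in xi_values:
        n_reject = 0
        for _ in range(n_reps):
            pair, _ = synthetic_data.simulate_pair(ref, xi, n_events,
                                                   seed=seeds[k])
            res = clonality.clonality_test(pair, ref, n_sims=n_sims,
                                           seed=seeds[k + 1])
            if res.p_value <= alpha:
                n_reject += 1
            k += 2
        power[xi] = n_reject / n_reps
    return {"power": power, "n_events": n_events, "n_reps": n_reps,
            "n_sims": n_sims, "alpha": alpha}


def phylogeny_identity_study(seed: int, n_pairs: int = 1_000) -> dict:
    """Fraction of random pairs whose tree branch lengths equal the partition counts."""
    ref = synthetic_data.simulate_reference_frequencies(universe_size=5_000,
                                                        seed=seed)
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed, n_pairs)
    n_exact = 0
    for i in range(n_pairs):
        xi = float(rng.uniform(0.0, 0.95))
        n_events = int(rng.integers(1, 301))
        pair, _ = synthetic_data.simulate_pair(ref, xi, n_events, seed=seeds[i])
        part = phylo.partition_mutations(pair)
        tree = phylo.build_tree(pair)
        if (tree.branch_uc == part.n_a and tree.branch_sqd == part.n_b
                and tree.branch_normal == part.n_sh):
            n_exact += 1
    return {"fraction_exact": n_exact / n_pairs, "n_pairs": n_pairs}


def ssgsea_oracle_study(seed: int, n_instances: int = 100,
                        max_genes: int = 50) -> dict:
    """Max |implementation - running-sum enumeration| over random instances."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_instances):
        G = int(rng.integers(5, max_genes + 1))
        genes = [f"g{i}" for i in range(G)]
        values = dict(zip(genes, rng.normal(size=G)))
        m = int(rng.integers(1, G))
        members = list(rng.choice(genes, size=m, replace=False))
        alpha = float(rng.choice([0.0, 0.25, 1.0]))
        ours = expr_scoring.ssgsea_score(
            values, GeneSet(name="S", genes=tuple(members)), alpha=alpha
        ).value
        oracle = ssgsea_running_sum_reference(values, members, alpha)
        max_diff = max(max_diff, abs(ours - oracle))
    return {"max_abs_diff": max_diff, "n_instances": n_instances}


def _random_genome(rng: np.random.Generator) -> tuple[list[GeneModel], list[Peak], int]:
    length = int(rng.integers(50_000, 100_001))
    n_genes = int(rng.integers(1, 6))
    genes = []
    for g in range(n_genes):
        a = int(rng.integers(1, length - 1_000))
        b = a + int(rng.integers(500, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (a, b) if strand == "+" else (b, a)
        genes.append(GeneModel(gene_id=f"g{g}", chrom="1", strand=strand,
                               tss=tss, tes=tes))
    peaks = []
    for _ in range(int(rng.integers(20, 101))):
        s = int(rng.integers(0, length - 200))
        peaks.append(Peak(chrom="1", start=s, end=s + int(rng.integers(100, 200))))
    return genes, peaks, length


def annotation_oracle_study(seed: int, n_genomes: int = 50) -> dict:
    """Category agreement between the window annotator and per-base painting."""
    rng = np.random.default_rng(seed)
    n_peaks = n_agree = 0
    for _ in range(n_genomes):
        genes, peaks, length = _random_genome(rng)
        labels = per_base_annotation_reference(genes, length)
        annotated = regulatory.annotate_peaks(peaks, genes)
        for ap in annotated:
            n_peaks += 1
            if ap.category == labels[ap.peak.midpoint]:
                n_agree += 1
    return {"agreement": n_agree / n_peaks, "n_peaks": n_peaks,
            "n_genomes": n_genomes}


def overlap_recovery_study(
    seed: int,
    n_regions: int = 1_000,
    class_fractions: tuple[float, float, float] = (0.55, 0.29, 0.16),
) -> dict:
    """Recovered factor/mark overlap-class proportions on a planted landscape."""
    genes, factor_peaks, marks, truth = synthetic_data.simulate_regulatory_landscape(
        n_regions=n_regions, class_fractions=class_fractions, seed=seed
    )
    _, proportions = regulatory.classify_overlap(factor_peaks, marks)
    return {"recovered": proportions, "planted": truth["class_fractions"],
            "n_regions": n_regions}


def subtype_recovery_study(seed: int, holdout_fraction: float = 0.5,
                           genes_per_class: int = 500) -> dict:
    """Held-out nearest-centroid accuracy on synthetic 4-subtype expression."""
    cfg = synthetic_data.ExprSimConfig(seed=seed)
    expr, labels, _ = synthetic_data.simulate_expression(cfg)
    samples = expr.sample_ids
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_test = int(round(holdout_fraction * len(samples)))
    test_ids = [samples[i] for i in perm[:n_test]]
    train_ids = [samples[i] for i in perm[n_test:]]
    centroids = expr_scoring.build_centroids(
        expr.data[train_ids], labels[train_ids], genes_per_class=genes_per_class
    )
    n_correct = 0
    for sid in test_ids:
        pred, _ = expr_scoring.classify_nearest_centroid(expr.sample(sid), centroids)
        if pred == labels[sid]:
            n_correct += 1
    return {"accuracy": n_correct / n_test, "n_test": n_test,
            "n_train": len(train_ids)}


def kmeans_separation_study(seed: int, n_per_group: int = 50,
                            n_bins: int = 8) -> dict:
    """Adjusted Rand index of k=2 signal clustering on two planted groups."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    high = rng.normal(10.0, 0.5, size=(n_per_group, n_bins))
    low = rng.normal(0.0, 0.5, size=(n_per_group, n_bins))
    x = np.vstack([high, low])
    truth = np.array([1] * n_per_group + [2] * n_per_group)
    labels = regulatory.kmeans_cluster_signal(x, k=2, seed=seed)
    return {"ari": float(adjusted_rand_score(truth, labels)),
            "n_rows": 2 * n_per_group}
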