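import numpy as np
import pytest

from mixhet import regulatory as reg
from mixhet.io_formats import GeneModel, Peak
from mixhet.oracles import per_base_annotation_reference


GENE_PLUS = GeneModel(gene_id="gp", chrom="1", strand="+",
                      tss=100_000, tes=110_000)
GENE_MINUS = GeneModel(gene_id="gm", chrom="2", strand="-",
                       tss=300_000, tes=290_000)


def peak_at(mid, chrom="1"):
    return Peak(chrom=chrom, start=mid - 50, end=mid + 50)


class TestAnnotateInterval:
    def test_promoter_window(self):
        ap = reg.annotate_interval(peak_at(99_500), [GENE_PLUS])
        assert ap.category == "promoter"
        assert ap.assigned_gene == "gp"
        assert abs(ap.distance_to_tss) <= 2_000

    def test_enhancer_window_upstream(self):
        ap = reg.annotate_interval(peak_at(60_000), [GENE_PLUS])
        assert ap.category == "enhancer"

    def test_intergenic(self):
        ap = reg.annotate_interval(peak_at(200_000), [GENE_PLUS])
        assert ap.category == "intergenic"
        assert ap.assigned_gene is None and ap.distance_to_tss is None

    def test_minus_strand_upstream_extends_right(self):
        # 40 kb "upstream" of a minus-strand TSS is at higher coordinates
        ap = reg.annotate_interval(peak_at(340_000, chrom="2"), [GENE_MINUS])
        assert ap.category == "enhancer"
        assert ap.distance_to_tss < 0  # upstream in gene orientation
        # and beyond 50 kb it is intergenic
        assert reg.annotate_interval(peak_at(355_000, chrom="2"),
                                     [GENE_MINUS]).category == "intergenic"

    def test_promoter_precedence_over_enhancer(self):
        # a promoter-window hit of one gene beats an enhancer hit of another
        other = GeneModel(gene_id="go", chrom="1", strand="+",
                          tss=95_000, tes=99_000)
        ap = reg.annotate_interval(peak_at(99_500), [other, GENE_PLUS])
        assert ap.category == "promoter"
        assert ap.assigned_gene == "gp"

    def test_missing_chromosome_warns_intergenic(self):
        with pytest.warns(UserWarning, match="absent"):
            ap = reg.annotate_interval(peak_at(5_000, chrom="99"), [GENE_PLUS])
        assert ap.category == "intergenic"

    def test_summit_overrides_midpoint(self):
        p = Peak(chrom="1", start=50_000, end=120_000, summit=99_900)
        assert reg.annotate_interval(p, [GENE_PLUS]).category == "promoter"

    def test_categories_partition_peak_set(self):
        rng = np.random.default_rng(0)
        peaks = [peak_at(int(rng.integers(100, 400_000))) for _ in range(200)]
        cats = {a.category for a in reg.annotate_peaks(peaks, [GENE_PLUS])}
        assert cats <= {"promoter", "enhancer", "intergenic"}

    def test_agreement_with_per_base_oracle(self):
        """Window annotation agrees with literal per-base rule painting on
        random small genomes."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            length = int(rng.integers(50_000, 100_001))
            genes = []
            for g in range(int(rng.integers(1, 5))):
                a = int(rng.integers(1, length - 1_000))
                b = a + int(rng.integers(500, 20_000))
                strand = "+" if rng.random() < 0.5 else "-"
                tss, tes = (a, b) if strand == "+" else (b, a)
                genes.append(GeneModel(gene_id=f"g{g}", chrom="1",
                                       strand=strand, tss=tss, tes=tes))
            labels = per_base_annotation_reference(genes, length)
            peaks = [Peak(chrom="1", start=s, end=s + 100)
                     for s in rng.integers(0, length - 100, size=50)]
            for ap in reg.annotate_peaks(peaks, genes):
                assert ap.category == labels[ap.peak.midpoint]


class TestClassifyOverlap:
    def test_gap_within_limit_is_overlapping(self):
        factor = [Peak(chrom="1", start=1_000, end=1_200)]
        mark = [Peak(chrom="1", start=5_900, end=6_100)]  # gap 4,700
        records, props = reg.classify_overlap(factor, mark)
        assert {r.cls for r in records} == {"overlapping"}
        assert props["overlapping"] == 1.0

    def test_gap_beyond_limit_splits(self):
        factor = [Peak(chrom="1", start=1_000, end=1_200)]
        mark = [Peak(chrom="1", start=6_201, end=6_400)]  # gap 5,001
        records, props = reg.classify_overlap(factor, mark)
        assert {r.cls for r in records} == {"factor_only", "mark_only"}
        assert props["overlapping"] == 0.0

    def test_touching_intervals_gap_zero(self):
        factor = [Peak(chrom="1", start=1_000, end=1_200)]
        mark = [Peak(chrom="1", start=1_200, end=1_400)]
        _, props = reg.classify_overlap(factor, mark, max_gap_bp=0)
        assert props["overlapping"] == 1.0

    def test_proportions_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(2)
        factor = [Peak(chrom="1", start=int(s), end=int(s) + 200)
                  for s in rng.integers(0, 1_000_000, size=40)]
        mark = [Peak(chrom="1", start=int(s), end=int(s) + 400)
                for s in rng.integers(0, 1_000_000, size=30)]
        _, props = reg.classify_overlap(factor, mark)
        assert sum(props.values()) == pytest.approx(1.0)
        _, props_rev = reg.classify_overlap(factor[::-1], mark[::-1])
        assert props == props_rev

    def test_overlap_count_monotone_in_gap(self):
        rng = np.random.default_rng(3)
        factor = [Peak(chrom="1", start=int(s), end=int(s) + 100)
                  for s in rng.integers(0, 500_000, size=50)]
        mark = [Peak(chrom="1", start=int(s), end=int(s) + 100)
                for s in rng.integers(0, 500_000, size=50)]
        counts = []
        for gap in (0, 1_000, 5_000, 20_000):
            _, props = reg.classify_overlap(factor, mark, max_gap_bp=gap)
            counts.append(props["overlapping"])
        assert counts == sorted(counts)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            reg.classify_overlap([], [])


class TestFilterNearTss:
    def test_boundaries(self):
        gene = GeneModel(gene_id="g", chrom="1", strand="+",
                         tss=100_000, tes=120_000)
        near = peak_at(100_000 - 1 + 9_999)
        far = peak_at(100_000 - 1 + 10_001)
        kept = reg.filter_near_tss([near, far], [gene])
        assert kept == [near]

    def test_empty_gene_models(self):
        assert reg.filter_near_tss([peak_at(1_000)], []) == []


class TestKmeans:
    def test_separated_groups_ari_one(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 0.5, size=(50, 4)),
                       rng.normal(10, 0.5, size=(50, 4))])
        truth = np.array([0] * 50 + [1] * 50)
        labels = reg.kmeans_cluster_signal(x, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        # cluster 1 carries the higher mean signal
        assert x[labels == 1].mean() > x[labels == 2].mean()

    def test_k_equals_rows_zero_wcss(self):
        x = np.arange(8, dtype=float).reshape(4, 2) * 10
        labels = reg.kmeans_cluster_signal(x, k=4, seed=0)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_duplicate_rows_identical_labels(self):
        rng = np.random.default_rng(5)
        base = np.vstack([rng.normal(0, 1, size=(10, 3)),
                          rng.normal(8, 1, size=(10, 3))])
        x = np.vstack([base, base])
        labels = reg.kmeans_cluster_signal(x, k=2, seed=1)
        assert (labels[:20] == labels[20:]).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="fewer rows"):
            reg.kmeans_cluster_signal(np.ones((1, 3)), k=2)
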