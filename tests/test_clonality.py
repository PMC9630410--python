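import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixhet import clonality as clon
from mixhet import synthetic_data as sd
from mixhet.oracles import xi_grid_search_reference
from mixhet.phylo import MutationPartition, partition_mutations

from conftest import make_pair


def part(n_sh, n_a, n_b):
    """Partition over synthetic locus keys matching the simulator's universe."""
    sh = frozenset(f"1:{i + 1}:A:C" for i in range(n_sh))
    a = frozenset(f"2:{i + 1}:A:C" for i in range(n_sh, n_sh + n_a))
    b = frozenset(f"3:{i + 1}:A:C" for i in range(n_sh + n_a, n_sh + n_a + n_b))
    return MutationPartition(shared=sh, private_a=a, private_b=b)


class TestReferenceFrequencies:
    def test_smoothing_formula(self):
        ref = clon.estimate_reference_frequencies({"x": 40, "y": 2}, n_ref=400,
                                                  pseudocount=0.5)
        assert ref.p("x") == pytest.approx(40.5 / 401, rel=1e-9)
        # unseen locus falls back to the pseudocount probability
        assert ref.p("unseen") == pytest.approx(0.5 / 401, rel=1e-9)

    def test_zero_count_zero_pseudocount_clipped(self):
        ref = clon.estimate_reference_frequencies({"x": 0, "y": 1}, n_ref=400,
                                                  pseudocount=0.0)
        assert ref.p("x") == pytest.approx(1e-6)

    def test_count_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError):
            clon.estimate_reference_frequencies({"x": 401, "y": 1}, n_ref=400)
        with pytest.raises(ValueError):
            clon.estimate_reference_frequencies({"x": 1, "y": 1}, n_ref=0)


class TestConfigProbs:
    def test_symmetric_case(self):
        assert clon.conditional_config_probs(0.5, 0.0) == pytest.approx(
            (1 / 3, 1 / 3, 1 / 3)
        )

    def test_mixture_arithmetic(self):
        assert clon.conditional_config_probs(0.5, 0.4) == pytest.approx(
            (0.6, 0.2, 0.2)
        )

    def test_rare_locus_limit(self):
        p_sh, p_a, p_b = clon.conditional_config_probs(1e-9, 0.0)
        assert p_sh == pytest.approx(0.0, abs=1e-8)
        assert p_a == pytest.approx(0.5, abs=1e-8)

    def test_normalization_on_grid(self):
        """P_sh + P_a + P_b = 1 over a 100x100 (p, xi) grid, to 1e-12."""
        for p in np.linspace(0.005, 0.995, 100):
            for xi in np.linspace(0.0, 0.99, 100):
                assert sum(clon.conditional_config_probs(p, xi)) == \
                    pytest.approx(1.0, abs=1e-12)

    def test_h0_reduction_exact(self):
        for p in (0.01, 0.2, 0.7):
            p_sh, p_a, p_b = clon.conditional_config_probs(p, 0.0)
            assert p_sh == p / (2 - p)
            assert p_a == (1 - p) / (2 - p) == p_b

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clon.conditional_config_probs(0.0, 0.5)
        with pytest.raises(ValueError):
            clon.conditional_config_probs(0.5, 1.0)


class TestLogLikelihood:
    def test_empty_partition_is_zero(self, small_reference):
        empty = MutationPartition(frozenset(), frozenset(), frozenset())
        assert clon.log_likelihood(empty, small_reference, 0.3) == 0.0

    def test_single_shared_term(self):
        ref = clon.ReferenceFrequencies(
            locus_keys=("1:1:A:C", "1:2:A:C"), probs=np.array([0.5, 0.5]),
            n_ref=100,
        )
        p = MutationPartition(frozenset({"1:1:A:C"}), frozenset(), frozenset())
        assert clon.log_likelihood(p, ref, 0.0) == pytest.approx(math.log(1 / 3))

    def test_no_shared_likelihood_decreasing_in_xi(self, small_reference):
        p = part(0, 10, 5)
        lls = [clon.log_likelihood(p, small_reference, xi)
               for xi in (0.0, 0.2, 0.5, 0.9)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_xi_one_with_privates_rejected(self, small_reference):
        with pytest.raises(ValueError):
            clon.log_likelihood(part(1, 1, 0), small_reference, 1.0)


class TestFitXi:
    def test_no_shared_boundary(self, small_reference):
        xi, lrt = clon.fit_xi(part(0, 10, 10), small_reference)
        assert xi == 0.0 and lrt == 0.0

    def test_all_shared_rare_loci_at_upper_boundary(self):
        keys = tuple(f"1:{i + 1}:A:C" for i in range(50))
        ref = clon.ReferenceFrequencies(locus_keys=keys,
                                        probs=np.full(50, 0.01), n_ref=400)
        p = MutationPartition(frozenset(keys), frozenset(), frozenset())
        xi, lrt = clon.fit_xi(p, ref)
        assert xi >= 0.99
        assert lrt > 0

    def test_empty_partition_rejected(self, small_reference):
        with pytest.raises(ValueError, match="no informative loci"):
            clon.fit_xi(MutationPartition(frozenset(), frozenset(), frozenset()),
                        small_reference)

    def test_lrt_matches_dense_grid_oracle(self, default_reference):
        """Optimizer agrees with an exhaustive 10^4-point grid on 100 random
        partitions, to 1e-4 on the LRT."""
        rng = np.random.default_rng(7)
        ref = default_reference
        for _ in range(100):
            xi_true = float(rng.uniform(0, 0.9))
            n_events = int(rng.integers(5, 200))
            pair, _ = sd.simulate_pair(ref, xi_true, n_events,
                                       seed=int(rng.integers(2**31)))
            partn = partition_mutations(pair)
            _, lrt = clon.fit_xi(partn, ref)
            if partn.n_sh == 0:
                assert lrt == 0.0
                continue
            q = ref.p_many(sorted(partn.shared))
            q = q / (2.0 - q)
            _, lrt_oracle = xi_grid_search_reference(q, partn.n_a + partn.n_b)
            assert lrt == pytest.approx(lrt_oracle, abs=1e-4)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n_sh=st.integers(0, 30), n_a=st.integers(0, 30),
           n_b=st.integers(0, 30))
    def test_lrt_nonnegative(self, small_reference, n_sh, n_a, n_b):
        if n_sh + n_a + n_b == 0:
            return
        _, lrt = clon.fit_xi(part(n_sh, n_a, n_b), small_reference)
        assert lrt >= 0.0


class TestClonalityTest:
    def test_zero_shared_gives_p_one(self, small_reference):
        pair = make_pair([1, 2, 3], [4, 5, 6])
        res = clon.clonality_test(pair, small_reference, n_sims=99, seed=0)
        assert res.lrt == 0.0 and res.p_value == 1.0

    def test_simulated_clonal_pair_rejects(self, default_reference):
        pair, _ = sd.simulate_pair(default_reference, 0.8, 100, seed=11)
        res = clon.clonality_test(pair, default_reference, n_sims=999, seed=13)
        assert res.p_value <= 0.01

    def test_seed_determinism(self, small_reference):
        pair, _ = sd.simulate_pair(small_reference, 0.5, 40, seed=3)
        r1 = clon.clonality_test(pair, small_reference, n_sims=199, seed=5)
        r2 = clon.clonality_test(pair, small_reference, n_sims=199, seed=5)
        assert r1 == r2

    def test_p_value_floor(self, default_reference):
        pair, _ = sd.simulate_pair(default_reference, 0.9, 100, seed=1)
        res = clon.clonality_test(pair, default_reference, n_sims=199, seed=2)
        assert res.p_value >= 1.0 / 200

    def test_input_validation(self, small_reference):
        pair = make_pair([1, 2], [2, 3])
        with pytest.raises(ValueError, match="n_sims"):
            clon.clonality_test(pair, small_reference, n_sims=50)
        tiny = clon.ReferenceFrequencies(
            locus_keys=("1:1:A:C", "1:2:A:C"), probs=np.array([0.1, 0.1]),
            n_ref=10,
        )
        big_pair = make_pair(list(range(1, 10)), list(range(5, 14)))
        with pytest.raises(ValueError, match="universe"):
            clon.clonality_test(big_pair, tiny, n_sims=99)
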