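import numpy as np
import pytest

from mixhet.io_formats import Mutation, PatientPair, RegionProfile


def make_mutation(pos, chrom="1", ref="A", alt="C", **kw):
    return Mutation(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def make_pair(keys_a, keys_b, patient="P1", covered_mb=30.0, **mut_kw):
    """Pair from plain position lists; key identity is chrom:pos:A:C."""
    prof_a = RegionProfile(
        patient_id=patient, region_label="UC",
        mutations=tuple(make_mutation(p, **mut_kw) for p in keys_a),
        covered_mb=covered_mb,
    )
    prof_b = RegionProfile(
        patient_id=patient, region_label="SqD",
        mutations=tuple(make_mutation(p, **mut_kw) for p in keys_b),
        covered_mb=covered_mb,
    )
    return PatientPair(profile_a=prof_a, profile_b=prof_b)


@pytest.fixture(scope="session")
def small_reference():
    """A 2,000-locus Beta(0.5, 50) reference universe, fixed seed."""
    from mixhet.synthetic_data import simulate_reference_frequencies

    return simulate_reference_frequencies(universe_size=2_000, seed=42)


@pytest.fixture(scope="session")
def default_reference():
    """The 10,000-locus default universe used by the recovery studies."""
    from mixhet.synthetic_data import simulate_reference_frequencies

    return simulate_reference_frequencies(universe_size=10_000, seed=42)
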