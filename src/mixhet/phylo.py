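"""Shared/private mutation partitioning and paired-region phylogeny statistics.

For two tumor regions of the same patient plus a hypothetical normal cell of
origin (carrying none of the somatic mutations), the three-taxon tree is
determined analytically: with binary presence vectors over the union of
mutations, the pairwise Hamming distances are d(N,U) = n_sh + n_a,
d(N,S) = n_sh + n_b and d(U,S) = n_a + n_b, and the three-point decomposition
returns branch lengths equal to the partition counts exactly. No general
tree-search engine is needed — the study topology is fixed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .io_formats import Mutation, PatientPair, RegionProfile

__all__ = [
    "MutationPartition",
    "PhylogenyResult",
    "partition_mutations",
    "phylogenic_ratio",
    "concordance",
    "tmb",
    "build_tree",
    "EFFECT_FILTERS",
]


def _accept_all(m: Mutation) -> bool:
    return True


def _nonsyn(m: Mutation) -> bool:
    return m.effect == "nonsynonymous"


def _oncogenic(m: Mutation) -> bool:
    return m.oncogenicity in {"oncogenic", "likely_oncogenic"}


EFFECT_FILTERS: dict[str, Callable[[Mutation], bool]] = {
    "all": _accept_all,
    "nonsyn": _nonsyn,
    "oncogenic": _oncogenic,
}


@dataclass(frozen=True)
class MutationPartition:
    """Union of a pair's mutations split into shared / private-A / private-B.

    Keys are chrom:pos:ref:alt — mutation identity is allele-level, so e.g.
    the same hotspot substitution present in both regions is shared while a
    different substitution at the same codon is not.
    """

    shared: frozenset[str]
    private_a: frozenset[str]
    private_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.shared & self.private_a or self.shared & self.private_b or \
                self.private_a & self.private_b:
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def n_sh(self) -> int:
        return len(self.shared)

    @property
    def n_a(self) -> int:
        return len(self.private_a)

    @property
    def n_b(self) -> int:
        return len(self.private_b)

    @property
    def n_union(self) -> int:
        return self.n_sh + self.n_a + self.n_b


@dataclass(frozen=True)
class PhylogenyResult:
    """Three-taxon tree over {NORMAL, UC, SqD} with mutation-count branch lengths."""

    newick: str
    branch_normal: int
    branch_uc: int
    branch_sqd: int
    ratio_uc: float
    ratio_sqd: float


def partition_mutations(
    pair: PatientPair,
    effect_filter: str | Callable[[Mutation], bool] | None = None,
) -> MutationPartition:
    """Partition the union of a pair's mutations into shared and private sets.

    ``effect_filter`` restricts the universe first: a name from
    :data:`EFFECT_FILTERS` ("all", "nonsyn", "oncogenic") or any predicate on
    :class:`Mutation`. An empty result is returned with a warning rather than
    an error (the clonality test errors downstream on empty partitions).
    """
    if effect_filter is None:
        pred = _accept_all
    elif callable(effect_filter):
        pred = effect_filter
    else:
        try:
            pred = EFFECT_FILTERS[effect_filter]
        except KeyError:
            raise ValueError(f"unknown effect filter {effect_filter!r}") from None
    keys_a = frozenset(m.key for m in pair.profile_a.mutations if pred(m))
    keys_b = frozenset(m.key for m in pair.profile_b.mutations if pred(m))
    part = MutationPartition(
        shared=keys_a & keys_b,
        private_a=keys_a - keys_b,
        private_b=keys_b - keys_a,
    )
    if part.n_union == 0:
        warnings.warn(
            f"effect filter left no mutations for patient {pair.patient_id}",
            stacklevel=2,
        )
    return part


def phylogenic_ratio(partition: MutationPartition, region: str) -> float:
    """Private-over-shared mutation count for one region ("a" or "b").

    Returns ``math.inf`` when there are no shared mutations (sentinel policy:
    downstream fold/median comparisons must tolerate it).
    """
    if region not in {"a", "b"}:
        raise ValueError("region must be 'a' or 'b'")
    n_priv = partition.n_a if region == "a" else partition.n_b
    if partition.n_sh == 0:
        return math.inf
    return n_priv / partition.n_sh


def concordance(
    pairs: Sequence[PatientPair],
    oncogenicity_filter: str = "all_nonsynonymous",
) -> tuple[dict[str, float], float]:
    """Per-pair shared-over-union percentages and their unweighted cohort mean.

    ``oncogenicity_filter`` is "all_nonsynonymous" (every nonsynonymous
    mutation) or "oncogenic_or_likely" (curated oncogenic calls only). Pairs
    whose filtered union is empty are excluded with a warning.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    if oncogenicity_filter == "all_nonsynonymous":
        pred = _nonsyn
    elif oncogenicity_filter == "oncogenic_or_likely":
        pred = _oncogenic
    else:
        raise ValueError(f"unknown filter {oncogenicity_filter!r}")
    per_pair: dict[str, float] = {}
    for pair in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = partition_mutations(pair, pred)
        if part.n_union == 0:
            warnings.warn(
                f"patient {pair.patient_id} excluded from concordance: "
                "empty union under filter",
                stacklevel=2,
            )
            continue
        per_pair[pair.patient_id] = 100.0 * part.n_sh / part.n_union
    if not per_pair:
        raise ValueError("no pair has a non-empty union under the filter")
    cohort = float(sum(per_pair.values()) / len(per_pair))
    return per_pair, cohort


def tmb(profile: RegionProfile) -> float:
    """Tumor mutational burden: nonsynonymous mutations per covered megabase."""
    n = sum(1 for m in profile.mutations if m.effect == "nonsynonymous")
    return n / profile.covered_mb


def build_tree(
    pair: PatientPair,
    effect_filter: str | Callable[[Mutation], bool] | None = None,
) -> PhylogenyResult:
    """Three-taxon phylogeny of a pair plus a synthetic mutation-free normal.

    Branch lengths come from the three-point decomposition of the pairwise
    Hamming distances over the mutation union and equal the partition counts.
    """
    part = partition_mutations(pair, effect_filter)
    if part.n_union == 0:
        raise ValueError("cannot build a tree from an empty mutation union")
    d_nu = part.n_sh + part.n_a
    d_ns = part.n_sh + part.n_b
    d_us = part.n_a + part.n_b
    # three-point formulas; integral by construction
    b_u = (d_nu + d_us - d_ns) // 2
    b_s = (d_ns + d_us - d_nu) // 2
    b_n = (d_nu + d_ns - d_us) // 2
    label_a = pair.profile_a.region_label
    label_b = pair.profile_b.region_label
    newick = f"(({label_a}:{b_u},{label_b}:{b_s}):0,NORMAL:{b_n});"
    return PhylogenyResult(
        newick=newick,
        branch_normal=b_n,
        branch_uc=b_u,
        branch_sqd=b_s,
        ratio_uc=phylogenic_ratio(part, "a"),
        ratio_sqd=phylogenic_ratio(part, "b"),
    )
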