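"""Readers/writers and domain types for the formats the pipeline touches.

Coordinate conventions are fixed once, at the boundary: BED intervals are
0-based half-open; mutation positions and gene TSS/TES are kept 1-based (the
MAF / gene-model convention) and converted only when an interval query needs
them. Chromosome names are normalized by stripping any ``chr`` prefix so that
sample tables and reference tables merge safely.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Mutation",
    "RegionProfile",
    "PatientPair",
    "GeneModel",
    "Peak",
    "GeneSet",
    "ExpressionMatrix",
    "read_mutation_table",
    "read_gene_models",
    "read_bed_peaks",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_newick",
    "write_table",
    "normalize_chrom",
]

EFFECT_CATEGORIES = frozenset({"nonsynonymous", "synonymous", "other"})
ONCOGENICITY_LABELS = frozenset({"oncogenic", "likely_oncogenic", "unknown"})


class FormatError(ValueError):
    """Malformed input file: parsers reject rather than silently coerce."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class Mutation:
    """A somatic point mutation identified by chrom:pos:ref:alt.

    ``effect`` and ``oncogenicity`` are curated input labels, not computed
    here; ``ccf`` is the optional cancer-cell fraction in [0, 1].
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = "other"
    oncogenicity: str = "unknown"
    ccf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"mutation position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")
        if self.effect not in EFFECT_CATEGORIES:
            raise ValueError(f"unknown effect category {self.effect!r}")
        if self.oncogenicity not in ONCOGENICITY_LABELS:
            raise ValueError(f"unknown oncogenicity label {self.oncogenicity!r}")
        if self.ccf is not None and not (0.0 <= self.ccf <= 1.0):
            raise ValueError(f"ccf must lie in [0, 1], got {self.ccf}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class RegionProfile:
    """All somatic mutations of one macrodissected tumor region.

    ``covered_mb`` is the exome footprint in megabases; it is a required
    per-sample quantity (the TMB denominator), not a constant.
    """

    patient_id: str
    region_label: str
    mutations: tuple[Mutation, ...]
    covered_mb: float = 30.0

    def __post_init__(self) -> None:
        if self.covered_mb <= 0:
            raise ValueError("covered_mb must be positive")
        keys = [m.key for m in self.mutations]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate mutation keys within one region profile")

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(m.key for m in self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass(frozen=True)
class PatientPair:
    """Two same-patient region profiles (canonically UC and SqD)."""

    profile_a: RegionProfile
    profile_b: RegionProfile

    def __post_init__(self) -> None:
        if self.profile_a.patient_id != self.profile_b.patient_id:
            raise ValueError("paired profiles must share a patient_id")
        if self.profile_a.region_label == self.profile_b.region_label:
            raise ValueError("paired profiles must carry distinct region labels")

    @property
    def patient_id(self) -> str:
        return self.profile_a.patient_id


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with strand-oriented TSS/TES (1-based).

    On the + strand tss < tes; on the − strand tss > tes, i.e. the numbers are
    stored as strand-oriented positions, not as a sorted interval.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")


@dataclass(frozen=True)
class Peak:
    """A genomic interval in BED convention (0-based half-open)."""

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak start must be < end, got [{self.start}, {self.end})")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must lie in [0, 1]")

    @property
    def midpoint(self) -> int:
        """Anchor position: the summit if provided, else the interval midpoint."""
        if self.summit is not None:
            return self.summit
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


class ExpressionMatrix:
    """Gene-by-sample expression values backed by a pandas DataFrame.

    Values must be finite; non-negativity is enforced unless ``log_scale``
    is set (log-transformed data may dip below zero).
    """

    def __init__(self, data: pd.DataFrame, log_scale: bool = False) -> None:
        if data.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")
        if not log_scale and (values < 0).any():
            raise FormatError("negative expression values in a linear-scale matrix")
        self.data = data.astype(float)
        self.log_scale = log_scale

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_MUTATION_REQUIRED = ("patient", "region", "chrom", "pos", "ref", "alt")


def read_mutation_table(path: str | Path, dialect: str = "tsv") -> list[RegionProfile]:
    """Parse a MAF-like TSV into one :class:`RegionProfile` per (patient, region).

    Duplicate chrom:pos:ref:alt keys within a region are collapsed to one
    record, with a warning stating how many were dropped.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _MUTATION_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"mutation table is missing mandatory column {col!r}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"non-integer pos at line {line} of {path}")
    df["pos"] = pos.astype(int)
    df["chrom"] = df["chrom"].map(normalize_chrom)

    profiles: list[RegionProfile] = []
    n_dups_total = 0
    for (patient, region), grp in df.groupby(["patient", "region"], sort=True):
        seen: dict[str, Mutation] = {}
        n_dups = 0
        for row in grp.itertuples(index=False):
            d = row._asdict()
            ccf = d.get("ccf")
            mut = Mutation(
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=str(d.get("gene") or ""),
                effect=str(d.get("effect") or "other"),
                oncogenicity=str(d.get("oncogenicity") or "unknown"),
                ccf=float(ccf) if ccf not in (None, "", "NA") and not pd.isna(ccf) else None,
            )
            if mut.key in seen:
                n_dups += 1
            else:
                seen[mut.key] = mut
        n_dups_total += n_dups
        covered = 30.0
        if "covered_mb" in grp.columns and not pd.isna(grp["covered_mb"].iloc[0]):
            covered = float(grp["covered_mb"].iloc[0])
        profiles.append(
            RegionProfile(
                patient_id=str(patient),
                region_label=str(region),
                mutations=tuple(seen.values()),
                covered_mb=covered,
            )
        )
    if n_dups_total:
        warnings.warn(
            f"collapsed {n_dups_total} duplicate mutation record(s) in {path}",
            stacklevel=2,
        )
    return profiles


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a gene-model TSV (gene_id, chrom, strand, tss, tes)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("gene_id", "chrom", "strand", "tss", "tes"):
        if col not in df.columns:
            raise FormatError(f"gene model table is missing column {col!r}")
    models = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            models.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    chrom=normalize_chrom(row.chrom),
                    strand=str(row.strand),
                    tss=int(row.tss),
                    tes=int(row.tes),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"gene model line {i + 2} of {path}: {exc}") from exc
    return models


def index_by_chrom(models: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    index: dict[str, list[GeneModel]] = {}
    for m in models:
        index.setdefault(m.chrom, []).append(m)
    return index


def read_bed_peaks(path: str | Path) -> list[Peak]:
    """Parse BED3+ peaks. Column 5 (if present) populates ``score``."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"BED line {i} of {path}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"BED line {i} of {path}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"BED line {i} of {path}: start >= end ({start} >= {end})")
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"BED line {i} of {path}: non-numeric score") from exc
            summit = None
            if len(fields) >= 7 and fields[6] not in (".", ""):
                try:
                    summit = int(fields[6])
                except ValueError:
                    summit = None
            peaks.append(
                Peak(chrom=normalize_chrom(fields[0]), start=start, end=end,
                     summit=summit, score=score)
            )
    return peaks


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT gene-set collection (name, description, members...).

    Empty sets are skipped with a warning; duplicate members within a set are
    collapsed preserving first occurrence.
    """
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if not members:
                warnings.warn(f"skipping empty gene set {name!r} at line {i}", stacklevel=2)
                continue
            uniq = list(dict.fromkeys(members))
            sets.append(GeneSet(name=name, genes=tuple(uniq)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def read_expression_matrix(path: str | Path, log_scale: bool = False) -> ExpressionMatrix:
    """Parse a genes-by-samples TSV (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene row {dup!r} in {path}")
    return ExpressionMatrix(df, log_scale=log_scale)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def write_newick(tree, path: str | Path) -> None:
    """Write a Newick string (or any object with a ``newick`` attribute)."""
    newick = getattr(tree, "newick", tree)
    if not isinstance(newick, str):
        raise TypeError("expected a Newick string or an object with a .newick attribute")
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def write_table(records, path: str | Path) -> None:
    """Write records (DataFrame or iterable of mappings) as a headered TSV."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
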