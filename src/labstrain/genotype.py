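"""Multi-locus genotypes: allele calling, binary encoding, diversity, typing.

SSR alleles are integer fragment sizes in bp (capillary sizing) or, for the
mononucleotide locus, the repeat-tract length; a failed amplification is a
*null allele*, a distinct allele category in its own right (``None`` in
memory, the token ``NULL`` on disk).  Genotypes are encoded as a 0/1
allele-presence matrix — one column per observed allele per locus, one 1
per locus per strain — which feeds the association-distance clustering.
MLST handling assigns sequence types (identical sequences share an ST, a
null gene is its own ST, length variants are distinct STs) and summarizes
SNPs over pre-aligned genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

NULL = None  # the null allele: no amplification product

_MISSING_RESIDUES = {"-", "N", "?", "."}


@dataclass(frozen=True)
class AlleleCall:
    locus_id: str
    allele: int | None  # bp size, MNR tract length, or None (null allele)

    def __post_init__(self) -> None:
        if self.allele is not None and (not isinstance(self.allele, (int, np.integer)) or self.allele <= 0):
            raise ValueError("allele must be a positive integer or None")


@dataclass
class StrainGenotype:
    strain_id: str
    calls: dict[str, int | None]  # locus_id -> allele (exactly one per locus)
    host: str = ""


@dataclass
class BinaryMatrix:
    """0/1 allele-presence matrix; columns are (locus, allele) pairs."""

    strain_ids: list[str]
    columns: list[tuple[str, int | None]]
    cells: np.ndarray  # shape (n_strains, n_columns), dtype int8

    @property
    def frame(self) -> pd.DataFrame:
        cols = [f"{l}:{'NULL' if a is None else a}" for l, a in self.columns]
        return pd.DataFrame(self.cells, index=self.strain_ids, columns=cols)


@dataclass
class MLSTProfile:
    strain_id: str
    gene_seqs: dict[str, str | None]
    sequence_type: dict[str, int] = field(default_factory=dict)
    combined_type: int | None = None


@dataclass(frozen=True)
class SNPSummary:
    n_snps: int
    total_bp: int

    @property
    def pct(self) -> float:
        return round(100.0 * self.n_snps / self.total_bp, 1)


# ---------------------------------------------------------------------------
# allele calling and encoding
# ---------------------------------------------------------------------------

def call_allele(locus_id: str, observation: float | None) -> AlleleCall:
    """Round a measured fragment size to an integer-bp allele.

    ``None`` (no amplification product) yields the null allele.  Rounding is
    to the nearest integer, ties up.
    """
    if observation is None:
        return AlleleCall(locus_id, NULL)
    if observation <= 0:
        raise ValueError(f"non-positive size {observation} at {locus_id}")
    return AlleleCall(locus_id, int(math.floor(observation + 0.5)))


def encode_binary(genotypes: Sequence[StrainGenotype]) -> BinaryMatrix:
    """Score every observed allele as present (1) or absent (0) per strain.

    Columns enumerate the distinct alleles observed at each locus (the null
    allele included), so the matrix width equals the summed per-locus allele
    counts and every row sums to the number of loci.
    """
    if not genotypes:
        raise ValueError("no genotypes")
    loci = list(genotypes[0].calls)
    bad = [g.strain_id for g in genotypes if set(g.calls) != set(loci)]
    if bad:
        raise ValueError(f"inconsistent locus sets for strains: {bad}")
    columns: list[tuple[str, int | None]] = []
    for locus in loci:
        alleles = {g.calls[locus] for g in genotypes}
        # numeric order, null allele last
        ordered = sorted([a for a in alleles if a is not None])
        if None in alleles:
            ordered.append(None)
        columns += [(locus, a) for a in ordered]
    col_index = {c: i for i, c in enumerate(columns)}
    cells = np.zeros((len(genotypes), len(columns)), dtype=np.int8)
    for r, g in enumerate(genotypes):
        for locus in loci:
            cells[r, col_index[(locus, g.calls[locus])]] = 1
    return BinaryMatrix([g.strain_id for g in genotypes], columns, cells)


def decode_binary(matrix: BinaryMatrix) -> list[StrainGenotype]:
    """Inverse of :func:`encode_binary` (round-trip check helper)."""
    out = []
    for r, sid in enumerate(matrix.strain_ids):
        calls: dict[str, int | None] = {}
        for c, (locus, allele) in enumerate(matrix.columns):
            if matrix.cells[r, c]:
                calls[locus] = allele
        out.append(StrainGenotype(sid, calls))
    return out


def diversity_index(calls: Iterable[int | None]) -> float:
    """Simpson-type locus diversity, D = 1 - sum_j P_j^2.

    ``P_j`` is the empirical frequency of the j-th allele among the strains;
    the null allele counts as an allele category.  D is the probability that
    two randomly drawn strains differ at the locus.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no allele calls")
    freqs = pd.Series(["NULL" if c is None else c for c in calls]).value_counts(normalize=True)
    return float(1.0 - (freqs ** 2).sum())


# ---------------------------------------------------------------------------
# type assignment
# ---------------------------------------------------------------------------

def assign_ssr_types(genotypes: Sequence[StrainGenotype]) -> tuple[dict[str, int], int]:
    """Group strains with identical multi-locus profiles into SSR types.

    Types are numbered 1.. by first occurrence.  Returns the strain -> type
    mapping and the number of distinct types.
    """
    loci = list(genotypes[0].calls) if genotypes else []
    profiles: dict[tuple, int] = {}
    assignment: dict[str, int] = {}
    for g in genotypes:
        key = tuple(g.calls[l] for l in loci)
        if key not in profiles:
            profiles[key] = len(profiles) + 1
        assignment[g.strain_id] = profiles[key]
    return assignment, len(profiles)


def assign_sequence_types(
    gene_id: str,
    seqs: Mapping[str, str | None],
) -> tuple[dict[str, int], int]:
    """Sequence types at one gene: identical sequences share an ST.

    The null allele (no product) is one ST of its own; sequences of
    different length (e.g. a large-deletion variant) are automatically
    distinct STs.  STs are numbered 1.. by first occurrence.
    """
    sts: dict[str | None, int] = {}
    assignment: dict[str, int] = {}
    for strain, seq in seqs.items():
        key = seq.upper() if isinstance(seq, str) else None
        if key not in sts:
            sts[key] = len(sts) + 1
        assignment[strain] = sts[key]
    return assignment, len(sts)


def combined_sequence_types(profiles: Sequence[MLSTProfile]) -> tuple[dict[str, int], int]:
    """Combined MLST type: the tuple of per-gene STs, numbered by occurrence."""
    seen: dict[tuple, int] = {}
    assignment: dict[str, int] = {}
    for p in profiles:
        key = tuple(p.sequence_type[g] for g in sorted(p.sequence_type))
        if key not in seen:
            seen[key] = len(seen) + 1
        assignment[p.strain_id] = seen[key]
        p.combined_type = seen[key]
    return assignment, len(seen)


# ---------------------------------------------------------------------------
# SNP summary and exclusion
# ---------------------------------------------------------------------------

def snp_summary(per_gene_alignments: Iterable[Sequence[str | None]]) -> SNPSummary:
    """Count polymorphic columns over pre-aligned gene sequence sets.

    Within each gene all non-null sequences must be equal length.  A column
    is a SNP when >= 2 distinct residues occur among its non-missing entries
    (gap/N/?/. are missing; null sequences are skipped).  ``total_bp`` sums
    the per-gene alignment lengths.
    """
    n_snps = 0
    total = 0
    for gene_seqs in per_gene_alignments:
        seqs = [s.upper() for s in gene_seqs if s is not None]
        if not seqs:
            continue
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"unaligned gene: sequence lengths {sorted(lengths)}")
        L = lengths.pop()
        total += L
        for col in range(L):
            residues = {s[col] for s in seqs} - _MISSING_RESIDUES
            if len(residues) >= 2:
                n_snps += 1
    if total == 0:
        raise ValueError("no aligned sequence")
    return SNPSummary(n_snps, total)


def exclude_untypable(profiles: Sequence[MLSTProfile]) -> tuple[list[MLSTProfile], list[MLSTProfile]]:
    """Drop strains with no product at *any* gene from the MLST analysis."""
    kept, excluded = [], []
    for p in profiles:
        (excluded if all(s is None for s in p.gene_seqs.values()) else kept).append(p)
    return kept, excluded


def repeat_count_from_size(size_bp: int, motif_len: int, flank_bp: int) -> float:
    """Convert a sized SSR allele to a repeat copy number given flank length."""
    return (size_bp - flank_bp) / motif_len
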