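"""Readers and writers for the formats the pipeline touches.

FASTA for sequences; TSV/CSV for genotype tables, peak tables, metadata and
matrices; PHYLIP square format and TSV for distance matrices; Newick for
dendrograms; BED for interval masks; JSON for ground truth and run
manifests.  Output files are staged to a temporary name and moved into
place atomically so a failed run never leaves a partial file.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotype import BinaryMatrix, StrainGenotype
from .phylo import DistanceMatrix
from .repeats import RepeatCatalog, RepeatLocus
from .trflp import PeakTable


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# atomic writing
# ---------------------------------------------------------------------------

@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temporary file and move it into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence), order preserved."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
            break
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(_io.StringIO(text), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with atomic_write(path) as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_fastas(paths: Mapping[str, str | Path], strains: Iterable[str] | None = None,
                     ) -> dict[str, dict[str, str | None]]:
    """One FASTA per gene, record ids = strain ids; absent record = null allele."""
    genes: dict[str, dict[str, str | None]] = {}
    all_strains = set(strains) if strains is not None else set()
    parsed = {g: dict(read_fasta(p)) for g, p in paths.items()}
    if strains is None:
        for recs in parsed.values():
            all_strains |= set(recs)
    for g, recs in parsed.items():
        genes[g] = {s: recs.get(s) for s in sorted(all_strains)}
    return genes


# ---------------------------------------------------------------------------
# repeat catalogs
# ---------------------------------------------------------------------------

_CATALOG_COLS = ["contig", "start", "end", "motif", "motif_len", "copies", "purity", "kind"]


def write_catalog(path: str | Path, catalog: RepeatCatalog) -> None:
    with atomic_write(path) as fh:
        fh.write("\t".join(_CATALOG_COLS) + "\n")
        for l in catalog:
            fh.write(f"{l.contig_id}\t{l.start}\t{l.end}\t{l.motif}\t{l.motif_len}"
                     f"\t{l.copies:g}\t{l.purity:.4g}\t{l.kind}\n")


def read_catalog(path: str | Path) -> RepeatCatalog:
    df = pd.read_csv(path, sep="\t")
    loci = [RepeatLocus(str(r.contig), int(r.start), int(r.end), str(r.motif),
                        int(r.motif_len), float(r.copies), float(r.purity), str(r.kind))
            for r in df.itertuples()]
    return RepeatCatalog(loci)


def write_bed(path: str | Path, catalog: RepeatCatalog) -> None:
    """BED6 export: name = motif_len x copies, score = purity * 1000."""
    with atomic_write(path) as fh:
        for l in catalog:
            name = f"({l.motif_len})_{l.copies:g}_{l.kind}"
            fh.write(f"{l.contig_id}\t{l.start}\t{l.end}\t{name}\t{int(l.purity * 1000)}\t+\n")


def read_bed_mask(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED line needs >= 3 fields")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def write_genotypes(path: str | Path, genotypes: Iterable[StrainGenotype]) -> None:
    """Strains as rows, loci as columns; null alleles as the token NULL."""
    genotypes = list(genotypes)
    loci = list(genotypes[0].calls)
    with atomic_write(path) as fh:
        fh.write("strain_id\thost\t" + "\t".join(loci) + "\n")
        for g in genotypes:
            vals = ["NULL" if g.calls[l] is None else str(g.calls[l]) for l in loci]
            fh.write(f"{g.strain_id}\t{g.host}\t" + "\t".join(vals) + "\n")


def read_genotypes(path: str | Path) -> list[StrainGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise FormatError(f"{path}: missing strain_id column")
    loci = [c for c in df.columns if c not in ("strain_id", "host")]
    out = []
    for _, row in df.iterrows():
        calls: dict[str, int | None] = {}
        for l in loci:
            v = row[l]
            calls[l] = None if (pd.isna(v) or str(v).upper() == "NULL") else int(v)
        out.append(StrainGenotype(str(row["strain_id"]), calls,
                                  host=str(row.get("host", "") or "")))
    return out


# ---------------------------------------------------------------------------
# peak tables and profiles
# ---------------------------------------------------------------------------

def read_peaks(peaks_csv: str | Path, metadata_csv: str | Path | None = None) -> list[PeakTable]:
    df = pd.read_csv(peaks_csv)
    need = {"sample_id", "size", "area"}
    if not need <= set(df.columns):
        raise FormatError(f"{peaks_csv}: needs columns {sorted(need)}")
    meta: dict[str, dict] = {}
    if metadata_csv is not None:
        m = pd.read_csv(metadata_csv)
        for _, row in m.iterrows():
            meta[str(row["sample_id"])] = {k: row[k] for k in m.columns if k != "sample_id"}
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        out.append(PeakTable(str(sid), list(zip(grp["size"], grp["area"])),
                             metadata=meta.get(str(sid), {})))
    return out


def write_profiles(path: str | Path, profiles) -> None:
    labels = list(profiles[0].abundances)
    with atomic_write(path) as fh:
        fh.write("sample_id\t" + "\t".join(labels) + "\tunassigned\n")
        for p in profiles:
            vals = [f"{p.abundances[l]:.6f}" for l in labels]
            fh.write(f"{p.sample_id}\t" + "\t".join(vals) + f"\t{p.unassigned:.6f}\n")


# ---------------------------------------------------------------------------
# matrices and trees
# ---------------------------------------------------------------------------

def write_binary_matrix(path: str | Path, bm: BinaryMatrix) -> None:
    with atomic_write(path) as fh:
        bm.frame.to_csv(fh, sep="\t", index_label="strain_id")


def write_distance_phylip(path: str | Path, dm: DistanceMatrix) -> None:
    with atomic_write(path) as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{x:.6f}" for x in dm.d[i])
            fh.write(f"{name[:10]:<10s} {row}\n")


def write_distance_tsv(path: str | Path, dm: DistanceMatrix) -> None:
    df = pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids)
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index_label="id", float_format="%.6f")


def write_newick(path: str | Path, tree) -> None:
    with atomic_write(path) as fh:
        fh.write(tree.to_newick() + "\n")


def write_tsv(path: str | Path, df: pd.DataFrame, **kwargs) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False, **kwargs)


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o, key=lambda x: (x is None, x))
        return str(o)
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=1, default=default)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
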