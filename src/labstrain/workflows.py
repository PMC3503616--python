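"""End-to-end workflows: SSR typing and MLST, with a run manifest.

``run_ssr_workflow`` chains binary allele encoding, per-locus diversity,
Nei–Li association distance, UPGMA (optionally with bootstrap), cluster
extraction and within/between distance summaries.  ``run_mlst_workflow``
chains untypable-strain exclusion, per-gene sequence typing, missing-aware
gene concatenation, SNP summary, p-distance and UPGMA.  Both return their
artifacts in memory and, when an output directory is given, write them with
a manifest recording seeds, parameters and input digests.
"""

from __future__ import annotations

import sys
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as lio
from .genotype import (
    MLSTProfile,
    StrainGenotype,
    assign_sequence_types,
    assign_ssr_types,
    combined_sequence_types,
    diversity_index,
    encode_binary,
    exclude_untypable,
    snp_summary,
)
from .phylo import (
    binary_association_distance,
    bootstrap_support,
    cluster_distance_summary,
    extract_clusters,
    p_distance,
    upgma,
)

__version__ = "0.1.0"


def _manifest(stage: str, seed: int | None, params: dict, inputs: Mapping[str, str] = {}) -> dict:
    return {
        "tool": f"labstrain {__version__}",
        "stage": stage,
        "command": " ".join(sys.argv),
        "seed": seed,
        "parameters": params,
        "input_digests": dict(inputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _stage(name):
    """Re-raise stage errors with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, et, ev, tb):
            if et is not None and issubclass(et, Exception):
                raise RuntimeError(f"[{name}] {ev}") from ev
            return False
    return _Ctx()


def run_ssr_workflow(
    genotypes: Sequence[StrainGenotype],
    k: int = 3,
    n_bootstrap: int = 1000,
    seed: int = 0,
    distance_method: str = "neili",
    out_dir: str | Path | None = None,
    cluster_ids: Sequence[str] | None = None,
) -> dict:
    """SSR branch: genotypes -> binary matrix -> distances -> dendrogram.

    ``cluster_ids`` restricts cluster extraction and distance summaries to a
    subset of strains (e.g. excluding singleton isolates); the tree itself
    always carries every strain.  Returns a dict with the binary matrix,
    diversity table, distance matrix, tree, SSR types, cluster assignment
    and per-cluster distance summaries.
    """
    with _stage("encode"):
        bm = encode_binary(genotypes)
        loci = list(genotypes[0].calls)
        div = pd.DataFrame({
            "locus": loci,
            "n_alleles": [len({g.calls[l] for g in genotypes}) for l in loci],
            "diversity_index": [round(diversity_index([g.calls[l] for g in genotypes]), 2)
                                for l in loci],
        })
        types, n_types = assign_ssr_types(genotypes)
    with _stage("distance"):
        dm = binary_association_distance(bm, method=distance_method)
    with _stage("tree"):
        if n_bootstrap > 0:
            tree = bootstrap_support(bm, n_reps=n_bootstrap, seed=seed,
                                     method=distance_method)
        else:
            tree = upgma(dm)
    with _stage("clusters"):
        sub_ids = list(cluster_ids) if cluster_ids is not None else list(bm.strain_ids)
        if k > len(sub_ids):
            raise ValueError(f"k={k} exceeds {len(sub_ids)} strains")
        sub_dm = dm.submatrix(sub_ids)
        clusters = extract_clusters(upgma(sub_dm), k=k) if cluster_ids is not None \
            else extract_clusters(tree, k=k)
        summaries = []
        for label in sorted(set(clusters.values())):
            members = [s for s, c in clusters.items() if c == label]
            if len(members) >= 2:
                summaries.append(cluster_distance_summary(sub_dm, members, label=str(label)))
    result = {
        "binary_matrix": bm, "diversity": div, "distance": dm, "tree": tree,
        "ssr_types": types, "n_ssr_types": n_types,
        "clusters": clusters, "summaries": summaries,
    }
    if out_dir is not None:
        out = Path(out_dir)
        lio.write_binary_matrix(out / "binary_matrix.tsv", bm)
        lio.write_tsv(out / "diversity.tsv", div)
        lio.write_distance_phylip(out / "distance.phy", dm)
        lio.write_distance_tsv(out / "distance.tsv", dm)
        lio.write_newick(out / "tree.nwk", tree)
        lio.write_tsv(out / "ssr_types.tsv",
                      pd.DataFrame({"strain_id": list(types), "ssr_type": list(types.values())}))
        lio.write_tsv(out / "clusters.tsv",
                      pd.DataFrame({"strain_id": list(clusters), "cluster": list(clusters.values())}))
        lio.write_tsv(out / "cluster_summary.tsv", pd.DataFrame([{
            "cluster": s.label, "n": len(s.members),
            "within_mean": round(s.within_mean, 4), "within_sd": round(s.within_sd, 4),
            "between_mean": round(s.between_mean, 4), "between_sd": round(s.between_sd, 4),
        } for s in summaries]))
        lio.write_json(out / "manifest.json", _manifest(
            "run-ssr", seed,
            dict(k=k, n_bootstrap=n_bootstrap, distance=distance_method,
                 n_strains=len(genotypes))))
    return result


def concatenate_genes(
    gene_seqs: Mapping[str, Mapping[str, str | None]],
    strains: Sequence[str],
) -> dict[str, str]:
    """Missing-aware concatenation: a null gene becomes an all-gap block.

    Keeps partially typed strains (e.g. deletion variants re-padded per
    gene) in one alignment.  Within a gene, all non-null sequences must
    share one length.
    """
    concat = {s: [] for s in strains}
    for gid in gene_seqs:
        seqs = gene_seqs[gid]
        lengths = {len(x) for x in seqs.values() if x is not None}
        if len(lengths) > 1:
            raise ValueError(f"gene {gid}: unaligned lengths {sorted(lengths)}")
        L = lengths.pop() if lengths else 0
        for s in strains:
            x = seqs.get(s)
            concat[s].append(x if x is not None else "-" * L)
    return {s: "".join(parts) for s, parts in concat.items()}


def run_mlst_workflow(
    gene_seqs: Mapping[str, Mapping[str, str | None]],
    n_bootstrap: int = 1000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """MLST branch: gene sequences -> sequence types -> p-distance -> tree.

    Strains with no product at any gene are excluded up front (and listed);
    null alleles at single genes stay in as their own sequence type and as
    all-missing blocks in the concatenated alignment.
    """
    if not gene_seqs:
        raise ValueError("need >= 1 gene")
    strains = sorted({s for g in gene_seqs.values() for s in g})
    profiles = [MLSTProfile(s, {g: gene_seqs[g].get(s) for g in gene_seqs}) for s in strains]
    with _stage("exclude"):
        kept, excluded = exclude_untypable(profiles)
    with _stage("sequence-types"):
        st_counts = {}
        for gid in gene_seqs:
            st, n_st = assign_sequence_types(gid, {p.strain_id: p.gene_seqs[gid] for p in kept})
            st_counts[gid] = n_st
            for p in kept:
                p.sequence_type[gid] = st[p.strain_id]
        combined, n_combined = combined_sequence_types(kept)
    with _stage("snp-summary"):
        snps = snp_summary([[p.gene_seqs[g] for p in kept] for g in gene_seqs])
    with _stage("distance"):
        kept_ids = [p.strain_id for p in kept]
        concat = concatenate_genes(gene_seqs, kept_ids)
        dm = p_distance(concat)
    with _stage("tree"):
        if n_bootstrap > 0:
            tree = bootstrap_support(concat, n_reps=n_bootstrap, seed=seed)
        else:
            tree = upgma(dm)
    result = {
        "profiles": kept, "excluded": [p.strain_id for p in excluded],
        "st_counts": st_counts, "combined_types": combined, "n_combined_types": n_combined,
        "snp_summary": snps, "distance": dm, "tree": tree,
    }
    if out_dir is not None:
        out = Path(out_dir)
        st_df = pd.DataFrame([
            {"strain_id": p.strain_id,
             **{g: p.sequence_type[g] for g in gene_seqs},
             "combined_type": p.combined_type}
            for p in kept
        ])
        lio.write_tsv(out / "sequence_types.tsv", st_df)
        lio.write_tsv(out / "exclusions.tsv",
                      pd.DataFrame({"strain_id": result["excluded"]}))
        lio.write_json(out / "snp_summary.json",
                       {"n_snps": snps.n_snps, "total_bp": snps.total_bp, "pct": snps.pct})
        lio.write_distance_phylip(out / "distance.phy", dm)
        lio.write_newick(out / "tree.nwk", tree)
        lio.write_json(out / "manifest.json", _manifest(
            "run-mlst", seed,
            dict(n_bootstrap=n_bootstrap, genes=list(gene_seqs), n_strains=len(kept))))
    return result


def anova_table(profiles, grouping, labels) -> pd.DataFrame:
    """Per-peak one-way ANOVA results as a tidy table."""
    from .trflp import peak_group_anova
    rows = []
    for label in labels:
        r = peak_group_anova(profiles, grouping, label)
        rows.append({"peak": r.peak_label, "F": round(r.F, 4), "p": r.p,
                     "df_between": r.df_between, "df_within": r.df_within})
    return pd.DataFrame(rows)
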