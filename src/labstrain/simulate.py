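"""Synthetic data for every pipeline stage, with ground truth.

The generator emulates a host-specificity strain-typing study at desk
scale: a bacterial reference genome carrying a known set of planted tandem
repeats; a population of ~47 strains drawn from a few host-specific founder
populations (plus scattered singleton isolates) typed at 11 SSR loci with
occasional null alleles and at three conserved genes with ~12 % polymorphic
sites; and a fecal-community tRFLP cohort with four recurring species peaks
whose abundance is shifted in one host taxonomic group.

SSR alleles evolve by a symmetric stepwise random walk on repeat copy
number (±1 copy per step, Poisson-distributed step counts) — the standard
abstraction for SSR mutation.  Cluster structure is founder-based: each
host group descends from one founder genotype, with founders spaced
``founder_divergence`` copy-number steps apart, which is sufficient for
recovery testing without a coalescent model.

Everything is driven by one seeded generator: identical configuration
(seed included) reproduces identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype import StrainGenotype
from .repeats import RepeatLocus, screen_genome

_BASES = np.array(list("ACGT"))

# Table-2-like default plant: eleven typing loci (motif size, copies,
# purity) spanning 480 bp down to a mononucleotide tract, plus one
# non-perfect array.
DEFAULT_PLANTED: tuple[tuple[int, float, float], ...] = (
    (480, 3, 1.0), (90, 9, 1.0), (66, 7, 1.0), (27, 6, 1.0), (18, 3, 1.0),
    (12, 4, 1.0), (9, 3, 1.0), (6, 7, 1.0), (6, 3, 1.0), (3, 5, 1.0),
    (1, 11, 1.0), (15, 4, 0.8),
)

DEFAULT_LOCUS_IDS = ("LJ480", "LJ90", "LJ66", "LJ27", "LJ18", "LJ12",
                     "LJ9", "LJ6", "LJ6_1", "LJ3", "LJ_mono")

DEFAULT_SPECIES: tuple[tuple[str, float], ...] = (
    ("74", 74.0), ("181", 181.0), ("189", 189.0), ("566", 566.0),
)
# Dirichlet base concentrations: a dominant enterococcal peak (74), a rare
# lactobacillus (181) and two intermediate species.
DEFAULT_ALPHA: tuple[float, ...] = (5.0, 1.0, 2.0, 2.0)


@dataclass
class GeneratorConfig:
    seed: int = 0
    # genome
    genome_length: int = 50_000
    planted_repeats: Sequence[tuple[int, float, float]] = DEFAULT_PLANTED
    scrub_background: bool = True
    # strain population
    n_hosts: int = 3
    strains_per_host: int = 13
    n_singletons: int = 8
    ssr_loci: int = 11
    founder_divergence: int = 6
    within_host_steps: float = 0.2
    null_rate: float = 0.05
    genes: Sequence[int] = (1113, 522, 286)
    between_snp_frac: float = 0.01
    within_snp_frac: float = 0.0003
    # tRFLP cohort
    trflp_species: Sequence[tuple[str, float]] = DEFAULT_SPECIES
    group_effect: float = 1.0
    n_samples: int = 50
    area_noise: float = 0.2

    @property
    def n_strains(self) -> int:
        return self.n_hosts * self.strains_per_host + self.n_singletons


@dataclass
class SyntheticTruth:
    """Ground truth of one generator run (only relevant parts populated)."""

    cluster_of: dict[str, str | None] = field(default_factory=dict)
    planted_loci: list[RepeatLocus] = field(default_factory=list)
    allele_sets: dict[str, set] = field(default_factory=dict)
    sample_group: dict[str, str] = field(default_factory=dict)
    true_abundance: dict[str, list[float]] = field(default_factory=dict)
    shifted_species: tuple[str, str] | None = None  # (down, up) in affected group


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _primitive_motif(rng: np.random.Generator, p: int) -> str:
    from .repeats import _is_primitive
    while True:
        m = "".join(_random_seq(rng, p))
        if p == 1 or _is_primitive(m):
            return m


def _build_array(rng: np.random.Generator, motif: str, copies: float, purity: float) -> str:
    p = len(motif)
    full = int(copies)
    frac = int(round((copies - full) * p))
    text = list(motif * full)
    if purity < 1.0:
        # spread mutations one per column so the consensus stays the motif
        n_mut = int(round((1 - purity) * p * full))
        n_mut = min(n_mut, p)
        cols = rng.permutation(p)[:n_mut]
        per_copy = np.array_split(cols, max(full - 1, 1))
        for k, copy_cols in enumerate(per_copy, start=1):
            if k >= full:
                break
            for c in copy_cols:
                orig = motif[c]
                alt = rng.choice([b for b in "ACGT" if b != orig])
                text[k * p + c] = alt
    return "".join(text) + motif[:frac]


def make_reference_genome(cfg: GeneratorConfig) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Uniform-background genome with planted repeats at known positions.

    Background positions that happen to form detectable repeats of their own
    are broken by single-base edits (when ``scrub_background``), so that the
    screen recovers exactly the planted catalog; the planting is retried
    with fresh randomness if an attempt cannot be cleaned up.
    """
    total_planted = sum(int(round(p * c)) + 2 for p, c, _ in cfg.planted_repeats)
    if cfg.genome_length <= total_planted:
        raise ValueError("genome_length too small for the planted repeats")
    rng = np.random.default_rng(cfg.seed)
    for _attempt in range(20):
        result = _try_make_genome(cfg, rng)
        if result is not None:
            return result
    raise RuntimeError("could not realize a clean genome in 20 attempts")


def _try_make_genome(cfg, rng):
    n = cfg.genome_length
    g = _random_seq(rng, n)
    # non-overlapping placement, left to right with random gaps
    sizes = [int(round(p * c)) for p, c, _ in cfg.planted_repeats]
    margin = 25
    free = n - sum(sizes) - 2 * margin * len(sizes)
    if free <= 0:
        raise ValueError("genome_length too small for the planted repeats")
    gaps = rng.multinomial(free, np.ones(len(sizes) + 1) / (len(sizes) + 1))
    planted: list[RepeatLocus] = []
    pos = 0
    for (p, c, purity), size, gap in zip(cfg.planted_repeats, sizes, gaps):
        pos += int(gap) + margin
        motif = _primitive_motif(rng, p)
        text = _build_array(rng, motif, c, purity)
        g[pos : pos + size] = list(text)
        # guard bases so the array does not extend into the flanks
        g[pos - 1] = rng.choice([b for b in "ACGT" if b != text[p - 1] and b != text[0]])
        if pos + size < n:
            g[pos + size] = rng.choice([b for b in "ACGT" if b != text[size - p] and b != text[size - 1]])
        kind = "mnr" if p == 1 else ("perfect" if purity == 1.0 else "nonperfect")
        planted.append(RepeatLocus("chr", pos, pos + size, motif, p, float(c),
                                   purity if purity < 1 else 1.0, kind))
        pos += size + margin
    planted_spans = [(l.start, l.end) for l in planted]

    def is_planted(loc: RepeatLocus) -> bool:
        return any(loc.start == s and loc.end == e for s, e in planted_spans)

    def pm_screen(text: str) -> list[RepeatLocus]:
        # background cleanup targets perfect/MNR loci only: short arrays that
        # clear the 70 % NP-similarity bar occur throughout random DNA and
        # are genuine detections, not noise to remove
        from .repeats import find_mnr, find_perfect_ssr
        return find_mnr(text, contig_id="chr") + find_perfect_ssr(text, contig_id="chr")

    if cfg.scrub_background:
        for _round in range(12):
            catalog = pm_screen("".join(g))
            extras = [l for l in catalog if not is_planted(l)]
            if not extras:
                break
            progress = False
            for loc in extras:
                if any(loc.start < e and s < loc.end for s, e in planted_spans):
                    continue  # overlaps a planted locus: cannot edit, retry genome
                mid = (loc.start + loc.end) // 2
                old = g[mid]
                forbid = {str(old)}
                for off in (loc.motif_len, -loc.motif_len, 1, -1):
                    if 0 <= mid + off < n:
                        forbid.add(str(g[mid + off]))
                choices = [b for b in "ACGT" if b not in forbid]
                if choices:
                    g[mid] = rng.choice(choices)
                    progress = True
            if not progress:
                return None
        else:
            return None
        catalog = screen_genome([("chr", "".join(g))], genome_id="synthetic")
        found_pm = {(l.start, l.end, l.motif_len) for l in catalog
                    if l.kind in ("perfect", "mnr")}
        want_pm = {(l.start, l.end, l.motif_len) for l in planted
                   if l.kind in ("perfect", "mnr")}
        if found_pm != want_pm:
            return None
        found_np = {(l.start, l.end, l.motif_len) for l in catalog if l.kind == "nonperfect"}
        if not all((l.start, l.end, l.motif_len) in found_np
                   for l in planted if l.kind == "nonperfect"):
            return None
    truth = SyntheticTruth(planted_loci=planted)
    return [("chr", "".join(g))], truth


# ---------------------------------------------------------------------------
# strain population
# ---------------------------------------------------------------------------

_HOST_NAMES = ("chicken", "human", "mouse", "turkey", "rat", "hamster")
_SINGLETON_HOSTS = ("dog", "calf", "peacock", "silkworm", "owl", "caracal",
                    "psammomys", "cheese")


def _step_walk(rng: np.random.Generator, expected_steps: float) -> int:
    """Net displacement of a symmetric ±1 stepwise walk (Poisson #steps)."""
    n = rng.poisson(expected_steps)
    if n == 0:
        return 0
    return int(rng.integers(0, 2, size=n).sum() * 2 - n)


def _mutate_seq(rng: np.random.Generator, seq: np.ndarray, n_sites: int) -> np.ndarray:
    out = seq.copy()
    if n_sites <= 0:
        return out
    sites = rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False)
    for s in sites:
        out[s] = rng.choice([b for b in "ACGT" if b != out[s]])
    return out


def simulate_strain_population(
    cfg: GeneratorConfig,
) -> tuple[list[StrainGenotype], dict[str, dict[str, str | None]], SyntheticTruth]:
    """Host-structured multi-locus genotypes and per-gene sequences.

    Returns (genotypes, gene_seqs, truth) where ``gene_seqs`` maps
    gene id -> {strain id -> sequence}.  Allele sizes are
    flank + motif_len * copy_number for SSR loci and the tract length itself
    for the mononucleotide locus; null alleles appear at a per-locus rate.
    """
    if cfg.n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    loci = [r for r in cfg.planted_repeats if r[2] == 1.0][: cfg.ssr_loci]
    if len(loci) < cfg.ssr_loci:
        raise ValueError("not enough perfect planted repeats for the typing loci")
    locus_ids = list(DEFAULT_LOCUS_IDS[: cfg.ssr_loci]) if cfg.ssr_loci <= len(DEFAULT_LOCUS_IDS) \
        else [f"LOC{i}" for i in range(cfg.ssr_loci)]
    flanks = {lid: int(rng.integers(60, 200)) for lid in locus_ids}
    null_p = {lid: cfg.null_rate for lid in locus_ids}

    base_counts = {lid: max(3, int(round(c))) for lid, (p, c, _) in zip(locus_ids, loci)}
    motif_lens = {lid: p for lid, (p, c, _) in zip(locus_ids, loci)}

    def allele(lid: str, count: int) -> int:
        count = max(1, count)
        if motif_lens[lid] == 1:
            return count  # MNR: tract length, sequenced not sized
        return flanks[lid] + motif_lens[lid] * count

    hosts = [_HOST_NAMES[h % len(_HOST_NAMES)] for h in range(cfg.n_hosts)]
    founder_counts = {
        lid: [base_counts[lid] + f * cfg.founder_divergence for f in range(cfg.n_hosts)]
        for lid in locus_ids
    }

    genotypes: list[StrainGenotype] = []
    truth = SyntheticTruth()
    truth.allele_sets = {lid: set() for lid in locus_ids}

    def add_strain(sid: str, host: str, counts: dict[str, int], cluster: str | None):
        calls: dict[str, int | None] = {}
        for lid in locus_ids:
            if rng.random() < null_p[lid]:
                calls[lid] = None
            else:
                calls[lid] = allele(lid, counts[lid])
            truth.allele_sets[lid].add(calls[lid])
        genotypes.append(StrainGenotype(sid, calls, host=host))
        truth.cluster_of[sid] = cluster

    k = 0
    member_counts: dict[str, dict[str, int]] = {}
    for h, host in enumerate(hosts):
        for _ in range(cfg.strains_per_host):
            sid = f"LJ_{k:03d}"
            k += 1
            counts = {
                lid: founder_counts[lid][h] + _step_walk(rng, cfg.within_host_steps)
                for lid in locus_ids
            }
            member_counts[sid] = counts
            add_strain(sid, host, counts, host)
    for s in range(cfg.n_singletons):
        sid = f"LJ_{k:03d}"
        k += 1
        host = _SINGLETON_HOSTS[s % len(_SINGLETON_HOSTS)]
        # singletons are per-locus mosaics of the founder lattice: roughly
        # equidistant from every host cluster, so they spread out in the tree
        counts = {
            lid: founder_counts[lid][int(rng.integers(0, cfg.n_hosts))]
            + _step_walk(rng, cfg.within_host_steps)
            for lid in locus_ids
        }
        member_counts[sid] = counts
        add_strain(sid, host, counts, None)

    # conserved genes: founder sequences diverged between hosts, members
    # mutated within hosts; singletons get independent founder-level draws
    gene_seqs: dict[str, dict[str, str | None]] = {}
    for gi, L in enumerate(cfg.genes):
        gid = f"gene{gi}"
        root = _random_seq(rng, L)
        founder_seqs = [
            _mutate_seq(rng, root, int(round(cfg.between_snp_frac * L))) for _ in hosts
        ]
        seqs: dict[str, str | None] = {}
        for g in genotypes:
            cluster = truth.cluster_of[g.strain_id]
            if cluster is not None:
                base = founder_seqs[hosts.index(cluster)]
            else:
                base = _mutate_seq(rng, root, int(round(cfg.between_snp_frac * L)))
            n_within = rng.poisson(cfg.within_snp_frac * L)
            seqs[g.strain_id] = "".join(_mutate_seq(rng, base, n_within))
        gene_seqs[gid] = seqs
    return genotypes, gene_seqs, truth


# ---------------------------------------------------------------------------
# tRFLP cohort
# ---------------------------------------------------------------------------

_ORDERS = ("Rodentia", "Carnivora", "Galliformes", "Primates", "Artiodactyla")
_DIETS = ("herbivore", "omnivore", "carnivore")
_LOCATIONS = ("north", "center", "south")


def simulate_trflp_cohort(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Fecal-community peak tables for a cohort of host individuals.

    Per sample, a true abundance vector over the reference species is drawn
    from a Dirichlet whose concentrations are shifted in the affected host
    group (``Rodentia``): the dominant species is shifted down and the rare
    one up by a factor ``exp(group_effect)`` — the abundance opposition
    between two species competing for one niche.  Peak sizes are jittered
    within ±1 bp and areas carry multiplicative lognormal noise.

    Returns (peaks, metadata, truth): peaks has columns
    ``sample_id,size,area``; metadata has
    ``sample_id,host_species,tax_order,diet,location``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    labels = [l for l, _ in cfg.trflp_species]
    sizes = {l: s for l, s in cfg.trflp_species}
    alpha0 = np.array(DEFAULT_ALPHA[: len(labels)], dtype=float)
    if len(alpha0) < len(labels):
        alpha0 = np.concatenate([alpha0, np.ones(len(labels) - len(alpha0))])
    down, up = labels[0], labels[1 % len(labels)]
    if cfg.group_effect > 0 and cfg.n_samples < 4:
        raise ValueError("need >= 4 samples for a group contrast")

    peak_rows = []
    meta_rows = []
    truth = SyntheticTruth(shifted_species=(down, up))
    for i in range(cfg.n_samples):
        sid = f"S{i:03d}"
        order = _ORDERS[int(rng.integers(0, len(_ORDERS)))] if cfg.group_effect == 0 \
            else ("Rodentia" if i < max(2, int(0.3 * cfg.n_samples)) else
                  _ORDERS[1 + int(rng.integers(0, len(_ORDERS) - 1))])
        if cfg.group_effect == 0:
            # balanced two-group design for null calibration
            order = "Rodentia" if i % 2 == 0 else "Carnivora"
        alpha = alpha0.copy()
        if order == "Rodentia" and cfg.group_effect > 0:
            # shift concentration from the dominant to the rare species while
            # keeping the pair total (hence every other species' marginal,
            # by Dirichlet aggregation) unchanged
            i_d, i_u = labels.index(down), labels.index(up)
            pair = alpha[i_d] + alpha[i_u]
            w = alpha[i_d] * np.exp(-cfg.group_effect)
            v = alpha[i_u] * np.exp(cfg.group_effect)
            alpha[i_d] = pair * w / (w + v)
            alpha[i_u] = pair * v / (w + v)
        abund = rng.dirichlet(alpha)
        truth.sample_group[sid] = order
        truth.true_abundance[sid] = [float(a) for a in abund]
        total = float(rng.lognormal(np.log(50_000), 0.3))
        for l, a in zip(labels, abund):
            size = sizes[l] + float(rng.uniform(-1, 1))
            area = a * total * float(rng.lognormal(0.0, cfg.area_noise))
            peak_rows.append((sid, round(size, 2), round(area, 2)))
        meta_rows.append((
            sid, f"species_{int(rng.integers(0, 20)):02d}", order,
            _DIETS[int(rng.integers(0, 3))], _LOCATIONS[int(rng.integers(0, 3))],
        ))
    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "size", "area"])
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "host_species",
                                            "tax_order", "diet", "location"])
    return peaks, meta, truth
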