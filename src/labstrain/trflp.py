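"""In-silico tRFLP and analysis of community peak tables.

Terminal restriction fragment length polymorphism (tRFLP) profiles a
bacterial community by the length of the restriction fragment that carries
the fluorescently labeled PCR primer: only the terminal fragment is seen by
the capillary sizer.  This module predicts terminal fragment lengths from
template sequences (primer-site location with a 3'-anchored match, then
digestion, MspI ``C^CGG`` by default) and turns measured peak tables into
relative-abundance profiles, discretized abundance matrices and per-peak
one-way ANOVAs across host groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PrimerMatch:
    position: int          # 0-based start of the binding site on the template
    strand: str            # "forward" | "reverse"
    mismatches: int


@dataclass(frozen=True)
class TerminalFragment:
    length: int
    uncut: bool = False    # no recognition site before the amplicon end


@dataclass
class PeakTable:
    sample_id: str
    peaks: list[tuple[float, float]]           # (size bp, area)
    metadata: dict = field(default_factory=dict)


@dataclass
class TRFLPProfile:
    sample_id: str
    abundances: dict[str, float]               # reference label -> rel. abundance
    unassigned: float
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroupTestResult:
    peak_label: str
    F: float
    p: float
    df_between: int
    df_within: int


# ---------------------------------------------------------------------------
# primer matching and digestion
# ---------------------------------------------------------------------------

def _mismatches_at(template: str, primer: str, pos: int) -> int:
    m = 0
    for off, sym in enumerate(primer):
        if template[pos + off] not in _IUPAC[sym]:
            m += 1
    return m


def find_primer_site(template: str, primer: str, max_mismatch: int = 2) -> PrimerMatch | None:
    """Best (fewest-mismatch) primer binding site on either strand.

    The 3'-terminal base of the primer must match exactly — the anchor that
    makes a species-specific primer specific.  Ties prefer the forward
    strand, then the leftmost position.  Returns ``None`` if no site has
    <= ``max_mismatch`` mismatches.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 bases")
    bad = set(primer) - set(_IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC symbols in primer: {sorted(bad)}")
    template = template.upper()
    best: PrimerMatch | None = None
    for strand, tpl in (("forward", template), ("reverse", reverse_complement(template))):
        for pos in range(len(tpl) - len(primer) + 1):
            if tpl[pos + len(primer) - 1] not in _IUPAC[primer[-1]]:
                continue  # 3'-anchor rule
            m = _mismatches_at(tpl, primer, pos)
            if m > max_mismatch:
                continue
            if strand == "reverse":
                # report coordinates on the input template
                pos_t = len(template) - (pos + len(primer))
            else:
                pos_t = pos
            cand = PrimerMatch(pos_t, strand, m)
            if best is None or m < best.mismatches:
                best = cand
    return best


def terminal_fragment_length(
    template: str,
    fwd_primer: str,
    site: str = "CCGG",
    cut_offset: int = 1,
    rev_primer: str | None = None,
    max_mismatch: int = 2,
) -> TerminalFragment | None:
    """Length of the labeled terminal fragment after restriction digestion.

    Measured from the 5' end of the forward-primer binding site to the first
    cut downstream on the labeled strand; the cut falls ``cut_offset`` bases
    into the recognition site (MspI ``C^CGG`` => offset 1).  Without any site
    before the amplicon end the full amplicon length is returned, flagged
    ``uncut``.  The amplicon ends at the reverse primer's binding site when
    one is given, else at the template end.  Returns ``None`` when the
    forward primer does not bind.
    """
    template = template.upper()
    match = find_primer_site(template, fwd_primer, max_mismatch)
    if match is None:
        return None
    if match.strand == "reverse":
        template = reverse_complement(template)
        match = find_primer_site(template, fwd_primer, max_mismatch)
        assert match is not None and match.strand == "forward"
    start = match.position
    end = len(template)
    if rev_primer is not None:
        rc = reverse_complement(rev_primer.upper())
        hit = template.find(rc, start)
        if hit != -1:
            end = hit + len(rc)
    amplicon = template[start:end]
    cut = amplicon.find(site)
    if cut == -1 or cut + cut_offset > len(amplicon):
        return TerminalFragment(len(amplicon), uncut=True)
    return TerminalFragment(cut + cut_offset, uncut=False)


# ---------------------------------------------------------------------------
# peak tables -> profiles
# ---------------------------------------------------------------------------

def profile_from_peaks(
    peaks: PeakTable,
    reference: Mapping[str, float],
    tolerance: float = 2.0,
) -> TRFLPProfile:
    """Relative abundance of each reference peak in one sample.

    Every peak is assigned to the nearest reference size within
    ``tolerance`` bp (else it stays unassigned); abundances are peak areas
    over the total area of *all* peaks, so assigned + unassigned sum to 1.
    """
    total = sum(a for _, a in peaks.peaks)
    if total <= 0:
        raise ValueError(f"sample {peaks.sample_id}: total peak area is zero")
    if any(a < 0 for _, a in peaks.peaks):
        raise ValueError(f"sample {peaks.sample_id}: negative peak area")
    abund = {label: 0.0 for label in reference}
    unassigned = 0.0
    for size, area in peaks.peaks:
        label = min(reference, key=lambda l: abs(reference[l] - size), default=None)
        if label is not None and abs(reference[label] - size) <= tolerance:
            abund[label] += area / total
        else:
            unassigned += area / total
    return TRFLPProfile(peaks.sample_id, abund, unassigned, dict(peaks.metadata))


def abundance_matrix(
    profiles: Iterable[TRFLPProfile],
    levels: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x reference-peaks abundance matrix, real and discretized.

    The discretized copy uses ``levels`` equal-width bins on [0, 1]:
    level 1 covers [0, 1/levels) and the top level includes 1.0 — the
    shading scheme of a banded community heatmap.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    labels = list(profiles[0].abundances)
    real = pd.DataFrame(
        [[p.abundances.get(l, 0.0) for l in labels] for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=labels,
    )
    codes = np.minimum(np.floor(real.to_numpy() * levels).astype(int) + 1, levels)
    return real, pd.DataFrame(codes, index=real.index, columns=real.columns)


def peak_group_anova(
    profiles: Iterable[TRFLPProfile],
    grouping: Mapping[str, str],
    peak_label: str,
) -> GroupTestResult:
    """One-way ANOVA of one peak's relative abundance across host groups.

    Each peak is analyzed separately; ``grouping`` maps sample id to a group
    label (e.g. host taxonomic order).  Groups need >= 2 samples each.
    """
    by_group: dict[str, list[float]] = {}
    for p in profiles:
        if p.sample_id not in grouping:
            continue
        if peak_label not in p.abundances:
            raise KeyError(f"peak {peak_label!r} not in profile {p.sample_id}")
        by_group.setdefault(grouping[p.sample_id], []).append(p.abundances[peak_label])
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    arrays = [np.asarray(v) for v in by_group.values()]
    F, p = stats.f_oneway(*arrays)
    df_b = len(arrays) - 1
    df_w = sum(len(a) for a in arrays) - len(arrays)
    return GroupTestResult(peak_label, float(F), float(p), df_b, df_w)
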