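"""Genome-wide detection of tandem repeats (SSR / VNTR loci).

Three finders cover the repeat classes used for bacterial strain typing:

* mononucleotide repeats (MNR): runs of a single base, length >= 6 bp;
* perfect SSRs: exact tandem arrays with a primitive motif of >= 3 bp
  repeated at least three times (a trailing partial copy is allowed and
  counted fractionally);
* non-perfect SSRs (NP-SSR): tandem arrays whose copies are each at least
  70 % identical (ungapped) to the array consensus.

All coordinates are 0-based half-open.  ``N`` bases break arrays: an
ambiguous base cannot support a repeat claim.  Arrays are reported once, at
their primitive period and leftmost phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

_VALID = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatLocus:
    """A detected tandem repeat.

    ``copies`` may be fractional when a perfect array ends in a partial
    motif copy; ``end - start == round(motif_len * copies)`` always holds.
    ``purity`` is the mean ungapped identity of the copies to the array
    consensus (1.0 for perfect arrays and MNRs).
    """

    contig_id: str
    start: int
    end: int
    motif: str
    motif_len: int
    copies: float
    purity: float
    kind: str  # "perfect" | "nonperfect" | "mnr"

    def __post_init__(self) -> None:
        if self.end - self.start != round(self.motif_len * self.copies):
            raise ValueError("span inconsistent with motif_len * copies")
        if self.kind not in ("perfect", "nonperfect", "mnr"):
            raise ValueError(f"unknown repeat kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatCatalog:
    """Position-sorted, deduplicated union of repeat loci over a genome."""

    loci: list[RepeatLocus]
    genome_id: str = ""
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)


def _check_seq(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return seq


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


# ---------------------------------------------------------------------------
# mononucleotide repeats
# ---------------------------------------------------------------------------

def find_mnr(seq: str, min_len: int = 6, contig_id: str = "") -> list[RepeatLocus]:
    """Report every maximal single-base run of length >= ``min_len``.

    Runs of ``N`` are never reported.
    """
    seq = _check_seq(seq)
    out: list[RepeatLocus] = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] != "N":
            out.append(RepeatLocus(contig_id, i, j, seq[i], 1, float(j - i), 1.0, "mnr"))
        i = j
    return out


# ---------------------------------------------------------------------------
# perfect SSRs
# ---------------------------------------------------------------------------

def find_perfect_ssr(
    seq: str,
    min_motif: int = 3,
    max_motif: int = 500,
    min_copies: int = 3,
    contig_id: str = "",
) -> list[RepeatLocus]:
    """Report maximal perfect tandem arrays.

    An array qualifies when its primitive motif length lies in
    ``[min_motif, max_motif]`` and it contains at least ``min_copies`` full
    copies; a trailing partial copy extends the span and makes ``copies``
    fractional.  Each array is reported once, at its primitive period.
    """
    if min_motif < 2:
        raise ValueError("min_motif must be >= 2")
    if max_motif < min_motif:
        raise ValueError("max_motif must be >= min_motif")
    seq = _check_seq(seq)
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out: list[RepeatLocus] = []
    for p in range(min_motif, min(max_motif, n // min_copies) + 1):
        eq = (arr[p:] == arr[:-p]) & (arr[p:] != b"N") & (arr[:-p] != b"N")
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive in eq-space
        for s, e in zip(starts, ends):
            length = int(e - s) + p  # array span length
            if length // p < min_copies:
                continue
            motif = seq[s : s + p]
            if not _is_primitive(motif):
                continue
            out.append(
                RepeatLocus(contig_id, int(s), int(s) + length, motif, p,
                            length / p, 1.0, "perfect")
            )
    out.sort(key=lambda l: (l.start, l.end, l.motif_len))
    return out


# ---------------------------------------------------------------------------
# non-perfect SSRs
# ---------------------------------------------------------------------------

def _consensus(windows: list[str]) -> str:
    """Column-wise majority consensus; ties broken in A<C<G<T order."""
    cols = []
    for i in range(len(windows[0])):
        counts: dict[str, int] = {}
        for w in windows:
            counts[w[i]] = counts.get(w[i], 0) + 1
        best = max(sorted(counts), key=lambda b: counts[b])
        cols.append(best)
    return "".join(cols)


def _np_needed(p: int, min_similarity: float) -> int:
    """Matches per window needed for identity strictly above the threshold."""
    return int(np.floor(min_similarity * p + 1e-9)) + 1


def _validate_np(seq: str, s: int, p: int, c: int, min_similarity: float):
    """Check the (s, p, c) candidate; return (purity, is_perfect) or None."""
    windows = [seq[s + k * p : s + (k + 1) * p] for k in range(c)]
    if any("N" in w for w in windows):
        return None
    cons = _consensus(windows)
    need = _np_needed(p, min_similarity)
    idents = []
    for w in windows:
        m = sum(a == b for a, b in zip(w, cons))
        if m < need:
            return None
        idents.append(m / p)
    purity = float(np.mean(idents))
    return purity, all(i == 1.0 for i in idents)


def find_nonperfect_ssr(
    seq: str,
    min_motif: int = 3,
    min_similarity: float = 0.70,
    min_copies: int = 3,
    max_motif: int = 500,
    include_perfect: bool = False,
    contig_id: str = "",
) -> list[RepeatLocus]:
    """Report maximal arrays of similar (not necessarily identical) copies.

    An array of ``c`` consecutive motif-length windows is valid when every
    window has ungapped identity strictly greater than ``min_similarity``
    to the column-wise majority consensus of the array ("more than 70 %
    similar").  Valid arrays contained in a longer valid array of the same
    period are suppressed, as are fully perfect arrays unless
    ``include_perfect`` is set (those belong to :func:`find_perfect_ssr`).

    Note that random DNA contains many short arrays that clear a 70 %
    similarity bar by chance; downstream locus selection should rank or
    filter by copy number and kind.
    """
    if not 0 < min_similarity <= 1:
        raise ValueError("min_similarity must be in (0, 1]")
    seq = _check_seq(seq)
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out: list[RepeatLocus] = []
    for p in range(min_motif, min(max_motif, n // min_copies) + 1):
        if n < min_copies * p:
            break
        eq = ((arr[p:] == arr[:-p]) & (arr[p:] != b"N") & (arr[:-p] != b"N")).astype(np.int32)
        # adjacent-window identity: windows at s and s+p share >= p*(2*sim-1)
        # matches whenever both are within (1-sim)*p of a common consensus.
        csum = np.concatenate(([0], np.cumsum(eq)))
        max_s = n - 2 * p
        if max_s < 0:
            continue
        adj = csum[p : p + max_s + 1] - csum[:max_s + 1]  # matches for window pair at s
        # two windows both within (p - need) of a consensus agree on
        # >= 2*need - p positions: a necessary condition used as a seed
        need = _np_needed(p, min_similarity)
        ok = adj >= max(0, 2 * need - p)
        # candidate starts: chains of >= min_copies-1 consecutive adjacencies
        valid: list[tuple[int, int]] = []  # (start, c)
        for s in np.flatnonzero(ok):
            s = int(s)
            # longest adjacency chain from s with spacing p
            chain = 0
            while s + chain * p <= max_s and ok[s + chain * p]:
                chain += 1
            for c in range(min_copies, chain + 2):
                if s + c * p > n:
                    break
                res = _validate_np(seq, s, p, c, min_similarity)
                if res is None:
                    continue
                valid.append((s, c))
        # maximality: drop intervals contained in a longer valid interval
        spans = {(s, s + c * p) for s, c in valid}
        for s, c in sorted(set(valid)):
            a, b = s, s + c * p
            if any((x <= a and b <= y) and (x, y) != (a, b) for x, y in spans):
                continue
            purity, perfect = _validate_np(seq, s, p, c, min_similarity)
            if perfect and not include_perfect:
                continue
            # the array's motif is the copy consensus; report only primitive
            # periods (a non-primitive consensus belongs to a smaller period)
            motif = _consensus([seq[s + k * p : s + (k + 1) * p] for k in range(c)])
            if not _is_primitive(motif):
                continue
            out.append(
                RepeatLocus(contig_id, s, s + c * p, motif, p, float(c),
                            purity, "perfect" if perfect else "nonperfect")
            )
    out.sort(key=lambda l: (l.start, l.end, l.motif_len))
    return out


# ---------------------------------------------------------------------------
# genome screen and locus selection
# ---------------------------------------------------------------------------

def screen_genome(
    contigs: Iterable[tuple[str, str]],
    mnr_min: int = 6,
    min_motif: int = 3,
    max_motif: int = 500,
    min_copies: int = 3,
    np_similarity: float = 0.70,
    genome_id: str = "",
) -> RepeatCatalog:
    """Union of the three repeat finders over all contigs.

    ``contigs`` is an iterable of ``(contig_id, sequence)`` pairs (see
    :func:`labstrain.io.read_fasta`).  The catalog is deduplicated on
    ``(contig, start, end, motif_len)`` and sorted by position.
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("genome has no contigs")
    seen: dict[tuple, RepeatLocus] = {}
    for cid, seq in contigs:
        loci: list[RepeatLocus] = []
        loci += find_mnr(seq, min_len=mnr_min, contig_id=cid)
        loci += find_perfect_ssr(seq, min_motif, max_motif, min_copies, contig_id=cid)
        loci += find_nonperfect_ssr(seq, min_motif, np_similarity, min_copies,
                                    max_motif, contig_id=cid)
        for loc in loci:
            key = (cid, loc.start, loc.end, loc.motif_len)
            prev = seen.get(key)
            if prev is None or (prev.kind == "nonperfect" and loc.kind == "perfect"):
                seen[key] = loc
    ordered = sorted(seen.values(), key=lambda l: (l.contig_id, l.start, l.end))
    params = dict(mnr_min=mnr_min, min_motif=min_motif, max_motif=max_motif,
                  min_copies=min_copies, np_similarity=np_similarity)
    return RepeatCatalog(ordered, genome_id=genome_id, parameters=params)


def select_typing_loci(
    catalog: RepeatCatalog,
    n: int = 11,
    mask: Sequence[tuple[str, int, int]] | None = None,
) -> list[RepeatLocus]:
    """Pick the ``n`` loci with the largest copy number as typing loci.

    ``mask`` is a collection of excluded ``(contig, start, end)`` intervals
    (e.g. phage or prophage regions); loci intersecting any are removed
    before ranking.  Ties on copy number are broken by larger motif length,
    then by genome position.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def masked(loc: RepeatLocus) -> bool:
        if not mask:
            return False
        return any(c == loc.contig_id and loc.start < e and s < loc.end
                   for c, s, e in mask)

    pool = [l for l in catalog if not masked(l)]
    pool.sort(key=lambda l: (-l.copies, -l.motif_len, l.contig_id, l.start))
    if len(pool) < n:
        warnings.warn(f"only {len(pool)} loci available after masking (requested {n})")
        return pool
    return pool[:n]


def shift_locus(loc: RepeatLocus, offset: int) -> RepeatLocus:
    """Return the locus translated by ``offset`` bases."""
    return replace(loc, start=loc.start + offset, end=loc.end + offset)
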