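"""Sequence-motif scanners for five non-B DNA structure classes.

The five classes and their motif grammars:

* **G4** (G-quadruplex): at least ``g4_min_runs`` runs of at least
  ``g4_min_run`` consecutive guanines separated by loops of
  ``g4_loop_min``..``g4_loop_max`` nt.  Loops may contain any non-N base,
  including G.  G4 is the only class scanned on both strands (see
  :func:`scan_all`).
* **CRUCIFORM** (inverted repeat): arm - spacer - arm where the right arm is
  the reverse complement of the left arm, arm >= ``ir_min_arm``,
  spacer <= ``ir_max_spacer``.
* **TRIPLEX** (mirror repeat): right arm is the *reverse* of the left arm,
  arm >= ``mr_min_arm``, spacer <= ``mr_max_spacer``, and the purine (A/G)
  or pyrimidine (C/T) fraction of the whole site is at least
  ``triplex_min_purity``.
* **SLIPPED** (direct repeat): unit - spacer - unit with identical units,
  unit >= ``dr_min_unit``, spacer <= ``dr_max_spacer``.
* **ZDNA**: a tract of length >= ``z_min_len`` whose every adjacent
  dinucleotide step belongs to ``z_allowed_dinucleotides`` (by default the
  alternating purine-pyrimidine steps GC/CG/GT/TG/AC/CA; AT and TA are
  excluded because they rarely adopt the left-handed form).

Multiple-match resolution is deterministic and identical for every class:
all grammar-valid candidate sites are enumerated, ordered by
(start ascending, span descending, arm/unit descending, spacer ascending),
and selected greedily so that no two reported hits of the same (class,
strand) overlap.  This "leftmost-greedy, longest-first" convention is what
the brute-force oracles in the test-suite reproduce.

N bases never match: they break G-runs, arms, units, spacers, loops and
Z-DNA steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from .seq import G, N, bool_runs, encode, kmer_codes, prefix_counts, revcomp

__all__ = [
    "StructureClass",
    "Strand",
    "ScanParams",
    "MotifHit",
    "find_g4",
    "find_inverted_repeats",
    "find_triplex_mirror_repeats",
    "find_direct_repeats",
    "find_z_dna",
    "find_polypyrimidine_tract",
    "scan_all",
    "max_g_run",
    "hits_to_bed_rows",
]


class StructureClass(str, Enum):
    G4 = "G4"
    CRUCIFORM = "CRUCIFORM"
    TRIPLEX = "TRIPLEX"
    SLIPPED = "SLIPPED"
    ZDNA = "ZDNA"


class Strand(str, Enum):
    FORWARD = "FORWARD"
    REVERSE_COMPLEMENT = "REVERSE_COMPLEMENT"


_PURU_PYR_PAIRS = {
    "AC", "AT", "GC", "GT",  # purine-pyrimidine
    "CA", "TA", "CG", "TG",  # pyrimidine-purine
}

DEFAULT_Z_DINUCLEOTIDES = frozenset({"GC", "CG", "GT", "TG", "AC", "CA"})


@dataclass(frozen=True)
class ScanParams:
    """Search criteria for the five structure classes and the polypyrimidine
    tract.

    Defaults follow the common motif-database conventions: G-runs of >= 3 G
    with 1-7 nt loops and at least four runs for G4; inverted-repeat arms of
    >= 6 nt with spacers of <= 3 nt; mirror-repeat arms of >= 10 nt with
    spacers <= 8 nt and >= 90 % purine or pyrimidine content for triplex;
    direct-repeat units of >= 10 nt with spacers <= 10 nt; alternating
    purine-pyrimidine tracts of >= 12 nt (AT/TA steps excluded) for Z-DNA.
    The polypyrimidine tract is a 20-nt window with at most five purines in
    the last 40 nt of an intron.
    """

    g4_min_run: int = 3
    g4_min_runs: int = 4
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    ir_min_arm: int = 6
    ir_max_spacer: int = 3
    mr_min_arm: int = 10
    mr_max_spacer: int = 8
    triplex_min_purity: float = 0.9
    dr_min_unit: int = 10
    dr_max_spacer: int = 10
    z_min_len: int = 12
    z_allowed_dinucleotides: frozenset[str] = DEFAULT_Z_DINUCLEOTIDES
    ppt_window: int = 20
    ppt_max_purines: int = 5
    ppt_search_span: int = 40

    def __post_init__(self) -> None:
        positive = [
            "g4_min_run", "g4_min_runs", "g4_loop_min", "g4_loop_max",
            "ir_min_arm", "mr_min_arm", "dr_min_unit", "z_min_len",
            "ppt_window", "ppt_search_span",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("ir_max_spacer", "mr_max_spacer", "dr_max_spacer",
                     "ppt_max_purines"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.g4_loop_min > self.g4_loop_max:
            raise ValueError("g4_loop_min must not exceed g4_loop_max")
        if not 0.0 < self.triplex_min_purity <= 1.0:
            raise ValueError("triplex_min_purity must lie in (0, 1]")
        if self.ppt_max_purines >= self.ppt_window:
            raise ValueError("ppt_max_purines must be below ppt_window")
        if self.ppt_window > self.ppt_search_span:
            raise ValueError("ppt_window must not exceed ppt_search_span")
        dinucs = frozenset(d.upper() for d in self.z_allowed_dinucleotides)
        for d in dinucs:
            if len(d) != 2 or d not in _PURU_PYR_PAIRS:
                raise ValueError(
                    f"Z-DNA dinucleotide {d!r} is not a purine-pyrimidine "
                    "or pyrimidine-purine step"
                )
        object.__setattr__(self, "z_allowed_dinucleotides", dinucs)


@dataclass(frozen=True)
class MotifHit:
    """One non-overlapping motif occurrence on a scanned sequence.

    ``start``/``end`` are 0-based half-open offsets on the *forward*
    coordinate system of the input sequence, even for hits found on the
    reverse complement (``scanned_strand == REVERSE_COMPLEMENT``);
    ``matched_sequence`` is always the substring as scanned, i.e. on the
    reverse-complement strand for such hits.
    """

    structure_class: StructureClass
    start: int
    end: int
    scanned_strand: Strand = Strand.FORWARD
    attributes: dict = field(default_factory=dict)
    matched_sequence: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# candidate selection

def _select_leftmost_greedy(cands: list[tuple]) -> list[tuple]:
    """Greedy non-overlap resolution of ``(start, end, *payload)`` tuples.

    Candidates are ranked by start ascending, span descending, then by the
    remaining payload fields (descending arm/unit, ascending spacer is
    achieved by the caller storing ``-arm`` before ``spacer``).  A candidate
    is kept iff it overlaps no previously kept candidate; kept candidates
    therefore never overlap and are emitted sorted by start.
    """
    cands = sorted(cands, key=lambda c: (c[0], c[0] - c[1]) + c[2:])
    kept: list[tuple] = []
    for cand in cands:
        s, e = cand[0], cand[1]
        ok = True
        for k in reversed(kept):
            if k[1] <= s:
                break
            if k[0] < e and s < k[1]:
                ok = False
                break
        if ok:
            # kept list stays start-sorted because overlap with the last
            # kept interval is checked first; a non-overlapping candidate
            # can still start before an earlier kept interval, so insert
            # in order.
            kept.append(cand)
            kept.sort(key=lambda c: c[0])
    return kept


def _max_run_of(sub: str, base: str = "G") -> int:
    best = cur = 0
    for ch in sub:
        if ch == base:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


# ---------------------------------------------------------------------------
# G4

def _g_extents(codes: np.ndarray) -> np.ndarray:
    """gext[i] = length of the maximal G stretch starting at position i."""
    n = len(codes)
    gext = np.zeros(n, dtype=np.int64)
    starts, lengths = bool_runs(codes == G)
    for s, L in zip(starts, lengths):
        gext[s : s + L] = np.arange(L, 0, -1)
    return gext


def find_g4(seq: str, params: Optional[ScanParams] = None) -> list[MotifHit]:
    """All maximal, leftmost-greedy non-overlapping G-quadruplex motifs.

    A match is any substring admitting a decomposition into
    >= ``g4_min_runs`` G-runs of >= ``g4_min_run`` guanines separated by
    N-free loops of ``g4_loop_min``..``g4_loop_max`` nt.  Scanning picks the
    leftmost position where a match starts, extends it to the farthest
    reachable end, emits it and continues past it.
    """
    params = params or ScanParams()
    codes = encode(seq)
    n = len(codes)
    minr, nruns = params.g4_min_run, params.g4_min_runs
    lmin, lmax = params.g4_loop_min, params.g4_loop_max
    gext = _g_extents(codes)
    run_starts = np.flatnonzero(gext >= minr)
    if len(run_starts) == 0:
        return []
    n_count = prefix_counts(codes == N)
    pos_index = {int(p): i for i, p in enumerate(run_starts)}
    m = len(run_starts)
    # M[k][i]: farthest end of a decomposition starting a run at run_starts[i]
    # that still needs >= k runs (k capped at nruns); -1 if impossible.
    M = np.full((nruns + 1, m), -1, dtype=np.int64)
    for i in range(m - 1, -1, -1):
        p = int(run_starts[i])
        ext = int(gext[p])
        lo = p + minr + lmin
        hi = p + ext + lmax
        j0 = np.searchsorted(run_starts, lo, side="left")
        j1 = np.searchsorted(run_starts, hi, side="right")
        reachable = []
        for j in range(j0, j1):
            q = int(run_starts[j])
            # longest usable first run gives the shortest (most N-safe) loop
            r = min(ext, q - p - lmin)
            if r < minr or q - p - r > lmax:
                continue
            if n_count[q] - n_count[p + r] > 0:
                continue
            reachable.append(j)
        M[1, i] = p + ext
        for j in reachable:
            if M[1, j] > M[1, i]:
                M[1, i] = M[1, j]
        for k in range(2, nruns + 1):
            best = -1
            for j in reachable:
                if M[k - 1, j] > best:
                    best = M[k - 1, j]
            M[k, i] = best
    hits: list[MotifHit] = []
    cursor = 0
    for i, p in enumerate(run_starts):
        p = int(p)
        if p < cursor or M[nruns, i] < 0:
            continue
        end = int(M[nruns, i])
        sub = seq[p:end]
        run_list, loop_list = _g4_run_layout(sub, minr)
        hits.append(
            MotifHit(
                StructureClass.G4,
                p,
                end,
                Strand.FORWARD,
                {
                    "g_run_lengths": run_list,
                    "loop_lengths": loop_list,
                    "max_g_run": max(run_list) if run_list else 0,
                },
                sub,
            )
        )
        cursor = end
    return hits


def _g4_run_layout(sub: str, min_run: int) -> tuple[list[int], list[int]]:
    """Maximal G-runs >= min_run within a matched substring and the gaps
    (loops) between consecutive ones."""
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(sub):
        if sub[i] == "G":
            j = i
            while j < len(sub) and sub[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    lengths = [L for _, L in runs]
    loops = [
        runs[k + 1][0] - (runs[k][0] + runs[k][1]) for k in range(len(runs) - 1)
    ]
    return lengths, loops


# ---------------------------------------------------------------------------
# paired-arm scanners (inverted / mirror / direct repeats)

def _repeat_hits(
    seq: str,
    cands: list[tuple],
    cls: StructureClass,
    extra: Optional[dict] = None,
) -> list[MotifHit]:
    hits = []
    for cand in _select_leftmost_greedy(cands):
        start, end, neg_arm, spacer = cand[:4]
        attrs = {"arm_or_unit_length": -neg_arm, "spacer_length": spacer}
        if extra is not None:
            attrs.update(extra.get(cand[:4], {}))
        if len(cand) > 4:
            attrs["purity"] = cand[4]
        hits.append(MotifHit(cls, start, end, Strand.FORWARD, attrs, seq[start:end]))
    return hits


def find_inverted_repeats(
    seq: str, params: Optional[ScanParams] = None
) -> list[MotifHit]:
    """Inverted repeats (cruciform-forming sites): arm - spacer - arm with the
    right arm equal to the reverse complement of the left arm."""
    params = params or ScanParams()
    codes = encode(seq)
    n = len(codes)
    k = min(params.ir_min_arm, 20)
    fwd = kmer_codes(codes, k)
    rc = kmer_codes(codes, k, reverse=True, complement=True)
    n_count = prefix_counts(codes == N)
    cands: list[tuple] = []
    for s in range(params.ir_max_spacer + 1):
        limit = n - 2 * k - s + 1
        if limit <= 0:
            continue
        match = np.flatnonzero((rc[:limit] == fwd[k + s :][:limit]) & (rc[:limit] >= 0))
        for i in match:
            c = int(i) + k  # spacer is [c, c+s)
            if s and n_count[c + s] - n_count[c] > 0:
                continue
            a = k
            # confirm arm out to ir_min_arm if the seed was capped, then extend
            while (
                c - a - 1 >= 0
                and c + s + a < n
                and int(codes[c - a - 1]) + int(codes[c + s + a]) == 3
            ):
                a += 1
            if a < params.ir_min_arm:
                continue
            for arm in range(params.ir_min_arm, a + 1):
                cands.append((c - arm, c + arm + s, -arm, s))
    return _repeat_hits(seq, cands, StructureClass.CRUCIFORM)


def find_triplex_mirror_repeats(
    seq: str, params: Optional[ScanParams] = None
) -> list[MotifHit]:
    """Mirror repeats passing the triplex purine/pyrimidine purity filter.

    The purity of a candidate is the larger of its purine and pyrimidine
    fraction computed over the whole site (both arms plus the spacer);
    candidates below ``triplex_min_purity`` are discarded *before* the
    greedy non-overlap selection.
    """
    params = params or ScanParams()
    codes = encode(seq)
    n = len(codes)
    k = min(params.mr_min_arm, 20)
    fwd = kmer_codes(codes, k)
    rev = kmer_codes(codes, k, reverse=True)
    n_count = prefix_counts(codes == N)
    pur_count = prefix_counts((codes == 0) | (codes == 2))  # A or G
    cands: list[tuple] = []
    for s in range(params.mr_max_spacer + 1):
        limit = n - 2 * k - s + 1
        if limit <= 0:
            continue
        match = np.flatnonzero((rev[:limit] == fwd[k + s :][:limit]) & (rev[:limit] >= 0))
        for i in match:
            c = int(i) + k
            if s and n_count[c + s] - n_count[c] > 0:
                continue
            a = k
            while (
                c - a - 1 >= 0
                and c + s + a < n
                and codes[c - a - 1] == codes[c + s + a]
                and codes[c - a - 1] != N
            ):
                a += 1
            if a < params.mr_min_arm:
                continue
            for arm in range(params.mr_min_arm, a + 1):
                start, end = c - arm, c + arm + s
                span = end - start
                pur = (pur_count[end] - pur_count[start]) / span
                purity = max(pur, 1.0 - pur)
                if purity >= params.triplex_min_purity:
                    cands.append((start, end, -arm, s, round(purity, 10)))
    return _repeat_hits(seq, cands, StructureClass.TRIPLEX)


def find_direct_repeats(
    seq: str, params: Optional[ScanParams] = None
) -> list[MotifHit]:
    """Direct (tandem) repeats: unit - spacer - unit with identical units."""
    params = params or ScanParams()
    codes = encode(seq)
    n = len(codes)
    min_u, max_s = params.dr_min_unit, params.dr_max_spacer
    k = min(min_u, 20)
    km = kmer_codes(codes, k)
    n_count = prefix_counts(codes == N)
    cands: list[tuple] = []
    if len(km):
        order = np.argsort(km, kind="stable")
        sorted_codes = km[order]
        valid = sorted_codes >= 0
        order = order[valid]
        sorted_codes = sorted_codes[valid]
        boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
        groups = np.split(order, boundaries)
        seen: set[tuple[int, int]] = set()
        for grp in groups:
            if len(grp) < 2:
                continue
            pos = np.sort(grp)
            for ai in range(len(pos)):
                for bi in range(ai + 1, len(pos)):
                    i, j = int(pos[ai]), int(pos[bi])
                    d = j - i
                    if d < min_u:
                        continue
                    # walk to the leftmost anchor of this agreement run
                    while i > 0 and codes[i - 1] == codes[j - 1] and codes[i - 1] != N:
                        i -= 1
                        j -= 1
                    if (i, d) in seen:
                        continue
                    seen.add((i, d))
                    agree = k
                    while (
                        i + agree + d < n
                        and codes[i + agree] == codes[i + agree + d]
                        and codes[i + agree] != N
                    ):
                        agree += 1
                    for p in range(i, i + agree):
                        rem = i + agree - p
                        u_lo = max(min_u, d - max_s)
                        u_hi = min(d, rem)
                        for u in range(u_lo, u_hi + 1):
                            s = d - u
                            if s and n_count[p + d] - n_count[p + u] > 0:
                                continue
                            cands.append((p, p + d + u, -u, s))
    return _repeat_hits(seq, cands, StructureClass.SLIPPED)


# ---------------------------------------------------------------------------
# Z-DNA

def find_z_dna(seq: str, params: Optional[ScanParams] = None) -> list[MotifHit]:
    """Maximal tracts of allowed alternating dinucleotide steps of length
    >= ``z_min_len``.  Maximal tracts never overlap, so no greedy resolution
    is needed."""
    params = params or ScanParams()
    codes = encode(seq)
    n = len(codes)
    if n < 2:
        return []
    allowed = np.zeros(25, dtype=bool)
    for d in params.z_allowed_dinucleotides:
        allowed[int(encode(d)[0]) * 5 + int(encode(d)[1])] = True
    steps = allowed[codes[:-1].astype(np.int64) * 5 + codes[1:].astype(np.int64)]
    hits = []
    for s, L in zip(*bool_runs(steps)):
        length = int(L) + 1  # L steps cover L+1 bases
        if length >= params.z_min_len:
            start = int(s)
            hits.append(
                MotifHit(
                    StructureClass.ZDNA,
                    start,
                    start + length,
                    Strand.FORWARD,
                    {"tract_length": length},
                    seq[start : start + length],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# polypyrimidine tract

def find_polypyrimidine_tract(
    intron_seq: str, params: Optional[ScanParams] = None
) -> Optional[tuple[int, int]]:
    """The 3'-most qualifying polypyrimidine-tract window of an intron.

    Returns the 0-based half-open interval of the 3'-most window of
    ``ppt_window`` nt that lies fully inside the last ``ppt_search_span`` nt
    and contains at most ``ppt_max_purines`` purines (A/G; N is counted as a
    purine, conservatively), or ``None`` when no window qualifies or the
    intron is shorter than the window.
    """
    params = params or ScanParams()
    codes = encode(intron_seq, "intron")
    n = len(codes)
    w = params.ppt_window
    if n < w:
        return None
    region_start = max(0, n - params.ppt_search_span)
    purines = prefix_counts((codes == 0) | (codes == 2) | (codes == N))
    for start in range(n - w, region_start - 1, -1):
        if purines[start + w] - purines[start] <= params.ppt_max_purines:
            return (start, start + w)
    return None


# ---------------------------------------------------------------------------
# combined scan

_SCANNERS = {
    StructureClass.G4: find_g4,
    StructureClass.CRUCIFORM: find_inverted_repeats,
    StructureClass.TRIPLEX: find_triplex_mirror_repeats,
    StructureClass.SLIPPED: find_direct_repeats,
    StructureClass.ZDNA: find_z_dna,
}


def scan_all(
    seq: str,
    params: Optional[ScanParams] = None,
    remove_both: bool = True,
) -> dict[StructureClass, list[MotifHit]]:
    """Run all five scanners and apply the cross-class overlap exclusion.

    G4 is additionally scanned on the reverse complement; its hits are
    projected back to forward coordinates with
    ``scanned_strand = REVERSE_COMPLEMENT``.  After within-class resolution,
    any position shared (strand-agnostically, in forward coordinates) by
    hits of two *different* classes disqualifies the pair: with
    ``remove_both`` (the default) both members are dropped, otherwise only
    the later-ranked one (by start, then span, then class declaration
    order).
    """
    params = params or ScanParams()
    n = len(seq)
    results: dict[StructureClass, list[MotifHit]] = {}
    for cls, fn in _SCANNERS.items():
        results[cls] = list(fn(seq, params))
    rc_hits = []
    for h in find_g4(revcomp(seq), params):
        rc_hits.append(
            replace(
                h,
                start=n - h.end,
                end=n - h.start,
                scanned_strand=Strand.REVERSE_COMPLEMENT,
            )
        )
    results[StructureClass.G4] = sorted(
        results[StructureClass.G4] + rc_hits, key=lambda h: (h.start, h.end)
    )
    # cross-class exclusion
    order = list(_SCANNERS)
    flat = [
        (h.start, h.end, order.index(cls), i)
        for cls in order
        for i, h in enumerate(results[cls])
    ]
    flat.sort()
    removed: dict[int, set[int]] = {c: set() for c in range(len(order))}
    for a in range(len(flat)):
        s1, e1, c1, i1 = flat[a]
        for b in range(a + 1, len(flat)):
            s2, e2, c2, i2 = flat[b]
            if s2 >= e1:
                break
            if c1 != c2:
                if remove_both:
                    removed[c1].add(i1)
                    removed[c2].add(i2)
                else:
                    removed[c2].add(i2)
    return {
        cls: [h for i, h in enumerate(results[cls]) if i not in removed[ci]]
        for ci, cls in enumerate(order)
    }


def max_g_run(hits: Iterable[MotifHit]) -> int:
    """Longest G-run across a collection of G4 hits (0 when empty)."""
    best = 0
    for h in hits:
        if h.structure_class is not StructureClass.G4:
            raise ValueError(f"max_g_run expects G4 hits, got {h.structure_class}")
        best = max(best, int(h.attributes.get("max_g_run", 0)))
    return best


# ---------------------------------------------------------------------------
# BED output

def hits_to_bed_rows(
    hits: Iterable[MotifHit],
    chrom: str,
    offset: int = 0,
    genome_strand: str = "+",
) -> list[str]:
    """Render hits as BED6+1 rows (0-based half-open).

    ``offset`` shifts scan coordinates to genome coordinates for a sequence
    extracted from ``chrom`` at that offset on the ``+`` strand; for a
    sequence extracted from the ``-`` strand, coordinates are mirrored and
    the reported strand flipped accordingly.  The seventh column packs the
    class-specific attributes as ``key=value`` pairs.
    """
    rows = []
    for h in hits:
        if genome_strand == "+":
            start, end = offset + h.start, offset + h.end
            fwd = h.scanned_strand is Strand.FORWARD
        else:
            start, end = offset - h.end, offset - h.start
            fwd = h.scanned_strand is not Strand.FORWARD
        strand = "+" if fwd else "-"
        attrs = ";".join(f"{k}={v}" for k, v in sorted(h.attributes.items()))
        rows.append(
            f"{chrom}\t{start}\t{end}\t{h.structure_class.value}\t0\t{strand}\t{attrs}"
        )
    return rows
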