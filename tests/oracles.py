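"""Brute-force reference implementations of the motif grammars.

These oracles enumerate candidate sites exhaustively (every substring or
every (start, arm/unit, spacer) triple), test the grammar directly on the
extracted strings, and resolve overlaps with an explicitly iterative
"pick leftmost-start, longest-span, largest-arm candidate; delete
everything overlapping it; repeat" loop.  They share no scanning code with
the package and are only feasible for short sequences.
"""

from __future__ import annotations

from functools import lru_cache

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PURINES = {"A", "G"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def greedy_select(cands):
    """cands: list of (start, end, arm, spacer, *extra).  Returns the
    non-overlapping selection under the leftmost-start, longest-span,
    largest-arm, smallest-spacer preference."""
    remaining = list(cands)
    chosen = []
    while remaining:
        best = min(
            remaining,
            key=lambda c: (c[0], -(c[1] - c[0]), -c[2], c[3]),
        )
        chosen.append(best)
        remaining = [
            c for c in remaining if c[1] <= best[0] or c[0] >= best[1]
        ]
    return sorted(chosen)


# ---------------------------------------------------------------------------
# G4

def g4_substring_matches(sub: str, min_run: int, min_runs: int,
                         loop_min: int, loop_max: int) -> bool:
    """True iff the substring admits a decomposition into >= min_runs
    G-runs separated by N-free loops of loop_min..loop_max nt."""

    @lru_cache(maxsize=None)
    def ok(pos: int, needed: int) -> bool:
        # a run of length r >= min_run must start at pos
        g = 0
        while pos + g < len(sub) and sub[pos + g] == "G":
            g += 1
        if g < min_run:
            return False
        for r in range(min_run, g + 1):
            after = pos + r
            if needed <= 1 and after == len(sub):
                return True
            for loop in range(loop_min, loop_max + 1):
                nxt = after + loop
                if nxt >= len(sub):
                    break
                if "N" in sub[after:nxt]:
                    continue
                if ok(nxt, max(needed - 1, 1)):
                    return True
        return False

    if not sub or sub[0] != "G" or sub[-1] != "G":
        return False
    return ok(0, min_runs)


def oracle_g4(seq: str, params) -> list[tuple[int, int]]:
    """Greedy G4 hit intervals: leftmost match start, farthest end."""
    n = len(seq)
    matches = {}
    for a in range(n):
        if seq[a : a + params.g4_min_run] != "G" * params.g4_min_run:
            continue
        min_len = params.g4_min_runs * params.g4_min_run + (
            params.g4_min_runs - 1
        ) * params.g4_loop_min
        for b in range(a + min_len, n + 1):
            if seq[b - 1] != "G":
                continue
            if g4_substring_matches(
                seq[a:b], params.g4_min_run, params.g4_min_runs,
                params.g4_loop_min, params.g4_loop_max,
            ):
                matches[a] = b  # later b overwrites: farthest end kept
    hits = []
    cursor = 0
    for a in sorted(matches):
        if a >= cursor:
            hits.append((a, matches[a]))
            cursor = matches[a]
    return hits


# ---------------------------------------------------------------------------
# paired-arm classes

def oracle_inverted_repeats(seq: str, params) -> list[tuple]:
    n = len(seq)
    cands = []
    for start in range(n):
        for spacer in range(params.ir_max_spacer + 1):
            for arm in range(params.ir_min_arm, (n - start - spacer) // 2 + 1):
                left = seq[start : start + arm]
                mid = seq[start + arm : start + arm + spacer]
                right = seq[start + arm + spacer : start + 2 * arm + spacer]
                if "N" in left or "N" in mid or "N" in right:
                    continue
                if right == revcomp(left):
                    cands.append((start, start + 2 * arm + spacer, arm, spacer))
    return greedy_select(cands)


def oracle_mirror_repeats(seq: str, params) -> list[tuple]:
    n = len(seq)
    cands = []
    for start in range(n):
        for spacer in range(params.mr_max_spacer + 1):
            for arm in range(params.mr_min_arm, (n - start - spacer) // 2 + 1):
                site = seq[start : start + 2 * arm + spacer]
                left = site[:arm]
                mid = site[arm : arm + spacer]
                right = site[arm + spacer :]
                if "N" in site:
                    continue
                if right != left[::-1]:
                    continue
                pur = sum(1 for c in site if c in PURINES) / len(site)
                if max(pur, 1 - pur) >= params.triplex_min_purity:
                    cands.append(
                        (start, start + 2 * arm + spacer, arm, spacer,
                         round(max(pur, 1 - pur), 10))
                    )
    return greedy_select(cands)


def oracle_direct_repeats(seq: str, params) -> list[tuple]:
    n = len(seq)
    cands = []
    for start in range(n):
        for spacer in range(params.dr_max_spacer + 1):
            for unit in range(params.dr_min_unit, (n - start - spacer) // 2 + 1):
                left = seq[start : start + unit]
                mid = seq[start + unit : start + unit + spacer]
                right = seq[start + unit + spacer : start + 2 * unit + spacer]
                if "N" in left or "N" in mid or "N" in right:
                    continue
                if left == right:
                    cands.append((start, start + 2 * unit + spacer, unit, spacer))
    return greedy_select(cands)


# ---------------------------------------------------------------------------
# Z-DNA

def oracle_z_dna(seq: str, params) -> list[tuple[int, int]]:
    n = len(seq)
    allowed = set(params.z_allowed_dinucleotides)

    def tract(a: int, b: int) -> bool:
        return all(seq[i : i + 2] in allowed for i in range(a, b - 1))

    hits = []
    for a in range(n):
        for b in range(a + params.z_min_len, n + 1):
            if not tract(a, b):
                continue
            left_ext = a > 0 and seq[a - 1 : a + 1] in allowed
            right_ext = b < n and seq[b - 1 : b + 1] in allowed
            if not left_ext and not right_ext:
                hits.append((a, b))
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# polypyrimidine tract

def oracle_ppt(seq: str, params):
    n = len(seq)
    w = params.ppt_window
    if n < w:
        return None
    lo = max(0, n - params.ppt_search_span)
    best = None
    for start in range(lo, n - w + 1):
        window = seq[start : start + w]
        purines = sum(1 for c in window if c in PURINES or c == "N")
        if purines <= params.ppt_max_purines:
            best = (start, start + w)  # later (more 3') windows overwrite
    return best


# ---------------------------------------------------------------------------
# cross-class overlap exclusion

def oracle_cross_class(hit_sets: dict) -> dict:
    """Remove every hit overlapping a hit of a different class (both
    members of each overlapping pair)."""
    removed = {cls: set() for cls in hit_sets}
    for cls1, hits1 in hit_sets.items():
        for cls2, hits2 in hit_sets.items():
            if cls1 == cls2:
                continue
            for i, (s1, e1) in enumerate(hits1):
                for s2, e2 in hits2:
                    if s1 < e2 and s2 < e1:
                        removed[cls1].add(i)
    return {
        cls: [h for i, h in enumerate(hits) if i not in removed[cls]]
        for cls, hits in hit_sets.items()
    }
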