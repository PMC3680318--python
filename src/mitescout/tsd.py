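"""Target site duplication (TSD) detection at element junctions.

A TSD is a 2-10 nt direct repeat created on both sides of an element at
insertion.  The primary search looks at the 10-nt flanks immediately outside
the putative element and requires the repeat to abut both junctions (a suffix
of the left flank equal to a prefix of the right flank).  Some superfamilies
(Stowaway, PiggyBac) carry the TSD inside their TIR termini because the
apparent element boundary includes the duplicated target site; the fallback
therefore searches the most terminal 5 nt of the arms themselves for a
prefix/suffix direct repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["TSDMatch", "find_tsd", "find_tsd_with_fallback"]

TSD_MIN = 2
TSD_MAX = 10
FLANK_PROBE = 10
TIR_TERMINAL = 5


@dataclass(frozen=True)
class TSDMatch:
    """A direct repeat at the element junctions.

    left_end_offset / right_start_offset measure, in nt, how far inside the
    element the repeat ends/starts: 0 means it abuts the junction exactly
    (flank source); d > 0 means the boundary was shifted d nt into the TIR
    termini (tir_terminal source).
    """

    sequence: str
    length: int
    source: str  # "flank" | "tir_terminal"
    left_end_offset: int = 0
    right_start_offset: int = 0


def _abutting(left_window: str, right_window: str, lo: int, hi: int) -> Optional[str]:
    """Longest string of length in [lo, hi] that is both a suffix of
    left_window and a prefix of right_window, N-free; None if absent."""
    top = min(hi, len(left_window), len(right_window))
    for length in range(top, lo - 1, -1):
        cand = left_window[-length:]
        if "N" in cand:
            continue
        if cand == right_window[:length]:
            return cand
    return None


def _anywhere(left_window: str, right_window: str, lo: int, hi: int) -> Optional[tuple[str, int, int]]:
    """Best shared substring under the relaxed placement rule.

    Returns (sequence, left_gap, right_gap) where the gaps are distances from
    the junction (left window end / right window start).  Preference: longest,
    then smallest summed gap, then lexicographically smallest.
    """
    top = min(hi, len(left_window), len(right_window))
    for length in range(top, lo - 1, -1):
        right_index: dict[str, int] = {}
        for rs in range(len(right_window) - length, -1, -1):
            sub = right_window[rs : rs + length]
            if "N" not in sub:
                right_index[sub] = rs  # smallest rs (closest to junction) wins
        best: Optional[tuple[int, str, int, int]] = None  # (gap_sum, seq, lg, rg)
        for ls in range(len(left_window) - length + 1):
            sub = left_window[ls : ls + length]
            if "N" in sub:
                continue
            rs = right_index.get(sub)
            if rs is None:
                continue
            left_gap = len(left_window) - (ls + length)
            key = (left_gap + rs, sub, left_gap, rs)
            if best is None or key < best:
                best = key
        if best is not None:
            return best[1], best[2], best[3]
    return None


def find_tsd(
    left_flank: str,
    right_flank: str,
    *,
    anywhere: bool = False,
    tsd_min: int = TSD_MIN,
    tsd_max: int = TSD_MAX,
) -> Optional[TSDMatch]:
    """Best 2-10 nt direct repeat in the 10-nt flanks, or None.

    Flanks must be exactly 10 nt (callers pad with N at sequence ends).  By
    default the repeat must abut both junctions; with anywhere=True any
    placement within the windows qualifies (longest wins, then closest to the
    junctions, then lexicographically smallest).
    """
    if len(left_flank) != FLANK_PROBE or len(right_flank) != FLANK_PROBE:
        raise ValueError("flanks must be exactly 10 nt; pad with N at sequence ends")
    if anywhere:
        hit = _anywhere(left_flank, right_flank, tsd_min, tsd_max)
        if hit is None:
            return None
        seq, lg, rg = hit
        return TSDMatch(seq, len(seq), "flank", -lg, -rg)
    seq = _abutting(left_flank, right_flank, tsd_min, tsd_max)
    if seq is None:
        return None
    return TSDMatch(seq, len(seq), "flank", 0, 0)


def find_tsd_with_fallback(
    left_flank: str,
    right_flank: str,
    left_tir_head: str,
    right_tir_tail: str,
    *,
    anywhere: bool = False,
    tsd_min: int = TSD_MIN,
    tsd_max: int = TSD_MAX,
) -> Optional[TSDMatch]:
    """Flank search first; on failure, search the most terminal 5 nt of the
    TIRs themselves.

    When the apparent element boundary includes the duplicated target site
    (Stowaway, PiggyBac), the TSD appears as the element's first k nt equal to
    its last k nt: a prefix of left_tir_head matching a suffix of
    right_tir_tail.  Such matches carry source="tir_terminal" and offsets = k
    (the repeat ends/starts k nt inside the apparent element).
    """
    primary = find_tsd(
        left_flank, right_flank, anywhere=anywhere, tsd_min=tsd_min, tsd_max=tsd_max
    )
    if primary is not None:
        return primary
    depth = min(TIR_TERMINAL, len(left_tir_head), len(right_tir_tail), tsd_max)
    for k in range(depth, tsd_min - 1, -1):
        cand = left_tir_head[:k]
        if "N" in cand:
            continue
        if cand == right_tir_tail[len(right_tir_tail) - k :]:
            return TSDMatch(cand, k, "tir_terminal", k, k)
    return None
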