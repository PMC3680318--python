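"""Terminal-inverted-repeat detection inside a genome slice.

The scan compares a slice against its own reverse complement.  An ungapped
inverted-repeat alignment pairs position p with position q = c - p for a fixed
anti-diagonal c, so every candidate arm pair lives on one anti-diagonal of the
self-vs-reverse-complement comparison.  A reported arm pair is a window
[a, b] on an anti-diagonal satisfying ALL of:

  * both ends of the window are complementary matches (trimmed alignment);
  * no N on either arm;
  * window length (= arm length) >= min_arm_len;
  * fraction of complementary positions >= min_arm_identity;
  * the window contains at least seed_len consecutive perfect matches
    (the perfect core that seeds detection);
  * element span = right_end - left_start within [min_element_len,
    max_element_len], and the two arms do not overlap;
  * the window is maximal: not strictly contained in another window on the
    same anti-diagonal that satisfies all of the above;
  * neither arm is a simple repeat (is_simple_arm).

`find_inverted_repeats` evaluates this rule with seed-nominated anti-diagonals
and vectorized window enumeration; `brute_force_ir` evaluates the identical
rule by direct enumeration and serves as the independent oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .sequence_model import GenomeSlice

__all__ = [
    "ScanParams",
    "IRPair",
    "find_inverted_repeats",
    "brute_force_ir",
    "is_simple_arm",
    "mask_low_complexity",
]

_SENSITIVITY_SEED = {"low": 11, "normal": 8, "high": 6}


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the inverted-repeat scan.

    sensitivity picks the exact-seed length ("low"=11, "normal"=8, "high"=6)
    unless seed_len is set explicitly; shorter seeds find more marginal arms
    at higher cost, mirroring a permissive e-value in an external search.
    """

    min_element_len: int = 50
    max_element_len: int = 800
    min_arm_len: int = 10
    min_arm_identity: float = 0.80
    seed_len: int = 8
    sensitivity: str = "normal"

    def __post_init__(self) -> None:
        if not (0 < self.min_element_len < self.max_element_len):
            raise ParameterError("need 0 < min_element_len < max_element_len")
        if 2 * self.min_arm_len > self.min_element_len:
            raise ParameterError("need 2*min_arm_len <= min_element_len")
        if not (0 < self.min_arm_identity <= 1):
            raise ParameterError("min_arm_identity must be in (0, 1]")
        if self.seed_len < 2:
            raise ParameterError("seed_len must be >= 2")
        if self.sensitivity not in _SENSITIVITY_SEED:
            raise ParameterError(f"unknown sensitivity {self.sensitivity!r}")

    @classmethod
    def from_sensitivity(cls, level: str, **kwargs) -> "ScanParams":
        return cls(seed_len=_SENSITIVITY_SEED[level], sensitivity=level, **kwargs)


@dataclass(frozen=True)
class IRPair:
    """A candidate terminal-inverted-repeat pair, slice coordinates, 0-based half-open."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_len: int
    arm_identity: float

    @property
    def element_span(self) -> tuple[int, int]:
        return (self.left_start, self.right_end)

    @property
    def element_length(self) -> int:
        return self.right_end - self.left_start

    def coords(self) -> tuple[int, int, int, int]:
        return (self.left_start, self.left_end, self.right_start, self.right_end)


def is_simple_arm(arm_seq: str) -> bool:
    """True for arms that are simple repeats (or unusable due to N).

    Simple means: alphabet within {G,C}; alphabet within {A,T}; a run of a
    single base; or a perfect period-2 repeat (one trailing partial period
    allowed).
    """
    if not arm_seq:
        raise ParameterError("empty arm")
    if "N" in arm_seq:
        return True
    alphabet = set(arm_seq)
    if alphabet <= {"G", "C"} or alphabet <= {"A", "T"}:
        return True
    if len(alphabet) == 1:
        return True
    if all(arm_seq[i] == arm_seq[i - 2] for i in range(2, len(arm_seq))):
        return True
    return False


# ---------------------------------------------------------------------------
# shared helpers (pure geometry / encoding, no search strategy)


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, N=-1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(raw.size, -1, dtype=np.int64)
    for base, val in zip(b"ACGT", range(4)):
        code[raw == base] = val
    return code


def _diag_region(c: int, n: int, params: ScanParams) -> tuple[int, int]:
    """Left-arm position range [lo, hi] on anti-diagonal c.

    lo enforces element length <= max_element_len and both arms in bounds;
    hi enforces non-overlapping arms (left_end <= right_start).
    """
    lo = max(0, c - n + 1, math.ceil((c + 1 - params.max_element_len) / 2))
    hi = (c - 1) // 2
    return lo, hi


def _identity_ok(matches: int, length: int, tau: float) -> bool:
    return matches + 1e-9 >= tau * length


def _maximal(windows: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Drop windows strictly contained in another window of the same diagonal."""
    if len(windows) <= 1:
        return list(windows)
    out = []
    best_b = -1
    for a, b, ident in sorted(windows, key=lambda w: (w[0], -w[1])):
        if b > best_b:
            out.append((a, b, ident))
            best_b = b
    return out


def _build_pairs(
    seq: str, c: int, windows: list[tuple[int, int, float]], _cache: dict
) -> list[IRPair]:
    pairs = []
    for a, b, ident in windows:
        left = seq[a : b + 1]
        right = seq[c - b : c - a + 1]
        simple_l = _cache.get(left)
        if simple_l is None:
            simple_l = _cache[left] = is_simple_arm(left)
        if simple_l:
            continue
        simple_r = _cache.get(right)
        if simple_r is None:
            simple_r = _cache[right] = is_simple_arm(right)
        if simple_r:
            continue
        pairs.append(
            IRPair(
                left_start=a,
                left_end=b + 1,
                right_start=c - b,
                right_end=c - a + 1,
                arm_len=b - a + 1,
                arm_identity=ident,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# fast scanner


def _seed_diagonals(code: np.ndarray, params: ScanParams) -> set[int]:
    """Anti-diagonals holding at least one exact seed pair within element range.

    A window containing seed_len consecutive matches implies an exact match
    between a seed_len-mer and the reverse complement of another seed_len-mer
    on the same anti-diagonal, with seed span <= window element span; so
    every qualifying window lies on a nominated diagonal.
    """
    k = params.seed_len
    n = code.size
    if n < k:
        return set()
    nk = n - k + 1
    valid = np.ones(nk, dtype=bool)
    fwd = np.zeros(nk, dtype=np.int64)
    rcv = np.zeros(nk, dtype=np.int64)
    for t in range(k):
        window = code[t : t + nk]
        valid &= window >= 0
        fwd = fwd * 4 + np.where(window >= 0, window, 0)
        rcv += np.where(window >= 0, 3 - window, 0) * (4**t)
    index: dict[int, list[int]] = {}
    for i in np.nonzero(valid)[0]:
        index.setdefault(int(fwd[i]), []).append(int(i))
    diagonals: set[int] = set()
    max_span = params.max_element_len
    for j in np.nonzero(valid)[0]:
        hits = index.get(int(rcv[j]))
        if not hits:
            continue
        j = int(j)
        for i in hits:
            if i <= j and 0 < j + k - i <= max_span:
                diagonals.add(i + j + k - 1)
    return diagonals


def _enumerate_diagonal(
    code: np.ndarray, c: int, params: ScanParams
) -> list[tuple[int, int, float]]:
    """All windows on anti-diagonal c passing the acceptance rule (vectorized),
    before maximality and simple-arm filtering."""
    n = code.size
    lo, hi = _diag_region(c, n, params)
    if hi < lo or hi - lo + 1 < params.min_arm_len:
        return []
    ps = np.arange(lo, hi + 1)
    left = code[ps]
    right = code[c - ps]
    is_n = (left < 0) | (right < 0)
    match = (~is_n) & (left + right == 3)
    k = params.seed_len
    # run lengths of consecutive matches ending at each local position
    run = np.zeros(match.size, dtype=np.int64)
    acc = 0
    for idx, m in enumerate(match):
        acc = acc + 1 if m else 0
        run[idx] = acc
    if run.max(initial=0) < k:
        return []
    pm = np.concatenate(([0], np.cumsum(match)))
    pn = np.concatenate(([0], np.cumsum(is_n)))
    pk = np.concatenate(([0], np.cumsum(run >= k)))
    idx_match = np.nonzero(match)[0]
    # a must allow element length >= min_element_len
    a_hi_local = (c + 1 - params.min_element_len) // 2 - lo
    a_cand = idx_match[idx_match <= a_hi_local]
    b_cand = idx_match
    if a_cand.size == 0 or b_cand.size == 0:
        return []
    A = a_cand[:, None]
    B = b_cand[None, :]
    L = B - A + 1
    ok = L >= params.min_arm_len
    matches = pm[B + 1] - pm[A]
    ok &= matches + 1e-9 >= params.min_arm_identity * L
    ok &= (pn[B + 1] - pn[A]) == 0
    # seed-run containment: some local j in [a+k-1, b] with run[j] >= k
    lo_j = np.minimum(A + k - 1, match.size)
    ok &= (pk[np.minimum(B + 1, match.size)] - pk[lo_j]) > 0
    ai, bi = np.nonzero(ok)
    out = []
    for x, y in zip(a_cand[ai], b_cand[bi]):
        a = int(x) + lo
        b = int(y) + lo
        out.append((a, b, float(pm[y + 1] - pm[x]) / (y - x + 1)))
    return out


def find_inverted_repeats(
    slice_or_seq: GenomeSlice | str, params: ScanParams | None = None
) -> list[IRPair]:
    """Detect candidate TIR pairs in a slice (or bare sequence).

    Returns every maximal, non-simple arm pair passing the module acceptance
    rule, sorted by (left_start, right_end).  Slices shorter than
    min_element_len yield an empty list.
    """
    params = params or ScanParams()
    seq = slice_or_seq.residues if isinstance(slice_or_seq, GenomeSlice) else slice_or_seq
    n = len(seq)
    if n < params.min_element_len:
        return []
    code = _encode(seq)
    pairs: list[IRPair] = []
    cache: dict[str, bool] = {}
    for c in sorted(_seed_diagonals(code, params)):
        windows = _enumerate_diagonal(code, c, params)
        windows = _maximal(windows)
        pairs.extend(_build_pairs(seq, c, windows, cache))
    pairs.sort(key=lambda p: (p.left_start, p.right_end, p.left_end))
    return pairs


# ---------------------------------------------------------------------------
# oracle


def brute_force_ir(seq: str, params: ScanParams | None = None) -> list[IRPair]:
    """Direct enumeration of every arm placement; test oracle for the scanner.

    Applies the identical acceptance rule by checking all (a, b) windows on
    every anti-diagonal with plain Python arithmetic.  Refuses inputs longer
    than 2000 nt.
    """
    params = params or ScanParams()
    n = len(seq)
    if n > 2000:
        raise ParameterError("brute_force_ir is restricted to sequences <= 2000 nt")
    if n < params.min_element_len:
        return []
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    k = params.seed_len
    tau = params.min_arm_identity
    pairs: list[IRPair] = []
    cache: dict[str, bool] = {}
    for c in range(2 * n - 1):
        lo, hi = _diag_region(c, n, params)
        if hi < lo:
            continue
        width = hi - lo + 1
        match = [False] * width
        bad = [False] * width
        for off in range(width):
            p = lo + off
            q = c - p
            l, r = seq[p], seq[q]
            if l == "N" or r == "N":
                bad[off] = True
            elif comp[l] == r:
                match[off] = True
        # run length ending at each offset
        run = [0] * width
        acc = 0
        for off in range(width):
            acc = acc + 1 if match[off] else 0
            run[off] = acc
        if max(run, default=0) < k:
            continue
        pm = [0]
        pn = [0]
        pk = [0]
        for off in range(width):
            pm.append(pm[-1] + (1 if match[off] else 0))
            pn.append(pn[-1] + (1 if bad[off] else 0))
            pk.append(pk[-1] + (1 if run[off] >= k else 0))
        windows: list[tuple[int, int, float]] = []
        for ai in range(width):
            if not match[ai]:
                continue
            a = lo + ai
            elem = c - 2 * a + 1
            if elem < params.min_element_len or elem > params.max_element_len:
                continue
            for bi in range(ai + params.min_arm_len - 1, width):
                if not match[bi]:
                    continue
                length = bi - ai + 1
                m = pm[bi + 1] - pm[ai]
                if not _identity_ok(m, length, tau):
                    continue
                if pn[bi + 1] - pn[ai] > 0:
                    continue
                if pk[bi + 1] - pk[min(ai + k - 1, width)] <= 0:
                    continue
                windows.append((a, lo + bi, m / length))
        windows = _maximal(windows)
        pairs.extend(_build_pairs(seq, c, windows, cache))
    pairs.sort(key=lambda p: (p.left_start, p.right_end, p.left_end))
    return pairs


# ---------------------------------------------------------------------------
# low-complexity masking


def mask_low_complexity(
    seq: str, window: int = 64, entropy_threshold: float = 1.0
) -> str:
    """Hard-mask positions covered by any low-entropy window.

    Shannon entropy (bits) of the mononucleotide composition is computed for
    every length-`window` window (the whole sequence if shorter); windows with
    entropy <= entropy_threshold mask all positions they cover.  N residues do
    not contribute counts; an all-N window has entropy 0.
    """
    if window < 4:
        raise ParameterError("window must be >= 4")
    n = len(seq)
    if n == 0:
        return seq
    w = min(window, n)
    code = _encode(seq)
    onehot = np.zeros((4, n), dtype=np.int32)
    for v in range(4):
        onehot[v] = code == v
    cum = np.concatenate([np.zeros((4, 1), dtype=np.int64), np.cumsum(onehot, axis=1)], axis=1)
    counts = cum[:, w:] - cum[:, :-w]  # (4, n - w + 1)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts / np.where(totals > 0, totals, 1)
        ent = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=0)
    low = ent <= entropy_threshold + 1e-12
    if not low.any():
        return seq
    # union of covered intervals via difference array
    diff = np.zeros(n + 1, dtype=np.int64)
    starts = np.nonzero(low)[0]
    diff[starts] += 1
    diff[starts + w] -= 1
    covered = np.cumsum(diff[:-1]) > 0
    buf = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    buf[covered] = ord("N")
    return buf.tobytes().decode("ascii")
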