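"""Family-level evaluation of a putative element.

A genuine MITE family has many near-identical full-length copies inserted at
independent loci, so the 50-nt flanking contexts of its copies are diverse.
A "false family" (typically the internal structure of a retroelement that
happens to carry short inverted and direct repeats) also has many copies, but
every copy sits inside the same larger repeat, so all flanks look alike.
This module counts full-length genomic copies of an element, retrieves their
flanks and groups the flanks into classes, yielding the verdict:

  candidate             copies >= copy_threshold and flank classes >= flank_class_threshold
  false_family          copies >= copy_threshold and flank classes <  flank_class_threshold
  below_copy_threshold  copies <  copy_threshold

Homology search is exact k-mer seeding over the whole database followed by
edlib alignment of the full query at each seeded locus; overlapping hits are
collapsed to the best-scoring one per locus.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .errors import ParameterError
from .sequence_model import GenomeDatabase, reverse_complement

__all__ = [
    "FamilyHit",
    "FlankPair",
    "CandidateEvaluation",
    "GenomeIndex",
    "count_full_length_copies",
    "collect_flanks",
    "count_distinct_flanks",
    "evaluate_candidate",
    "sequence_identity",
]

VERDICT_CANDIDATE = "candidate"
VERDICT_FALSE = "false_family"
VERDICT_BELOW = "below_copy_threshold"


@dataclass(frozen=True)
class FamilyHit:
    """One full-length genomic copy; global 0-based half-open coordinates."""

    entry_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    identity: float
    query_coverage: float

    @property
    def score(self) -> float:
        return self.identity * self.query_coverage


@dataclass(frozen=True)
class FlankPair:
    """Element-oriented 50-nt contexts of one hit (shorter if truncated)."""

    left: str
    right: str
    hit: FamilyHit
    left_truncated: bool = False
    right_truncated: bool = False


@dataclass(frozen=True)
class CandidateEvaluation:
    element_seq: str
    copy_count: int
    distinct_flank_count: int
    verdict: str
    hits: tuple[FamilyHit, ...] = field(default=(), repr=False)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences over the shorter length."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / min(len(a), len(b)))


class GenomeIndex:
    """Exact k-mer index over a database for seeding homology searches.

    Built once per database; k-mers containing N are not indexed, and entries
    are kept separate so seeds never span an entry boundary.
    """

    def __init__(self, db: GenomeDatabase, k: int = 12):
        if len(db) == 0:
            raise ParameterError("empty database")
        self.db = db
        self.k = k
        self._offsets: list[int] = []
        self._ids: list[str] = []
        joined = []
        off = 0
        spacer = "N" * k
        for entry in db:
            self._offsets.append(off)
            self._ids.append(entry.id)
            joined.append(entry.residues)
            off += len(entry.residues) + k
            joined.append(spacer)
        self._seq = "".join(joined)
        self._index = self._build(self._seq, k)

    @staticmethod
    def _codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        code = np.full(raw.size, -1, dtype=np.int64)
        for base, val in zip(b"ACGT", range(4)):
            code[raw == base] = val
        n = raw.size
        if n < k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        nk = n - k + 1
        valid = np.ones(nk, dtype=bool)
        val_arr = np.zeros(nk, dtype=np.int64)
        for t in range(k):
            window = code[t : t + nk]
            valid &= window >= 0
            val_arr = val_arr * 4 + np.where(window >= 0, window, 0)
        return val_arr, valid

    @classmethod
    def _build(cls, seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        values, valid = cls._codes(seq, k)
        pos = np.nonzero(valid)[0]
        vals = values[pos]
        order = np.argsort(vals, kind="stable")
        return vals[order], pos[order]

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate to (entry_id, local_pos)."""
        i = bisect_right(self._offsets, global_pos) - 1
        return self._ids[i], global_pos - self._offsets[i]

    def entry_bounds(self, i: int) -> tuple[int, int]:
        start = self._offsets[i]
        return start, start + len(self.db.entries[i].residues)

    def seed_clusters(self, query: str, tol: int = 20) -> list[tuple[int, int]]:
        """Candidate (global start, supporting seed count) per locus.

        Seed-implied starts within `tol` nt of each other are one cluster;
        the smallest start represents the cluster.
        """
        values, valid = self._codes(query, self.k)
        vals_sorted, pos_sorted = self._index
        offsets = np.nonzero(valid)[0]
        if offsets.size == 0:
            return []
        keys = values[offsets]
        lo = np.searchsorted(vals_sorted, keys, side="left")
        hi = np.searchsorted(vals_sorted, keys, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            return []
        starts = np.concatenate(
            [pos_sorted[a:b] - off for off, a, b, c in zip(offsets, lo, hi, counts) if c]
        )
        starts.sort()
        boundaries = np.nonzero(np.diff(starts) > tol)[0] + 1
        groups = np.split(starts, boundaries)
        return [(int(g[0]), int(g.size)) for g in groups]

    def search(
        self,
        query: str,
        min_identity: float = 0.80,
        min_coverage: float = 0.90,
        both_strands: bool = True,
        cluster_tol: int = 20,
        pad: int = 20,
        min_seed_support: int = 2,
    ) -> list[FamilyHit]:
        """All full-length matches of `query` in the database.

        Seeds nominate candidate loci; loci supported by at least
        min_seed_support exact k-mers are verified by aligning the whole query
        (edlib infix mode) against a padded window -- a genuine full-length
        copy within the identity tolerance shares many exact k-mers with the
        query, while chance loci almost always show a single one.  Overlapping
        hits at one locus are collapsed to the best identity*coverage.
        """
        hits: list[FamilyHit] = []
        qlen = len(query)
        strands = [("+", query)]
        if both_strands:
            strands.append(("-", reverse_complement(query)))
        for strand, qseq in strands:
            for s, support in self.seed_clusters(qseq, cluster_tol):
                if support < min_seed_support:
                    continue
                entry_id, local = self.locate(s)
                entry = self.db.get(entry_id)
                w_start = max(0, local - pad)
                w_end = min(len(entry.residues), local + qlen + pad)
                window = entry.residues[w_start:w_end]
                if len(window) < qlen * min_coverage:
                    continue
                aln = edlib.align(qseq, window, mode="HW", task="locations")
                dist = aln["editDistance"]
                if dist < 0 or not aln["locations"]:
                    continue
                identity = 1.0 - dist / qlen
                if identity < min_identity:
                    continue
                loc0, loc1 = aln["locations"][0]
                span = loc1 - loc0 + 1
                coverage = min(1.0, span / qlen)
                if coverage < min_coverage:
                    continue
                hits.append(
                    FamilyHit(
                        entry_id=entry_id,
                        start=w_start + loc0,
                        end=w_start + loc1 + 1,
                        strand=strand,
                        identity=identity,
                        query_coverage=coverage,
                    )
                )
        return _collapse_loci(hits)


def _collapse_loci(hits: list[FamilyHit]) -> list[FamilyHit]:
    """Merge hits overlapping by more than half of the shorter hit."""
    hits = sorted(hits, key=lambda h: (h.entry_id, h.start, -h.score))
    kept: list[FamilyHit] = []
    for h in hits:
        merged = False
        for i, other in enumerate(kept):
            if other.entry_id != h.entry_id:
                continue
            ov = min(h.end, other.end) - max(h.start, other.start)
            shorter = min(h.end - h.start, other.end - other.start)
            if ov > 0.5 * shorter:
                if h.score > other.score:
                    kept[i] = h
                merged = True
                break
        if not merged:
            kept.append(h)
    kept.sort(key=lambda h: (h.entry_id, h.start))
    return kept


def count_full_length_copies(
    element_seq: str,
    db: GenomeDatabase,
    copy_identity_min: float = 0.80,
    full_length_coverage_min: float = 0.90,
    index: Optional[GenomeIndex] = None,
) -> list[FamilyHit]:
    """Full-length genomic copies of the element on both strands.

    The element's own source locus is one of the hits.  Pass a prebuilt
    GenomeIndex to amortize index construction over many queries.
    """
    if len(db) == 0:
        raise ParameterError("empty database")
    idx = index if index is not None else GenomeIndex(db)
    return idx.search(
        element_seq, min_identity=copy_identity_min, min_coverage=full_length_coverage_min
    )


def collect_flanks(
    hits: Sequence[FamilyHit], db: GenomeDatabase, flank_window: int = 50
) -> list[FlankPair]:
    """Element-oriented flanking windows for each hit.

    Minus-strand hits get their genomic flanks swapped and reverse
    complemented so left/right always mean upstream/downstream of the element
    as the element reads.  Flanks truncated by entry ends are flagged.
    """
    pairs: list[FlankPair] = []
    for h in hits:
        res = db.get(h.entry_id).residues
        gl = res[max(0, h.start - flank_window) : h.start]
        gr = res[h.end : h.end + flank_window]
        l_trunc = len(gl) < flank_window
        r_trunc = len(gr) < flank_window
        if h.strand == "-":
            left, right = reverse_complement(gr), reverse_complement(gl)
            l_trunc, r_trunc = r_trunc, l_trunc
        else:
            left, right = gl, gr
        pairs.append(FlankPair(left, right, h, l_trunc, r_trunc))
    return pairs


def count_distinct_flanks(
    pairs: Sequence[FlankPair],
    subset_max: int = 20,
    flank_identity_max: float = 0.80,
) -> int:
    """Number of flank classes among (a subset of) the copies.

    Two copies share a class when either their left flanks or their right
    flanks align at more than flank_identity_max identity over the shorter
    length; classes are single-linkage groups.  Comparing a small subset
    (first subset_max copies in genome order) is sufficient because a false
    family's copies all share one context.
    """
    if not pairs:
        raise ParameterError("no flank pairs")
    subset = list(pairs)[:subset_max]
    n = len(subset)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            same = (
                sequence_identity(subset[i].left, subset[j].left) > flank_identity_max
                or sequence_identity(subset[i].right, subset[j].right) > flank_identity_max
            )
            if same:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def evaluate_candidate(
    element_seq: str,
    db: GenomeDatabase,
    *,
    index: Optional[GenomeIndex] = None,
    copy_identity_min: float = 0.80,
    full_length_coverage_min: float = 0.90,
    flank_window: int = 50,
    subset_max: int = 20,
    flank_identity_max: float = 0.80,
    copy_threshold: int = 10,
    flank_class_threshold: int = 3,
) -> CandidateEvaluation:
    """Copy counting + flank diversity, composed into a verdict."""
    hits = count_full_length_copies(
        element_seq, db, copy_identity_min, full_length_coverage_min, index=index
    )
    copy_count = len(hits)
    if copy_count == 0:
        # should not happen (self-hit), but keep the partition total
        return CandidateEvaluation(element_seq, 0, 0, VERDICT_BELOW, ())
    flanks = collect_flanks(hits, db, flank_window)
    distinct = count_distinct_flanks(flanks, subset_max, flank_identity_max)
    if copy_count < copy_threshold:
        verdict = VERDICT_BELOW
    elif distinct >= flank_class_threshold:
        verdict = VERDICT_CANDIDATE
    else:
        verdict = VERDICT_FALSE
    return CandidateEvaluation(element_seq, copy_count, distinct, verdict, tuple(hits))
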