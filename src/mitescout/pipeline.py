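"""End-to-end discovery pipeline.

Slices the genome, masks already-deposited families and low-complexity
sequence, scans for inverted-repeat pairs, screens for TSDs, evaluates each
surviving candidate genome-wide, and deposits exemplars:

  candidate    -> candidates.fasta + filter database
  false_family -> false.fasta + filter database
  below copy threshold -> nothing

The filter database masks all upcoming slices, so each family is processed
essentially once -- the redundancy-reduction design.  An optional early stop
derives from the uniform-placement sampling model: if a family's N copies are
placed uniformly at random, the probability that none falls in the first
fraction X of the database is P = (1-X)^N, so scanning X = 1 - P^(1/N) of the
database misses an N-copy family with probability at most P.  Early stopping
applies to discovery only; copy counting and flank retrieval always use the
whole database.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib

from .errors import ParameterError
from .family_eval import (
    VERDICT_BELOW,
    VERDICT_CANDIDATE,
    VERDICT_FALSE,
    GenomeIndex,
    evaluate_candidate,
)
from .ir_scan import ScanParams, find_inverted_repeats, mask_low_complexity
from .sequence_model import (
    GenomeDatabase,
    GenomeSlice,
    hard_mask,
    read_fasta,
    slice_entries,
    write_fasta,
)
from .tsd import TSDMatch, find_tsd_with_fallback

__all__ = [
    "PipelineParams",
    "FilterDatabase",
    "ProgressRecord",
    "RunResult",
    "coverage_fraction",
    "miss_probability",
    "discovery_stop_point",
    "mask_known",
    "is_redundant",
    "run",
    "write_report",
]


# ---------------------------------------------------------------------------
# sampling model


def coverage_fraction(p_miss: float, n_copies: int) -> float:
    """Fraction X of the database to scan so that a uniformly placed
    n_copies-copy family is missed with probability p_miss: X = 1 - P^(1/N)."""
    if not (0 < p_miss <= 1):
        raise ParameterError("p_miss must be in (0, 1]")
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    return 1.0 - p_miss ** (1.0 / n_copies)


def miss_probability(x: float, n_copies: int) -> float:
    """P = (1-X)^N: probability that no copy lies in the first fraction x."""
    if not (0 <= x <= 1):
        raise ParameterError("x must be in [0, 1]")
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    return (1.0 - x) ** n_copies


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PipelineParams:
    scan: ScanParams = field(default_factory=ScanParams)
    tsd_min: int = 2
    tsd_max: int = 10
    flank_probe: int = 10
    tir_terminal: int = 5
    flank_window: int = 50
    copy_threshold: int = 10
    flank_class_threshold: int = 3
    copy_identity_min: float = 0.80
    full_length_coverage_min: float = 0.90
    subset_max: int = 20
    flank_identity_max: float = 0.80
    redundancy_identity: float = 0.80
    redundancy_coverage: float = 0.80
    max_slice_size: int = 100_000
    slice_overlap: int = 900
    low_complexity_window: int = 64
    low_complexity_entropy: float = 1.0
    p_miss: Optional[float] = None
    tsd_anywhere: bool = False
    workers: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.tsd_min <= self.tsd_max <= 10):
            raise ParameterError("need 2 <= tsd_min <= tsd_max <= 10")
        if self.p_miss is not None and not (0 < self.p_miss < 1):
            raise ParameterError("p_miss must be in (0, 1) when set")
        if self.workers < 1:
            raise ParameterError("workers must be >= 1")
        if self.slice_overlap < self.scan.max_element_len + 2 * self.flank_window:
            raise ParameterError(
                "slice_overlap must be >= max_element_len + 2*flank_window "
                "so no element plus its context straddles two slices undetected"
            )
        if self.slice_overlap >= self.max_slice_size:
            raise ParameterError("slice_overlap must be smaller than max_slice_size")


def discovery_stop_point(params: PipelineParams) -> float:
    """Fraction of the database after which discovery scanning halts (1.0 if
    early stopping is disabled)."""
    if params.p_miss is None:
        return 1.0
    return coverage_fraction(params.p_miss, params.copy_threshold)


# ---------------------------------------------------------------------------
# filter database


@dataclass(frozen=True)
class FilterRecord:
    name: str
    label: str  # "candidate" | "false_family"
    sequence: str


class FilterDatabase:
    """Deposited exemplars (candidate and false) used to mask upcoming slices.

    The similarity machinery works directly on the record list; `version`
    increments on every deposit, standing in for the index rebuild the
    original performs after each deposit.
    """

    def __init__(self) -> None:
        self.records: list[FilterRecord] = []
        self.version = 0

    def add(self, name: str, label: str, sequence: str) -> None:
        self.records.append(FilterRecord(name, label, sequence))
        self.version += 1

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def _matches(query: str, target: str, min_identity: float, min_coverage: float) -> bool:
    """True if the shorter sequence aligns inside the longer at the given
    identity, covering at least min_coverage of the shorter length."""
    short, long_ = (query, target) if len(query) <= len(target) else (target, query)
    if not short:
        return False
    aln = edlib.align(short, long_, mode="HW", task="locations")
    dist = aln["editDistance"]
    if dist < 0 or not aln["locations"]:
        return False
    # infix mode aligns the whole shorter sequence into the longer, so the
    # matched span covers it entirely; the identity requirement alone decides
    loc0, loc1 = aln["locations"][0]
    coverage = min(1.0, (loc1 - loc0 + 1) / len(short))
    identity = 1.0 - dist / len(short)
    return identity >= min_identity and coverage >= min_coverage


def is_redundant(
    element_seq: str,
    deposited: Sequence[str],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> bool:
    """True if the element matches any deposited sequence at >= min_identity
    over >= min_coverage of the shorter length."""
    return any(
        _matches(element_seq, rec, min_identity, min_coverage) for rec in deposited
    )


def mask_known(
    sl: GenomeSlice, filter_db: FilterDatabase, params: PipelineParams
) -> GenomeSlice:
    """Hard-mask every region of the slice matching a filter record at the
    copy-counting thresholds."""
    if len(filter_db) == 0:
        return sl
    from .sequence_model import GenomeDatabase as _DB, SequenceEntry as _Entry

    pseudo = _DB([_Entry("slice", "", sl.residues)])
    idx = GenomeIndex(pseudo, k=12)
    intervals: list[tuple[int, int]] = []
    for rec in filter_db.records:
        hits = idx.search(
            rec.sequence,
            min_identity=params.copy_identity_min,
            min_coverage=params.full_length_coverage_min,
        )
        intervals.extend((h.start, h.end) for h in hits)
    return hard_mask(sl, intervals)


# ---------------------------------------------------------------------------
# progress reporting


@dataclass(frozen=True)
class ProgressRecord:
    fraction_processed: float
    n_candidates: int
    n_false: int
    elapsed: float  # seconds
    rate: float  # fraction of database per hour (cumulative average)
    predicted_remaining: float  # seconds


def write_report(records: Sequence[ProgressRecord], path: str | Path) -> None:
    """Tab-separated progress report, one row per new candidate."""
    header = "fraction_processed\tn_candidates\tn_false\telapsed_s\trate_per_hour\tpredicted_remaining_s"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for r in records:
            fh.write(
                f"{r.fraction_processed:.6f}\t{r.n_candidates}\t{r.n_false}\t"
                f"{r.elapsed:.2f}\t{r.rate:.6f}\t{r.predicted_remaining:.1f}\n"
            )


# ---------------------------------------------------------------------------
# run


@dataclass
class Deposit:
    name: str
    label: str
    sequence: str
    entry_id: str
    start: int  # global, 0-based half-open
    end: int
    arm_len: int
    tsd: TSDMatch
    copy_count: int
    flank_classes: int

    def header(self) -> str:
        return (
            f"{self.name} len={len(self.sequence)} tir={self.arm_len} "
            f"tsd={self.tsd.sequence} copies={self.copy_count} "
            f"flank_classes={self.flank_classes} "
            f"locus={self.entry_id}:{self.start + 1}-{self.end}"
        )


@dataclass
class RunResult:
    candidates: list[Deposit]
    false_families: list[Deposit]
    filter_db: FilterDatabase
    report: list[ProgressRecord]
    out_dir: Path

    @property
    def candidates_path(self) -> Path:
        return self.out_dir / "candidates.fasta"

    @property
    def false_path(self) -> Path:
        return self.out_dir / "false.fasta"


@dataclass
class _Candidate:
    element_seq: str
    entry_id: str
    g_start: int
    g_end: int
    arm_len: int
    tsd: TSDMatch


def _slice_candidates(
    sl: GenomeSlice,
    masked: GenomeSlice,
    params: PipelineParams,
    seen: set[tuple[str, int, int]],
) -> list[_Candidate]:
    """IR scan + TSD screen on one slice; dedupes overlap-region repeats.

    Chance complementary matches just outside a real element can extend the
    detected arms a few nt beyond the true boundary (the extended window then
    shadows the exact one by maximality), which would hide the TSD from the
    abutting search.  The screen therefore retries the TSD search with the
    boundary trimmed symmetrically up to 5 nt; the first boundary with a TSD
    defines the element span.
    """
    out: list[_Candidate] = []
    res = sl.residues  # original residues for flanks/element sequence
    fp = params.flank_probe
    max_trim = 5
    for pair in find_inverted_repeats(masked, params.scan):
        found = None
        for trim in range(0, min(max_trim, pair.arm_len - 1) + 1):
            start = pair.left_start + trim
            end = pair.right_end - trim
            if end - start < params.scan.min_element_len:
                break
            left_flank = res[max(0, start - fp) : start].rjust(fp, "N")
            right_flank = res[end : end + fp].ljust(fp, "N")
            tir_head = res[start : start + params.tir_terminal]
            tir_tail = res[max(0, end - params.tir_terminal) : end]
            tsd = find_tsd_with_fallback(
                left_flank,
                right_flank,
                tir_head,
                tir_tail,
                anywhere=params.tsd_anywhere,
                tsd_min=params.tsd_min,
                tsd_max=params.tsd_max,
            )
            if tsd is not None:
                found = (start, end, tsd, trim)
                break
        if found is None:
            continue
        start, end, tsd, trim = found
        g_start = sl.parent_offset + start
        g_end = sl.parent_offset + end
        key = (sl.parent_id, g_start, g_end)
        if key in seen:
            continue
        seen.add(key)
        element = res[start:end]
        out.append(
            _Candidate(element, sl.parent_id, g_start, g_end, pair.arm_len - trim, tsd)
        )
    # Process strongest TIR evidence first (longest arm, then tightest span,
    # then leftmost).  Around a real element or decoy core, chance short-arm
    # pairs span wider (element + background) or narrower (internal fragment)
    # windows; with the genuine pair deposited first, those chance spans are
    # suppressed as redundant instead of becoming malformed exemplars.
    out.sort(key=lambda c: (-c.arm_len, c.g_end - c.g_start, c.g_start))
    return out


def run(
    genome_path: str | Path,
    params: PipelineParams | None = None,
    out_dir: str | Path = ".",
) -> RunResult:
    """Run the whole discovery pipeline on a FASTA genome database.

    Deterministic for a fixed (genome, params) regardless of worker count:
    candidate evaluations may run concurrently but deposits are serialized in
    discovery order, and masking for a slice uses the filter state at the
    time the slice begins.
    """
    params = params or PipelineParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = read_fasta(genome_path)
    index = GenomeIndex(db, k=12)
    slices = slice_entries(db, params.max_slice_size, params.slice_overlap)
    stop = discovery_stop_point(params)
    total = db.total_length

    filter_db = FilterDatabase()
    candidates: list[Deposit] = []
    false_families: list[Deposit] = []
    report: list[ProgressRecord] = []
    seen: set[tuple[str, int, int]] = set()
    log_lines: list[str] = [f"params: {params}"]
    t0 = time.monotonic()
    processed = 0  # novel nt processed (overlaps counted once)
    prev_end: dict[str, int] = {}

    pool = ThreadPoolExecutor(max_workers=params.workers) if params.workers > 1 else None
    try:
        for sl in slices:
            if processed / total >= stop - 1e-12:
                log_lines.append(
                    f"early stop at fraction {processed / total:.4f} (stop point {stop:.4f})"
                )
                break
            masked = mask_known(sl, filter_db, params)
            masked = GenomeSlice(
                masked.parent_id,
                masked.parent_offset,
                mask_low_complexity(
                    masked.residues,
                    params.low_complexity_window,
                    params.low_complexity_entropy,
                ),
                masked.slice_index,
            )
            cands = _slice_candidates(sl, masked, params, seen)
            survivors = [
                c
                for c in cands
                if not is_redundant(
                    c.element_seq,
                    filter_db.sequences(),
                    params.redundancy_identity,
                    params.redundancy_coverage,
                )
            ]

            def _eval(c: _Candidate):
                return evaluate_candidate(
                    c.element_seq,
                    db,
                    index=index,
                    copy_identity_min=params.copy_identity_min,
                    full_length_coverage_min=params.full_length_coverage_min,
                    flank_window=params.flank_window,
                    subset_max=params.subset_max,
                    flank_identity_max=params.flank_identity_max,
                    copy_threshold=params.copy_threshold,
                    flank_class_threshold=params.flank_class_threshold,
                )

            if pool is not None:
                evaluations = list(pool.map(_eval, survivors))
            else:
                evaluations = [_eval(c) for c in survivors]

            # serial deposits in discovery order
            slice_deposits: list[str] = []
            new_end = sl.parent_offset + len(sl)
            frac_after = min(
                1.0, (processed + new_end - prev_end.get(sl.parent_id, 0)) / total
            )
            for cand, ev in zip(survivors, evaluations):
                if slice_deposits and is_redundant(
                    cand.element_seq,
                    slice_deposits,
                    params.redundancy_identity,
                    params.redundancy_coverage,
                ):
                    continue
                if ev.verdict == VERDICT_BELOW:
                    continue
                if ev.verdict == VERDICT_CANDIDATE:
                    if is_redundant(
                        cand.element_seq,
                        [d.sequence for d in candidates],
                        params.redundancy_identity,
                        params.redundancy_coverage,
                    ):
                        continue
                    name = f"MD_{len(candidates) + 1}"
                    dep = Deposit(
                        name,
                        VERDICT_CANDIDATE,
                        cand.element_seq,
                        cand.entry_id,
                        cand.g_start,
                        cand.g_end,
                        cand.arm_len,
                        cand.tsd,
                        ev.copy_count,
                        ev.distinct_flank_count,
                    )
                    candidates.append(dep)
                    filter_db.add(name, VERDICT_CANDIDATE, cand.element_seq)
                    slice_deposits.append(cand.element_seq)
                    elapsed = time.monotonic() - t0
                    rate = frac_after / (elapsed / 3600.0) if elapsed > 0 else 0.0
                    remaining = (
                        (1.0 - frac_after) / rate * 3600.0 if rate > 0 else float("inf")
                    )
                    report.append(
                        ProgressRecord(
                            frac_after,
                            len(candidates),
                            len(false_families),
                            elapsed,
                            rate,
                            remaining,
                        )
                    )
                    _write_outputs(out_dir, candidates, false_families, filter_db, report)
                else:  # false family
                    name = f"MDF_{len(false_families) + 1}"
                    dep = Deposit(
                        name,
                        VERDICT_FALSE,
                        cand.element_seq,
                        cand.entry_id,
                        cand.g_start,
                        cand.g_end,
                        cand.arm_len,
                        cand.tsd,
                        ev.copy_count,
                        ev.distinct_flank_count,
                    )
                    false_families.append(dep)
                    filter_db.add(name, VERDICT_FALSE, cand.element_seq)
                    slice_deposits.append(cand.element_seq)
                    _write_outputs(out_dir, candidates, false_families, filter_db, report)
            processed += new_end - prev_end.get(sl.parent_id, 0)
            prev_end[sl.parent_id] = new_end
            log_lines.append(
                f"slice {sl.slice_index} ({sl.parent_id}:{sl.parent_offset}): "
                f"{len(cands)} IR+TSD candidates, {len(survivors)} evaluated, "
                f"{len(candidates)} candidates / {len(false_families)} false so far"
            )
            _write_outputs(out_dir, candidates, false_families, filter_db, report)
            _write_state(out_dir, sl.slice_index, len(candidates), len(false_families))
    finally:
        if pool is not None:
            pool.shutdown()

    log_lines.append(
        f"done: {len(candidates)} candidates, {len(false_families)} false families, "
        f"{time.monotonic() - t0:.1f}s"
    )
    _write_outputs(out_dir, candidates, false_families, filter_db, report)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return RunResult(candidates, false_families, filter_db, report, out_dir)


def _write_outputs(
    out_dir: Path,
    candidates: list[Deposit],
    false_families: list[Deposit],
    filter_db: FilterDatabase,
    report: list[ProgressRecord],
) -> None:
    write_fasta([(d.header(), d.sequence) for d in candidates], out_dir / "candidates.fasta")
    write_fasta([(d.header(), d.sequence) for d in false_families], out_dir / "false.fasta")
    write_fasta(
        [(f"{r.name} label={r.label}", r.sequence) for r in filter_db.records],
        out_dir / "filter.fasta",
    )
    write_report(report, out_dir / "report.tsv")


def _write_state(out_dir: Path, slice_index: int, n_cand: int, n_false: int) -> None:
    (out_dir / "state.json").write_text(
        json.dumps(
            {"last_slice": slice_index, "n_candidates": n_cand, "n_false": n_false}
        )
    )
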