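"""Synthetic genomes with planted MITE families, false families and simple
repeats, plus truth records and an output evaluator.

The generator emulates the structures the discovery pipeline must separate:

* true MITE families: TIR + random interior + reverse-complement TIR, each
  copy inserted at an independent uniformly random locus with a genuine
  target site duplication (the tsd_len nt at the insertion point duplicated
  on both sides) and an independent per-copy substitution load;
* false families: the same IR/DR-bearing core, but every copy embedded in one
  fixed 50-nt left/right context before planting -- the signature of a repeat
  that rides inside a larger element (retroelement internal structure);
* simple repeats: homopolymer, (AT)n and (GC)n stretches.

Insertions overwrite background sequence (rather than growing the genome) so
all truth coordinates stay valid; loci are non-overlapping by rejection
sampling with a margin wide enough that planted flank contexts stay
independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np

from .errors import ParameterError
from .ir_scan import is_simple_arm
from .sequence_model import GenomeDatabase, SequenceEntry, reverse_complement

__all__ = [
    "FamilySpec",
    "TruthRecord",
    "SimulatedGenome",
    "make_background",
    "make_mite_consensus",
    "plant_family",
    "plant_false_family",
    "plant_simple_repeats",
    "simulate",
    "evaluate_output",
]

KIND_TRUE = "true_mite"
KIND_FALSE = "false_retro_like"
KIND_SIMPLE = "simple_repeat"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# margin around a planted locus: room for 50-nt flank retrieval plus slack
_MARGIN = 60


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    element_len: int
    tir_len: int
    tsd_len: int
    copy_number: int
    mutation_rate: float = 0.0
    kind: str = KIND_TRUE

    def __post_init__(self) -> None:
        if not (50 <= self.element_len <= 800):
            raise ParameterError("element_len must be within [50, 800]")
        if 2 * self.tir_len >= self.element_len:
            raise ParameterError("need 2*tir_len < element_len")
        if not (2 <= self.tsd_len <= 10):
            raise ParameterError("tsd_len must be within [2, 10]")
        if not (0 <= self.mutation_rate <= 0.2):
            raise ParameterError("mutation_rate must be within [0, 0.2]")
        if self.kind not in (KIND_TRUE, KIND_FALSE, KIND_SIMPLE):
            raise ParameterError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class TruthRecord:
    """One planted copy; global 0-based half-open element coordinates."""

    family_id: str
    entry_id: str
    start: int
    end: int
    strand: str
    identity: float  # to the family consensus
    flank_context_id: str


@dataclass
class SimulatedGenome:
    db: GenomeDatabase
    truths: list[TruthRecord]
    consensus_by_family: dict[str, str]
    specs: list[FamilySpec]
    simple_intervals: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# background


def make_background(
    total_len: int, n_entries: int, gc: float, seed: int
) -> GenomeDatabase:
    """I.i.d. random genome at the given GC content, split into n_entries."""
    if total_len < n_entries or n_entries < 1:
        raise ParameterError("need total_len >= n_entries >= 1")
    if not (0 <= gc <= 1):
        raise ParameterError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_len = total_len // n_entries
    lengths = [base_len] * n_entries
    lengths[0] += total_len - base_len * n_entries
    entries = []
    for i, ln in enumerate(lengths):
        draw = rng.choice(4, size=ln, p=probs)
        residues = _BASES[draw].tobytes().decode("ascii")
        entries.append(SequenceEntry(f"chr{i + 1}", f"synthetic background", residues))
    return GenomeDatabase(entries)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def make_mite_consensus(spec: FamilySpec, seed: int) -> str:
    """TIR + random interior + reverse complement TIR; TIR is never simple."""
    if spec.kind != KIND_TRUE and spec.kind != KIND_FALSE:
        raise ParameterError("consensus generation needs an element-bearing kind")
    rng = np.random.default_rng(seed)
    while True:
        tir = _random_seq(rng, spec.tir_len)
        if not is_simple_arm(tir):
            break
    interior = _random_seq(rng, spec.element_len - 2 * spec.tir_len)
    return tir + interior + reverse_complement(tir)


# ---------------------------------------------------------------------------
# planting


class _Occupancy:
    """Per-entry reserved intervals for non-overlapping placement."""

    def __init__(self) -> None:
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, entry_id: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._iv.get(entry_id, []))

    def reserve(self, entry_id: str, start: int, end: int) -> None:
        self._iv.setdefault(entry_id, []).append((start, end))


def _choose_locus(
    rng: np.random.Generator,
    db: GenomeDatabase,
    slot: int,
    occupancy: _Occupancy,
    max_tries: int = 10_000,
) -> tuple[str, int]:
    lengths = np.array([len(e) for e in db.entries], dtype=float)
    usable = lengths - slot - 2 * _MARGIN
    if (usable <= 0).all():
        raise ParameterError("no entry large enough for the requested insertion")
    probs = np.clip(usable, 0, None)
    probs = probs / probs.sum()
    for _ in range(max_tries):
        i = int(rng.choice(len(db.entries), p=probs))
        entry = db.entries[i]
        pos = int(rng.integers(_MARGIN, len(entry) - slot - _MARGIN))
        if not occupancy.conflicts(entry.id, pos - _MARGIN, pos + slot + _MARGIN):
            return entry.id, pos
    raise ParameterError("could not place insertion: genome too crowded")


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    exempt: Sequence[tuple[int, int]] = (),
) -> tuple[str, int]:
    """Substitution-only mutation; positions inside `exempt` intervals kept."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    for s, e in exempt:
        hit[s:e] = False
    n_mut = 0
    for i in np.nonzero(hit)[0]:
        current = arr[i]
        choices = [b for b in b"ACGT" if b != current]
        arr[i] = choices[int(rng.integers(0, 3))]
        n_mut += 1
    return arr.tobytes().decode("ascii"), n_mut


def _as_buffers(db: GenomeDatabase) -> dict[str, bytearray]:
    return {e.id: bytearray(e.residues, "ascii") for e in db.entries}


def _rebuild(db: GenomeDatabase, buffers: dict[str, bytearray]) -> GenomeDatabase:
    return GenomeDatabase(
        [
            SequenceEntry(e.id, e.description, buffers[e.id].decode("ascii"))
            for e in db.entries
        ]
    )


def plant_family(
    db: GenomeDatabase,
    consensus: str,
    spec: FamilySpec,
    seed: int,
    occupancy: Optional[_Occupancy] = None,
) -> tuple[GenomeDatabase, list[TruthRecord]]:
    """Insert copy_number mutated copies at independent uniform loci.

    Each insertion duplicates the tsd_len nt at the target site on both sides
    of the element (true TSD semantics).  The terminal 5 nt of each TIR are
    exempt from mutation so junction signatures stay decidable at high rates.
    """
    rng = np.random.default_rng(seed)
    occupancy = occupancy if occupancy is not None else _Occupancy()
    buffers = _as_buffers(db)
    truths: list[TruthRecord] = []
    elen = len(consensus)
    slot = spec.tsd_len + elen + spec.tsd_len
    exempt = [(0, 5), (elen - 5, elen)]
    for i in range(spec.copy_number):
        entry_id, pos = _choose_locus(rng, db, slot, occupancy)
        buf = buffers[entry_id]
        ts = buf[pos : pos + spec.tsd_len].decode("ascii")
        copy, n_mut = _mutate(consensus, spec.mutation_rate, rng, exempt)
        start = pos + spec.tsd_len
        end = start + elen
        buf[start:end] = copy.encode("ascii")
        buf[end : end + spec.tsd_len] = ts.encode("ascii")
        occupancy.reserve(entry_id, pos - _MARGIN, pos + slot + _MARGIN)
        truths.append(
            TruthRecord(
                spec.family_id,
                entry_id,
                start,
                end,
                "+",
                1.0 - n_mut / elen,
                f"{spec.family_id}_locus{i}",
            )
        )
    return _rebuild(db, buffers), truths


def plant_false_family(
    db: GenomeDatabase,
    spec: FamilySpec,
    seed: int,
    occupancy: Optional[_Occupancy] = None,
) -> tuple[GenomeDatabase, list[TruthRecord], str]:
    """Plant a retroelement-like decoy: an IR/DR-bearing core inside one fixed
    flanking context, repeated verbatim at every locus.

    Returns (db', truths, core_consensus); the core alone passes the IR and
    TSD screens, but every copy shares identical 50-nt flanks.
    """
    if spec.kind != KIND_FALSE:
        raise ParameterError("spec.kind must be false_retro_like")
    rng = np.random.default_rng(seed)
    occupancy = occupancy if occupancy is not None else _Occupancy()
    element = make_mite_consensus(spec, seed)
    ts = _random_seq(rng, spec.tsd_len)
    ctx_left = _random_seq(rng, 50)
    ctx_right = _random_seq(rng, 50)
    cassette = ctx_left + ts + element + ts + ctx_right
    buffers = _as_buffers(db)
    truths: list[TruthRecord] = []
    elen = len(element)
    core_start_in_cassette = 50 + spec.tsd_len
    for i in range(spec.copy_number):
        entry_id, pos = _choose_locus(rng, db, len(cassette), occupancy)
        buf = buffers[entry_id]
        copy, n_mut = _mutate(
            element, spec.mutation_rate, rng, [(0, 5), (elen - 5, elen)]
        )
        full = ctx_left + ts + copy + ts + ctx_right
        buf[pos : pos + len(full)] = full.encode("ascii")
        occupancy.reserve(entry_id, pos - _MARGIN, pos + len(full) + _MARGIN)
        start = pos + core_start_in_cassette
        truths.append(
            TruthRecord(
                spec.family_id,
                entry_id,
                start,
                start + elen,
                "+",
                1.0 - n_mut / elen,
                f"{spec.family_id}_shared",
            )
        )
    return _rebuild(db, buffers), truths, element


def plant_simple_repeats(
    db: GenomeDatabase,
    n_stretches: int,
    len_range: tuple[int, int] = (100, 300),
    seed: int = 0,
    occupancy: Optional[_Occupancy] = None,
) -> tuple[GenomeDatabase, list[tuple[str, int, int]]]:
    """Overwrite random loci with homopolymer, (AT)n and (GC)n stretches."""
    rng = np.random.default_rng(seed)
    occupancy = occupancy if occupancy is not None else _Occupancy()
    buffers = _as_buffers(db)
    motifs = ["A", "T", "AT", "GC", "TA", "CG"]
    intervals: list[tuple[str, int, int]] = []
    for i in range(n_stretches):
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        motif = motifs[int(rng.integers(0, len(motifs)))]
        stretch = (motif * ln)[:ln]
        entry_id, pos = _choose_locus(rng, db, ln, occupancy)
        buffers[entry_id][pos : pos + ln] = stretch.encode("ascii")
        occupancy.reserve(entry_id, pos - _MARGIN, pos + ln + _MARGIN)
        intervals.append((entry_id, pos, pos + ln))
    return _rebuild(db, buffers), intervals


# ---------------------------------------------------------------------------
# whole-scenario convenience


def simulate(
    total_len: int,
    n_entries: int,
    specs: Sequence[FamilySpec],
    seed: int,
    gc: float = 0.43,
    n_simple: int = 0,
    simple_len_range: tuple[int, int] = (100, 300),
) -> SimulatedGenome:
    """Background + all planted families and simple repeats, with truth."""
    db = make_background(total_len, n_entries, gc, seed)
    occupancy = _Occupancy()
    truths: list[TruthRecord] = []
    consensus: dict[str, str] = {}
    rng = np.random.default_rng(seed + 1)
    for spec in specs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if spec.kind == KIND_TRUE:
            cons = make_mite_consensus(spec, sub_seed)
            db, t = plant_family(db, cons, spec, sub_seed, occupancy)
            consensus[spec.family_id] = cons
            truths.extend(t)
        elif spec.kind == KIND_FALSE:
            db, t, core = plant_false_family(db, spec, sub_seed, occupancy)
            consensus[spec.family_id] = core
            truths.extend(t)
        else:
            raise ParameterError("simple repeats go through n_simple")
    simple_intervals: list[tuple[str, int, int]] = []
    if n_simple > 0:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        db, simple_intervals = plant_simple_repeats(
            db, n_simple, simple_len_range, sub_seed, occupancy
        )
    return SimulatedGenome(db, truths, consensus, list(specs), simple_intervals)


# ---------------------------------------------------------------------------
# evaluation


def _read_fasta_seqs(path: str | Path) -> list[str]:
    from .sequence_model import read_fasta
    from .errors import FormatError

    try:
        return [e.residues for e in read_fasta(path)]
    except FormatError:
        return []  # empty output file


def _matches_consensus(candidate: str, consensus: str, match_identity: float) -> bool:
    short, long_ = (
        (candidate, consensus) if len(candidate) <= len(consensus) else (consensus, candidate)
    )
    if len(short) < 0.80 * len(long_):
        return False
    dist = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return dist >= 0 and 1.0 - dist / len(short) >= match_identity


def evaluate_output(
    candidates_path: str | Path,
    false_path: str | Path,
    truth: Sequence[TruthRecord],
    consensus_by_family: Mapping[str, str],
    match_identity: float = 0.90,
) -> dict:
    """Compare pipeline output against the planted truth.

    A true family is recovered iff some candidate matches its consensus at
    >= match_identity over >= 0.80 of the longer length; precision is the
    fraction of candidates matching any planted true family;
    false_family_leakage counts planted false families with a record in the
    candidates output.  Also reports which false families appear in the false
    output.
    """
    cand_seqs = _read_fasta_seqs(candidates_path)
    false_seqs = _read_fasta_seqs(false_path)
    true_ids = sorted(
        {t.family_id for t in truth if not t.flank_context_id.endswith("_shared")}
    )
    false_ids = sorted(
        {t.family_id for t in truth if t.flank_context_id.endswith("_shared")}
    )
    recovered = {
        fid: any(
            _matches_consensus(c, consensus_by_family[fid], match_identity)
            for c in cand_seqs
        )
        for fid in true_ids
    }
    matching_candidates = [
        c
        for c in cand_seqs
        if any(
            _matches_consensus(c, consensus_by_family[fid], match_identity)
            for fid in true_ids
        )
    ]
    leakage = [
        fid
        for fid in false_ids
        if any(
            _matches_consensus(c, consensus_by_family[fid], match_identity)
            for c in cand_seqs
        )
    ]
    false_in_false_output = {
        fid: any(
            _matches_consensus(c, consensus_by_family[fid], match_identity)
            for c in false_seqs
        )
        for fid in false_ids
    }
    n_true = len(true_ids)
    return {
        "recall": (sum(recovered.values()) / n_true) if n_true else float("nan"),
        "precision": (len(matching_candidates) / len(cand_seqs)) if cand_seqs else float("nan"),
        "false_family_leakage": len(leakage),
        "recovered": recovered,
        "false_in_false_output": false_in_false_output,
        "n_candidates": len(cand_seqs),
        "candidates_per_true_family": {
            fid: sum(
                _matches_consensus(c, consensus_by_family[fid], match_identity)
                for c in cand_seqs
            )
            for fid in true_ids
        },
    }


def write_truth_bed(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """BED6 + family_id + identity columns."""
    with open(path, "w") as fh:
        for i, t in enumerate(truths):
            fh.write(
                f"{t.entry_id}\t{t.start}\t{t.end}\t{t.flank_context_id}\t"
                f"{int(round(t.identity * 1000))}\t{t.strand}\t{t.family_id}\t{t.identity:.4f}\n"
            )


def write_specs_json(sim: SimulatedGenome, path: str | Path) -> None:
    payload = {
        "specs": [
            {
                "family_id": s.family_id,
                "element_len": s.element_len,
                "tir_len": s.tir_len,
                "tsd_len": s.tsd_len,
                "copy_number": s.copy_number,
                "mutation_rate": s.mutation_rate,
                "kind": s.kind,
            }
            for s in sim.specs
        ],
        "consensus_by_family": sim.consensus_by_family,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
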