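# Methods

## Pipeline model

A MITE family is modelled as a set of near-identical 50–800 nt elements, each
bounded by terminal inverted repeats (TIRs) and flanked by a 2–10 nt target
site duplication (TSD), inserted at many independent genomic loci. Discovery
proceeds slice by slice over the database (slices of at most `max_slice_size`
nt, default 100,000), and each slice passes through:

1. **filter masking** — regions matching any previously deposited sequence
   (candidate or false) are hard-masked with N, at the same thresholds used
   for copy counting;
2. **low-complexity masking** — Shannon entropy of the mononucleotide
   composition is computed in every sliding 64-nt window; windows at or below
   1.0 bit mask the positions they cover. The threshold is inclusive because
   dinucleotide repeats — the canonical source of false TIR/TSD motifs — sit
   at exactly 1.0 bit; homopolymers (0 bits) and (AT)n/(GC)n tracts are
   masked, random sequence (≈2 bits) virtually never is;
3. **inverted-repeat scan** (below);
4. **TSD screen** — the 10-nt flanks immediately outside the putative element
   must share a direct repeat of 2–10 nt abutting both junctions; if none is
   found, the terminal 5 nt of the TIRs are searched for a prefix/suffix
   repeat (families whose TSD rides inside the apparent element boundary,
   e.g. the TA of Stowaway-like elements). Windows containing N never
   contribute a TSD;
5. **family evaluation** — the element (TIRs included) is searched against
   the *whole, unmasked* database on both strands; full-length copies are
   hits with identity ≥ 0.80 over the query and coverage ≥ 0.90, collapsed to
   one per locus (overlap > 50% of the shorter hit). For families at or above
   `copy_threshold` (default 10) copies, the 50-nt flanking contexts of up to
   20 copies are compared pairwise; copies sharing either flank at > 0.80
   identity over the shorter length join the same class (single linkage).
   At least `flank_class_threshold` (default 3) classes ⇒ **candidate**;
   fewer ⇒ **false family** (an abundant repeat embedded in one context,
   i.e. the internal structure of a larger element); below the copy
   threshold ⇒ discarded;
6. **deposit** — candidates go to `candidates.fasta`, false families to
   `false.fasta`, both to the filter database that masks subsequent slices;
   a deposit is suppressed when the element already matches a deposited
   sequence at ≥ 0.80 identity over ≥ 0.80 of the shorter length. Outputs
   are rewritten after every deposit.

"Full length" is operationalized as coverage ≥ 0.90 at identity ≥ 0.80
(both configurable): tolerant of young-family divergence, exclusive of
fragments. The flank subset cap of 20 bounds the pairwise comparisons at 190
while keeping the chance that a genuine family looks context-locked
negligible.

## Inverted-repeat scan

The scan compares a slice against its own reverse complement. On the
anti-diagonal c, position p pairs with position c − p, so every ungapped arm
pair is a window on one anti-diagonal. A window is accepted when it starts
and ends on complementary matches, contains a perfect complementary core of
`seed_len` (default 8) consecutive matches, reaches `min_arm_len` (10) at
`min_arm_identity` (0.80), contains no N, keeps the arms disjoint with an
element span in [`min_element_len`, `max_element_len`], and is maximal (not
contained in another accepted window on its diagonal). Arms that are simple
repeats — single-base runs, perfect period-2 repeats, or G/C-only / A/T-only
composition — are rejected. The `sensitivity` levels map to seed lengths
(low 11, normal 8, high 6), playing the role of a permissive e-value in an
external search engine.

The production scanner nominates anti-diagonals from exact seed pairs (a
k-mer index of the slice against reverse-complemented k-mers) and enumerates
windows per diagonal with vectorized prefix sums. `brute_force_ir` evaluates
the identical acceptance rule by direct enumeration in plain Python (inputs
≤ 2 kb) and serves as the independent oracle; the test suite asserts exact
set equality on random and adversarial sequences. Requiring the perfect seed
core is what makes the rule strategy-independent: any window containing a
seed-length run of matches implies an exact k-mer/reverse-complement match on
its own diagonal with a span no larger than the window's, so seed nomination
is lossless.

### Boundary refinement

Chance complementary matches immediately outside a real element extend the
maximal window a few nt past the true boundary in a substantial fraction of
copies, and the extended window shadows the exact one by maximality. The
candidate screen therefore retries the TSD search with the boundary trimmed
symmetrically 0–5 nt inward and takes the first success as the element span;
the TSD, which exists only at the true junction, arbitrates the boundary.

### Deposit ordering

Within a slice, candidates are processed by decreasing arm length, then
increasing element span, then position — the same preference the scanner uses
among overlapping windows — and the first deposit wins; across slices,
database order decides. Chance short-arm pairs around a real element or a
decoy cassette span wider (element plus background, whose per-locus flanks
would defeat the identical-flank test) or narrower (internal fragments)
windows; with the genuine long-armed pair deposited first, those spans are
suppressed by the redundancy check instead of becoming malformed exemplars.
This matters because the 0.80 identity gate alone cannot reject a query
padded with ≲40% random sequence: optimal alignment absorbs random junk at
roughly 0.5 edits per nt.

## Sampling model and early stopping

Under uniform random placement of N copies, the probability that none falls
in the first fraction X of the database is P = (1 − X)^N, hence
X = 1 − P^(1/N) bounds the scanned fraction needed to miss an N-copy family
with probability at most P. With `p_miss` set, discovery halts once the
processed fraction reaches X computed at N = `copy_threshold`; whole slices
are processed, so the scanned fraction only overshoots the bound
(conservative). Copy counting and flank retrieval always see the entire
database, keeping copy-threshold semantics independent of `p_miss`. The
progress report uses the cumulative average processing rate for its
remaining-time prediction.

## Homology search

Copy counting, filter masking and redundancy checks share one engine: an
exact 12-mer index over the database (k-mers containing N excluded, entries
never bridged), candidate loci nominated by seed clusters (starts within
20 nt merged) and verified by aligning the full query with edlib in infix
mode. Loci need at least two supporting seeds: a genuine full-length copy
within the identity tolerance shares many exact 12-mers with the query
(≈0.9^12 ≈ 28% of positions even at 10% pairwise divergence), while chance
loci almost always show exactly one. Identity is 1 − edits/|query|; pairwise
flank identity uses global alignment over the shorter length.

## Synthetic genomes

The generator emulates exactly the structures the pipeline must separate:

* **background** — i.i.d. nucleotides at a configurable GC content (default
  0.43, a typical plant-genome value);
* **true families** — consensus = TIR + random interior + reverse-complement
  TIR (TIRs resampled until non-simple); each copy is inserted at a
  uniformly random locus with true TSD semantics (the `tsd_len` nt at the
  insertion point duplicated on both sides) and an independent per-copy
  substitution load. Substitution-only mutation keeps full-length semantics
  crisp; the terminal 5 nt of each TIR and the TSD copies are exempt so
  junction signatures stay decidable at high rates. Insertions overwrite
  background rather than growing the genome, so truth coordinates remain
  valid; loci are non-overlapping by rejection sampling with a 60-nt margin
  that keeps planted flank contexts independent. Plants are +-strand only:
  a MITE family is strand-symmetric and the copy search covers both strands;
* **false families** — the same IR/DR-bearing core embedded in one fixed
  50-nt left/right context, the whole cassette planted verbatim at every
  locus, so each copy passes the IR and TSD screens but all copies share
  identical flanks;
* **simple repeats** — homopolymer, (AT)n and (GC)n stretches.

What the generator does **not** model: nested or fragmented insertions,
indel divergence (available as no default), isochore structure, gene content,
segmental duplication, or sequencing artefacts. Passing tests therefore
demonstrate the algorithm's behaviour under its own structural assumptions,
not performance on real genomes, where boundary ambiguity, subfamily
structure and nested repeats are harder.

## Problem sizes in the test suite

The acceptance-style tests use a 2-Mb genome with 8 true families (12–40
copies, ≤5% divergence), 5 identical-flank decoys and 10 simple-repeat
stretches for the recovery and redundancy checks; 200 replicates of 20-kb
genomes with one 10-copy family for the early-stopping bound (stopping at
whole-slice granularity overshoots the scanned fraction, so the measured
miss rate sits below the nominal bound); and 100+ sequences up to 2 kb for
scanner/oracle equality. These sizes are the package's own desk-scale test
bed; the pipeline itself streams slice by slice and has no intrinsic genome
size limit.

## Numerical and degenerate-input choices

* Identity comparisons use a 1e-9 slack on the ≥ threshold so the scanner
  and the oracle agree bit-for-bit.
* Ties among TSDs: longest wins; in anywhere mode (placement relaxed via
  `--tsd-anywhere`), longest, then closest to the junctions, then
  lexicographically smallest.
* Non-ACGT input characters normalize to N; N never appears inside a
  reported arm or TSD, and all-N or empty windows simply yield no hits.
* Slices shorter than `min_element_len` scan to an empty result; an entry at
  exactly the slice limit yields one slice. Slice overlap (default 900 ≥
  `max_element_len` + 2·`flank_window`) guarantees every element plus its
  TSD context lies wholly inside at least one slice; candidates rediscovered
  in an overlap are deduplicated by their global span.
* Re-running with identical inputs and parameters is byte-identical on all
  FASTA outputs regardless of worker count: evaluations may run in a thread
  pool, but deposits are serialized in discovery order and slice masking uses
  the filter state at slice start.

## Known limitations

* Arms are ungapped; a TIR pair interrupted by an indel is found only via
  its longer gap-free side.
* TSDs must match exactly; mismatch-tolerant TSDs and superfamily-specific
  priors (TA for Stowaway, TAA/TTA for Tourist) are out of scope.
* The copy-count engine is seeded by exact 12-mers with a two-seed minimum,
  so copies beyond ~20% divergence from the query may be missed — consistent
  with the 0.80 identity gate but not an exhaustive search.
* Exemplar boundaries are TSD-arbitrated and usually exact on synthetic
  data, but a chance direct repeat near the junction can shift a boundary by
  a few nt.
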