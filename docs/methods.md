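# Methods

## Text model and conventions

A text is a concatenation of one or more sequences over A–Z, each terminated
by its own sentinel. Sentinel ranks (1..s, in sequence order) sort strictly
below every regular symbol rank, and each occurs exactly once, so no match
can cross a sequence boundary. The entire external contract — positions,
suffix-array rows, interval indices, serialized values, TSV output — is
1-based and inclusive. Characters are case-folded; anything outside A–Z is
rejected rather than guessed at (there is no ambiguity-code policy).
Pattern symbols absent from the text alphabet are encoded as rank 0, which
matches nothing and simply bounds match lengths.

## Reference construction

Index construction is deliberately uncompressed and simple: suffix array by
prefix doubling (O(n log n) with numpy), PLCP/LCP by the Kasai recurrence,
LF/φ/φ⁻¹ directly from SA and ISA. The artifact's contribution is the query
side; any correct construction serves. The full arrays are discarded once
the index is assembled, and the same arrays double as the testing oracle.

## Move structures and balancing

A permutation with k conserved intervals is stored as k (input-start,
output-start) pairs. A move query maps (i, x) → (f(i), x′) where x is the
input interval of i: the output position is q_x + (i − p_x), and x′ is found
by scanning forward from a precomputed pointer to the interval containing
q_x. Balancing makes that scan constant: while some output interval
overlaps ≥ 2d input intervals, the corresponding input interval is split at
the position aligned with the d-th overlapped boundary, iterated to a
fixpoint. The result has at most k + ⌈k/(d−1)⌉ intervals (≤ 2k for the
default d = 2) and every output interval overlaps ≤ 2d − 1 input intervals;
both properties are asserted in the tests rather than trusted. `interval_of`
(binary search) exists for construction and tests only — query algorithms
always carry their interval index.

The φ structure is built on the run-top suffix positions (the SA values at
run heads), the φ⁻¹ structure on the run-bottom suffix positions. Inside
any such interval PLCP falls by exactly 1 per position, so one sample per
balanced interval start (PLCP[p] for φ, PLCP[φ⁻¹(p)] for φ⁻¹) answers
PLCP[i] and PLCP[φ⁻¹(i)] in constant time as sample − (i − p).

## The index

`MoveIndex` holds the three balanced move structures, the run symbol of
each LF interval (`lfirst`), ND/PD jump arrays to the next/previous LF
interval with a different run symbol, SA samples at every LF-interval start
and end, and the φ-/φ⁻¹-interval indices of each sample. Rank-select over
`lfirst` is per-symbol sorted occurrence lists with binary search — O(log r)
per query rather than the asymptotically optimal loglog structure, which is
a performance refinement with no effect on output; both extension variants
(rank-select and ND/PD run-scan) are implemented and cross-checked. The
index additionally stores one 13-tuple seed per alphabet symbol (the
interval of the single-symbol string) so windows can be seeded without any
O(n) array, plus sequence names/offsets for coordinate resolution. Total
storage is O(#intervals + σ + #sequences) integers; the space-honesty test
checks the count against a fixed per-interval multiple at two panel sizes.

The index keeps no SA, ISA, BWT or text. The command-line tools recover the
text when they need it (for matching statistics) by an O(n) LF walk from the
final sentinel's row.

Serialization is a versioned JSON container of named integer arrays —
human-readable and platform-independent; derived data (successor pointers,
occurrence lists, ND/PD) are rebuilt on load.

## Query algorithm

Extension by symbol c follows three cases per tracked row (top b, middle d,
bottom e): if the row's run symbol is c, one LF step and an O(1) sample-index
update; otherwise the nearest run of c inside [b, e] is located (rank-select
or ND/PD walk) and the row re-seeded from the stored SA samples of that
run's boundary, whose φ/φ⁻¹ interval cross-references make the update O(1).
The middle is reseeded from a preceding c-run like the bottom if one exists,
else from a succeeding one like the top. Extending by a sentinel rank is
refused: the BWT's cyclic wrap row would yield a rotation rather than a
linear occurrence, and encoded patterns can never contain sentinels.

Advancement from window [f+1, f+ℒ] to [f, f+ℒ−1] first sweeps the LF
intervals of the current interval, skipping runs equal to P[f] via ND and
emitting all other suffixes by φ-walks (top partial interval) or φ⁻¹-walks
(middle/bottom intervals); each emitted suffix's diagonal key is removed
from the dictionary and its stored value g yields the triple
(f+1, s, g−f). The interval is then extended by P[f] and expanded: upward
while PLCP[SA[b]] ≥ ℒ and downward while PLCP[φ⁻¹(SA[e])] ≥ ℒ, inserting
each admitted suffix with value f+ℒ−1 — exactly the suffixes whose common
prefix with P[f, m] is ℒ. If the extension dies (or the previous window was
already empty), the window is reseeded from the matching-statistics entry
when MS[f].len = ℒ — the only case in which it can be nonempty — or, in the
no-matching-statistics variant, by ℒ backward-extension steps from the
stored single-symbol seed. The iteration runs f = m−ℒ+1 down to 1; a final
flush performs the output sweep with a symbol matching nothing, emitting
every surviving suffix as a LEM touching the pattern's left edge. Windows
outside [1, m−ℒ+1] are undefined and treated as empty.

Dictionary keys are diagonals s − f (negative keys legal); simultaneous
left-extension preserves the diagonal so carried entries never need
rewriting, and each text suffix occurs at most once in any interval so keys
are unique. The default dictionary is a hash map (expected O(1) per
operation); an AVL-tree map with worst-case O(log) operations is provided
for callers wanting a deterministic bound. Both are exercised by every
acceptance instance.

Matching statistics are computed from the uncompressed oracle structures
(binary search per pattern position, witness = smallest qualifying SA row
for determinism); no compressed-space matching-statistics algorithm is
included, which is why the query is stated *given* matching statistics and
why the direct window-seeded variant exists.

## Work accounting

The O(m + occ) expected-time claim is made assertable as a step counter:
every LF/φ/φ⁻¹/move/scan/jump/dictionary operation increments a shared
counter, and the tests require total steps ≤ 32·(m + occ) on every suite
instance. The constant 32 is a design margin over the per-step cost of the
algorithm (a handful of move and dictionary operations per window plus
amortized run-scans); measured worst-case ratios are around 7.

## Synthetic data

The panel generator emulates the repetitive regime the index targets: one
uniform random founder over a 2- or 4-letter alphabet, H haplotypes each
mutated independently at a per-site rate μ (random non-founder allele), one
extra mutated copy held out as the query. Defaults
(H = 8, length 200, μ = 0.01, ACGT) give BWT run counts r ≪ n; the tests
confirm r/n falls monotonically as μ → 0. The generator is deterministic
under its seed. It does **not** model recombination, coalescent structure,
indels or sequencing error, so passing tests demonstrate correctness of the
match semantics on repetitive panels, not biological realism of the matches.

The acceptance suite uses 200 instances (100 in the acceptance script)
cycling ℒ through {2, 4, 8, 16, 32}, with haplotype lengths scaled to the
threshold (25–70 symbols for ℒ = 2 up to 110–460 for ℒ = 32, panels of 2–8
haplotypes, μ ∈ {0, 0.001, 0.005, 0.02, 0.05, 0.1}) so every instance stays
well under n = 5000, m = 500 and each check in the suite runs in well
under a minute on one CPU. Every instance is compared *exactly* (as a
set of triples) against the brute-force diagonal-scan enumerator, in all
four extension/dictionary combinations and in the direct variant.

## Numerical and degenerate-input choices

* n = 1 texts (a lone sentinel), single-symbol alphabets, and patterns
  sharing no symbol with the text are all legal and covered by tests.
* `run_scan` is the default extension variant, matching the amortization
  argument that charges run-jumps to emitted matches; `rank_select` is kept
  and cross-checked.
* Emission order is discovery order; the CLI sorts records by
  (p_start, t_start) and deduplicates for canonical diffs; library tests
  compare sets and assert no duplicates are produced.
* Ties in matching statistics (several rows achieving the maximum length)
  resolve to the smallest SA row, making witnesses reproducible.

## Known limitations

* Construction is O(n log n) time and O(n) transient space; no
  compressed-space construction is provided, so the O(r) footprint holds
  for the stored/loaded index, not for building it.
* Matching statistics come from the uncompressed oracle; the O(m + occ)
  bound is conditional on them being supplied, as is inherent to the
  algorithm.
* The brute-force enumerators are O(n·m) and intended for verification at
  desk scale only.
* No ambiguity-code (N) handling; unsupported characters are an error in
  texts and match-nothing in patterns.
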