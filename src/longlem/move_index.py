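"""The run-length compressed query index.

:class:`MoveIndex` bundles three move structures -- over LF, phi and
phi-inverse -- with the per-interval samples that let the long-match
query step through the suffix array without ever touching an O(n)
array:

* ``f_lf``          : move structure of LF; every input interval lies
                      inside one BWT run, so the run symbol of interval
                      i is ``lfirst[i]``.
* ``f_phi``         : move structure of phi built on the run-top suffix
                      positions, carrying PLCP[i] samples.
* ``f_phiinv``      : move structure of phi-inverse built on the
                      run-bottom suffix positions, carrying
                      PLCP[phi_inv(i)] samples.
* ``nd`` / ``pd``   : next / previous LF-interval whose run symbol
                      differs (k + 1 / -1 when absent).
* ``sa_plus/minus`` : SA samples at the start / end of each LF input
                      interval, with cross-references giving the phi-
                      and phi-inverse-interval of each sample
                      (``sa_phi_plus``, ``sa_phi_minus``,
                      ``sa_index_plus``, ``sa_index_minus``).

The index stores O(#intervals) integers plus O(alphabet) seeds; the
uncompressed arrays used to assemble it are discarded.  The text itself
is recoverable in O(n) by an LF walk (:meth:`MoveIndex.reconstruct_text`),
which is how the command-line tools recompute matching statistics
without the index having to keep the text around.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right

from .core_arrays import SuffixStructures, Text, run_length_encode
from .move_structure import DisjointIntervalSequence, MoveStructure

__all__ = ["MoveIndex", "build_index", "save_index", "load_index", "IndexFormatError"]

_FORMAT = "longlem-move-index"
_VERSION = 1


class IndexFormatError(Exception):
    """Corrupt, truncated or version-mismatched index container."""


class MoveIndex:
    def __init__(self, **kw):
        for name, value in kw.items():
            setattr(self, name, value)
        self._finalize()

    def _finalize(self):
        """Derive rank-select occurrence lists and succ pointers from stored data."""
        self.occ_lists = {}
        for i in range(1, self.k_lf + 1):
            self.occ_lists.setdefault(self.lfirst[i], []).append(i)
        if not hasattr(self, "counters") or self.counters is None:
            self.counters = {}
        for ms in (self.f_lf, self.f_phi, self.f_phiinv):
            ms.counters = self.counters

    # -- basic geometry -------------------------------------------------------

    @property
    def k_lf(self) -> int:
        return self.f_lf.k

    def lf_start(self, i: int) -> int:
        """Start row of LF input interval i (n + 1 for i = k + 1)."""
        return self.f_lf.starts[i] if i <= self.f_lf.k else self.n + 1

    def lf_end(self, i: int) -> int:
        return self.lf_start(i + 1) - 1

    def phi_start(self, w: int) -> int:
        return self.f_phi.starts[w]

    def phiinv_start(self, x: int) -> int:
        return self.f_phiinv.starts[x]

    # -- stepping primitives --------------------------------------------------

    def lf_step(self, row: int, x: int):
        """(row, LF-interval) -> (LF[row], its LF-interval)."""
        self.counters["lf"] = self.counters.get("lf", 0) + 1
        return self.f_lf.move_query(row, x)

    def phi_step(self, s: int, w: int):
        """(suffix, phi-interval) -> (phi(s), PLCP[s], phi-interval of phi(s))."""
        self.counters["phi"] = self.counters.get("phi", 0) + 1
        plcp = self.f_phi.plcp_query(s, w)
        s2, w2 = self.f_phi.move_query(s, w)
        return s2, plcp, w2

    def phi_inv_step(self, s: int, x: int):
        """(suffix, phi-inv-interval) -> (phi_inv(s), PLCP[phi_inv(s)], interval)."""
        self.counters["phi_inv"] = self.counters.get("phi_inv", 0) + 1
        plcp = self.f_phiinv.plcp_of_phi_inv_query(s, x)
        s2, x2 = self.f_phiinv.move_query(s, x)
        return s2, plcp, x2

    def plcp_at(self, s: int, w: int) -> int:
        """PLCP[s] given s's phi-interval (no movement)."""
        return self.f_phi.plcp_query(s, w)

    def plcp_below(self, s: int, x: int) -> int:
        """PLCP[phi_inv(s)] given s's phi-inverse-interval (no movement)."""
        return self.f_phiinv.plcp_of_phi_inv_query(s, x)

    def rank_select_next(self, from_interval: int, to_interval: int, c, direction: str):
        """First LF interval in [from, to] whose run symbol is c.

        ``direction="down"``: smallest index >= from; ``"up"``: largest
        index <= to.  Returns None when absent.  O(log r) binary search
        over per-symbol occurrence lists.
        """
        self.counters["rank_select"] = self.counters.get("rank_select", 0) + 1
        occ = self.occ_lists.get(c)
        if not occ or from_interval > to_interval:
            return None
        if direction == "down":
            pos = bisect_left(occ, from_interval)
            if pos < len(occ) and occ[pos] <= to_interval:
                return occ[pos]
            return None
        if direction == "up":
            pos = bisect_right(occ, to_interval) - 1
            if pos >= 0 and occ[pos] >= from_interval:
                return occ[pos]
            return None
        raise ValueError("direction must be 'up' or 'down'")

    # -- text recovery --------------------------------------------------------

    def reconstruct_text(self) -> Text:
        """Rebuild the text by an LF walk from the top suffix-array row.

        Suffix n is the final sentinel alone; sentinel suffixes sort by
        sentinel rank, so it occupies row ``sentinel_count``.  Stepping
        LF from there yields the text right-to-left, reading each row's
        symbol from ``lfirst``.
        """
        n = self.n
        out = [0] * (n + 1)
        out[n] = self.sentinel_count  # last symbol is the final sentinel
        row = min(self.sentinel_count, n)
        x = self.f_lf.interval_of(row)
        for pos in range(n - 1, 0, -1):
            out[pos] = self.lfirst[x]
            row, x = self.f_lf.move_query(row, x)
        alphabet = dict(self.alphabet)
        return Text(tuple(out), self.sentinel_count, tuple(self.names), alphabet)

    def resolve_position(self, t_start: int):
        """Concatenated text position -> (sequence name, 1-based offset)."""
        idx = bisect_right(self.seq_starts, t_start) - 1
        return self.names[idx], t_start - self.seq_starts[idx] + 1

    # -- accounting -----------------------------------------------------------

    def reset_counters(self):
        self.counters.clear()

    def total_ops(self) -> int:
        return sum(self.counters.values())

    def stored_element_count(self) -> int:
        """Total integers/symbols the index retains (space-honesty audit)."""
        count = sum(
            ms.stored_element_count() for ms in (self.f_lf, self.f_phi, self.f_phiinv)
        )
        count += 9 * self.k_lf  # lfirst, nd, pd, six sample arrays
        count += sum(len(v) for v in self.occ_lists.values())
        count += 13 * len(self.char_seeds)
        count += len(self.seq_starts)
        return count

    def total_intervals(self) -> int:
        return self.f_lf.k + self.f_phi.k + self.f_phiinv.k

    # -- equality (serialization round-trip) ----------------------------------

    def _state(self):
        return (
            self.n,
            self.r,
            self.d,
            self.sentinel_count,
            tuple(self.names),
            tuple(self.seq_starts),
            tuple(sorted(self.alphabet.items())),
            self.f_lf.sequence.pairs,
            self.f_phi.sequence.pairs,
            self.f_phiinv.sequence.pairs,
            tuple(self.f_phi.plcp_samples),
            tuple(self.f_phiinv.plcp_samples),
            tuple(self.lfirst),
            tuple(self.nd),
            tuple(self.pd),
            tuple(self.sa_plus),
            tuple(self.sa_minus),
            tuple(self.sa_phi_plus),
            tuple(self.sa_phi_minus),
            tuple(self.sa_index_plus),
            tuple(self.sa_index_minus),
            tuple(sorted(self.char_seeds.items())),
        )

    def __eq__(self, other):
        return isinstance(other, MoveIndex) and self._state() == other._state()


def build_index(text: Text, d: int = 2) -> MoveIndex:
    """Assemble the compressed index from a text.

    Construction goes through the full uncompressed suffix structures
    (naive, O(n log n)); only O(#intervals) data is retained.
    """
    structs = SuffixStructures.from_text(text)
    n = text.n
    sa, bwt, lf = structs.sa, structs.bwt, structs.lf
    phi, phi_inv, plcp = structs.phi, structs.phi_inv, structs.plcp
    rl = run_length_encode(bwt)
    run_starts = [start for _, start in rl.runs]
    r = rl.r
    counters = {}

    # LF: one input interval per BWT run, then balanced (splits stay in-run).
    seq_lf = DisjointIntervalSequence(
        tuple((l, lf[l]) for l in run_starts), n
    )
    f_lf = MoveStructure.from_sequence(seq_lf, d=d, counters=counters)

    # phi: input starts are the run-top suffix positions.
    p_plus = sorted(sa[l] for l in run_starts)
    seq_phi = DisjointIntervalSequence(tuple((p, phi[p]) for p in p_plus), n)
    f_phi = MoveStructure.from_sequence(
        seq_phi, d=d, sample_fn=lambda p: plcp[p], sample_role="plcp_at_start",
        counters=counters,
    )

    # phi-inverse: input starts are the run-bottom suffix positions.
    bottom_rows = [l - 1 for l in run_starts[1:]] + [n]
    p_minus = sorted(sa[row] for row in bottom_rows)
    seq_phiinv = DisjointIntervalSequence(
        tuple((p, phi_inv[p]) for p in p_minus), n
    )
    f_phiinv = MoveStructure.from_sequence(
        seq_phiinv, d=d, sample_fn=lambda p: plcp[phi_inv[p]],
        sample_role="plcp_of_phi_inv_at_start", counters=counters,
    )

    k = f_lf.k
    lfirst = [0] + [bwt[f_lf.starts[i]] for i in range(1, k + 1)]
    nd = [0] * (k + 1)
    pd = [0] * (k + 1)
    nd[k] = k + 1
    for i in range(k - 1, 0, -1):
        nd[i] = i + 1 if lfirst[i + 1] != lfirst[i] else nd[i + 1]
    pd[1] = -1
    for i in range(2, k + 1):
        pd[i] = i - 1 if lfirst[i - 1] != lfirst[i] else pd[i - 1]

    sa_plus = [0] + [sa[f_lf.starts[i]] for i in range(1, k + 1)]
    ends = [f_lf.starts[i + 1] - 1 for i in range(1, k)] + [n]
    sa_minus = [0] + [sa[end] for end in ends]
    sa_phi_plus = [0] + [f_phi.interval_of(sa_plus[i]) for i in range(1, k + 1)]
    sa_phi_minus = [0] + [f_phi.interval_of(sa_minus[i]) for i in range(1, k + 1)]
    sa_index_plus = [0] + [f_phiinv.interval_of(sa_plus[i]) for i in range(1, k + 1)]
    sa_index_minus = [0] + [f_phiinv.interval_of(sa_minus[i]) for i in range(1, k + 1)]

    # Per-symbol seed tuples: the 13-tuple of the single-character string.
    isa = structs.isa
    first_row = {}
    last_row = {}
    for row in range(1, n + 1):
        c = text.symbols[sa[row]]
        if c not in first_row:
            first_row[c] = row
        last_row[c] = row
    char_seeds = {}
    for c, b in first_row.items():
        e = last_row[c]
        sab, sae = sa[b], sa[e]
        seed = (
            b, b, e, sab, sab, sae,
            f_lf.interval_of(b), f_lf.interval_of(b), f_lf.interval_of(e),
            f_phi.interval_of(sab), f_phi.interval_of(sab),
            f_phiinv.interval_of(sab), f_phiinv.interval_of(sae),
        )
        char_seeds[c] = seed

    return MoveIndex(
        n=n,
        r=r,
        d=d,
        sentinel_count=text.sentinel_count,
        names=tuple(text.names),
        seq_starts=list(text.sequence_starts()),
        alphabet=dict(text.alphabet),
        f_lf=f_lf,
        f_phi=f_phi,
        f_phiinv=f_phiinv,
        lfirst=lfirst,
        nd=nd,
        pd=pd,
        sa_plus=sa_plus,
        sa_minus=sa_minus,
        sa_phi_plus=sa_phi_plus,
        sa_phi_minus=sa_phi_minus,
        sa_index_plus=sa_index_plus,
        sa_index_minus=sa_index_minus,
        char_seeds=char_seeds,
        counters=counters,
    )


# -- serialization ------------------------------------------------------------


def save_index(idx: MoveIndex, sink) -> None:
    """Write a versioned, human-readable JSON container."""
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "n": idx.n,
        "r": idx.r,
        "d": idx.d,
        "sentinel_count": idx.sentinel_count,
        "names": list(idx.names),
        "seq_starts": list(idx.seq_starts),
        "alphabet": sorted(idx.alphabet.items()),
        "lf_pairs": [list(p) for p in idx.f_lf.sequence.pairs],
        "phi_pairs": [list(p) for p in idx.f_phi.sequence.pairs],
        "phiinv_pairs": [list(p) for p in idx.f_phiinv.sequence.pairs],
        "lcp_plus": list(idx.f_phi.plcp_samples),
        "lcp_minus": list(idx.f_phiinv.plcp_samples),
        "lfirst": list(idx.lfirst),
        "nd": list(idx.nd),
        "pd": list(idx.pd),
        "sa_plus": list(idx.sa_plus),
        "sa_minus": list(idx.sa_minus),
        "sa_phi_plus": list(idx.sa_phi_plus),
        "sa_phi_minus": list(idx.sa_phi_minus),
        "sa_index_plus": list(idx.sa_index_plus),
        "sa_index_minus": list(idx.sa_index_minus),
        "char_seeds": [[c, list(seed)] for c, seed in sorted(idx.char_seeds.items())],
    }
    if hasattr(sink, "write"):
        json.dump(payload, sink)
    else:
        with open(sink, "w") as fh:
            json.dump(payload, fh)


def load_index(source) -> MoveIndex:
    """Load a container written by :func:`save_index`."""
    try:
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexFormatError(f"corrupt index container: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise IndexFormatError("not a longlem index container")
    if payload.get("version") != _VERSION:
        raise IndexFormatError(
            f"unsupported container version {payload.get('version')!r}"
        )
    try:
        n = payload["n"]
        f_lf = MoveStructure(
            DisjointIntervalSequence(tuple(tuple(p) for p in payload["lf_pairs"]), n)
        )
        f_phi = MoveStructure(
            DisjointIntervalSequence(tuple(tuple(p) for p in payload["phi_pairs"]), n),
            plcp_samples=list(payload["lcp_plus"]),
            sample_role="plcp_at_start",
        )
        f_phiinv = MoveStructure(
            DisjointIntervalSequence(
                tuple(tuple(p) for p in payload["phiinv_pairs"]), n
            ),
            plcp_samples=list(payload["lcp_minus"]),
            sample_role="plcp_of_phi_inv_at_start",
        )
        return MoveIndex(
            n=n,
            r=payload["r"],
            d=payload["d"],
            sentinel_count=payload["sentinel_count"],
            names=tuple(payload["names"]),
            seq_starts=list(payload["seq_starts"]),
            alphabet={c: rank for c, rank in payload["alphabet"]},
            f_lf=f_lf,
            f_phi=f_phi,
            f_phiinv=f_phiinv,
            lfirst=list(payload["lfirst"]),
            nd=list(payload["nd"]),
            pd=list(payload["pd"]),
            sa_plus=list(payload["sa_plus"]),
            sa_minus=list(payload["sa_minus"]),
            sa_phi_plus=list(payload["sa_phi_plus"]),
            sa_phi_minus=list(payload["sa_phi_minus"]),
            sa_index_plus=list(payload["sa_index_plus"]),
            sa_index_minus=list(payload["sa_index_minus"]),
            char_seeds={c: tuple(seed) for c, seed in payload["char_seeds"]},
            counters={},
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise IndexFormatError(f"malformed index container: {exc}") from exc
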