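"""Disjoint interval sequences and constant-amortized move queries.

A permutation f of [1, n] with k conserved intervals (maximal ranges on
which f(i) - i is constant) can be written as k (input-start,
output-start) pairs.  A *move query* maps (i, x) -> (f(i), x') where x
is the input interval holding i and x' the one holding f(i), so a
caller that carries its interval index along never needs a search.
Balancing splits intervals until no output interval overlaps more than
2d - 1 input intervals, which bounds the successor scan inside a move
query by a constant depending only on d.

A move structure over the phi (or phi-inverse) permutation can carry
one PLCP sample per input interval: inside an interval the PLCP value
decreases by exactly 1 per position, so PLCP[i] (or PLCP[phi_inv(i)])
is the sampled value at the interval start minus the offset.
"""

from __future__ import annotations

import math
from bisect import bisect_right, insort
from dataclasses import dataclass

__all__ = [
    "ContractViolationError",
    "DisjointIntervalSequence",
    "balance",
    "MoveStructure",
]


class ContractViolationError(Exception):
    """A caller passed an interval index inconsistent with its position."""


@dataclass(frozen=True)
class DisjointIntervalSequence:
    """Sorted (input-start, output-start) pairs representing a bijection on [1, n]."""

    pairs: tuple
    n: int

    @property
    def k(self) -> int:
        return len(self.pairs)

    def input_start(self, x: int) -> int:
        """Start of input interval x; n + 1 for x = k + 1."""
        return self.pairs[x - 1][0] if x <= self.k else self.n + 1

    def length(self, x: int) -> int:
        return self.input_start(x + 1) - self.input_start(x)

    @classmethod
    def from_permutation(cls, perm: list) -> "DisjointIntervalSequence":
        """Minimal sequence: a new input interval starts exactly where
        perm(i) - i changes (or at i = 1)."""
        n = len(perm) - 1
        if n < 1 or sorted(perm[1:]) != list(range(1, n + 1)):
            raise ValueError("not a bijection on [1, n]")
        pairs = []
        for i in range(1, n + 1):
            if i == 1 or perm[i] - i != perm[i - 1] - (i - 1):
                pairs.append((i, perm[i]))
        return cls(tuple(pairs), n)

    def evaluate(self, i: int) -> int:
        """Direct evaluation of the represented bijection (test aid)."""
        starts = [p for p, _ in self.pairs]
        x = bisect_right(starts, i) - 1
        p, q = self.pairs[x]
        return q + (i - p)

    def validate(self) -> None:
        """Assert the three defining conditions (input/output partitions)."""
        k, n = self.k, self.n
        if k < 1 or self.pairs[0][0] != 1:
            raise ValueError("first input interval must start at 1")
        for x in range(1, k):
            if not self.pairs[x - 1][0] < self.pairs[x][0] <= n:
                raise ValueError("input starts must be strictly increasing and <= n")
        by_q = sorted(
            (q, self.input_start(x + 1) - p) for x, (p, q) in enumerate(self.pairs, start=1)
        )
        running = 1
        for q, length in by_q:
            if q != running:
                raise ValueError("output intervals do not partition [1, n]")
            running += length
        if running != n + 1:
            raise ValueError("output intervals do not cover [1, n]")


def balance(seq: DisjointIntervalSequence, d: int = 2) -> DisjointIntervalSequence:
    """Split intervals until every output interval overlaps < 2d input intervals.

    Whenever an output interval overlaps >= 2d input intervals, its input
    interval is split at the position aligned with the d-th overlapped
    input-interval boundary (so the first part overlaps exactly d), and
    this is iterated to a fixpoint.  The result represents the same
    bijection with at most k + ceil(k / (d - 1)) intervals.
    """
    if d < 2:
        raise ValueError("balancing parameter d must be >= 2")
    pairs = list(seq.pairs)
    starts = [p for p, _ in pairs]
    n = seq.n
    dirty = True
    while dirty:
        dirty = False
        idx = 0
        while idx < len(pairs):
            p, q = pairs[idx]
            nxt = pairs[idx + 1][0] if idx + 1 < len(pairs) else n + 1
            lo = bisect_right(starts, q)
            hi = bisect_right(starts, q + (nxt - p) - 1)
            if hi - lo + 1 >= 2 * d:
                s_d = starts[lo + d - 1]  # d-th overlapped boundary, in output space
                p_new = p + (s_d - q)
                pairs.insert(idx + 1, (p_new, s_d))
                insort(starts, p_new)
                dirty = True
            idx += 1
    return DisjointIntervalSequence(tuple(pairs), n)


def balanced_size_bound(k: int, d: int) -> int:
    """Guaranteed maximum interval count after balancing k intervals."""
    return k + math.ceil(k / (d - 1))


class MoveStructure:
    """Move queries over a balanced disjoint interval sequence.

    Parameters
    ----------
    sequence:
        A *balanced* disjoint interval sequence (see :func:`balance`).
    plcp_samples:
        Optional 1-based list of one PLCP sample per input interval.
        With role ``"plcp_at_start"`` sample x is PLCP[p_x] (phi
        structure); with role ``"plcp_of_phi_inv_at_start"`` it is
        PLCP[phi_inv(p_x)] (phi-inverse structure).
    counters:
        Optional dict for operation accounting ("move", "scan").
    """

    def __init__(self, sequence, plcp_samples=None, sample_role="none", counters=None):
        self.sequence = sequence
        self.n = sequence.n
        self.k = sequence.k
        self.starts = [0] + [p for p, _ in sequence.pairs]  # 1-based
        self.outs = [0] + [q for _, q in sequence.pairs]
        self.plcp_samples = plcp_samples
        self.sample_role = sample_role
        self.counters = counters if counters is not None else {}
        self.succ_ptr = [0] * (self.k + 1)
        for x in range(1, self.k + 1):
            self.succ_ptr[x] = self.interval_of(self.outs[x])

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_sequence(cls, seq, d=2, sample_fn=None, sample_role="none", counters=None):
        """Balance ``seq`` and optionally sample PLCP at each balanced start.

        ``sample_fn`` receives the 1-based start position of a balanced
        input interval and returns the sample stored for it.
        """
        bal = balance(seq, d)
        samples = None
        if sample_fn is not None:
            samples = [0] + [sample_fn(p) for p, _ in bal.pairs]
        return cls(bal, samples, sample_role if samples else "none", counters)

    def interval_of(self, i: int) -> int:
        """Input interval containing position i, by binary search.

        Construction / preprocessing aid only: query algorithms carry
        their interval index and must not call this on the hot path.
        """
        if not 1 <= i <= self.n:
            raise ContractViolationError(f"position {i} outside [1, {self.n}]")
        return bisect_right(self.starts, i, lo=1) - 1

    def _check(self, i: int, x: int) -> None:
        if not (1 <= x <= self.k):
            raise ContractViolationError(f"interval index {x} outside [1, {self.k}]")
        nxt = self.starts[x + 1] if x < self.k else self.n + 1
        if not self.starts[x] <= i < nxt:
            raise ContractViolationError(
                f"position {i} not inside input interval {x} "
                f"[{self.starts[x]}, {nxt - 1}]"
            )

    # -- queries --------------------------------------------------------------

    def move_query(self, i: int, x: int):
        """Map (i, x) to (f(i), interval of f(i)) in O(d) time."""
        self._check(i, x)
        self.counters["move"] = self.counters.get("move", 0) + 1
        i2 = self.outs[x] + (i - self.starts[x])
        x2 = self.succ_ptr[x]
        while x2 < self.k and self.starts[x2 + 1] <= i2:
            x2 += 1
            self.counters["scan"] = self.counters.get("scan", 0) + 1
        return i2, x2

    def plcp_query(self, i: int, x: int) -> int:
        """PLCP[i] from the sample at the interval start (phi structure)."""
        if self.sample_role != "plcp_at_start":
            raise ContractViolationError("structure carries no PLCP-at-start samples")
        self._check(i, x)
        return self.plcp_samples[x] - (i - self.starts[x])

    def plcp_of_phi_inv_query(self, i: int, x: int) -> int:
        """PLCP[phi_inv(i)] from the sample at the interval start."""
        if self.sample_role != "plcp_of_phi_inv_at_start":
            raise ContractViolationError(
                "structure carries no PLCP-of-phi-inv samples"
            )
        self._check(i, x)
        return self.plcp_samples[x] - (i - self.starts[x])

    def stored_element_count(self) -> int:
        count = 3 * self.k  # starts, outs, succ_ptr
        if self.plcp_samples is not None:
            count += self.k
        return count
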