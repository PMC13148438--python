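"""Matching statistics and window seeding.

The matching statistics of a pattern P w.r.t. a text T store, for every
pattern position, the length of the longest substring of P starting
there that occurs in T, together with one witness occurrence and its
suffix-array row.  The long-match query consumes them *augmented* with
the move-structure interval indices of the witness (row in the LF
structure, suffix position in the phi and phi-inverse structures), so a
dead window can be reseeded in constant time.

No compressed-space matching-statistics algorithm is implemented here:
:func:`compute_ms_oracle` works from the full uncompressed suffix
structures at desk scale (the query path that avoids matching
statistics entirely is :func:`~longlem.long_lem_query.long_lem_query_direct`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MsEntry", "compute_ms_oracle", "augment_ms", "seed_window"]


@dataclass
class MsEntry:
    """One matching-statistics record (all 1-based; zeros mean 'no match')."""

    len: int
    suff: int  # witness occurrence start in the text
    row: int   # SA row with SA[row] == suff
    i: int = 0  # LF-structure interval of row
    w: int = 0  # phi-structure interval of suff
    x: int = 0  # phi-inverse-structure interval of suff

    @property
    def usable(self) -> bool:
        return self.len > 0


def _lcp_with_suffix(sym, n, start, P, f, m):
    """|lcp(T[start, n], P[f, m])| by direct comparison."""
    length = 0
    while start + length <= n and f + length <= m and sym[start + length] == P[f + length]:
        length += 1
    return length


def _suffix_less_than_pattern(sym, n, start, P, f, m):
    """Is T[start, n] lexicographically smaller than P[f, m]?"""
    h = _lcp_with_suffix(sym, n, start, P, f, m)
    if start + h > n:
        return True  # suffix is a proper prefix of the pattern tail
    if f + h > m:
        return False
    return sym[start + h] < P[f + h]


def compute_ms_oracle(structs, P) -> list:
    """Matching statistics of P (1-based encoded list) w.r.t. structs.text.

    The witness is the smallest qualifying SA row, which makes the
    result deterministic.  Pattern symbols absent from the text (rank
    0) match nothing and force zero-length entries.
    """
    text = structs.text
    sym, n = text.symbols, text.n
    sa = structs.sa
    m = len(P) - 1
    out = [MsEntry(0, 0, 0)]
    for f in range(1, m + 1):
        # binary search for the insertion row of P[f, m] among the suffixes
        lo, hi = 1, n + 1
        while lo < hi:
            mid = (lo + hi) // 2
            if _suffix_less_than_pattern(sym, n, sa[mid], P, f, m):
                lo = mid + 1
            else:
                hi = mid
        best_len, best_row = 0, 0
        for row in (lo - 1, lo):
            if 1 <= row <= n:
                h = _lcp_with_suffix(sym, n, sa[row], P, f, m)
                if h > best_len or (h == best_len and h > 0 and
                                    (best_row == 0 or row < best_row)):
                    best_len, best_row = h, row
        if best_len == 0:
            out.append(MsEntry(0, 0, 0))
            continue
        row = best_row
        while row > 1 and _lcp_with_suffix(sym, n, sa[row - 1], P, f, m) == best_len:
            row -= 1
        out.append(MsEntry(best_len, sa[row], row))
    return out


def augment_ms(idx, ms) -> list:
    """Fill in the move-structure interval indices of every usable entry.

    Binary-searching the interval of each witness is preprocessing, not
    part of the O(m + occ) query itself.
    """
    for entry in ms[1:]:
        if entry.usable:
            entry.i = idx.f_lf.interval_of(entry.row)
            entry.w = idx.f_phi.interval_of(entry.suff)
            entry.x = idx.f_phiinv.interval_of(entry.suff)
        else:
            entry.i = entry.w = entry.x = 0
    return ms


def seed_window(idx, P, f: int, L: int, variant: str = "run_scan"):
    """Balanced sa_lcp-interval of the window P[f, f+L-1], or None.

    Computed by L backward-extension steps starting from the stored
    single-symbol seed of P[f+L-1]; used by the query variant that does
    not consume matching statistics.
    """
    from .long_lem_query import BalancedSaLcpInterval, extend_interval

    m = len(P) - 1
    if L > m or not 1 <= f <= m - L + 1:
        return None
    seed = idx.char_seeds.get(P[f + L - 1])
    if seed is None:
        return None
    itv = BalancedSaLcpInterval(*seed)
    for pos in range(f + L - 2, f - 1, -1):
        itv = extend_interval(idx, itv, P[pos], variant)
        if itv is None:
            return None
    return itv
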