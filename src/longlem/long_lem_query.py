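"""Long locally-maximal exact match (LEM) queries.

A LEM between pattern P and text T is a match P[i, j] = T[i', j'] that
cannot be extended *simultaneously* on both sides: left-blocked when
i = 1, i' = 1 or P[i-1] != T[i'-1], right-blocked symmetrically.  A
long LEM is one of length >= L.  Matches maximal in the pattern (MEMs)
are a subset.

The query sweeps a length-L window right-to-left over the pattern,
maintaining the *balanced sa_lcp-interval* of the current window -- the
suffix-array interval [b, e] of the window string together with a
middle row d, the SA values of the three rows, and the move-structure
interval indices needed to step any of them in constant time -- plus a
diagonal-keyed dictionary of the live text suffixes.  Each advance by
one position

1. emits every live suffix whose preceding text symbol differs from the
   next pattern symbol (its match just became left-maximal),
2. left-extends the interval by that symbol, and
3. re-expands the interval with the suffixes whose common prefix with
   the remaining pattern is exactly L (their matches are right-maximal
   at the current window end), inserting them into the dictionary.

Given matching statistics the whole sweep takes O(m + occ) expected
dictionary/move operations; without them each window can be reseeded by
L backward-extension steps instead (O(mL + occ)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Optional

from .move_structure import ContractViolationError
from .occdict import InternalConsistencyError, make_occ_dict

__all__ = [
    "LemTriple",
    "BalancedSaLcpInterval",
    "extend_interval",
    "output_matches_up",
    "output_matches_down",
    "advance",
    "long_lem_query",
    "long_lem_query_direct",
]


class LemTriple(NamedTuple):
    """A match P[p_start, p_start+length-1] = T[t_start, t_start+length-1]."""

    p_start: int
    t_start: int
    length: int


@dataclass(frozen=True)
class BalancedSaLcpInterval:
    """13-tuple tracking the SA interval [b, e] of the current window.

    ``i, j, k`` are the LF-structure intervals of rows b, d, e;
    ``v, w`` the phi-structure intervals of SA[b], SA[d]; ``x, y`` the
    phi-inverse-structure intervals of SA[d], SA[e].
    """

    b: int
    d: int
    e: int
    sa_b: int
    sa_d: int
    sa_e: int
    i: int
    j: int
    k: int
    v: int
    w: int
    x: int
    y: int

    def astuple(self):
        return (
            self.b, self.d, self.e, self.sa_b, self.sa_d, self.sa_e,
            self.i, self.j, self.k, self.v, self.w, self.x, self.y,
        )

    def check_consistency(self, idx) -> None:
        if not self.b <= self.d <= self.e:
            raise ContractViolationError("interval rows out of order")
        for row, itv in ((self.b, self.i), (self.d, self.j), (self.e, self.k)):
            idx.f_lf._check(row, itv)
        idx.f_phi._check(self.sa_b, self.v)
        idx.f_phi._check(self.sa_d, self.w)
        idx.f_phiinv._check(self.sa_d, self.x)
        idx.f_phiinv._check(self.sa_e, self.y)


# -- symbol search inside the interval ----------------------------------------


def _first_c_interval(idx, frm, to, c, variant):
    """Smallest LF interval in [frm, to] with run symbol c (None if absent)."""
    if variant == "rank_select":
        return idx.rank_select_next(frm, to, c, "down")
    o = frm
    while o <= to and idx.lfirst[o] != c:
        idx.counters["nd"] = idx.counters.get("nd", 0) + 1
        o = idx.nd[o]
    return o if o <= to else None


def _last_c_interval(idx, frm, to, c, variant):
    """Largest LF interval in [frm, to] with run symbol c (None if absent)."""
    if variant == "rank_select":
        return idx.rank_select_next(frm, to, c, "up")
    o = to
    while o >= frm and idx.lfirst[o] != c:
        idx.counters["pd"] = idx.counters.get("pd", 0) + 1
        o = idx.pd[o]
    return o if o >= frm else None


# -- balanced sa_lcp-interval extension (one backward step) -------------------


def extend_interval(idx, itv: BalancedSaLcpInterval, c, variant: str = "run_scan"):
    """Balanced sa_lcp-interval of cQ from the interval of Q, or None.

    ``variant="rank_select"`` finds the nearest run of c by binary
    search over run-symbol occurrence lists; ``"run_scan"`` walks the
    ND/PD jump arrays, linear in the number of runs the interval spans.
    Both produce identical results.
    """
    if itv is None:
        return None
    if c is not None and 1 <= c <= idx.sentinel_count:
        # Sentinel symbols never appear in patterns; extending by the final
        # sentinel would follow the BWT's cyclic wrap to a rotation that is
        # not a linear occurrence, so sentinel extension is refused outright.
        raise ContractViolationError("cannot extend by a sentinel symbol")
    lfirst = idx.lfirst
    b, d, e = itv.b, itv.d, itv.e
    i, j, k = itv.i, itv.j, itv.k

    # top values
    if lfirst[i] == c:
        b2, i2 = idx.lf_step(b, i)
        sa_b2 = itv.sa_b - 1  # never wraps: row b's BWT symbol is not a sentinel
        v2 = itv.v - 1 if itv.sa_b == idx.phi_start(itv.v) else itv.v
    else:
        i_hat = _first_c_interval(idx, i, k, c, variant)
        if i_hat is None:
            return None
        b_hat = idx.lf_start(i_hat)
        b2, i2 = idx.lf_step(b_hat, i_hat)
        sa_b2 = idx.sa_plus[i_hat] - 1
        v2 = idx.sa_phi_plus[i_hat] - 1  # run-top SA sample starts its interval

    # bottom values
    if lfirst[k] == c:
        e2, k2 = idx.lf_step(e, k)
        sa_e2 = itv.sa_e - 1
        y2 = itv.y - 1 if itv.sa_e == idx.phiinv_start(itv.y) else itv.y
    else:
        k_hat = _last_c_interval(idx, i, k, c, variant)
        if k_hat is None:
            return None
        e_hat = idx.lf_end(k_hat)
        e2, k2 = idx.lf_step(e_hat, k_hat)
        sa_e2 = idx.sa_minus[k_hat] - 1
        y2 = idx.sa_index_minus[k_hat] - 1  # run-bottom SA sample starts its interval

    # middle values
    if lfirst[j] == c:
        d2, j2 = idx.lf_step(d, j)
        sa_d2 = itv.sa_d - 1
        w2 = itv.w - 1 if itv.sa_d == idx.phi_start(itv.w) else itv.w
        x2 = itv.x - 1 if itv.sa_d == idx.phiinv_start(itv.x) else itv.x
    else:
        j_hat = _last_c_interval(idx, i, j, c, variant)
        if j_hat is not None:
            # reseed from the end of the preceding c-interval, like the bottom
            d_hat = idx.lf_end(j_hat)
            d2, j2 = idx.lf_step(d_hat, j_hat)
            sample = idx.sa_minus[j_hat]
            sa_d2 = sample - 1
            x2 = idx.sa_index_minus[j_hat] - 1
            t = idx.sa_phi_minus[j_hat]
            w2 = t - 1 if sample == idx.phi_start(t) else t
        else:
            j_hat = _first_c_interval(idx, j, k, c, variant)
            if j_hat is None:
                return None
            # reseed from the start of the succeeding c-interval, like the top
            d_hat = idx.lf_start(j_hat)
            d2, j2 = idx.lf_step(d_hat, j_hat)
            sample = idx.sa_plus[j_hat]
            sa_d2 = sample - 1
            w2 = idx.sa_phi_plus[j_hat] - 1
            t = idx.sa_index_plus[j_hat]
            x2 = t - 1 if sample == idx.phiinv_start(t) else t

    return BalancedSaLcpInterval(
        b2, d2, e2, sa_b2, sa_d2, sa_e2, i2, j2, k2, v2, w2, x2, y2
    )


# -- match output -------------------------------------------------------------


def output_matches_up(idx, occ, s, iota, z, f, emit):
    """Emit z matches for suffixes walking up the SA from s (via phi).

    Each emitted suffix s has diagonal key s - (f + 1) in ``occ`` whose
    value g is the pattern end of its match: the match is
    P[f+1, g] = T[s, s + g - (f+1)].
    """
    for t in range(z):
        g = occ.pop(s - (f + 1))
        emit(LemTriple(f + 1, s, g - f))
        if t < z - 1:
            s, _, iota = idx.phi_step(s, iota)


def output_matches_down(idx, occ, s, iota, z, f, emit):
    """Emit z matches for suffixes walking down the SA from s (via phi-inverse)."""
    for t in range(z):
        g = occ.pop(s - (f + 1))
        emit(LemTriple(f + 1, s, g - f))
        if t < z - 1:
            s, _, iota = idx.phi_inv_step(s, iota)


def _output_phase(idx, itv, occ, f, c, emit):
    """Emit every live suffix whose BWT symbol differs from c.

    Called with c = P[f] during the sweep and with c = None (matching
    nothing) for the final flush; f = 0 there, so emitted matches start
    at pattern position 1.
    """
    lfirst = idx.lfirst
    if itv.i == itv.k:
        if lfirst[itv.i] != c:
            output_matches_up(idx, occ, itv.sa_d, itv.w, itv.d - itv.b + 1, f, emit)
            if itv.e > itv.d:
                s2, _, x2 = idx.phi_inv_step(itv.sa_d, itv.x)
                output_matches_down(idx, occ, s2, x2, itv.e - itv.d, f, emit)
        return
    if lfirst[itv.i] != c:
        output_matches_up(
            idx, occ, idx.sa_minus[itv.i], idx.sa_phi_minus[itv.i],
            idx.lf_start(itv.i + 1) - itv.b, f, emit,
        )
    o = itv.i + 1
    while o < itv.k:
        if lfirst[o] == c:
            idx.counters["nd"] = idx.counters.get("nd", 0) + 1
            o = idx.nd[o]
            continue
        output_matches_down(
            idx, occ, idx.sa_plus[o], idx.sa_index_plus[o],
            idx.lf_start(o + 1) - idx.lf_start(o), f, emit,
        )
        o += 1
    if o == itv.k and lfirst[itv.k] != c:
        output_matches_down(
            idx, occ, idx.sa_plus[itv.k], idx.sa_index_plus[itv.k],
            itv.e - idx.lf_start(itv.k) + 1, f, emit,
        )


# -- interval expansion (right-maximal suffix intake) -------------------------


def _expand(idx, itv, occ, f, L):
    """Grow [b, e] with every suffix whose LCP with P[f, m] is exactly L,
    inserting each under its diagonal with value f + L - 1."""
    b, i, sa_b, v = itv.b, itv.i, itv.sa_b, itv.v
    while idx.plcp_at(sa_b, v) >= L:
        if b == idx.lf_start(i):
            i -= 1
        b -= 1
        sa_b, _, v = idx.phi_step(sa_b, v)
        occ.insert(sa_b - f, f + L - 1)
    e, k, sa_e, y = itv.e, itv.k, itv.sa_e, itv.y
    while idx.plcp_below(sa_e, y) >= L:
        if e == idx.lf_end(k):
            k += 1
        e += 1
        sa_e, _, y = idx.phi_inv_step(sa_e, y)
        occ.insert(sa_e - f, f + L - 1)
    return replace(itv, b=b, i=i, sa_b=sa_b, v=v, e=e, k=k, sa_e=sa_e, y=y)


def _seed_from_ms(idx, occ, entry, f, L):
    """Singleton interval at the matching-statistics witness row."""
    itv = BalancedSaLcpInterval(
        b=entry.row, d=entry.row, e=entry.row,
        sa_b=entry.suff, sa_d=entry.suff, sa_e=entry.suff,
        i=entry.i, j=entry.i, k=entry.i,
        v=entry.w, w=entry.w, x=entry.x, y=entry.x,
    )
    occ.insert(entry.suff - f, f + L - 1)
    return _expand(idx, itv, occ, f, L)


def _populate_from_seed(idx, occ, itv, f, L):
    """Insert every suffix of a freshly seeded window interval."""
    occ.insert(itv.sa_d - f, f + L - 1)
    s, io = itv.sa_d, itv.w
    for _ in range(itv.d - itv.b):
        s, _, io = idx.phi_step(s, io)
        occ.insert(s - f, f + L - 1)
    s, io = itv.sa_d, itv.x
    for _ in range(itv.e - itv.d):
        s, _, io = idx.phi_inv_step(s, io)
        occ.insert(s - f, f + L - 1)
    return itv


def advance(
    idx,
    itv_prev,
    occ,
    P,
    f: int,
    L: int,
    emit,
    ms=None,
    seeder: Optional[Callable[[int], Optional[BalancedSaLcpInterval]]] = None,
    variant: str = "run_scan",
):
    """One window step: interval of P[f+1, f+L] -> interval of P[f, f+L-1].

    Emits all long LEMs of the form P[f+1, g], then left-extends by
    P[f] and re-expands (or reseeds from matching statistics / the
    ``seeder`` when the extension dies).  Returns the new interval (or
    None) and leaves ``occ`` holding exactly its suffixes.
    """
    c = P[f]
    itv = None
    if itv_prev is not None:
        _output_phase(idx, itv_prev, occ, f, c, emit)
        itv = extend_interval(idx, itv_prev, c, variant)
    if itv is not None:
        return _expand(idx, itv, occ, f, L)
    if ms is not None:
        entry = ms[f]
        if entry.len == L:
            return _seed_from_ms(idx, occ, entry, f, L)
        return None
    if seeder is not None:
        seeded = seeder(f)
        if seeded is not None:
            return _populate_from_seed(idx, occ, seeded, f, L)
    return None


# -- full queries -------------------------------------------------------------


def _run_query(idx, P, L, emit, ms, seeder, variant, dict_mode):
    if L < 1:
        raise ValueError("length threshold L must be >= 1")
    m = len(P) - 1
    results = []

    def _emit(triple):
        results.append(triple)
        if emit is not None:
            emit(triple)

    if L > m:
        return results
    occ = make_occ_dict(dict_mode, idx.counters)
    itv = None
    for f in range(m - L + 1, 0, -1):
        itv = advance(idx, itv, occ, P, f, L, _emit, ms=ms, seeder=seeder,
                      variant=variant)
    if itv is not None:
        _output_phase(idx, itv, occ, 0, None, _emit)
    if len(occ) != 0:
        raise InternalConsistencyError("live suffixes left after final flush")
    return results


def long_lem_query(idx, P, ms, L, emit=None, variant="run_scan", dict_mode="hashed"):
    """All long LEMs of P w.r.t. the indexed text, given matching statistics.

    Parameters
    ----------
    P : list
        Pattern as a 1-based list of symbol ranks (``P[0]`` unused);
        see :meth:`Text.encode_pattern`.
    ms : list
        Augmented matching statistics, 1-based list of
        :class:`~longlem.matching_stats.MsEntry`.
    L : int
        Length threshold (>= 1).
    emit : callable, optional
        Called with each :class:`LemTriple` as it is discovered.

    Returns the triples in discovery order; O(m + occ) expected
    dictionary/move operations.
    """
    return _run_query(idx, P, L, emit, ms, None, variant, dict_mode)


def long_lem_query_direct(idx, P, L, emit=None, variant="run_scan", dict_mode="hashed"):
    """All long LEMs without matching statistics.

    Windows that cannot be reached by extension are reseeded by L
    backward-extension steps each (O(mL + occ) overall).
    """
    from .matching_stats import seed_window

    def seeder(f):
        return seed_window(idx, P, f, L, variant=variant)

    return _run_query(idx, P, L, emit, None, seeder, variant, dict_mode)
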