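"""Ground-truth enumerators and a synthetic haplotype-panel generator.

The enumerators work straight from the definitions by scanning the
match diagonals of the pattern/text dynamic-programming grid, O(n * m)
per query; they exist to verify the compressed-index algorithms, not to
be fast.  The panel generator emulates the statistical shape of a
pangenome haplotype panel -- many near-identical copies of a founder
sequence -- which is the regime where a run-length compressed index
earns its keep (BWT run count r << n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_arrays import Text
from .long_lem_query import LemTriple

__all__ = [
    "PanelConfig",
    "enumerate_lems_bruteforce",
    "enumerate_mems_bruteforce",
    "simulate_panel",
]


def _as_arrays(text, P):
    t = np.asarray(text.symbols[1:] if isinstance(text, Text) else text[1:],
                   dtype=np.int64)
    p = np.asarray(P[1:], dtype=np.int64)
    return t, p


def _diagonal_runs(t, p):
    """Maximal equal runs per diagonal: yields (p_start, t_start, length)."""
    n, m = len(t), len(p)
    for c in range(1 - m, n):  # c = t_start - p_start
        i0 = max(1, 1 - c)
        i1 = min(m, n - c)
        if i0 > i1:
            continue
        eq = (p[i0 - 1 : i1] == t[i0 + c - 1 : i1 + c]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for a, bnd in zip(edges[::2], edges[1::2]):
            yield i0 + int(a), i0 + int(a) + c, int(bnd - a)


def enumerate_lems_bruteforce(text, P, L: int):
    """All long LEMs as a set of (p_start, t_start, length) triples.

    A locally maximal exact match is exactly a maximal run of equal
    symbols along one diagonal: extending it simultaneously on either
    side is blocked by an edge or a mismatching symbol pair.
    """
    t, p = _as_arrays(text, P)
    return {
        LemTriple(i, ip, k)
        for i, ip, k in _diagonal_runs(t, p)
        if k >= L
    }


def enumerate_mems_bruteforce(text, P, min_length: int = 1):
    """All MEMs (matches maximal in the pattern) of length >= min_length.

    From the diagonal runs: position i's longest match length is the
    best remaining run length over all diagonals through i; a MEM
    starts where that length is not covered by the previous position.
    """
    t, p = _as_arrays(text, P)
    m = len(p)
    runs = list(_diagonal_runs(t, p))
    best = np.zeros(m + 2, dtype=np.int64)
    for i, _, k in runs:
        seg = best[i : i + k]
        np.maximum(seg, np.arange(k, 0, -1), out=seg)
    out = set()
    for i, ip, k in runs:
        for off in range(k):
            pos = i + off
            rem = k - off
            if rem < min_length or best[pos] != rem:
                continue
            if pos == 1 or best[pos - 1] <= best[pos]:
                out.add(LemTriple(pos, ip + off, rem))
    return out


@dataclass(frozen=True)
class PanelConfig:
    """Synthetic panel: near-identical haplotypes from one founder.

    ``mutation_rate`` is the per-site probability that a haplotype
    carries a random non-founder allele.
    """

    n_haplotypes: int = 8
    haplotype_length: int = 200
    mutation_rate: float = 0.01
    alphabet: str = "ACGT"
    seed: int = 0

    def validate(self):
        if self.n_haplotypes < 1 or self.haplotype_length < 1:
            raise ValueError("panel dimensions must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if len(self.alphabet) < 1:
            raise ValueError("alphabet must be nonempty")


def _mutate(founder, rate, sigma, rng):
    hap = founder.copy()
    if sigma > 1 and rate > 0:
        mask = rng.random(len(founder)) < rate
        shift = rng.integers(1, sigma, size=len(founder))
        hap[mask] = (hap[mask] + shift[mask]) % sigma
    return hap


def simulate_panel(cfg: PanelConfig):
    """One founder, n mutated copies as the text, one more as the query.

    Returns ``(text, pattern)`` where ``text`` is a sentinel-separated
    :class:`Text` of the panel and ``pattern`` the held-out haplotype
    as a plain string.  Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sigma = len(cfg.alphabet)
    founder = rng.integers(0, sigma, size=cfg.haplotype_length)
    haps = []
    for _ in range(cfg.n_haplotypes):
        hap = _mutate(founder, cfg.mutation_rate, sigma, rng)
        haps.append("".join(cfg.alphabet[v] for v in hap))
    query_arr = _mutate(founder, cfg.mutation_rate, sigma, rng)
    query = "".join(cfg.alphabet[v] for v in query_arr)
    names = [f"hap{i + 1}" for i in range(cfg.n_haplotypes)]
    return Text.from_strings(haps, names), query
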