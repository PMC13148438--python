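"""Reference (uncompressed) suffix structures for a text.

Everything here is the plain, array-based view of a text: suffix array,
inverse suffix array, BWT, LCP/PLCP, and the LF / phi / phi-inverse
permutations.  These arrays are built once, in O(n log n) time and O(n)
space, and serve two roles: the compressed index is assembled from them
at construction time (and then discards them), and the test-suite uses
them as the ground-truth oracle for every query primitive.

Conventions
-----------
All positions, ranks and suffix-array rows are 1-based and inclusive, so
every array is stored with a throwaway element at index 0.  A text is a
sequence of integer ranks; rank values 1..sentinel_count are sentinels
(one per sequence, each occurring exactly once, the last symbol of the
text), and every regular symbol ranks strictly above every sentinel.
Matches can therefore never cross a sequence boundary.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Text",
    "SuffixStructures",
    "RLBWT",
    "build_suffix_array",
    "build_bwt",
    "build_lcp",
    "build_lf_phi",
    "run_length_encode",
]

_ALLOWED_CHARS = set(string.ascii_uppercase)


@dataclass(frozen=True)
class Text:
    """A concatenated, sentinel-terminated symbol sequence.

    ``symbols`` is 1-based (``symbols[0]`` is a dummy 0).  For a
    collection of ``s`` sequences, sentinel ranks 1..s are appended in
    sequence order and every regular character maps case-insensitively
    to a dense rank ``s + 1, s + 2, ...`` in lexicographic character
    order.
    """

    symbols: tuple
    sentinel_count: int
    names: tuple = ()
    alphabet: dict = field(default_factory=dict)  # char -> rank (regular symbols)

    @property
    def n(self) -> int:
        return len(self.symbols) - 1

    def validate(self) -> None:
        n = self.n
        if n < 1:
            raise ValueError("text must contain at least one symbol")
        if self.sentinel_count < 1:
            raise ValueError("text must contain at least one sentinel")
        seen = [0] * (self.sentinel_count + 1)
        for v in self.symbols[1:]:
            if v < 1:
                raise ValueError("symbol ranks must be >= 1")
            if v <= self.sentinel_count:
                seen[v] += 1
        if self.symbols[n] > self.sentinel_count:
            raise ValueError("text must end with a sentinel")
        if any(c != 1 for c in seen[1:]):
            raise ValueError("each sentinel rank must occur exactly once")

    @classmethod
    def from_strings(cls, seqs, names=None) -> "Text":
        """Build a Text from one or more character sequences.

        Characters are case-folded; anything outside A-Z is rejected
        (there is no policy for ambiguity codes: better to refuse than
        to guess).  Each sequence gets its own sentinel.
        """
        seqs = [s.upper() for s in seqs]
        if not seqs:
            raise ValueError("no sequences given")
        if names is None:
            names = tuple(f"seq{i + 1}" for i in range(len(seqs)))
        else:
            names = tuple(names)
            if len(names) != len(seqs):
                raise ValueError("names/sequence count mismatch")
        chars = set()
        for s in seqs:
            bad = set(s) - _ALLOWED_CHARS
            if bad:
                raise ValueError(f"unsupported characters in sequence: {sorted(bad)!r}")
            chars.update(s)
        s_count = len(seqs)
        alphabet = {c: s_count + 1 + i for i, c in enumerate(sorted(chars))}
        symbols = [0]
        for i, s in enumerate(seqs):
            symbols.extend(alphabet[c] for c in s)
            symbols.append(i + 1)  # sentinel of sequence i
        text = cls(tuple(symbols), s_count, names, alphabet)
        text.validate()
        return text

    def encode_pattern(self, pattern: str) -> list:
        """Encode a pattern over this text's alphabet (1-based list).

        Symbols absent from the alphabet are mapped to rank 0, which
        matches nothing; they bound matching-statistics lengths.
        """
        return [0] + [self.alphabet.get(c, 0) for c in pattern.upper()]

    def sequence_starts(self) -> list:
        """1-based start position of each sequence in the concatenation."""
        starts = [1]
        for i, v in enumerate(self.symbols[1:], start=1):
            if v <= self.sentinel_count and i < self.n:
                starts.append(i + 1)
        return starts


@dataclass(frozen=True)
class RLBWT:
    """Run-length encoded BWT: (symbol, 1-based run start) per maximal run."""

    runs: tuple

    @property
    def r(self) -> int:
        return len(self.runs)


def build_suffix_array(text: Text) -> list:
    """Suffix array by prefix doubling (O(n log n)); 1-based values."""
    text.validate()
    n = text.n
    sym = np.asarray(text.symbols[1:], dtype=np.int64)
    rank = np.unique(sym, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        kr, ks = rank[order], second[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (kr[1:] != kr[:-1]) | (ks[1:] != ks[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    return [0] + (order + 1).tolist()


def build_isa(sa: list) -> list:
    n = len(sa) - 1
    isa = [0] * (n + 1)
    for row in range(1, n + 1):
        isa[sa[row]] = row
    return isa


def build_bwt(text: Text, sa: list) -> list:
    """BWT[i] = T[SA[i]-1], wrapping to T[n] when SA[i] = 1."""
    n = text.n
    sym = text.symbols
    return [0] + [sym[sa[i] - 1] if sa[i] > 1 else sym[n] for i in range(1, n + 1)]


def build_lcp(text: Text, sa: list, isa: list) -> list:
    """LCP array (LCP[1] = 0) via the PLCP identity PLCP[j] = LCP[ISA[j]]."""
    n = text.n
    sym = text.symbols
    plcp = [0] * (n + 1)
    h = 0
    for j in range(1, n + 1):
        if isa[j] > 1:
            prev = sa[isa[j] - 1]
            while j + h <= n and prev + h <= n and sym[j + h] == sym[prev + h]:
                h += 1
            plcp[j] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return [0] + [plcp[sa[i]] for i in range(1, n + 1)]


def build_lf_phi(text: Text, sa: list, isa: list):
    """LF, phi and phi-inverse permutations (all 1-based)."""
    n = text.n
    lf = [0] * (n + 1)
    phi = [0] * (n + 1)
    phi_inv = [0] * (n + 1)
    for i in range(1, n + 1):
        lf[i] = isa[sa[i] - 1] if sa[i] > 1 else isa[n]
    for k in range(2, n + 1):
        phi[sa[k]] = sa[k - 1]
    phi[sa[1]] = sa[n]
    for j in range(1, n + 1):
        phi_inv[phi[j]] = j
    return lf, phi, phi_inv


def run_length_encode(bwt: list) -> RLBWT:
    """Maximal equal-symbol runs of the BWT as (symbol, start) pairs."""
    n = len(bwt) - 1
    if n < 1:
        raise ValueError("empty BWT")
    runs = [(bwt[1], 1)]
    for i in range(2, n + 1):
        if bwt[i] != runs[-1][0]:
            runs.append((bwt[i], i))
    return RLBWT(tuple(runs))


@dataclass(frozen=True)
class SuffixStructures:
    """Oracle bundle: every uncompressed array for one text."""

    text: Text
    sa: list
    isa: list
    bwt: list
    lcp: list
    plcp: list
    lf: list
    phi: list
    phi_inv: list

    @classmethod
    def from_text(cls, text: Text) -> "SuffixStructures":
        sa = build_suffix_array(text)
        isa = build_isa(sa)
        bwt = build_bwt(text, sa)
        lcp = build_lcp(text, sa, isa)
        n = text.n
        plcp = [0] * (n + 1)
        for row in range(1, n + 1):
            plcp[sa[row]] = lcp[row]
        lf, phi, phi_inv = build_lf_phi(text, sa, isa)
        return cls(text, sa, isa, bwt, lcp, plcp, lf, phi, phi_inv)

    def check_invariants(self) -> None:
        """Assert the defining relations between the arrays (test aid)."""
        n = self.text.n
        for i in range(1, n + 1):
            assert self.sa[self.isa[i]] == i
            assert self.isa[self.sa[i]] == i
            assert self.phi[self.phi_inv[i]] == i
            assert self.plcp[self.sa[i]] == self.lcp[i]
            if self.sa[i] != 1:
                assert self.sa[self.lf[i]] == self.sa[i] - 1
        assert self.lcp[1] == 0
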