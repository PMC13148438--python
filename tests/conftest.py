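"""Shared fixtures and instrumentation helpers."""

from __future__ import annotations

import random

import pytest

import longlem as ll
from longlem.long_lem_query import _output_phase, advance
from longlem.occdict import HashedOccDict


@pytest.fixture
def abaab():
    """The worked six-symbol fixture text with its oracle structures."""
    text = ll.Text.from_strings(["ABAAB"])
    structs = ll.SuffixStructures.from_text(text)
    idx = ll.build_index(text)
    return text, structs, idx


def random_text(rng: random.Random, n_max=120, sigma_max=4):
    """One uniform random single-sequence text."""
    sigma = rng.randint(1, sigma_max)
    n = rng.randint(1, n_max)
    return ll.Text.from_strings(
        ["".join(rng.choice("ABCD"[:sigma]) for _ in range(n))]
    )


def naive_suffix_sort(symbols):
    """Independent suffix-array oracle: sort suffixes as tuples (1-based)."""
    n = len(symbols) - 1
    order = sorted(range(1, n + 1), key=lambda i: tuple(symbols[i:]))
    return [0] + order


def sa_interval_of_string(structs, needle):
    """Rows whose suffix starts with ``needle`` (1-based list), via filtering."""
    text = structs.text
    sym, n = text.symbols, text.n
    rows = []
    for row in range(1, n + 1):
        start = structs.sa[row]
        piece = sym[start : start + len(needle) - 1]
        if len(piece) == len(needle) - 1 and list(piece) == needle[1:]:
            rows.append(row)
    return rows


class RecordingOccDict(HashedOccDict):
    """Occurrence dictionary counting inserts and removals."""

    def __init__(self):
        super().__init__({})
        self.inserted = 0
        self.removed = 0

    def insert(self, key, value):
        self.inserted += 1
        super().insert(key, value)

    def pop(self, key):
        self.removed += 1
        return super().pop(key)


def run_instrumented_query(idx, P, ms, L):
    """Run the sweep through ``advance`` directly, auditing the dictionary.

    Returns (triples, widths_consistent, inserted, removed).
    """
    m = len(P) - 1
    results = []
    emit = results.append
    occ = RecordingOccDict()
    widths_ok = True
    if L > m:
        return results, True, 0, 0
    itv = None
    for f in range(m - L + 1, 0, -1):
        itv = advance(idx, itv, occ, P, f, L, emit, ms=ms)
        width = itv.e - itv.b + 1 if itv is not None else 0
        if len(occ) != width:
            widths_ok = False
    if itv is not None:
        _output_phase(idx, itv, occ, 0, None, emit)
    if len(occ) != 0:
        widths_ok = False
    return results, widths_ok, occ.inserted, occ.removed


def panel_instance(seed: int, L: int):
    """One simulated panel instance of the study conditions for threshold L.

    Smaller thresholds get smaller panels so the match count stays
    proportionate; sizes stay within n <= 5000, m <= 500.
    """
    rng = random.Random(seed)
    length_by_L = {2: (25, 70), 4: (40, 140), 8: (60, 240), 16: (80, 340), 32: (110, 460)}
    lo, hi = length_by_L[L]
    cfg = ll.PanelConfig(
        n_haplotypes=rng.randint(2, 8),
        haplotype_length=rng.randint(lo, hi),
        mutation_rate=rng.choice([0.0, 0.001, 0.005, 0.02, 0.05, 0.1]),
        alphabet=rng.choice(["AB", "ACGT"]),
        seed=seed,
    )
    text, pattern = ll.simulate_panel(cfg)
    return cfg, text, pattern
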