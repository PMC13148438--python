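"""The long-LEM query: extension, advancement, and the full sweep."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

import longlem as ll
from longlem.long_lem_query import BalancedSaLcpInterval, output_matches_up
from longlem.occdict import HashedOccDict

from conftest import random_text, run_instrumented_query, sa_interval_of_string

WORKED_ANSWER = {ll.LemTriple(1, 3, 3), ll.LemTriple(2, 1, 2)}


def make_interval(structs, idx, rows):
    """Build a consistent 13-tuple for SA rows [rows[0], rows[-1]] (oracle aid)."""
    b, e = rows[0], rows[-1]
    d = b
    sa = structs.sa
    return BalancedSaLcpInterval(
        b, d, e, sa[b], sa[d], sa[e],
        idx.f_lf.interval_of(b), idx.f_lf.interval_of(d), idx.f_lf.interval_of(e),
        idx.f_phi.interval_of(sa[b]), idx.f_phi.interval_of(sa[d]),
        idx.f_phiinv.interval_of(sa[d]), idx.f_phiinv.interval_of(sa[e]),
    )


class TestExtendInterval:
    def test_ab_extends_to_aab(self, abaab):
        text, structs, idx = abaab
        itv = make_interval(structs, idx, [3, 4])  # sa-interval of "AB"
        for variant in ("run_scan", "rank_select"):
            out = ll.extend_interval(idx, itv, text.alphabet["A"], variant)
            assert (out.b, out.e) == (2, 2)
            assert out.sa_b == out.sa_e == 3
            out.check_consistency(idx)

    def test_absent_extension_is_empty(self, abaab):
        text, structs, idx = abaab
        itv = make_interval(structs, idx, [3, 4])
        assert ll.extend_interval(idx, itv, 99, "run_scan") is None

    def test_sentinel_extension_rejected(self, abaab):
        """Sentinels bound matches; extending by one is a caller error."""
        text, structs, idx = abaab
        itv = make_interval(structs, idx, [3, 4])
        with pytest.raises(ll.ContractViolationError):
            ll.extend_interval(idx, itv, 1, "run_scan")

    @pytest.mark.parametrize("seed", range(30))
    def test_variants_agree_and_match_oracle(self, seed):
        """Both extension variants produce the oracle interval of cQ."""
        rng = random.Random(seed + 1100)
        text = random_text(rng, n_max=100)
        structs = ll.SuffixStructures.from_text(text)
        idx = ll.build_index(text)
        sym = text.symbols
        # extension symbols are pattern symbols: regular ranks (or absent)
        ranks = sorted(set(sym[1:]) - set(range(1, text.sentinel_count + 1)))
        ranks.append(99)  # a rank occurring nowhere
        if not ranks:
            return
        cases = 0
        while cases < 120:
            # random occurring substring Q
            start = rng.randint(1, text.n)
            qlen = rng.randint(1, min(8, text.n - start + 1))
            Q = [0] + list(sym[start : start + qlen])
            rows = sa_interval_of_string(structs, Q)
            assert rows, "substring of the text must occur"
            itv = make_interval(structs, idx, rows)
            c = rng.choice(ranks)
            exp_rows = sa_interval_of_string(structs, [0, c] + Q[1:])
            outs = [
                ll.extend_interval(idx, itv, c, v)
                for v in ("run_scan", "rank_select")
            ]
            for out in outs:
                if not exp_rows:
                    assert out is None
                else:
                    out.check_consistency(idx)
                    assert (out.b, out.e) == (exp_rows[0], exp_rows[-1])
                    assert out.sa_b == structs.sa[out.b]
                    assert out.sa_d == structs.sa[out.d]
                    assert out.sa_e == structs.sa[out.e]
            cases += 1


class TestOutputMatches:
    def test_single_match_read_off(self, abaab):
        _, _, idx = abaab
        occ = HashedOccDict()
        occ.insert(1 - 2, 3)  # suffix 1 live for window start f+1 = 2, end 3
        got = []
        output_matches_up(idx, occ, 1, 1, 1, 1, got.append)
        assert got == [ll.LemTriple(2, 1, 2)]
        assert len(occ) == 0

    def test_emptying_walk(self, abaab):
        """z equal to the interval width leaves the dictionary empty."""
        text, structs, idx = abaab
        occ = HashedOccDict()
        # rows 2..4 all start with A; window start f+1 = 1
        for row in (2, 3, 4):
            occ.insert(structs.sa[row] - 1, 2)
        got = []
        s = structs.sa[4]
        output_matches_up(idx, occ, s, idx.f_phi.interval_of(s), 3, 0, got.append)
        assert len(occ) == 0 and len(got) == 3


class TestAdvance:
    def test_hand_trace_step(self, abaab):
        """Advance f=2 -> f=1 on the worked fixture."""
        text, structs, idx = abaab
        P = text.encode_pattern("AAB")
        ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
        occ = HashedOccDict()
        itv = ll.advance(idx, None, occ, P, 2, 2, lambda t: None, ms=ms)
        assert (itv.b, itv.e) == (3, 4)
        assert sorted(occ.items()) == [(-1, 3), (2, 3)]
        emitted = []
        itv = ll.advance(idx, itv, occ, P, 1, 2, emitted.append, ms=ms)
        assert emitted == [ll.LemTriple(2, 1, 2)]
        assert (itv.b, itv.e) == (2, 2)
        assert sorted(occ.items()) == [(2, 3)]

    def test_empty_window_without_ms_support(self, abaab):
        text, structs, idx = abaab
        P = text.encode_pattern("BB")  # "BB" never occurs
        ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
        occ = HashedOccDict()
        emitted = []
        itv = ll.advance(idx, None, occ, P, 1, 2, emitted.append, ms=ms)
        assert itv is None and emitted == [] and len(occ) == 0


class TestFullQuery:
    @pytest.mark.parametrize("variant,mode", list(itertools.product(
        ["run_scan", "rank_select"], ["hashed", "ordered"])))
    def test_worked_fixture(self, abaab, variant, mode):
        text, structs, idx = abaab
        P = text.encode_pattern("AAB")
        ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
        got = set(ll.long_lem_query(idx, P, ms, 2, variant=variant, dict_mode=mode))
        assert got == WORKED_ANSWER

    def test_direct_variant_worked_fixture(self, abaab):
        text, _, idx = abaab
        got = set(ll.long_lem_query_direct(idx, text.encode_pattern("AAB"), 2))
        assert got == WORKED_ANSWER

    def test_threshold_beyond_pattern(self, abaab):
        text, structs, idx = abaab
        P = text.encode_pattern("AAB")
        ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
        assert ll.long_lem_query(idx, P, ms, 4) == []
        assert ll.long_lem_query_direct(idx, P, 4) == []

    def test_invalid_threshold(self, abaab):
        text, _, idx = abaab
        with pytest.raises(ValueError):
            ll.long_lem_query(idx, text.encode_pattern("AAB"), [], 0)

    def test_empty_pattern(self, abaab):
        _, _, idx = abaab
        assert ll.long_lem_query_direct(idx, [0], 1) == []

    def test_exact_substring_pattern_reports_whole_match(self):
        text = ll.Text.from_strings(["GATTACAGATT"])
        structs = ll.SuffixStructures.from_text(text)
        idx = ll.build_index(text)
        P = text.encode_pattern("TTACAG")  # = T[3, 8]
        ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
        assert ll.LemTriple(1, 3, 6) in set(ll.long_lem_query(idx, P, ms, 3))

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_bruteforce_on_random_instances(self, seed):
        """Exactness against the diagonal-scan oracle, plus no duplicates,
        LEM predicate re-check, and MEM-subset."""
        rng = random.Random(seed + 1200)
        if seed % 2:
            text, pat = ll.simulate_panel(ll.PanelConfig(
                n_haplotypes=rng.randint(1, 6),
                haplotype_length=rng.randint(10, 120),
                mutation_rate=rng.choice([0.0, 0.01, 0.05, 0.2]),
                alphabet=rng.choice(["AB", "ACGT"]),
                seed=seed,
            ))
        else:
            text = random_text(rng, n_max=120)
            pat = "".join(rng.choice("ABCD") for _ in range(rng.randint(1, 50)))
        structs = ll.SuffixStructures.from_text(text)
        idx = ll.build_index(text)
        P = text.encode_pattern(pat)
        m, n, sym = len(P) - 1, text.n, text.symbols
        for L in (2, 3, 5, 9):
            exp = ll.enumerate_lems_bruteforce(text, P, L)
            ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
            got_list = ll.long_lem_query(idx, P, ms, L)
            got = set(got_list)
            assert len(got_list) == len(got), "duplicate triples emitted"
            assert got == exp
            assert set(ll.long_lem_query_direct(idx, P, L)) == exp
            for t in got:
                # re-verify the LEM predicate by direct character comparison
                i, ip, k = t
                assert list(sym[ip : ip + k]) == P[i : i + k]
                assert i == 1 or ip == 1 or sym[ip - 1] != P[i - 1]
                j, jp = i + k - 1, ip + k - 1
                assert j == m or jp == n or sym[jp + 1] != P[j + 1]
                assert k >= L
            mems = {t for t in ll.enumerate_mems_bruteforce(text, P) if t.length >= L}
            assert mems <= got

    @pytest.mark.parametrize("seed", range(15))
    def test_dict_width_tracks_interval_and_conservation(self, seed):
        """After every advance the dictionary holds exactly the interval's
        suffixes; inserted == emitted == |output|."""
        rng = random.Random(seed + 1300)
        text, pat = ll.simulate_panel(ll.PanelConfig(
            n_haplotypes=rng.randint(2, 6),
            haplotype_length=rng.randint(20, 120),
            mutation_rate=rng.choice([0.005, 0.02, 0.1]),
            seed=seed,
        ))
        structs = ll.SuffixStructures.from_text(text)
        idx = ll.build_index(text)
        P = text.encode_pattern(pat)
        for L in (4, 8, 16):
            ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
            results, widths_ok, inserted, removed = run_instrumented_query(
                idx, P, ms, L
            )
            assert widths_ok
            assert inserted == removed == len(results)

    @pytest.mark.parametrize("seed", range(10))
    def test_work_bound_proxy(self, seed):
        """Primitive operations stay within a fixed multiple of m + occ."""
        rng = random.Random(seed + 1400)
        text, pat = ll.simulate_panel(ll.PanelConfig(
            n_haplotypes=rng.randint(2, 10),
            haplotype_length=rng.randint(50, 300),
            mutation_rate=rng.choice([0.001, 0.01, 0.05]),
            seed=seed,
        ))
        structs = ll.SuffixStructures.from_text(text)
        idx = ll.build_index(text)
        P = text.encode_pattern(pat)
        for L in (4, 16):
            ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
            idx.reset_counters()
            res = ll.long_lem_query(idx, P, ms, L)
            assert idx.total_ops() <= 32 * (len(P) - 1 + len(res))


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    data=st.data(),
    n=st.integers(min_value=1, max_value=40),
    m=st.integers(min_value=1, max_value=14),
    L=st.integers(min_value=1, max_value=6),
)
def test_query_equals_oracle_property(data, n, m, L):
    """Property: on any small binary text/pattern the sweep output equals
    the brute-force LEM set, in every variant."""
    txt = data.draw(st.text(alphabet="AB", min_size=n, max_size=n))
    pat = data.draw(st.text(alphabet="AB", min_size=m, max_size=m))
    text = ll.Text.from_strings([txt])
    structs = ll.SuffixStructures.from_text(text)
    idx = ll.build_index(text)
    P = text.encode_pattern(pat)
    exp = ll.enumerate_lems_bruteforce(text, P, L)
    ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
    for variant in ("run_scan", "rank_select"):
        assert set(ll.long_lem_query(idx, P, ms, L, variant=variant)) == exp
    assert set(ll.long_lem_query_direct(idx, P, L)) == exp
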