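import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrmatch import (
    ConfigurationError,
    EmptyInputError,
    MatchResult,
    PeakList,
    ReferenceLibrary,
    SearchConfig,
    ValidationError,
    count_matches,
    mh1_search,
    mh2_search,
    mh3_search,
    percentage_score,
    rank_results,
    results_to_frame,
    search,
    significance_score,
)

from conftest import record


class TestSignificanceScore:
    def test_worked_examples(self):
        # 2 of 4 peaks -> 0.4; 5 of 10 -> 0.4545..., displayed 0.45
        assert significance_score(2, 4) == pytest.approx(0.4)
        assert significance_score(5, 10) == pytest.approx(5 / 11)
        assert round(significance_score(5, 10), 2) == 0.45
        assert significance_score(2, 4) < significance_score(5, 10)

    def test_no_matches_and_full_match(self):
        assert significance_score(0, 7) == 0.0
        assert significance_score(3, 3) == 0.75

    def test_matched_beyond_total_is_a_logic_error(self):
        with pytest.raises(ValidationError):
            significance_score(5, 4)
        with pytest.raises(ValidationError):
            significance_score(-1, 4)
        with pytest.raises(ValidationError):
            significance_score(0, 0)

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=200)
    def test_bounds_and_monotonicity(self, total, matched):
        matched = min(matched, total)
        s = significance_score(matched, total)
        assert 0.0 <= s < 1.0
        if matched < total:
            assert significance_score(matched + 1, total) > s

    @given(st.integers(1, 100), st.integers(2, 10))
    @settings(max_examples=100)
    def test_equal_fraction_favors_more_peaks(self, matched, factor):
        # same matched/total ratio, larger total scores strictly higher
        total = matched  # full match baseline
        assert significance_score(matched * factor, total * factor) > significance_score(
            matched, total
        )

    def test_percentage_score_is_plain_fraction(self):
        assert percentage_score(2, 4) == 0.5
        assert percentage_score(5, 10) == 0.5


class TestCountMatches:
    @pytest.mark.parametrize(
        "lib, sample, tol, expected",
        [
            ([1.00], [1.00], 0.0, (1, (1.00,))),
            ([1.00], [1.01], 0.0, (0, ())),
            ([1.00], [1.01], 0.01, (1, (1.00,))),
            # each library peak counts at most once however many sample
            # peaks fall inside its window
            ([1.00, 2.00], [1.00, 1.01], 0.01, (1, (1.00,))),
        ],
    )
    def test_window_semantics(self, lib, sample, tol, expected):
        assert count_matches(lib, sample, tol) == expected

    def test_boundary_is_inclusive_across_the_scale(self):
        # float subtraction of canonical ppm values can exceed the nominal
        # tolerance (2.01-2.00 > 0.01 in binary); matching must not care
        for q in (1.00, 2.00, 5.00, 7.30, 9.99):
            assert count_matches([q], [round(q + 0.01, 2)], 0.01)[0] == 1
            assert count_matches([q], [round(q - 0.01, 2)], 0.01)[0] == 1

    @given(
        st.lists(st.integers(0, 300), min_size=1, max_size=15),
        st.lists(st.integers(0, 300), min_size=1, max_size=15),
        st.sampled_from([0.0, 0.01, 0.03, 0.05]),
    )
    @settings(max_examples=200)
    def test_matches_equal_brute_force(self, lib_c, sample_c, tol):
        lib = sorted({c / 100 for c in lib_c})
        sample = sorted({c / 100 for c in sample_c})
        n, coords = count_matches(lib, sample, tol)
        brute = [
            q for q in lib if any(abs(round(q * 100) - round(p * 100)) <= tol * 100 + 1e-9 for p in sample)
        ]
        assert n == len(brute)
        assert list(coords) == brute


class TestSearchConfig:
    def test_mh1_forbids_tolerance(self):
        with pytest.raises(ConfigurationError):
            SearchConfig(method="MH1", tolerance=0.01)

    def test_mh3_tolerance_requires_opt_in(self):
        with pytest.raises(ConfigurationError):
            SearchConfig(method="MH3", tolerance=0.01)
        SearchConfig(method="MH3", tolerance=0.01, allow_mh3_tolerance=True)

    @pytest.mark.parametrize("kw", [{"r": 1.5}, {"r": -0.1}, {"tolerance": -1.0},
                                    {"method": "MH9"}, {"max_results": 0},
                                    {"score_function": "f3"}])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ConfigurationError):
            SearchConfig(**kw)


class TestMH1:
    def test_hand_traced_example(self, toy_library, sample_123):
        results = mh1_search(sample_123, toy_library, SearchConfig(method="MH1", r=0.5))
        assert [(m.metabolite_id, m.score) for m in results] == [("A", 0.75), ("B", 0.5)]
        assert [m.rank for m in results] == [1, 2]
        assert results[0].matched_coords == (1.0, 2.0, 3.0)

    def test_self_query_ranks_first(self, toy_library):
        rec = toy_library.get("A")
        sample = PeakList(rec.peaks)
        results = mh1_search(sample, toy_library, SearchConfig(method="MH1", r=0.0))
        assert results[0].metabolite_id == "A"
        assert results[0].score == rec.total / (rec.total + 1)

    def test_r_equal_one_gives_empty_output(self, toy_library, sample_123):
        assert mh1_search(sample_123, toy_library, SearchConfig(method="MH1", r=1.0)) == []

    def test_empty_sample_is_an_error(self, toy_library):
        with pytest.raises(EmptyInputError):
            mh1_search(PeakList(()), toy_library, SearchConfig(method="MH1"))

    def test_noise_threshold_drops_weak_query_peaks(self, toy_library):
        sample = PeakList.from_pairs([(1.0, 10.0), (2.0, 0.5), (3.0, 0.5)])
        results = mh1_search(
            sample, toy_library, SearchConfig(method="MH1", r=0.0, eta=1.0)
        )
        by_id = {m.metabolite_id: m for m in results}
        assert by_id["A"].matched == 1  # 2.00 and 3.00 were below eta

    def test_empty_post_filter_library_is_an_error(self, toy_library, sample_123):
        cfg = SearchConfig(method="MH1", features={"solvent": "CDCl3"})
        with pytest.raises(ConfigurationError):
            mh1_search(sample_123, toy_library, cfg)


class TestMH2:
    def test_tolerance_zero_equals_mh1(self, toy_library, sample_123):
        r1 = mh1_search(sample_123, toy_library, SearchConfig(method="MH1", r=0.0))
        r2 = mh2_search(sample_123, toy_library, SearchConfig(method="MH2", r=0.0, tolerance=0.0))
        assert r1 == r2

    def test_window_recaptures_uniform_shift(self, toy_library):
        shifted = PeakList.from_pairs([(1.01, 1), (2.01, 1), (3.01, 1)])
        hit = mh2_search(
            shifted, toy_library, SearchConfig(method="MH2", r=0.5, tolerance=0.01)
        )
        assert hit[0].metabolite_id == "A" and hit[0].score == 0.75

    def test_narrower_window_misses_the_shift(self, toy_library):
        shifted = PeakList.from_pairs([(1.01, 1), (2.01, 1), (3.01, 1)])
        miss = mh2_search(
            shifted, toy_library, SearchConfig(method="MH2", r=0.0, tolerance=0.005)
        )
        assert all(m.metabolite_id != "A" for m in miss)


def brute_force_greedy(lib, sample_ppms, r, tolerance=0.0):
    """Independent re-simulation of the greedy rule with plain python sets."""
    remaining = {round(p * 100) for p in sample_ppms}
    candidates = {rec.id: [round(p * 100) for p in rec.ppms()] for rec in lib}
    order = []
    while remaining and candidates:
        scored = []
        for rid, coords in candidates.items():
            matched = sum(
                1 for q in coords
                if any(abs(q - p) <= tolerance * 100 + 1e-9 for p in remaining)
            )
            scored.append((-(matched / (len(coords) + 1)), -len(coords), rid, matched))
        scored.sort()
        neg_score, _, rid, matched = scored[0]
        if matched == 0 or -neg_score < r:
            break
        consumed = {
            q for q in candidates[rid]
            if any(abs(q - p) <= tolerance * 100 + 1e-9 for p in remaining)
        }
        if tolerance == 0:
            remaining -= consumed
        else:
            remaining = {
                p for p in remaining
                if not any(abs(q - p) <= tolerance * 100 + 1e-9 for q in consumed)
            }
        candidates.pop(rid)
        order.append((rid, -neg_score))
    return order


class TestMH3:
    def test_hand_traced_example(self):
        lib = ReferenceLibrary([record("A", [1.0, 2.0]), record("B", [1.0])])
        sample = PeakList.from_pairs([(1.0, 1), (2.0, 1)])
        results = mh3_search(sample, lib, SearchConfig(method="MH3", r=0.5))
        # B's sole peak is consumed by A: deliberately a false negative
        assert [(m.metabolite_id, m.score) for m in results] == [("A", pytest.approx(2 / 3))]

    def test_disjoint_mixture_reports_every_member(self):
        lib = ReferenceLibrary(
            [record("A", [1.0, 2.0]), record("B", [3.0, 4.0, 5.0]), record("C", [7.0])]
        )
        sample = PeakList.from_pairs([(p, 1.0) for p in (1.0, 2.0, 3.0, 4.0, 5.0)])
        results = mh3_search(sample, lib, SearchConfig(method="MH3", r=0.5))
        assert {m.metabolite_id for m in results} == {"A", "B"}
        for m in results:
            assert m.score == m.total / (m.total + 1)

    def test_unmatchable_residual_terminates(self, toy_library):
        sample = PeakList.from_pairs([(1.0, 1), (2.0, 1), (3.0, 1), (9.5, 1)])
        results = mh3_search(sample, toy_library, SearchConfig(method="MH3", r=0.5))
        assert [m.metabolite_id for m in results] == ["A"]

    def test_mutual_exclusion_of_matched_coords(self):
        lib = ReferenceLibrary(
            [record("A", [1.0, 2.0, 3.0]), record("B", [3.0, 4.0]), record("C", [4.0, 5.0])]
        )
        sample = PeakList.from_pairs([(p, 1.0) for p in (1.0, 2.0, 3.0, 4.0, 5.0)])
        results = mh3_search(sample, lib, SearchConfig(method="MH3", r=0.0))
        seen = set()
        for m in results:
            coords = set(m.matched_coords)
            assert not (coords & seen)
            seen |= coords
        assert seen <= set(sample.ppms())

    def test_selection_ties_prefer_more_total_peaks(self):
        # equal scores are impossible at different totals; force a tie with
        # identical score by exact construction: 1/(1+1)=0.5 vs 2/(3+1)=0.5
        lib = ReferenceLibrary([record("ONE", [1.0]), record("TRI", [1.0, 2.0, 3.0])])
        sample = PeakList.from_pairs([(1.0, 1), (2.0, 1)])
        results = mh3_search(sample, lib, SearchConfig(method="MH3", r=0.5))
        assert results[0].metabolite_id == "TRI"

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        coords = rng.choice(np.arange(100, 400), size=40, replace=False)
        recs = []
        for i in range(k):
            n = int(rng.integers(1, 6))
            sel = rng.choice(coords, size=n, replace=False)
            recs.append(record(f"M{i:02d}", sorted(c / 100 for c in sel)))
        lib = ReferenceLibrary(recs)
        m = int(rng.integers(1, 20))
        sample_ppms = sorted({c / 100 for c in rng.choice(coords, size=m)})
        sample = PeakList.from_pairs([(p, 1.0) for p in sample_ppms])
        r = float(rng.choice([0.0, 0.3, 0.5]))
        got = mh3_search(sample, lib, SearchConfig(method="MH3", r=r))
        expected = brute_force_greedy(lib, sample_ppms, r)
        assert [(m.metabolite_id, m.score) for m in got] == [
            (rid, pytest.approx(s)) for rid, s in expected
        ]


class TestRankResults:
    cfg = SearchConfig(method="MH1", max_results=10)

    @staticmethod
    def mr(rid, score, matched=1, total=4):
        return MatchResult(rid, rid.lower(), score, matched, total, (1.0,) * 0)

    def test_descending_score(self):
        ranked = rank_results([self.mr("A", 0.5), self.mr("B", 0.75)], self.cfg)
        assert [m.metabolite_id for m in ranked] == ["B", "A"]
        assert [m.rank for m in ranked] == [1, 2]

    def test_tie_broken_by_matched_then_id(self):
        ranked = rank_results(
            [self.mr("B", 0.5, matched=2), self.mr("A", 0.5, matched=3)], self.cfg
        )
        assert [m.metabolite_id for m in ranked] == ["A", "B"]
        ranked = rank_results(
            [self.mr("B", 0.5, matched=2), self.mr("A", 0.5, matched=2)], self.cfg
        )
        assert [m.metabolite_id for m in ranked] == ["A", "B"]

    def test_truncation_at_max_results(self):
        cfg = SearchConfig(method="MH1", max_results=2)
        ranked = rank_results(
            [self.mr("A", 0.9), self.mr("B", 0.8), self.mr("C", 0.7)], cfg
        )
        assert len(ranked) == 2


class TestResultsTable:
    def test_display_score_and_metadata_columns(self, toy_library, sample_123):
        results = search(sample_123, toy_library, SearchConfig(method="MH1", r=0.0))
        df = results_to_frame(results, toy_library)
        assert list(df["score"][:2]) == ["0.75", "0.50"]
        assert set(
            ["rank", "id", "name", "score", "score_full", "matched", "total",
             "source", "mtype", "ph", "solvent", "frequency"]
        ) == set(df.columns)
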