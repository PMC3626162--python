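"""Indicator transformation T(I) and the 11-dimensional context distance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scattar import (
    ContextVector,
    DistanceUndefinedError,
    EvidenceFormatError,
    IndicatorTable,
    NotFoundError,
    Study,
    StudyType,
    UnresolvableDistanceError,
    context_distance,
    country_profile,
    load_indicators,
    rank_matches,
    study_distance,
    transform_indicator,
    write_indicators,
)
from scattar.context import INDICATORS, MAX_DISTANCE, N_DIMS
from scattar.evidence import Citation, Goal, ImpactScore

from conftest import CBHI


def brute_force_distance(a: ContextVector, b: ContextVector):
    """Independent loop-based oracle for the rescaled Euclidean distance."""
    total, k = 0.0, 0
    for j in range(N_DIMS):
        if a.present[j] and b.present[j]:
            k += 1
            total += (a.values[j] - b.values[j]) ** 2
    if k == 0:
        return None
    return math.sqrt(11.0 / k * total), k


def _vec(values, present=None) -> ContextVector:
    values = np.asarray(values, dtype=float)
    if present is None:
        present = ~np.isnan(values)
    return ContextVector(values=values, present=np.asarray(present, dtype=bool))


unit_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=N_DIMS, max_size=N_DIMS
).map(_vec)


class TestTransform:
    def test_boundaries_midpoint_and_clamping(self):
        assert transform_indicator(2.0, 2.0, 10.0) == 0.0
        assert transform_indicator(10.0, 2.0, 10.0) == 1.0
        assert transform_indicator(6.0, 2.0, 10.0) == 0.5
        assert transform_indicator(-5.0, 2.0, 10.0) == 0.0
        assert transform_indicator(99.0, 2.0, 10.0) == 1.0

    def test_degenerate_bounds_give_half(self):
        assert transform_indicator(3.0, 3.0, 3.0) == 0.5

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            transform_indicator(1.0, 5.0, 2.0)


class TestLoadIndicators:
    def _write_csv(self, path, rows, header=None):
        header = header or ["country_code", *INDICATORS]
        lines = [",".join(header)]
        lines += [",".join(str(c) for c in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")

    def test_ten_country_csv_gives_eleven_bounds(self, tmp_path):
        rows = [[f"C{i:02d}"] + [float(i + j) for j in range(11)] for i in range(10)]
        for r in rows:
            r[-1] = 10 ** (5 + 0.1 * rows.index(r))  # positive populations
        path = tmp_path / "ind.csv"
        self._write_csv(path, rows)
        table = load_indicators(path)
        assert table.mins.shape == (11,)
        assert np.all(table.mins <= table.maxs)

    def test_population_stored_as_log10(self, tmp_path):
        rows = [
            ["AAA"] + [1.0] * 10 + [1_000_000],
            ["BBB"] + [2.0] * 10 + [10_000_000],
        ]
        path = tmp_path / "ind.csv"
        self._write_csv(path, rows)
        table = load_indicators(path)
        assert table.values["AAA"][INDICATORS.index("population")] == pytest.approx(6.0)

    def test_missing_cell_flagged_and_bounds_over_rest(self, tmp_path):
        hiv = INDICATORS.index("hiv_prevalence")
        rows = [
            ["AAA"] + [1.0] * 10 + [1e6],
            ["BBB"] + [3.0] * 10 + [1e7],
            ["CCC"] + [9.0] * 10 + [1e8],
        ]
        rows[1][1 + hiv] = ""  # blank BBB's HIV prevalence
        path = tmp_path / "ind.csv"
        self._write_csv(path, rows)
        table = load_indicators(path)
        assert np.isnan(table.values["BBB"][hiv])
        # Brute-force bounds over the remaining rows.
        assert table.mins[hiv] == 1.0 and table.maxs[hiv] == 9.0
        assert not country_profile(table, "BBB").present[hiv]

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        rows = [["AAA"] + [1.0] * 10 + [1e6]]
        rows[0][3] = "lots"
        path = tmp_path / "ind.csv"
        self._write_csv(path, rows)
        with pytest.raises(EvidenceFormatError, match="AAA.*under5_mortality_rate"):
            load_indicators(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "ind.csv"
        header = ["country_code", *INDICATORS[:-1]]
        self._write_csv(path, [["AAA"] + [1.0] * 10], header=header)
        with pytest.raises(EvidenceFormatError, match="population"):
            load_indicators(path)

    def test_nonpositive_population_rejected(self, tmp_path):
        path = tmp_path / "ind.csv"
        self._write_csv(path, [["AAA"] + [1.0] * 10 + [0]])
        with pytest.raises(ValueError, match="population"):
            load_indicators(path)

    def test_write_load_round_trip(self, tmp_path, tiny_table):
        path = tmp_path / "ind.csv"
        write_indicators(tiny_table, path)
        reloaded = load_indicators(path)
        for code, row in tiny_table.values.items():
            np.testing.assert_allclose(reloaded.values[code], row, rtol=1e-9)


class TestProfile:
    def test_extreme_countries_map_to_corners(self, tiny_table):
        np.testing.assert_array_equal(
            country_profile(tiny_table, "AAA").values, np.zeros(11)
        )
        np.testing.assert_array_equal(
            country_profile(tiny_table, "BBB").values, np.ones(11)
        )
        np.testing.assert_allclose(
            country_profile(tiny_table, "CCC").values, np.full(11, 0.5)
        )

    def test_random_rows_match_scalar_oracle(self):
        rng = np.random.default_rng(42)
        values = {f"C{i}": rng.uniform(0, 100, size=11) for i in range(6)}
        table = IndicatorTable.from_values(values)
        for code, raw in values.items():
            profile = country_profile(table, code)
            for j in range(11):
                expected = (raw[j] - table.mins[j]) / (table.maxs[j] - table.mins[j])
                assert profile.values[j] == pytest.approx(expected, abs=1e-12)

    def test_unknown_country(self, tiny_table):
        with pytest.raises(NotFoundError):
            country_profile(tiny_table, "ZZZ")


class TestDistance:
    def test_identity_and_extremes(self):
        zero, one = _vec(np.zeros(11)), _vec(np.ones(11))
        assert context_distance(zero, zero).value == 0.0
        d = context_distance(zero, one)
        assert d.value == pytest.approx(math.sqrt(11), abs=1e-12)
        assert d.k_present == 11

    def test_single_axis_difference(self):
        a = _vec(np.zeros(11))
        b_vals = np.zeros(11)
        b_vals[4] = 0.5
        assert context_distance(a, _vec(b_vals)).value == pytest.approx(0.5)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a, b = _vec(rng.random(11)), _vec(rng.random(11))
            expected, k = brute_force_distance(a, b)
            d = context_distance(a, b)
            assert d.value == pytest.approx(expected, abs=1e-12)
            assert d.k_present == k

    def test_partial_coverage_rescaled(self):
        # One shared dimension differing by 0.3: d = sqrt(11/1 * 0.09).
        a_vals = np.full(11, np.nan)
        b_vals = np.full(11, np.nan)
        a_vals[0], b_vals[0] = 0.2, 0.5
        b_vals[1] = 0.9  # present only in b
        d = context_distance(_vec(a_vals), _vec(b_vals))
        assert d.k_present == 1
        assert d.value == pytest.approx(math.sqrt(11 * 0.09), abs=1e-12)
        assert d.value <= MAX_DISTANCE

    def test_no_shared_dimension_is_undefined(self):
        a_vals = np.full(11, np.nan)
        b_vals = np.full(11, np.nan)
        a_vals[0], b_vals[1] = 0.1, 0.2
        with pytest.raises(DistanceUndefinedError):
            context_distance(_vec(a_vals), _vec(b_vals))

    @settings(derandomize=True, max_examples=200)
    @given(a=unit_vectors, b=unit_vectors, c=unit_vectors)
    def test_metric_axioms(self, a, b, c):
        dab = context_distance(a, b).value
        dba = context_distance(b, a).value
        assert dab >= 0.0
        assert dab == pytest.approx(dba, abs=1e-12)
        assert context_distance(a, a).value == 0.0
        dac = context_distance(a, c).value
        dcb = context_distance(c, b).value
        assert dab <= dac + dcb + 1e-9
        assert dab <= MAX_DISTANCE + 1e-12

    def test_interior_country_does_not_move_existing_distances(self):
        rng = np.random.default_rng(5)
        values = {f"C{i}": rng.uniform(10, 90, size=11) for i in range(5)}
        table = IndicatorTable.from_values(values)
        before = {
            (x, y): context_distance(
                country_profile(table, x), country_profile(table, y)
            ).value
            for x in values
            for y in values
        }
        interior = (table.mins + table.maxs) / 2.0
        bigger = IndicatorTable.from_values({**values, "NEW": interior})
        for (x, y), d in before.items():
            d2 = context_distance(
                country_profile(bigger, x), country_profile(bigger, y)
            ).value
            assert d2 == pytest.approx(d, abs=1e-12)


class TestRanking:
    def test_hand_checked_order(self, tiny_table):
        ranked = rank_matches(tiny_table, "AAA")
        assert [code for code, _ in ranked] == ["CCC", "BBB"]
        assert ranked[0][1].value == pytest.approx(math.sqrt(11) / 2)
        assert ranked[1][1].value == pytest.approx(math.sqrt(11))

    def test_include_self_ranks_first_at_zero(self, tiny_table):
        ranked = rank_matches(tiny_table, "AAA", include_self=True)
        assert ranked[0] == ("AAA", ranked[0][1])
        assert ranked[0][1].value == 0.0

    def test_output_is_permutation_of_others(self, tiny_table):
        ranked = rank_matches(tiny_table, "CCC")
        assert sorted(code for code, _ in ranked) == ["AAA", "BBB"]

    def test_unknown_country(self, tiny_table):
        with pytest.raises(NotFoundError):
            rank_matches(tiny_table, "ZZZ")


def _study(sid, study_type, countries):
    return Study(
        study_id=sid,
        citation=Citation("A", "T", 2000, "J"),
        study_type=study_type,
        countries=countries,
        assessments={(CBHI, Goal.INCREASE_USE): ImpactScore.EVIDENCE_FOR},
    )


class TestStudyDistance:
    def test_exact_country_match_is_zero(self, tiny_table):
        s = _study("S1", StudyType.EVALUATION, ["AAA"])
        assert study_distance(s, "AAA", tiny_table).value == 0.0

    def test_multi_country_including_chosen_is_zero(self, tiny_table):
        s = _study("S1", StudyType.EVALUATION, ["BBB", "AAA"])
        assert study_distance(s, "AAA", tiny_table).value == 0.0

    def test_two_country_study_takes_minimum(self, tiny_table):
        s = _study("S1", StudyType.EVALUATION, ["BBB", "CCC"])
        d = study_distance(s, "AAA", tiny_table)
        assert d.value == pytest.approx(math.sqrt(11) / 2)  # CCC is nearer

    def test_adding_a_country_never_increases_distance(self, tiny_table):
        base = _study("S1", StudyType.EVALUATION, ["BBB"])
        extended = _study("S2", StudyType.EVALUATION, ["BBB", "CCC"])
        assert (
            study_distance(extended, "AAA", tiny_table).value
            <= study_distance(base, "AAA", tiny_table).value
        )

    def test_review_is_zero_by_convention(self, tiny_table):
        s = _study("S1", StudyType.REVIEW, ["BBB"])
        assert study_distance(s, "AAA", tiny_table).value == 0.0

    def test_unknown_study_country_skipped_with_warning(self, tiny_table):
        s = _study("S1", StudyType.EVALUATION, ["ZZZ", "CCC"])
        with pytest.warns(UserWarning, match="ZZZ"):
            d = study_distance(s, "AAA", tiny_table)
        assert d.value == pytest.approx(math.sqrt(11) / 2)

    def test_unresolvable_evaluation_raises(self, tiny_table):
        s = _study("S1", StudyType.EVALUATION, ["ZZZ"])
        with pytest.warns(UserWarning):
            with pytest.raises(UnresolvableDistanceError):
                study_distance(s, "AAA", tiny_table)
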