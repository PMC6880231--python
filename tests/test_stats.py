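"""Contingency tables, Pearson chi-square, group summaries, headline fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from probebias import (
    BaselineClass,
    ChangeDirection,
    ContingencyTable,
    SmallExpectedCountWarning,
    build_table,
    chi_square_upper_tail,
    classify_timelines,
    headline_proportions,
    pearson_chi_square,
    summarize_groups,
)

from test_scoring import timeline


def table(counts, name="f"):
    counts = np.asarray(counts)
    return ContingencyTable(
        factor_name=name,
        row_labels=[f"r{i}" for i in range(counts.shape[0])],
        column_labels=[f"c{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


def random_table(rng, max_rows=3, max_cols=4):
    while True:
        r = int(rng.integers(2, max_rows + 1))
        c = int(rng.integers(2, max_cols + 1))
        counts = rng.integers(0, 15, size=(r, c))
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            return counts


class TestPearsonChiSquare:
    def test_two_by_two_example(self):
        with pytest.warns(SmallExpectedCountWarning):
            res = pearson_chi_square(table([[12, 2], [15, 1]]))
        assert round(res.statistic, 3) == 0.536
        assert res.df == 1
        assert round(res.p_value, 2) == 0.46

    def test_proportional_table_gives_zero(self):
        res = pearson_chi_square(table([[2, 4, 6], [4, 8, 12]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(40):
            counts = random_table(rng)
            # brute-force loop over cells
            row = counts.sum(axis=1)
            col = counts.sum(axis=0)
            total = counts.sum()
            oracle = 0.0
            for i in range(counts.shape[0]):
                for j in range(counts.shape[1]):
                    e = row[i] * col[j] / total
                    oracle += (counts[i, j] - e) ** 2 / e
            with pytest.warns() if (np.outer(row, col) / total).min() < 5 else _nullcontext():
                res = pearson_chi_square(table(counts))
            assert res.statistic == pytest.approx(oracle, abs=1e-9)

    def test_matches_scipy_reference(self, rng):
        # independent reference implementation, uncorrected
        for _ in range(40):
            counts = random_table(rng)
            expected_stat, expected_p, expected_df, expected_e = sps.chi2_contingency(
                counts, correction=False
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallExpectedCountWarning)
                res = pearson_chi_square(table(counts))
            assert res.statistic == pytest.approx(expected_stat, abs=1e-9)
            assert res.df == expected_df
            assert res.p_value == pytest.approx(expected_p, abs=1e-9)
            assert np.allclose(res.expected_counts, expected_e)

    def test_two_by_two_equals_squared_pooled_z(self, rng):
        for _ in range(30):
            counts = random_table(rng, max_rows=2, max_cols=2)
            n1, n2 = counts.sum(axis=1)
            x1, x2 = counts[0, 0], counts[1, 0]
            p1, p2 = x1 / n1, x2 / n2
            pooled = (x1 + x2) / (n1 + n2)
            if pooled in (0.0, 1.0):
                continue
            z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallExpectedCountWarning)
                res = pearson_chi_square(table(counts))
            assert res.statistic == pytest.approx(z**2, abs=1e-9)

    def test_invariant_under_row_and_column_permutation(self, rng):
        import warnings

        counts = random_table(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            base = pearson_chi_square(table(counts)).statistic
            permuted = counts[rng.permutation(counts.shape[0])][
                :, rng.permutation(counts.shape[1])
            ]
            assert pearson_chi_square(table(permuted)).statistic == pytest.approx(
                base, abs=1e-9
            )

    def test_expected_margins_equal_observed_margins(self, rng):
        import warnings

        counts = random_table(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            res = pearson_chi_square(table(counts))
        assert np.allclose(res.expected_counts.sum(axis=1), counts.sum(axis=1))
        assert np.allclose(res.expected_counts.sum(axis=0), counts.sum(axis=0))

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            pearson_chi_square(table([[3, 0], [5, 0]]))

    def test_yates_correction_changes_the_statistic(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            plain = pearson_chi_square(table([[13, 1], [13, 3]]))
            corrected = pearson_chi_square(table([[13, 1], [13, 3]]), correction=True)
        assert round(plain.statistic, 3) == 0.871
        assert corrected.statistic < plain.statistic


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestUpperTail:
    def test_null_statistic_gives_one(self):
        assert chi_square_upper_tail(0.0, 1) == 1.0

    def test_printed_housing_p(self):
        assert round(chi_square_upper_tail(11.92, 6), 2) == 0.06

    def test_matches_quadrature_oracle(self):
        # numerically integrate the chi-square density over the upper tail
        for stat, df in [(4.078, 3), (0.536, 1), (11.92, 6), (2.5, 4), (0.01, 2)]:
            def density(x, k=df):
                from scipy.special import gamma

                return x ** (k / 2 - 1) * np.exp(-x / 2) / (2 ** (k / 2) * gamma(k / 2))

            oracle, err = integrate.quad(density, stat, np.inf)
            assert chi_square_upper_tail(stat, df) == pytest.approx(oracle, abs=1e-8)

    def test_monotone_decreasing_in_statistic(self):
        grid = [chi_square_upper_tail(x, 3) for x in np.linspace(0, 30, 50)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi_square_upper_tail(-0.1, 2)


def _metadata_for(classifications, factor, positive_levels, absent_levels):
    """Metadata frame realising given per-group level assignments."""
    pos = [p for p, c in classifications.items() if c is BaselineClass.POSITIVE]
    ab = [p for p, c in classifications.items() if c is BaselineClass.ABSENT]
    rows = []
    for pid, lvl in zip(sorted(pos), positive_levels):
        rows.append({"participant_id": pid, factor: lvl})
    for pid, lvl in zip(sorted(ab), absent_levels):
        rows.append({"participant_id": pid, factor: lvl})
    return pd.DataFrame(rows)


class TestBuildTable:
    @pytest.fixture
    def classifications(self, fixture_timelines):
        return classify_timelines(fixture_timelines)

    def test_nationality_counts(self, classifications):
        meta = _metadata_for(
            classifications,
            "nationality",
            ["Singaporean"] * 12 + ["Others"] * 2,
            ["Singaporean"] * 15 + ["Others"] * 1,
        )
        t = build_table(
            meta, classifications, "nationality", levels=["Singaporean", "Others"]
        )
        assert t.counts.tolist() == [[12, 2], [15, 1]]
        assert t.row_labels == ["positive", "absent"]

    def test_gender_counts(self, classifications):
        meta = _metadata_for(
            classifications,
            "gender",
            ["Male"] * 13 + ["Female"],
            ["Male"] * 13 + ["Female"] * 3,
        )
        t = build_table(meta, classifications, "gender", levels=["Male", "Female"])
        assert t.counts.tolist() == [[13, 1], [13, 3]]

    def test_zero_count_level_retained(self, classifications):
        meta = _metadata_for(
            classifications,
            "substance",
            ["Opioids"] * 14,
            ["Opioids"] * 14 + ["Cannabis"] * 2,
        )
        t = build_table(
            meta, classifications, "substance", levels=["Opioids", "Cannabis"]
        )
        # the positive group's empty Cannabis level is preserved, not dropped
        assert t.counts.tolist() == [[14.0, 0.0], [14.0, 2.0]]
        assert t.column_labels == ["Opioids", "Cannabis"]

    def test_level_map_collapses_and_unmapped_raises(self, classifications):
        meta = _metadata_for(
            classifications, "housing", ["4 rooms"] * 14, ["HDB 5-room"] * 16
        )
        with pytest.raises(ValueError, match="HDB 5-room"):
            build_table(
                meta, classifications, "housing", level_map={"4 rooms": "Public"}
            )
        t = build_table(
            meta,
            classifications,
            "housing",
            level_map={"4 rooms": "Public", "HDB 5-room": "Public2"},
        )
        assert t.counts.sum() == 30


class TestGroupSummariesAndHeadlines:
    def test_fixture_group_mean_ages(self, fixtures, fixture_timelines):
        ages = pd.concat(
            [
                fixtures.table3[["participant", "age"]],
                fixtures.table4[["participant", "age"]],
            ]
        ).rename(columns={"participant": "participant_id", "age": "age_years"})
        classifications = classify_timelines(fixture_timelines)
        groups = summarize_groups(
            ages, classifications, numeric_fields=("age_years",), categorical_fields=()
        )
        assert groups["positive"].n == 14
        assert groups["absent"].n == 16
        assert round(groups["positive"].numeric["age_years"][0], 1) == 46.3
        assert round(groups["absent"].numeric["age_years"][0], 1) == 45.8

    def test_single_participant_group_sd_undefined(self):
        meta = pd.DataFrame(
            {"participant_id": ["a", "b"], "age_years": [40, 50]}
        )
        groups = summarize_groups(
            meta,
            {"a": BaselineClass.POSITIVE, "b": BaselineClass.ABSENT},
            numeric_fields=("age_years",),
            categorical_fields=(),
        )
        assert groups["positive"].numeric["age_years"] == (40.0, None)

    def test_headline_proportions_on_fixture(self, fixture_timelines):
        head = headline_proportions(fixture_timelines)
        assert (head.n_absent, head.n_positive) == (16, 14)
        assert head.fraction_absent == pytest.approx(16 / 30)
        assert head.no_reduction_ids == ("008", "019", "020")
        assert head.fraction_no_reduction_among_positive == pytest.approx(3 / 14)

    def test_all_decreasing_cohort_has_zero_no_reduction(self):
        tls = [
            timeline(50.0, [30.0, 10.0], pid="a"),
            timeline(20.0, [5.0], pid="b"),
        ]
        head = headline_proportions(tls)
        assert head.fraction_no_reduction_among_positive == 0.0
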