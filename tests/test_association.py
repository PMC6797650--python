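"""Criterion validity: symmetrization, group tests, logistic fits."""

import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rfidcontacts.events import ConfigError, ValidationError
from rfidcontacts.association import (
    compare_fits,
    duration_by_nomination_test,
    dyad_table,
    fit_duration_logit,
    read_matrix_csv,
    read_nominations,
    reciprocity,
    symmetrize,
    write_matrix_csv,
)
from rfidcontacts.synthetic import generate_self_reports, simulate_minutes_matrix


def square(values, ids=None):
    values = np.asarray(values)
    ids = ids or list(range(1, len(values) + 1))
    return pd.DataFrame(values, index=ids, columns=ids)


class TestSymmetrize:
    def test_single_direction(self):
        y = square(np.zeros((3, 3), dtype=int))
        y.iloc[0, 1] = 1
        weak = symmetrize(y, "weak")
        strong = symmetrize(y, "strong")
        assert weak.iloc[0, 1] == weak.iloc[1, 0] == 1
        assert strong.to_numpy().sum() == 0

    def test_symmetric_matrix_unchanged(self):
        vals = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        y = square(vals)
        assert (symmetrize(y, "weak").to_numpy() == vals).all()
        assert (symmetrize(y, "strong").to_numpy() == vals).all()

    def test_strong_subset_weak_exhaustive_5x5(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y = square((rng.random((5, 5)) < 0.4).astype(int))
            np.fill_diagonal(y.values, 0)
            weak = symmetrize(y, "weak").to_numpy()
            strong = symmetrize(y, "strong").to_numpy()
            yv = symmetrize(y, "none").to_numpy()
            assert (strong <= yv).all() and (yv <= weak).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            symmetrize(square(np.zeros((2, 2))), "middling")


class TestReciprocity:
    def test_fully_mutual(self):
        vals = np.ones((3, 3), dtype=int)
        np.fill_diagonal(vals, 0)
        assert reciprocity(square(vals)) == 1.0

    def test_tournament_is_zero(self):
        vals = np.triu(np.ones((4, 4), dtype=int), k=1)
        assert reciprocity(square(vals)) == 0.0

    def test_counted_example(self):
        y = square(np.zeros((4, 4), dtype=int))
        y.loc[1, 2] = y.loc[2, 1] = y.loc[1, 3] = 1
        assert reciprocity(y) == pytest.approx(2 / 3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            reciprocity(square(np.zeros((3, 3), dtype=int)))


class TestDyadTable:
    def test_directed_row_count_and_duplication(self):
        x = square([[0.0, 2.0], [2.0, 0.0]])
        y = square([[0, 1], [0, 0]])
        table = dyad_table(x, y, unit="directed")
        assert len(table) == 2
        assert set(table["minutes"]) == {2.0}
        assert sorted(table["nominated"]) == [0, 1]

    def test_responder_exclusion_drops_ego_rows(self):
        x = square(np.zeros((3, 3)))
        y = square(np.zeros((3, 3), dtype=int))
        table = dyad_table(x, y, responders=[1, 2])
        assert set(table["ego"]) == {1, 2}
        assert len(table) == 4


def two_group_matrices(rng, n_people, shift_sd_units):
    """Symmetric duration matrix plus symmetric nominations with a mean shift."""
    ids = list(range(1, n_people + 1))
    pairs = list(itertools.combinations(range(n_people), 2))
    nominated = rng.random(len(pairs)) < 0.5
    durations = rng.normal(10 + shift_sd_units * 2.0, 2.0, len(pairs))
    durations[~nominated] = rng.normal(10, 2.0, (~nominated).sum())
    x = np.zeros((n_people, n_people))
    y = np.zeros((n_people, n_people), dtype=int)
    for (i, j), dur, nom in zip(pairs, np.clip(durations, 0, None), nominated):
        x[i, j] = x[j, i] = dur
        y[i, j] = y[j, i] = int(nom)
    return square(x, ids), square(y, ids)


class TestDurationByNominationTest:
    def test_identical_group_distributions_give_zero(self):
        # nominated dyads carry minutes {4, 5, 6}; non-nominated too
        ids = [1, 2, 3, 4]
        x = square(np.zeros((4, 4)), ids=ids)
        y = square(np.zeros((4, 4), dtype=int), ids=ids)
        assignment = {
            (1, 2): (4.0, 1), (1, 3): (5.0, 1), (1, 4): (6.0, 1),
            (2, 3): (4.0, 0), (2, 4): (5.0, 0), (3, 4): (6.0, 0),
        }
        for (i, j), (minutes, nom) in assignment.items():
            x.loc[i, j] = x.loc[j, i] = minutes
            y.loc[i, j] = y.loc[j, i] = nom
        res = duration_by_nomination_test(x, y, unit="undirected")
        assert res.t == pytest.approx(0.0)
        assert res.d == pytest.approx(0.0)

    def test_degenerate_zero_variance_rejected(self):
        ids = [1, 2, 3, 4]
        x = square(np.zeros((4, 4)), ids=ids)
        y = square(np.zeros((4, 4), dtype=int), ids=ids)
        for i, j in [(1, 2), (3, 4)]:
            x.loc[i, j] = x.loc[j, i] = 0.0
        y.loc[1, 2] = y.loc[2, 1] = 1
        x2 = x.copy()
        for i, j in [(1, 2), (1, 3), (2, 4)]:
            x2.loc[i, j] = x2.loc[j, i] = 0.0
        with pytest.raises(ValidationError):
            duration_by_nomination_test(x2, y)

    def test_t_sign_flips_under_label_swap(self, rng):
        x, y = two_group_matrices(rng, 30, 1.0)
        res = duration_by_nomination_test(x, y, unit="undirected")
        swapped = (1 - y.to_numpy()).astype(int)
        np.fill_diagonal(swapped, 0)
        flipped = duration_by_nomination_test(x, square(swapped, ids=list(y.index)), unit="undirected")
        assert flipped.t == pytest.approx(-res.t)

    def test_effect_size_recovery(self, rng):
        x, y = two_group_matrices(rng, 46, 1.0)  # >500 dyads per group
        res = duration_by_nomination_test(x, y, unit="undirected")
        assert res.d == pytest.approx(1.0, abs=0.2)
        assert res.t < 0  # nominated dyads interact longer -> negative contrast
        assert res.df == res.n - 2

    def test_empty_group_rejected(self):
        x = square(np.ones((3, 3)) - np.eye(3))
        y = square(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValidationError):
            duration_by_nomination_test(x, y)


class TestLogisticFit:
    def test_degenerate_predictor_flagged(self):
        x = square(np.zeros((4, 4)))
        y = square((np.arange(16).reshape(4, 4) % 3 == 0).astype(int))
        np.fill_diagonal(y.values, 0)
        res = fit_duration_logit(x, y)
        assert res.degenerate_predictor
        p = y.to_numpy()[~np.eye(4, dtype=bool)].mean()
        assert res.intercept == pytest.approx(math.log(p / (1 - p)))
        assert math.isnan(res.slope)

    def test_independent_outcome_near_zero_r2(self):
        x = simulate_minutes_matrix(roster_size=50, seed=7)
        rng = np.random.default_rng(8)
        y = square(
            (rng.random((50, 50)) < 0.3).astype(int), ids=list(x.index)
        )
        np.fill_diagonal(y.values, 0)
        res = fit_duration_logit(x, y)
        assert res.mcfadden_r2 < 0.01

    def test_recovers_generating_coefficients(self):
        x = simulate_minutes_matrix(roster_size=56, seed=21)
        y = generate_self_reports(x, intercept=-2.16, slope_per_minute=0.02, seed=22)
        res = fit_duration_logit(x, y)
        assert abs(res.intercept - (-2.16)) < 3 * res.intercept_se
        assert abs(res.slope - 0.02) < 3 * res.slope_se
        assert 0 <= res.mcfadden_r2 < 1

    def test_r2_monotone_in_generating_slope(self):
        x = simulate_minutes_matrix(roster_size=56, seed=31)
        r2 = []
        for slope in (0.0, 0.01, 0.02):
            y = generate_self_reports(x, intercept=-2.16, slope_per_minute=slope, seed=32)
            r2.append(fit_duration_logit(x, y).mcfadden_r2)
        assert r2[0] < r2[1] < r2[2]

    def test_single_class_outcome_rejected(self):
        x = simulate_minutes_matrix(roster_size=10, seed=1)
        y = square(np.zeros((10, 10), dtype=int), ids=list(x.index))
        with pytest.raises(ValidationError):
            fit_duration_logit(x, y)


class TestCompareFits:
    def test_self_comparison_zero(self):
        x = simulate_minutes_matrix(roster_size=30, seed=41)
        y = generate_self_reports(x, seed=42)
        res = fit_duration_logit(x, y)
        chi2, df = compare_fits(res, res)
        assert chi2 == 0.0 and df == 2

    def test_arithmetic(self):
        from rfidcontacts.association import AssociationResult

        a = AssociationResult(n=100, log_likelihood=-1000.0)
        b = AssociationResult(n=100, log_likelihood=-990.0)
        assert compare_fits(a, b) == (20.0, 2)

    def test_generating_matrix_fits_better_than_noised(self):
        x = simulate_minutes_matrix(roster_size=56, seed=51)
        y = generate_self_reports(x, seed=52)
        good = fit_duration_logit(x, y)
        rng = np.random.default_rng(53)
        perm = rng.permutation(len(x))
        noised = pd.DataFrame(
            x.to_numpy()[np.ix_(perm, perm)], index=x.index, columns=x.columns
        )
        bad = fit_duration_logit(noised, y)
        assert good.log_likelihood > bad.log_likelihood
        chi2, _ = compare_fits(good, bad)
        assert chi2 > 0

    def test_mismatched_n_rejected(self):
        from rfidcontacts.association import AssociationResult

        a = AssociationResult(n=10, log_likelihood=-5.0)
        b = AssociationResult(n=12, log_likelihood=-5.0)
        with pytest.raises(ValidationError):
            compare_fits(a, b)


class TestMatrixIO:
    def test_square_round_trip(self, tmp_path):
        x = simulate_minutes_matrix(roster_size=6, seed=61)
        path = tmp_path / "x.csv"
        write_matrix_csv(x, path)
        back = read_matrix_csv(path)
        assert list(back.index) == list(x.index)
        np.testing.assert_allclose(back.to_numpy(), x.to_numpy())

    def test_edge_list_nominations(self, tmp_path):
        path = tmp_path / "y.csv"
        path.write_text("from,to\n1,2\n2,1\n1,3\n")
        y = read_nominations(path)
        assert y.loc[1, 2] == 1 and y.loc[2, 1] == 1 and y.loc[3, 1] == 0

    def test_nonbinary_nominations_rejected(self, tmp_path):
        path = tmp_path / "y.csv"
        square([[0, 2], [0, 0]]).to_csv(path)
        with pytest.raises(ValidationError):
            read_nominations(path)
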