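"""Error metrics against brute-force references, and AIC ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glioforecast.core import ImageGrid, TumorState
from glioforecast.errors import InvalidParameterError, UndefinedMetricError
from glioforecast.metrics import (
    cell_count,
    compute_aic,
    dice,
    evaluate,
    kcc,
    percent_volume_error,
    rank_models,
    voxel_agreement,
)


# -- brute-force reference implementations (kept deliberately naive) --------

def dice_bruteforce(a, b):
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    return 2 * inter / (a.sum() + b.sum())


def pcc_bruteforce(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def ccc_bruteforce(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def kendall_bruteforce(x, y):
    """Tau-b by direct pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


class TestAic:
    def test_monotone_in_sse(self):
        assert compute_aic(1.0, 100, 3) < compute_aic(2.0, 100, 3)

    def test_complexity_penalty(self):
        assert compute_aic(1.0, 100, 2) < compute_aic(1.0, 100, 3)

    def test_arithmetic(self):
        expected = 100 * math.log(1 / 100) + 2 * (3 + 1)
        assert compute_aic(1.0, 100, 3) == pytest.approx(expected)

    def test_zero_sse_guard(self):
        with pytest.raises(InvalidParameterError, match="floor"):
            compute_aic(0.0, 100, 3)


class TestRankModels:
    def test_hand_set_matrix_matches_brute_sort(self):
        aics = {"a": [10.0, 12.0], "b": [9.0, 15.0], "c": [8.0, 11.0]}
        npar = {"a": 3, "b": 4, "c": 5}
        scores = rank_models(aics, npar)
        means = {k: np.mean(v) for k, v in aics.items()}
        expected = sorted(means, key=lambda k: (means[k], npar[k], k))
        assert [s.model_id for s in scores] == expected
        assert [s.rank for s in scores] == [1, 2, 3]

    def test_shift_invariance_of_order(self):
        aics = {"a": [10.0, 12.0], "b": [9.0, 15.0]}
        npar = {"a": 3, "b": 4}
        base = [s.model_id for s in rank_models(aics, npar)]
        shifted = {k: [v[0] + 7.0, v[1]] for k, v in aics.items()}
        # adding a constant to one patient's column shifts every mean equally
        assert [s.model_id for s in rank_models(shifted, npar)] == base

    def test_tie_breaks_toward_fewer_parameters(self):
        scores = rank_models({"big": [5.0], "small": [5.0]}, {"big": 9, "small": 2})
        assert scores[0].model_id == "small"

    def test_nonfinite_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="bad"):
            scores = rank_models({"ok": [1.0], "bad": [np.nan]}, {"ok": 1, "bad": 1})
        assert [s.model_id for s in scores] == ["ok"]


class TestDice:
    def test_identical_masks_give_one(self):
        m = np.zeros((5, 5, 2), bool)
        m[1:3, 1:3, :] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((5, 5, 2), bool)
        b = np.zeros((5, 5, 2), bool)
        a[0, 0, 0] = True
        b[4, 4, 1] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0:2, 0] = True
        b[0, 1:3, 0] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one_with_warning(self):
        e = np.zeros((3, 3, 1), bool)
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    def test_matches_bruteforce_and_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2)
        b = np.array([(bits_b >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2)
        if a.sum() + b.sum() == 0:
            return
        assert dice(a, b) == pytest.approx(dice_bruteforce(a, b))
        assert dice(a, b) == dice(b, a)


class TestVolumeError:
    @pytest.mark.parametrize(
        "pred, meas, expected", [(10.0, 10.0, 0.0), (11.0, 10.0, 10.0), (0.0, 10.0, -100.0)]
    )
    def test_signed_values(self, pred, meas, expected):
        assert percent_volume_error(pred, meas) == pytest.approx(expected)

    def test_zero_measured_rejected(self):
        with pytest.raises(UndefinedMetricError):
            percent_volume_error(1.0, 0.0)


class TestVoxelAgreement:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.5, 0.9, 0.3]).reshape(2, 2)
        pcc, ccc = voxel_agreement(x, x.copy(), np.ones((2, 2), bool))
        assert pcc == pytest.approx(1.0)
        assert ccc == pytest.approx(1.0)

    def test_known_shifted_sequence(self):
        # x=(1,2,3), y=(2,3,4): perfect correlation, concordance 4/7
        x = np.array([[1.0, 2.0, 3.0]])
        y = np.array([[2.0, 3.0, 4.0]])
        pcc, ccc = voxel_agreement(x, y, np.ones_like(x, bool))
        assert pcc == pytest.approx(1.0)
        assert ccc == pytest.approx(4 / 7)

    def test_anticorrelation(self):
        x = np.array([[1.0, 2.0, 3.0]])
        pcc, ccc = voxel_agreement(x, -x, np.ones_like(x, bool))
        assert pcc == pytest.approx(-1.0)
        assert ccc < 0

    def test_zero_variance_names_input(self):
        x = np.array([[1.0, 1.0, 1.0]])
        y = np.array([[1.0, 2.0, 3.0]])
        with pytest.raises(UndefinedMetricError, match="predicted"):
            voxel_agreement(x, y, np.ones_like(x, bool))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_and_ccc_bound(self, data):
        n = data.draw(st.integers(3, 12))
        vals = st.floats(-5, 5)
        x = data.draw(st.lists(vals, min_size=n, max_size=n))
        y = data.draw(st.lists(vals, min_size=n, max_size=n))
        # avoid numerically degenerate (near-constant) inputs
        if np.var(x) < 1e-6 or np.var(y) < 1e-6:
            return
        xa, ya = np.array(x), np.array(y)
        pcc, ccc = voxel_agreement(xa, ya, np.ones(n, bool))
        assert pcc == pytest.approx(pcc_bruteforce(x, y), abs=1e-10)
        assert ccc == pytest.approx(ccc_bruteforce(x, y), abs=1e-10)
        assert abs(ccc) <= abs(pcc) + 1e-12


class TestKcc:
    def test_monotone_sequences(self):
        assert kcc([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert kcc([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_one_swap_two_thirds(self):
        assert kcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    def test_all_ties_rejected(self):
        with pytest.raises(UndefinedMetricError):
            kcc([1, 1, 1], [1, 2, 3])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_with_ties(self, data):
        n = data.draw(st.integers(2, 8))
        vals = st.integers(0, 4)  # small alphabet forces ties
        x = data.draw(st.lists(vals, min_size=n, max_size=n))
        y = data.draw(st.lists(vals, min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert kcc(x, y) == pytest.approx(kendall_bruteforce(x, y), abs=1e-10)


class TestCellCount:
    def test_uniform_field_arithmetic(self):
        grid = ImageGrid(shape=(10, 1, 1), spacing=(1, 1, 1))
        state = TumorState("single", 0.0, phi_T=np.full((10, 1, 1), 0.5))
        assert cell_count(state, grid) == pytest.approx(5.0)

    def test_linear_in_phi(self):
        grid = ImageGrid(shape=(4, 4, 2), spacing=(1, 1, 2))
        phi = np.random.default_rng(0).uniform(0, 0.4, grid.shape)
        s1 = TumorState("single", 0.0, phi_T=phi)
        s2 = TumorState("single", 0.0, phi_T=2 * phi)
        assert cell_count(s2, grid) == pytest.approx(2 * cell_count(s1, grid))

    def test_empty_state_zero(self):
        grid = ImageGrid(shape=(4, 4, 2), spacing=(1, 1, 2))
        state = TumorState("two_species", 0.0, phi_E=np.zeros(grid.shape),
                           phi_N=np.zeros(grid.shape))
        assert cell_count(state, grid) == 0.0


class TestEvaluate:
    def test_oracle_identity_on_truth(self, small_patient):
        dataset, truth = small_patient
        report = evaluate(
            truth.states, dataset,
            cellularity=truth.cellularity,
            threshold=truth.config.mask_threshold,
        )
        dice_rows = report[report.metric == "dice"]
        assert np.allclose(dice_rows.value, 1.0)
        vol_rows = report[report.metric == "percent_volume_error"]
        assert np.allclose(vol_rows.value, 0.0)
        pcc_rows = report[report.metric == "pcc"]
        assert (pcc_rows.value > 0.97).all()
        kcc_rows = report[report.metric.str.startswith("kcc")]
        assert np.allclose(kcc_rows.value, 1.0)

    def test_row_count_contract(self, small_patient):
        dataset, truth = small_patient
        report = evaluate(truth.states, dataset, cellularity=truth.cellularity,
                          threshold=truth.config.mask_threshold)
        n_visits = len(dataset.visits)
        per_visit = report[report.metric.isin(["dice"])]
        # three regions per visit for the two-species model
        assert len(per_visit) == 3 * n_visits

    def test_no_aligned_visits_rejected(self, small_patient):
        dataset, truth = small_patient
        shifted = [TumorState(s.kind, s.time + 1000.0, phi_E=s.phi_E, phi_N=s.phi_N)
                   for s in truth.states]
        with pytest.raises(InvalidParameterError):
            evaluate(shifted, dataset, cellularity=truth.cellularity)
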