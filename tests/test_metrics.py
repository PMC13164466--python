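"""Metric suite: direct values, independent oracles, analytic properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cwqsar.errors import ZeroVarianceError
from cwqsar.metrics import (
    cii,
    f_ratio,
    iic,
    mae,
    q2_loo,
    q2f_family,
    r2,
    rm2_average,
    target_function,
)

# ---------------------------------------------------------------- oracles


def iic_oracle(obs, calc):
    """Direct transcription of the IIC definition: r * min(MAE-,MAE+)/max."""
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    delta = obs - calc
    r = np.corrcoef(obs, calc)[0, 1]
    neg, pos = delta[delta < 0], delta[delta >= 0]
    mae_n = np.abs(neg).mean() if len(neg) else 0.0
    mae_p = np.abs(pos).mean() if len(pos) else 0.0
    if max(mae_n, mae_p) == 0:
        return 1.0
    return r * min(mae_n, mae_p) / max(mae_n, mae_p)


def cii_oracle(obs, calc):
    """Brute-force CII: recompute the correlation n times, one point out."""
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    r2_full = np.corrcoef(obs, calc)[0, 1] ** 2
    protests = 0.0
    for k in range(len(obs)):
        o = np.delete(obs, k)
        c = np.delete(calc, k)
        r2_k = np.corrcoef(o, c)[0, 1] ** 2
        protests += max(0.0, r2_k - r2_full)
    return 1.0 - protests


# ---------------------------------------------------------------- r2 / mae


def test_r2_is_one_on_collinear_data():
    obs = [1.0, 2.0, 3.0, 4.0]
    assert r2(obs, [2.0, 4.0, 6.0, 8.0]) == pytest.approx(1.0)
    # squaring makes the statistic sign-blind
    assert r2(obs, [-1.0, -2.0, -3.0, -4.0]) == pytest.approx(1.0)


def test_r2_matches_covariance_formula():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=4), rng.normal(size=4)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    expected = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert r2(x, y) == pytest.approx(expected, abs=1e-12)


def test_r2_rejects_constant_input():
    with pytest.raises(ZeroVarianceError):
        r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_mae_values():
    assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mae([1.0, 2.0], [0.0, 3.0]) == 1.0
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert mae(x, y) == pytest.approx(float(np.abs(x - y).mean()))


# ---------------------------------------------------------------- IIC


def test_iic_equals_r_for_symmetric_residuals():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    calc = obs + np.array([-0.2, 0.2, -0.2, 0.2])
    assert iic(obs, calc) == pytest.approx(np.corrcoef(obs, calc)[0, 1])


def test_iic_zero_for_one_sided_residuals():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    calc = obs - np.array([0.1, 0.2, 0.1, 0.3])  # all deltas positive
    assert iic(obs, calc) == 0.0


def test_iic_perfect_fit_is_one():
    obs = [1.0, 2.0, 3.0]
    assert iic(obs, obs) == 1.0


def test_iic_matches_oracle_on_random_sets():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(3, 13))
        obs = rng.normal(size=n)
        calc = obs + rng.normal(scale=0.5, size=n)
        assert iic(obs, calc) == pytest.approx(iic_oracle(obs, calc), abs=1e-12)


def test_iic_bounded_by_correlation():
    rng = np.random.default_rng(8)
    for _ in range(50):
        obs = rng.normal(size=10)
        calc = obs + rng.normal(scale=0.3, size=10)
        assert abs(iic(obs, calc)) <= abs(np.corrcoef(obs, calc)[0, 1]) + 1e-12


# ---------------------------------------------------------------- CII


def test_cii_is_one_on_collinear_data():
    obs = np.linspace(0, 5, 8)
    assert cii(obs, 3 * obs - 1) == pytest.approx(1.0)


def test_cii_never_exceeds_one():
    rng = np.random.default_rng(11)
    for _ in range(150):
        n = int(rng.integers(5, 51))
        obs = rng.normal(size=n)
        calc = obs + rng.normal(scale=rng.uniform(0.1, 2.0), size=n)
        assert cii(obs, calc) <= 1.0 + 1e-12


def test_cii_matches_brute_force_oracle():
    rng = np.random.default_rng(13)
    for _ in range(200):
        n = int(rng.integers(4, 13))
        obs = rng.normal(size=n)
        calc = obs + rng.normal(scale=0.7, size=n)
        assert cii(obs, calc) == pytest.approx(cii_oracle(obs, calc), abs=1e-12)


def test_cii_invariant_to_affine_rescaling_of_predictions():
    rng = np.random.default_rng(17)
    obs = rng.normal(size=12)
    calc = obs + rng.normal(scale=0.4, size=12)
    assert cii(obs, 2.5 * calc + 3.0) == pytest.approx(cii(obs, calc), abs=1e-12)


# ---------------------------------------------------------------- Q2 family


def test_q2_loo_is_one_on_noise_free_linear_data():
    x = np.linspace(0, 1, 10)
    y = 0.4 + 0.2 * x
    assert q2_loo(y, x) == pytest.approx(1.0)


def test_q2_loo_matches_explicit_refits():
    rng = np.random.default_rng(19)
    x = rng.normal(size=15)
    y = 1.0 + 2.0 * x + rng.normal(scale=0.5, size=15)
    press = 0.0
    for k in range(len(x)):
        xs, ys = np.delete(x, k), np.delete(y, k)
        c1 = np.polyfit(xs, ys, 1)
        pred = np.polyval(c1, x[k])
        press += (y[k] - pred) ** 2
    expected = 1.0 - press / ((y - y.mean()) ** 2).sum()
    assert q2_loo(y, x) == pytest.approx(expected, abs=1e-10)


def test_q2_loo_never_exceeds_r2():
    rng = np.random.default_rng(23)
    for _ in range(30):
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.6, size=12)
        assert q2_loo(y, x) <= r2(x, y) + 1e-10


def test_q2f_perfect_predictions():
    obs = np.array([0.0, 1.0, 2.0, 3.0])
    f1, f2, f3 = q2f_family(obs, obs, train_endpoints=[0.5, 1.5, 2.5])
    assert (f1, f2, f3) == (1.0, 1.0, 1.0)


def test_q2f1_at_least_q2f2():
    rng = np.random.default_rng(29)
    for _ in range(30):
        obs = rng.normal(size=8)
        calc = obs + rng.normal(scale=0.5, size=8)
        ytr = rng.normal(loc=0.3, size=20)
        f1, f2, _ = q2f_family(obs, calc, ytr)
        assert f1 >= f2 - 1e-12


def test_q2f_hand_arithmetic():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    calc = np.array([1.1, 1.8, 3.2, 3.9])
    ytr = np.array([1.0, 2.0, 3.0])
    sse = float(((obs - calc) ** 2).sum())
    f1, f2, f3 = q2f_family(obs, calc, ytr)
    assert f1 == pytest.approx(1 - sse / ((obs - 2.0) ** 2).sum())
    assert f2 == pytest.approx(1 - sse / ((obs - 2.5) ** 2).sum())
    assert f3 == pytest.approx(1 - (sse / 4) / (2.0 / 3))


# ---------------------------------------------------------------- rm2 / F


def test_rm2_perfect_identity_is_one():
    obs = np.array([0.0, 1.0, 2.0, 3.0])
    assert rm2_average(obs, obs) == pytest.approx(1.0)


def test_rm2_never_exceeds_r2():
    rng = np.random.default_rng(31)
    for _ in range(30):
        obs = rng.normal(size=10)
        calc = obs + rng.normal(scale=0.4, size=10)
        assert rm2_average(obs, calc) <= r2(obs, calc) + 1e-12


def test_rm2_hand_example():
    obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    calc = np.array([1.2, 1.9, 3.1, 3.8, 5.2])

    def rm2_dir(x, y):
        rsq = np.corrcoef(x, y)[0, 1] ** 2
        k = (x * y).sum() / (x * x).sum()
        r0 = 1 - ((y - k * x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        return rsq * (1 - math.sqrt(abs(rsq - r0)))

    expected = 0.5 * (rm2_dir(obs, calc) + rm2_dir(calc, obs))
    assert rm2_average(obs, calc) == pytest.approx(expected, abs=1e-12)


def test_f_ratio_values_and_monotonicity():
    rng = np.random.default_rng(37)
    x = rng.normal(size=72)
    weak = x + rng.normal(scale=2.0, size=72)
    strong = x + rng.normal(scale=0.2, size=72)
    # n=72 with r2=0.5 would give F = 0.5*70/0.5 = 70; check the formula
    r = r2(x, weak)
    assert f_ratio(x, weak) == pytest.approx(r * 70 / (1 - r))
    assert f_ratio(x, strong) > f_ratio(x, weak)


def test_f_ratio_not_applicable_when_r2_is_one():
    x = np.arange(5, dtype=float)
    assert f_ratio(x, 2 * x) is None


# ---------------------------------------------------------------- TF


def test_target_function_arithmetic():
    assert target_function(0.9, 0.5, 1.0, 0.3) == pytest.approx(1.3)
    assert target_function(0.7, 0.7, 0.0) == pytest.approx(1.4)


@given(
    a=st.floats(0, 1), p=st.floats(0, 1), idx=st.floats(-1, 1)
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_target_function_symmetric_in_training_terms(a, p, idx):
    assert target_function(a, p, idx) == pytest.approx(target_function(p, a, idx))
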