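"""Population model: drives, attention fields, suppression, responses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dichoptic.grid import NeuronGrid, wrap_orientation
from dichoptic.population import (
    FEATURE_K,
    ModelParams,
    PsychometricPredictor,
    attention_fields,
    excitatory_drive,
    feature_profile,
    goal_attention,
    population_response,
    predict_dprime,
    predict_psychometric,
    spatial_profile,
    stimulus_attention_es,
    stimulus_attention_fs,
    suppression_kernel,
    suppression_width,
    suppressive_drive,
    _brute_force_suppressive_drive,
)
from dichoptic.stimulus import Condition, StimulusComponent, expand_condition
from dichoptic.synthetic import FS_GROUP_PARAMS, default_contrasts

CONDS = ("none", "small", "medium", "large", "split")


# ---------------------------------------------------------------------------
# excitatory drive
# ---------------------------------------------------------------------------

def test_drive_zero_for_unstimulated_eye(coarse_grid):
    comps = expand_condition(Condition("none", 0.1, "right"))
    e = excitatory_drive(comps, coarse_grid)
    assert np.all(e["left"] == 0.0)
    assert e["right"].max() > 0


def test_drive_peaks_at_stimulus_and_is_linear(coarse_grid):
    comps = expand_condition(Condition("none", 0.1, "right"))
    e1 = excitatory_drive(comps, coarse_grid)["right"]
    ix, it = np.unravel_index(np.argmax(e1), e1.shape)
    assert coarse_grid.x[ix] == 0.0
    assert coarse_grid.theta[it] == 45.0
    comps2 = expand_condition(Condition("none", 0.2, "right"))
    e2 = excitatory_drive(comps2, coarse_grid)["right"]
    np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-12)


# ---------------------------------------------------------------------------
# attention profiles
# ---------------------------------------------------------------------------

def test_feature_profile_values():
    assert feature_profile(0.0, 3.0) == pytest.approx(0.5)
    assert feature_profile(90.0, 3.0) == pytest.approx(np.exp(-6.0) - 0.5, abs=1e-12)


def test_feature_profile_fwhm_is_40_degrees():
    """The unshifted orientation profile exp(k(cos 2d - 1)) at k=3 has a 40 deg FWHM."""
    d = np.linspace(0, 90, 90001)
    prof = np.exp(FEATURE_K * (np.cos(np.deg2rad(2 * d)) - 1.0))
    half = d[np.argmin(np.abs(prof - 0.5))]
    assert round(2 * half) == 40


@given(d=st.floats(-1000, 1000), k=st.floats(0.1, 10))
@settings(deadline=None, max_examples=60)
def test_feature_profile_bounds_and_periodicity(d, k):
    v = feature_profile(d, k)
    assert np.exp(-2 * k) - 0.5 - 1e-12 <= v <= 0.5 + 1e-12
    assert feature_profile(d + 180.0, k) == pytest.approx(v, abs=1e-9)


def test_spatial_profile_peaks():
    assert spatial_profile(0.0, 0.0, 1.5, 0.0) == pytest.approx(1 / np.sqrt(2 * np.pi))
    assert spatial_profile(0.0, 0.0, 1.5, 0.17) == pytest.approx(0.37237, abs=1e-5)
    with pytest.raises(ValueError):
        spatial_profile(0.0, 0.0, -1.0, 0.5)


def test_spatial_profile_fixed_volume_at_p1():
    x = np.linspace(-200, 200, 40001)
    areas = [np.trapezoid(spatial_profile(x, 0.0, s, 1.0), x) for s in (1.5, 8.0)]
    assert areas[0] == pytest.approx(areas[1], rel=1e-6)


# ---------------------------------------------------------------------------
# stimulus-driven and goal-driven gain fields
# ---------------------------------------------------------------------------

def _gain_at_target(fields, grid, eye="right"):
    ix, it = grid.index_of(0.0, 45.0)
    return fields[eye][ix, it]


@pytest.mark.parametrize(
    "cond,expected",
    [("small", 0.13), ("medium", 0.20), ("large", 0.35)],
)
def test_fs_gains_match_published_values(coarse_grid, cond, expected):
    """FS gains at the target neuron for w_x=4.70, p=0.17 (two-competitor study)."""
    comps = expand_condition(Condition(cond, 0.1, "right"))
    f = stimulus_attention_fs(comps, coarse_grid, w_x=4.70, p=0.17)
    assert _gain_at_target(f, coarse_grid) == pytest.approx(expected, abs=0.01)
    np.testing.assert_array_equal(f["left"], f["right"])


@pytest.mark.parametrize(
    "cond,expected",
    [("small", 0.15), ("medium", 0.28), ("large", 0.50)],
)
def test_es_gains_match_published_values(coarse_grid, cond, expected):
    """ES target-eye gains for w_x=2.41, p=0.31: symmetric up/down rule."""
    comps = expand_condition(Condition(cond, 0.1, "right"))
    f = stimulus_attention_es(comps, coarse_grid, w_x=2.41, p=0.31)
    assert _gain_at_target(f, coarse_grid) == pytest.approx(expected, abs=0.01)
    # symmetric increase in the competitor eye
    up = _gain_at_target(f, coarse_grid, eye="left") - 1.0
    down = 1.0 - _gain_at_target(f, coarse_grid, eye="right")
    assert up == pytest.approx(down, abs=1e-12)


def test_no_competitor_gives_unit_fields(coarse_grid):
    comps = expand_condition(Condition("none", 0.1, "right"))
    for fn in (stimulus_attention_fs, stimulus_attention_es):
        f = fn(comps, coarse_grid, 4.0, 0.3)
        for eye in ("left", "right"):
            np.testing.assert_array_equal(f[eye], 1.0)


def test_goal_attention_gains(coarse_grid):
    f = goal_attention(45.0, coarse_grid, w_v=5.03)
    assert _gain_at_target(f, coarse_grid) == pytest.approx(2.00, abs=0.01)
    ix, it = coarse_grid.index_of(0.0, 135.0)
    assert f["right"][ix, it] == pytest.approx(0.0017, abs=1e-3)
    f0 = goal_attention(45.0, coarse_grid, w_v=0.0)
    np.testing.assert_array_equal(f0["right"], 1.0)


def test_negative_gain_rejected(coarse_grid):
    comps = expand_condition(Condition("small", 0.1, "right"))
    with pytest.raises(ValueError, match="non-negative"):
        stimulus_attention_fs(comps, coarse_grid, w_x=9.0, p=0.0)
    with pytest.raises(ValueError, match="non-negative"):
        stimulus_attention_es(comps, coarse_grid, w_x=9.0, p=0.0)
    with pytest.raises(ValueError, match="non-negative"):
        goal_attention(45.0, coarse_grid, w_v=9.0)


def test_fs_split_equals_large_exactly(coarse_grid):
    split = stimulus_attention_fs(
        expand_condition(Condition("split", 0.1, "right")), coarse_grid, 4.24, 0.13
    )
    large = stimulus_attention_fs(
        expand_condition(Condition("large", 0.1, "right")), coarse_grid, 4.24, 0.13
    )
    assert np.max(np.abs(split["right"] - large["right"])) == 0.0


def test_es_split_weaker_than_large_at_target(coarse_grid):
    """ES at the two-competitor-study parameters (w_x=2.41, p=0.31): the split
    center sits in the other eye, so the target-eye gain reduction at the
    center is partly cancelled by the same-eye surround."""
    es_split = stimulus_attention_es(
        expand_condition(Condition("split", 0.1, "right")), coarse_grid, 2.41, 0.31
    )
    es_large = stimulus_attention_es(
        expand_condition(Condition("large", 0.1, "right")), coarse_grid, 2.41, 0.31
    )
    assert _gain_at_target(es_split, coarse_grid) > _gain_at_target(es_large, coarse_grid)


def test_gain_baseline_far_from_attended_site(coarse_grid):
    """Stimulus-driven gains return to 1 beyond 5 sigma of the attended site."""
    comps = expand_condition(Condition("small", 0.1, "right"))
    for fn, w in ((stimulus_attention_fs, 4.24), (stimulus_attention_es, 2.46)):
        f = fn(comps, coarse_grid, w, 0.13)
        far = np.abs(coarse_grid.x) > 5 * 1.5
        for eye in ("left", "right"):
            assert np.max(np.abs(f[eye][far, :] - 1.0)) < 1e-6


# ---------------------------------------------------------------------------
# suppression kernel and suppressive drive
# ---------------------------------------------------------------------------

def test_suppression_width_values():
    assert suppression_width(0.0) == pytest.approx(6.0)
    assert suppression_width(20.0) == pytest.approx(6.0 * np.exp(-1.0))
    assert suppression_width(-20.0) == pytest.approx(6.0 * np.exp(-1.0))


def test_kernel_rows_integrate_like_the_continuous_kernel(tiny_grid):
    """Each orientation-offset row of the (cell-averaged) kernel has unit peak
    where the suppressive field is wide, and integrates to sqrt(2 pi) sigma
    (the exact Gaussian volume) at every offset."""
    K = suppression_kernel(tiny_grid, normalize=False)
    nx = tiny_grid.x.size
    offs = np.sort(wrap_orientation(tiny_grid.theta))
    wide = np.abs(offs) <= 20  # sigma(dtheta) >= 2.2 deg >> dx
    np.testing.assert_allclose(K[nx - 1, wide], 1.0, atol=0.01)
    row_sums = K.sum(axis=0) * tiny_grid.dx
    # rows whose Gaussian fits inside the tiny grid's +-10 deg offset range
    narrow = np.abs(offs) >= 20
    np.testing.assert_allclose(
        row_sums[narrow], np.sqrt(2 * np.pi) * suppression_width(offs[narrow]),
        rtol=1e-4,
    )


def test_kernel_normalization(tiny_grid):
    K = suppression_kernel(tiny_grid, normalize=True)
    assert K.sum() * tiny_grid.cell_area == pytest.approx(1.0)


def test_suppressive_drive_zero_input(tiny_grid):
    z = np.zeros(tiny_grid.shape)
    K = suppression_kernel(tiny_grid)
    S = suppressive_drive(z, np.ones_like(z), np.ones_like(z), K, tiny_grid)
    np.testing.assert_array_equal(S, 0.0)


def test_suppressive_drive_delta_kernel_is_identity(tiny_grid):
    rng = np.random.default_rng(3)
    E = rng.random(tiny_grid.shape)
    ax = 1 + rng.random(tiny_grid.shape)
    av = 1 + rng.random(tiny_grid.shape)
    nx, nt = tiny_grid.shape
    delta = np.zeros((2 * nx - 1, nt))
    j0 = np.argmin(np.abs(np.sort(wrap_orientation(tiny_grid.theta))))
    delta[nx - 1, j0] = 1.0 / tiny_grid.cell_area
    S = suppressive_drive(E, ax, av, delta, tiny_grid)
    np.testing.assert_allclose(S, ax * av * E, rtol=1e-10, atol=1e-12)


def test_suppressive_drive_matches_brute_force(tiny_grid):
    rng = np.random.default_rng(11)
    E = rng.random(tiny_grid.shape)
    ax = 0.5 + rng.random(tiny_grid.shape)
    av = 0.5 + rng.random(tiny_grid.shape)
    K = suppression_kernel(tiny_grid)
    fast = suppressive_drive(E, ax, av, K, tiny_grid)
    slow = _brute_force_suppressive_drive(E, ax, av, K, tiny_grid)
    assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-10


def test_suppressive_drive_shape_mismatch(tiny_grid):
    K = suppression_kernel(tiny_grid)
    bad = np.zeros((3, 3))
    with pytest.raises(ValueError, match="shape"):
        suppressive_drive(bad, bad, bad, K, tiny_grid)


# ---------------------------------------------------------------------------
# responses and d'
# ---------------------------------------------------------------------------

def test_zero_contrast_means_zero_response(coarse_grid):
    comps = expand_condition(Condition("none", 0.0, "right"))
    e = excitatory_drive(comps, coarse_grid)
    ax, av = attention_fields(comps, coarse_grid, FS_GROUP_PARAMS, "fs", 45.0)
    resp = population_response(e, ax, av, FS_GROUP_PARAMS, coarse_grid)
    assert np.all(resp["right"] == 0.0)
    assert predict_dprime(resp, comps[0], FS_GROUP_PARAMS, coarse_grid) == 0.0


def test_response_monotone_saturating_in_contrast(coarse_grid):
    """With unit gains and one monocular patch, the matched neuron's response
    rises monotonically with contrast and saturates (hyperbolic-ratio-like)."""
    params = ModelParams(n=2.0, sigma=0.002, w_I=0.5, w_x=0.0, w_v=0.0, p=0.0, sigma_n=1.0)
    pred = PsychometricPredictor([("none", "right")], np.geomspace(1e-3, 0.9, 12),
                                 grid=coarse_grid)
    d = pred.dprime(params)[0]
    assert np.all(np.diff(d) > 0)
    # saturation: the last doubling of contrast barely moves the response
    assert (d[-1] - d[-2]) / d[-1] < 0.02


def test_interocular_weight_zero_isolates_attention_path(coarse_grid):
    """With w_I = 0 and all attention weights 0, the competitor cannot affect
    the target response at all."""
    params = ModelParams(n=2.0, sigma=0.002, w_I=0.0, w_x=0.0, w_v=0.0, p=0.0, sigma_n=1.0)
    contrasts = default_contrasts()
    pred = PsychometricPredictor([("none", "right"), ("large", "right")], contrasts,
                                 grid=coarse_grid)
    d = pred.dprime(params)
    np.testing.assert_allclose(d[0], d[1], rtol=1e-12)


def test_point_predictor_matches_field_engine(coarse_grid):
    contrasts = default_contrasts()[::3]
    for variant in ("fs", "es"):
        params = FS_GROUP_PARAMS if variant == "fs" else ModelParams(
            n=1.85, sigma=0.0016, w_I=1.08, w_x=2.46, w_v=4.90, p=0.71, sigma_n=2.82
        )
        a = predict_psychometric(params, variant, CONDS, contrasts, grid=coarse_grid,
                                 engine="point")
        b = predict_psychometric(params, variant, CONDS, contrasts, grid=coarse_grid,
                                 engine="field")
        np.testing.assert_allclose(a.dprime.values, b.dprime.values, atol=1e-12)


def test_eye_swap_symmetry_exact(coarse_grid):
    """Mirroring eye labels and swapping the directional weights swaps the
    predicted psychometric functions exactly."""
    params = ModelParams(n=2.0, sigma=0.002, w_I=0.0, w_LR=0.3, w_RL=1.7,
                         w_x=3.0, w_v=4.0, p=0.2, sigma_n=3.0)
    contrasts = default_contrasts()[::2]
    right = predict_psychometric(params, "fs", CONDS, contrasts, grid=coarse_grid,
                                 target_eye="right")
    left = predict_psychometric(params.swap_directional(), "fs", CONDS, contrasts,
                                grid=coarse_grid, target_eye="left")
    np.testing.assert_array_equal(right.dprime.values, left.dprime.values)


def test_responses_nonnegative(coarse_grid):
    for cond in CONDS:
        comps = expand_condition(Condition(cond, 0.2, "right"))
        e = excitatory_drive(comps, coarse_grid)
        ax, av = attention_fields(comps, coarse_grid, FS_GROUP_PARAMS, "fs", 45.0)
        resp = population_response(e, ax, av, FS_GROUP_PARAMS, coarse_grid)
        assert resp["left"].min() >= 0 and resp["right"].min() >= 0


def test_grid_convergence_of_dprime():
    """Halving the RF-center step changes predicted d' by well under 1 %."""
    contrasts = default_contrasts()[::2]
    d = {}
    for dx in (0.5, 0.25):
        g = NeuronGrid(dx=dx, dtheta=3.0)
        pred = PsychometricPredictor([(c, "right") for c in CONDS], contrasts, grid=g)
        d[dx] = pred.dprime(FS_GROUP_PARAMS)
    rel = np.abs(d[0.5] - d[0.25]) / np.abs(d[0.25])
    assert rel.max() < 0.01


def test_all_attention_weights_zero_collapses_dichoptic_conditions(coarse_grid):
    """With w_x = w_v = w_I = 0 a competitor confined to the other eye has no
    pathway to the target response, so none/small/medium/large coincide.  The
    split surround shares the target eye, so its same-eye normalization still
    suppresses the target."""
    params = ModelParams(n=2.0, sigma=0.002, w_I=0.0, w_x=0.0, w_v=0.0, p=0.0,
                         sigma_n=2.0)
    pred = PsychometricPredictor([(c, "right") for c in CONDS],
                                 default_contrasts(), grid=coarse_grid)
    d = pred.dprime(params)
    for i in (1, 2, 3):
        np.testing.assert_allclose(d[i], d[0], rtol=1e-12)
    assert np.all(d[4] < d[0])
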