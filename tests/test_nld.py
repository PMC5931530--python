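"""Nonlinear measures against brute-force oracles and known dynamics."""

import numpy as np
import pytest

from eegnld import nld

from oracles import rqa_naive, sampen_naive

RQA_KEYS = ("RR", "DET", "LAM", "L_max", "L_entr", "L_mean", "TT")


def result_dict(res: nld.RQAResult) -> dict:
    return dict(zip(RQA_KEYS, res.as_tuple()))


# ---------------------------------------------------------------------------
# embedding / recurrence plot

def test_embed_enumerates_delay_vectors():
    e = nld.embed(np.array([1.0, 2, 3, 4]), dim=2, tau=1)
    assert e.points.tolist() == [[1, 2], [2, 3], [3, 4]]


def test_embed_dim_one_is_identity():
    x = np.arange(10.0)
    e = nld.embed(x, dim=1, tau=3)
    assert np.array_equal(e.points[:, 0], x)


def test_embed_point_count_formula():
    x = np.zeros(7500)
    assert nld.embed(x, dim=3, tau=2).points.shape == (7496, 3)
    with pytest.raises(ValueError):
        nld.embed(np.zeros(4), dim=3, tau=2)


def test_recurrence_matrix_identical_points_all_ones():
    e = nld.EmbeddedSeries(points=np.ones((4, 2)), dim=2, tau=1)
    rp = nld.recurrence_matrix(e, epsilon=0.5)
    assert rp.matrix.all()


def test_recurrence_matrix_separated_clusters_block_diagonal():
    pts = np.vstack([np.zeros((3, 2)), np.full((3, 2), 10.0)])
    rp = nld.recurrence_matrix(nld.EmbeddedSeries(pts, 2, 1), epsilon=1.0)
    assert rp.matrix[:3, :3].all() and rp.matrix[3:, 3:].all()
    assert not rp.matrix[:3, 3:].any()


def test_recurrence_matrix_matches_pairwise_distances():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 3, size=(5, 2))
    rp = nld.recurrence_matrix(nld.EmbeddedSeries(pts, 2, 1), epsilon=1.0)
    for i in range(5):
        for j in range(5):
            d = max(abs(pts[i, 0] - pts[j, 0]), abs(pts[i, 1] - pts[j, 1]))
            assert rp.matrix[i, j] == (d <= 1.0)


def test_rr_weakly_increases_with_epsilon():
    rng = np.random.default_rng(0)
    e = nld.embed(rng.standard_normal(200), dim=3, tau=1)
    last = -1.0
    for eps in [0.05, 0.1, 0.2, 0.5, 1.0, 2.0]:
        rr = nld.rqa_measures(nld.recurrence_matrix(e, eps)).rr
        assert rr >= last
        last = rr


# ---------------------------------------------------------------------------
# RQA statistics

def test_rqa_all_ones_plot():
    rp = nld.RecurrencePlot(np.ones((5, 5), dtype=bool), epsilon=1.0)
    res = nld.rqa_measures(rp, l_min=2, v_min=2)
    oracle = rqa_naive(np.ones((5, 5)))
    assert res.rr == 1.0
    assert res.l_max == 4.0   # longest off-identity diagonal
    # the two corner diagonals are single points, so DET/LAM sit just below 1
    assert res.det == pytest.approx(oracle["DET"]) == pytest.approx(18 / 20)
    assert res.lam == pytest.approx(oracle["LAM"])


def test_rqa_identity_only_plot_is_empty():
    rp = nld.RecurrencePlot(np.eye(6, dtype=bool), epsilon=1.0)
    res = nld.rqa_measures(rp)
    assert (res.rr, res.det, res.lam) == (0.0, 0.0, 0.0)


def test_rqa_handwritten_matrix_matches_oracle():
    m = np.array([
        [1, 1, 0, 0, 1, 0, 0, 1],
        [1, 1, 1, 0, 0, 1, 0, 0],
        [0, 1, 1, 1, 0, 0, 1, 0],
        [0, 0, 1, 1, 0, 0, 0, 1],
        [1, 0, 0, 0, 1, 1, 0, 0],
        [0, 1, 0, 0, 1, 1, 1, 0],
        [0, 0, 1, 0, 0, 1, 1, 1],
        [1, 0, 0, 1, 0, 0, 1, 1],
    ], dtype=bool)
    res = result_dict(nld.rqa_measures(nld.RecurrencePlot(m, 1.0)))
    oracle = rqa_naive(m)
    for key in RQA_KEYS:
        assert res[key] == pytest.approx(oracle[key], abs=1e-12), key


@pytest.mark.parametrize("seed", range(10))
def test_rqa_random_matrices_match_oracle(seed):
    rng = np.random.default_rng(seed)
    raw = rng.random((20, 20)) < 0.3
    m = raw | raw.T
    np.fill_diagonal(m, True)
    res = result_dict(nld.rqa_measures(nld.RecurrencePlot(m, 1.0)))
    oracle = rqa_naive(m)
    for key in RQA_KEYS:
        assert res[key] == pytest.approx(oracle[key], abs=1e-10), key


@pytest.mark.parametrize("seed", range(5))
def test_streaming_rqa_equals_matrix_path(seed):
    """The matrix-free numba path must agree exactly with the explicit plot."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(150)
    res_fast = nld.rqa_from_series(x, dim=3, tau=1, epsilon_sd=0.3)
    e = nld.embed(x, 3, 1)
    rp = nld.recurrence_matrix(e, epsilon=0.3 * x.std())
    res_mat = nld.rqa_measures(rp)
    for a, b in zip(res_fast.as_tuple(), res_mat.as_tuple()):
        assert a == pytest.approx(b, abs=1e-12)


def test_rqa_measures_respect_ranges():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.standard_normal(120)
        res = nld.rqa_from_series(x)
        assert 0 <= res.rr <= 1 and 0 <= res.det <= 1 and 0 <= res.lam <= 1
        assert res.l_entr >= 0
        if res.l_mean:
            assert res.l_mean >= 2
        if res.tt:
            assert res.tt >= 2


# ---------------------------------------------------------------------------
# sample entropy

def test_sampen_periodic_series_is_zero():
    x = np.tile([0.0, 1.0], 50)   # period 2 <= m
    assert nld.sample_entropy(x, m=2, r=0.2) == 0.0


def test_sampen_constant_series_absolute_tolerance():
    x = np.full(50, 3.0)
    assert nld.sample_entropy(x, m=2, r_absolute=0.5) == 0.0


def test_sampen_constant_series_sd_tolerance_is_sentinel():
    assert np.isnan(nld.sample_entropy(np.full(50, 3.0), m=2, r=0.2))


def test_sampen_noise_exceeds_sine():
    rng = np.random.default_rng(2)
    noise = rng.standard_normal(7500)
    t = np.arange(7500)
    sine = np.sin(2 * np.pi * t / 25)
    sine *= noise.std() / sine.std()
    assert nld.sample_entropy(noise) > nld.sample_entropy(sine)


@pytest.mark.parametrize("n,m,r", [(200, 2, 0.2), (300, 3, 0.15), (500, 2, 0.25)])
def test_sampen_matches_naive_oracle(n, m, r):
    rng = np.random.default_rng(n)
    x = rng.standard_normal(n)
    expected = sampen_naive(x, m, r * x.std())
    assert nld.sample_entropy(x, m=m, r=r) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# DFA

def test_dfa_white_noise_near_half():
    vals = [nld.dfa(np.random.default_rng(s).standard_normal(7500))
            for s in range(10)]
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_dfa_random_walk_near_three_halves():
    vals = [nld.dfa(np.cumsum(np.random.default_rng(s).standard_normal(7500)))
            for s in range(10)]
    assert abs(np.mean(vals) - 1.5) < 0.1


def test_dfa_needs_enough_box_sizes():
    with pytest.raises(ValueError):
        nld.dfa(np.random.default_rng(0).standard_normal(100), box_sizes=[64])


# ---------------------------------------------------------------------------
# per-band bundle

def test_channel_band_measures_returns_nine_canonical():
    rng = np.random.default_rng(0)
    ms = nld.channel_band_measures(rng.standard_normal(1500))
    assert ms.names == nld.MEASURE_NAMES
    assert ms.values.shape == (9,)
    assert np.isfinite(ms.values).all()


def test_sine_more_deterministic_than_noise():
    t = np.arange(2000)
    sine = np.sin(2 * np.pi * t / 20)
    noise = np.random.default_rng(4).standard_normal(2000)
    det_sine = nld.channel_band_measures(sine).as_dict()["DET"]
    det_noise = nld.channel_band_measures(noise).as_dict()["DET"]
    assert det_sine > 0.9
    assert det_noise < det_sine


def test_constant_band_is_fully_degenerate():
    ms = nld.channel_band_measures(np.zeros(1500))
    assert np.isnan(ms.values).all()
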