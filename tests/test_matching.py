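"""Dot-product MRF matching and map comparison."""

import numpy as np
import pytest

from cestgen.dictionary import Dictionary
from cestgen.matching import (
    DotProductMatcher,
    ImageSeries,
    QuantMaps,
    compare_maps,
    dot_product_match,
    match_trajectories,
)
from cestgen.presets import load_preset


@pytest.fixture(scope="module")
def toy_dictionary():
    preset = load_preset("l-arginine", 9.4)
    params, _, _ = preset.sample_parameters(64, seed=11, vary_schedule=False)
    rng = np.random.default_rng(11)
    signals = rng.uniform(0.05, 0.95, (64, 30))
    return Dictionary(params=params, signals=signals,
                      b1_ut=preset.b1_series_ut,
                      offset_ppm=preset.offset_series_ppm,
                      preset_name="l-arginine")


def test_self_match_returns_own_row_with_unit_score(toy_dictionary):
    idx, score = match_trajectories(toy_dictionary.signals,
                                    toy_dictionary.signals)
    assert np.array_equal(idx, np.arange(64))
    assert np.allclose(score, 1.0)


def test_match_invariant_to_positive_scaling(toy_dictionary):
    q = toy_dictionary.signals[:10]
    i1, s1 = match_trajectories(q, toy_dictionary.signals)
    i2, s2 = match_trajectories(3.0 * q, toy_dictionary.signals)
    assert np.array_equal(i1, i2)
    assert np.allclose(s1, s2)


def test_tie_breaks_to_lowest_row_index(toy_dictionary):
    signals = toy_dictionary.signals.copy()
    signals[40] = signals[7]  # exact duplicate later in the dictionary
    idx, _ = match_trajectories(signals[[40]], signals)
    assert idx[0] == 7


def test_chunk_size_invariance(toy_dictionary):
    q = toy_dictionary.signals[::3] * 2.0
    ref = match_trajectories(q, toy_dictionary.signals, chunk_size=10**6)
    for chunk in (1, 7, 64):
        out = match_trajectories(q, toy_dictionary.signals, chunk_size=chunk)
        assert np.array_equal(out[0], ref[0])
        assert np.allclose(out[1], ref[1])


def test_zero_trajectory_gets_nan_maps_and_zero_score(toy_dictionary):
    data = np.zeros((30, 4, 4))
    data[:, 0, 0] = toy_dictionary.signals[5]
    series = ImageSeries(data=data)
    maps = dot_product_match(series, toy_dictionary)
    assert maps.index[0, 0] == 5
    assert maps.score[0, 0] == pytest.approx(1.0)
    assert maps.score[2, 2] == 0.0
    assert maps.index[2, 2] == -1
    assert np.isnan(maps.maps["solute.k_sw"][2, 2])


def test_matcher_rejects_length_mismatch(toy_dictionary):
    series = ImageSeries(data=np.zeros((12, 4, 4)))
    with pytest.raises(ValueError):
        dot_product_match(series, toy_dictionary)


def test_matcher_estimator_api(toy_dictionary):
    m = DotProductMatcher(chunk_size=16)
    assert m.get_params()["chunk_size"] == 16
    fitted = m.fit(toy_dictionary)
    out = fitted.predict(toy_dictionary.signals[:5])
    assert out["match_index"].tolist() == [0, 1, 2, 3, 4]


def test_dictionary_row_order_invariance(toy_dictionary):
    perm = np.random.default_rng(0).permutation(64)
    shuffled = toy_dictionary.subset(perm)
    q = toy_dictionary.signals[:20]
    p1 = DotProductMatcher().fit(toy_dictionary).predict(q)
    p2 = DotProductMatcher().fit(shuffled).predict(q)
    assert np.allclose(p1["solute.k_sw"], p2["solute.k_sw"])


# ---------------------------------------------------------------------------
# map comparison


def _maps_from(arrays, mask):
    return QuantMaps(
        maps=dict(arrays), score=np.ones(mask.shape), index=np.zeros(mask.shape,
                                                                     int),
        mask=mask,
    )


def test_identical_maps_perfect_metrics():
    rng = np.random.default_rng(1)
    mask = np.ones((16, 16), bool)
    a = _maps_from({"k": rng.uniform(100, 1000, (16, 16))}, mask)
    out = compare_maps(a, a)
    row = out.iloc[0]
    assert row["nrmse"] == 0.0
    assert row["ssim"] == pytest.approx(1.0)
    assert row["pearson_r"] == pytest.approx(1.0)


def test_checkerboard_vs_inverse_has_low_ssim_matching_direct_formula():
    mask = np.ones((16, 16), bool)
    board = np.indices((16, 16)).sum(0) % 2 * 1.0
    a = _maps_from({"k": board}, mask)
    b = _maps_from({"k": 1.0 - board}, mask)
    out = compare_maps(a, b).iloc[0]
    assert out["ssim"] < 0.2
    # direct SSIM recomputation (global statistics formula on one window
    # equals skimage with a window covering the image)
    from skimage.metrics import structural_similarity

    ref = structural_similarity(board, 1.0 - board, data_range=1.0)
    assert out["ssim"] == pytest.approx(ref)
    # and the means/covariance give the expected global SSIM sign
    cov = np.cov(board.ravel(), 1.0 - board.ravel())[0, 1]
    assert cov < 0


def test_empty_mask_rejected():
    mask = np.zeros((4, 4), bool)
    a = _maps_from({"k": np.zeros((4, 4))}, mask)
    with pytest.raises(ValueError):
        compare_maps(a, a)


def test_nifti_round_trip(tmp_path, toy_dictionary):
    series = ImageSeries(data=np.random.default_rng(3).uniform(
        0, 1, (30, 8, 8)))
    path = tmp_path / "series.nii.gz"
    series.to_nifti(path)
    back = ImageSeries.from_nifti(path)
    assert np.allclose(back.data, series.data)
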