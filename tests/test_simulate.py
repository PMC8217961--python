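"""Fiber simulator: rendering, degradation kernels, white noise, and the
calibration design bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fiberaniso import (ANGLE_RANGES, FiberSimConfig, NoiseConfig,
                        add_white_noise, calibration_manifest,
                        generate_calibration_set, simulate_fiber_image,
                        white_noise_image)
from fiberaniso.simulate import (degrade, motion_kernel, pillbox_kernel,
                                 render_fibers, sample_fibers)

from conftest import small_sim_config


def test_angle_ranges_design():
    assert len(ANGLE_RANGES) == 19
    assert ANGLE_RANGES[0] == (90, 90)
    assert ANGLE_RANGES[1] == (85, 95)
    assert ANGLE_RANGES[-1] == (0, 180)
    widths = [hi - lo for lo, hi in ANGLE_RANGES]
    assert widths == list(range(0, 190, 10))


def test_kernels_sum_to_one():
    assert pillbox_kernel(3).sum() == pytest.approx(1.0, abs=1e-15)
    for angle in (0.0, 17.3, 45.0, 90.0, 133.0):
        assert motion_kernel(5, angle).sum() == pytest.approx(1.0, abs=1e-15)
    assert (pillbox_kernel(3) >= 0).all()


def test_impulse_through_pillbox_reproduces_kernel():
    cfg = small_sim_config(motion_len_px=1)  # blur stage only
    impulse = np.zeros((64, 64))
    impulse[32, 32] = 1.0
    out = degrade(impulse, cfg)
    k = pillbox_kernel(3)
    np.testing.assert_allclose(out[29:36, 29:36], k, atol=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_constant_image_unchanged_by_degradation():
    cfg = small_sim_config()
    const = np.full((64, 64), 5.0)
    np.testing.assert_allclose(degrade(const, cfg, motion_angle_deg=30.0),
                               const, atol=1e-12)


def test_step_edge_widening_matches_convolution_oracle():
    """10–90% edge width after the pillbox stage equals the width of the
    explicitly convolved step."""
    cfg = small_sim_config(motion_len_px=1)
    step = np.zeros((48, 48))
    step[:, 24:] = 1.0
    out = degrade(step, cfg)
    k = pillbox_kernel(3)
    r = 3
    padded = np.pad(step, r, mode="reflect")
    oracle = np.zeros_like(step)
    for i in range(step.shape[0]):       # direct double-loop convolution
        for j in range(step.shape[1]):
            oracle[i, j] = np.sum(k * padded[i:i + 2 * r + 1,
                                             j:j + 2 * r + 1])
    np.testing.assert_allclose(out, oracle, atol=1e-12)

    def width_10_90(profile):
        cols = np.arange(profile.size)
        return (np.interp(0.9, profile, cols) - np.interp(0.1, profile, cols))

    assert width_10_90(out[24]) == pytest.approx(width_10_90(oracle[24]))
    assert width_10_90(out[24]) > width_10_90(step[24])


def test_no_fibers_gives_uniform_background():
    img = simulate_fiber_image(small_sim_config(n_fibers=0, background=7.0))
    np.testing.assert_allclose(img.pixels, 7.0, atol=1e-12)


def test_same_seed_is_bit_identical():
    cfg = small_sim_config(seed=99)
    a = simulate_fiber_image(cfg)
    b = simulate_fiber_image(cfg)
    assert np.array_equal(a.pixels, b.pixels)


def test_rendered_fiber_count_and_overlap_by_maximum():
    cfg = small_sim_config(n_fibers=2, foreground=200.0)
    fibers = pd.DataFrame({
        "angle_deg": [90.0, 0.0], "length_um": [40.0, 40.0],
        "center_row": [128.0, 128.0], "center_col": [128.0, 128.0],
    })
    img = render_fibers(fibers, cfg)
    assert img.max() == pytest.approx(200.0)   # crossing composites by max


def test_fiber_angles_pass_uniformity_check():
    """KS goodness of fit of 1000 simulated fiber angles vs U(30, 150)."""
    cfg = FiberSimConfig(n_fibers=1000, angle_range_deg=(30, 150), seed=21)
    rng = np.random.default_rng(cfg.seed)
    angles = sample_fibers(cfg, rng)["angle_deg"].to_numpy()
    res = scipy.stats.kstest(angles, scipy.stats.uniform(30, 120).cdf)
    assert res.pvalue > 0.01


def test_white_noise_levels():
    img = simulate_fiber_image(small_sim_config(seed=5))
    assert add_white_noise(img, NoiseConfig(multiple=0)) is img
    noisy = add_white_noise(img, NoiseConfig(multiple=20, seed=8))
    mu = img.pixels.mean()
    assert noisy.pixels.mean() == pytest.approx(21 * mu, rel=0.01)
    assert noisy.pixels.min() >= 0
    zero = simulate_fiber_image(small_sim_config(n_fibers=0))
    with pytest.raises(ValueError, match="mean"):
        add_white_noise(zero, NoiseConfig(multiple=2))


def test_white_noise_image_mean_and_determinism():
    a = white_noise_image(100.0, (64, 64), seed=4)
    b = white_noise_image(100.0, (64, 64), seed=4)
    assert np.array_equal(a.pixels, b.pixels)
    assert a.pixels.mean() == pytest.approx(100.0, rel=0.05)


def test_manifest_counts_and_determinism():
    imgs, fibers = calibration_manifest(diameters_um=(4.0,),
                                        angle_ranges=[(85, 95), (0, 180)],
                                        n_per_cell=3, seed=7)
    assert len(imgs) == 6
    assert len(fibers) == 6 * 50
    imgs2, fibers2 = calibration_manifest(diameters_um=(4.0,),
                                          angle_ranges=[(85, 95), (0, 180)],
                                          n_per_cell=3, seed=7)
    pd.testing.assert_frame_equal(imgs, imgs2)
    pd.testing.assert_frame_equal(fibers, fibers2)
    assert (imgs["seed"] < 2 ** 31).all()


def test_generate_calibration_set_writes_and_refuses_overwrite(tmp_path):
    base = small_sim_config(image_px=64, fov_um=22.5, n_fibers=5)
    out = tmp_path / "calib"
    manifest = generate_calibration_set(
        out, diameters_um=(4.0,), angle_ranges=[(60, 120)], n_per_cell=2,
        seed=3, base_config=base)
    assert len(manifest) == 2
    assert sorted(p.name for p in out.glob("*.tif")) == \
        sorted(f"{i}.tif" for i in manifest["image_id"])
    assert (out / "manifest.csv").exists() and (out / "fibers.csv").exists()
    with pytest.raises(FileExistsError):
        generate_calibration_set(out, diameters_um=(4.0,),
                                 angle_ranges=[(60, 120)], n_per_cell=2,
                                 seed=3, base_config=base)
    # force=True regenerates deterministically
    again = generate_calibration_set(out, diameters_um=(4.0,),
                                     angle_ranges=[(60, 120)], n_per_cell=2,
                                     seed=3, base_config=base, force=True)
    pd.testing.assert_frame_equal(manifest, again)


def test_config_validation():
    with pytest.raises(ValueError):
        FiberSimConfig(angle_range_deg=(100, 90))
    with pytest.raises(ValueError):
        FiberSimConfig(angle_range_deg=(-5, 90))
    with pytest.raises(ValueError):
        FiberSimConfig(diameter_um=0)
    with pytest.raises(ValueError):
        NoiseConfig(multiple=-1)
    assert FiberSimConfig(angle_range_deg=(45, 45)).angle_range_deg == (45, 45)


def test_ground_truth_recovery_mode_perpendicular(aligned_image):
    """For near-vertical fibers ([85°, 95°]) the modal WTMM angle bin sits
    at the perpendicular (0 or ±π) within one 5° bin."""
    from fiberaniso import WaveletConfig, detect_maxima
    from fiberaniso.anisotropy import angle_pdf
    from fiberaniso.wavelet import cwt_px

    cfg = WaveletConfig(scales_px=(7.0,))
    mx = detect_maxima(cwt_px(aligned_image.pixels, 7.0, cfg), cfg)
    pdf = angle_pdf(mx, 72)
    centers = (pdf.bin_edges[:-1] + pdf.bin_edges[1:]) / 2
    mode = centers[np.argmax(pdf.density)]
    dev_from_perp = min(abs(mode), abs(abs(mode) - math.pi))
    assert dev_from_perp <= 2 * np.pi / 72  # within one bin of 0 or ±π
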