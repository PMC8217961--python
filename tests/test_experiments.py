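"""Experiment drivers: plumbing, determinism, cohort analysis, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fiberaniso import (AnisotropyProfile, WaveletConfig, analyze_cohorts,
                        run_calibration, run_noise_experiment,
                        simulate_fiber_image)
from fiberaniso.cli import main as cli_main

from conftest import small_sim_config

SMALL_RANGES = [(90, 90), (60, 120), (0, 180)]


@pytest.fixture(scope="module")
def small_calibration(tmp_path_factory):
    out = tmp_path_factory.mktemp("calib_out")
    res = run_calibration(diameters_um=(4.0,), angle_ranges=SMALL_RANGES,
                          n_per_group=3, scales_px=(7.0,), seed=9,
                          base_config=small_sim_config(),
                          out_dir=out)
    return res, out


def test_calibration_outputs_complete(small_calibration):
    res, out = small_calibration
    assert len(res.scores) == 3 * 3  # groups x reps x 1 scale
    assert set(res.discrimination["method"]) == {"wavelet", "fourier"}
    assert (res.discrimination["n_pairs"] == 2).all()
    assert len(res.summaries) == 3
    # every emitted file is readable and row-complete
    assert len(pd.read_csv(out / "scores.csv")) == 9
    assert len(pd.read_csv(out / "mean_pdfs.csv")) == 3 * 72
    assert (out / "discrimination.csv").exists()
    assert (out / "fourier_summaries.csv").exists()


def test_calibration_is_deterministic(small_calibration):
    res, _ = small_calibration
    res2 = run_calibration(diameters_um=(4.0,), angle_ranges=SMALL_RANGES,
                           n_per_group=3, scales_px=(7.0,), seed=9,
                           base_config=small_sim_config())
    pd.testing.assert_frame_equal(res.scores, res2.scores)
    pd.testing.assert_frame_equal(res.discrimination, res2.discrimination)


def test_calibration_fa_ordering(small_calibration):
    """Alignment separates even at 3 images/group for extreme ranges."""
    res, _ = small_calibration
    med = res.summaries.set_index("theta_min")["median_fa"]
    assert med[90] > med[60] > med[0]


def test_noise_experiment_structure():
    res = run_noise_experiment(n_per_group=3, noise_multiples=(1, 20),
                               scales_px=(7.0, 14.0), seed=11,
                               base_config=small_sim_config())
    groups = list(res.scores["group"].cat.categories)
    assert groups == ["clean", "noise1x", "noise20x", "whitenoise"]
    piv = res.summaries.pivot(index="group", columns="scale_um",
                              values="median_fa")
    # fibers beat pure noise at every scale; clean beats heavy noise
    assert (piv.loc["clean"] > piv.loc["whitenoise"]).all()
    assert (piv.loc["clean"] >= piv.loc["noise20x"]).all()
    assert res.comparison.label_b == "whitenoise"
    assert 0 <= res.comparison.p_value <= 1


def _profile(scales, fa, label):
    return AnisotropyProfile(scales_um=np.asarray(scales, float),
                             fa=np.asarray(fa, float), label=label)


def test_analyze_cohorts_control_vs_itself():
    imgs = [simulate_fiber_image(small_sim_config(seed=s))
            for s in (1, 2, 3)]
    cfg = WaveletConfig(scales_px=(7.0, 14.0))
    res = analyze_cohorts({"ctrl": imgs, "same": list(imgs)}, "ctrl", cfg)
    np.testing.assert_allclose(res.normalized["same"].fa, 1.0, rtol=1e-12)
    assert (res.comparisons["p_value"] == 1.0).all()
    assert res.crossovers.empty


def test_analyze_cohorts_crossover_detection():
    """Two hand-built monotone profile families crossing at a known scale
    are flagged within one ladder step."""
    scales = [2.5, 5.0, 10.0, 20.0, 40.0]
    ctrl = [_profile(scales, [0.5] * 5, f"c{i}") for i in range(3)]
    # rising cohort crosses falling cohort between 5 and 10 um
    rising = [_profile(scales, np.array([0.2, 0.3, 0.6, 0.8, 0.9]) + 0.01 * i,
                       f"r{i}") for i in range(3)]
    falling = [_profile(scales, np.array([0.9, 0.8, 0.4, 0.3, 0.2]) + 0.01 * i,
                        f"f{i}") for i in range(3)]
    res = analyze_cohorts({"ctrl": ctrl, "rise": rising, "fall": falling},
                          "ctrl")
    cross = res.crossovers
    assert len(cross) == 1
    assert cross.iloc[0]["scale_um_below"] == 5.0
    assert cross.iloc[0]["scale_um_above"] == 10.0


def test_analyze_cohorts_validation():
    imgs = [simulate_fiber_image(small_sim_config(seed=s)) for s in (1, 2, 3)]
    with pytest.raises(ValueError, match="control"):
        analyze_cohorts({"a": imgs}, "missing")
    with pytest.raises(ValueError, match="fewer than 3"):
        analyze_cohorts({"a": imgs, "b": imgs[:2]}, "a")


def test_cli_simulate_analyze_roundtrip(tmp_path):
    runner = CliRunner()
    sim_dir = tmp_path / "sims"
    r = runner.invoke(cli_main, [
        "simulate", "--out", str(sim_dir), "--seed", "3",
        "--n-per-cell", "2", "--diameters", "4",
        "--config", _tiny_config(tmp_path)])
    assert r.exit_code == 0, r.output
    tifs = list(sim_dir.glob("*.tif"))
    assert len(tifs) == 2 * 19
    out_dir = tmp_path / "scores"
    r = runner.invoke(cli_main, [
        "analyze", "--images", str(sim_dir), "--out", str(out_dir),
        "--scales", "7,14", "--pixel-size-um", "0.3515625"])
    assert r.exit_code == 0, r.output
    scores = pd.read_csv(out_dir / "image_scores.csv")
    assert len(scores) == 2 * 19 * 2
    assert {"image_id", "scale_um", "fa", "r_computed"} <= set(scores.columns)


def _tiny_config(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("image_px: 128\nfov_um: 45\nn_fibers: 8\n")
    return str(cfg)


def test_cli_calibrate_and_compare(tmp_path):
    runner = CliRunner()
    out = tmp_path / "cal"
    r = runner.invoke(cli_main, [
        "calibrate", "--out", str(out), "--seed", "2", "--n-per-group", "3",
        "--diameters", "4", "--scales", "7", "--config",
        _tiny_config(tmp_path)])
    assert r.exit_code == 0, r.output
    disc = pd.read_csv(out / "discrimination.csv")
    assert set(disc["method"]) == {"wavelet", "fourier"}

    sims = tmp_path / "sims2"
    runner.invoke(cli_main, ["simulate", "--out", str(sims), "--seed", "5",
                             "--n-per-cell", "1", "--diameters", "4",
                             "--config", _tiny_config(tmp_path)])
    comp_out = tmp_path / "comp"
    r = runner.invoke(cli_main, [
        "compare", "--out", str(comp_out),
        "--cohort", f"a={sims}", "--cohort", f"b={sims}",
        "--control", "a", "--scales", "7,14",
        "--pixel-size-um", "0.3515625"])
    assert r.exit_code == 0, r.output
    norm = pd.read_csv(comp_out / "cohort_normalized.csv")
    np.testing.assert_allclose(
        norm[norm["cohort"] == "b"]["ratio"], 1.0, rtol=1e-9)
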