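"""Experiment drivers: calibration, sensitivity, noise robustness, cohorts.

Every driver is a pure function of its configuration plus a master seed:
per-image seeds are derived deterministically, so two runs from one master
seed produce identical result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anisotropy import (DEFAULT_N_BINS, AngleDistribution, AnisotropyProfile,
                         angle_pdf, anisotropy_factor, multiscale_profile,
                         normalize_profiles)
from .image import IntensityImage
from .simulate import (ANGLE_RANGES, DIAMETERS_UM, FiberSimConfig,
                       NoiseConfig, _derive_seeds, add_white_noise,
                       simulate_fiber_image, white_noise_image)
from .stats import DiscriminationResult, GroupComparison, compare_groups, \
    discrimination_count
from .wavelet import NAMED_SCALES_PX, WaveletConfig, cwt_px, detect_maxima
from . import fourier

__all__ = ["CalibrationResult", "NoiseResult", "CohortResult",
           "run_calibration", "run_noise_experiment", "analyze_cohorts",
           "image_scores"]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _range_label(tmin, tmax) -> str:
    return f"[{tmin:g},{tmax:g}]"


def image_scores(pixels: np.ndarray, scales_px, wavelet_config: WaveletConfig,
                 n_bins: int = DEFAULT_N_BINS, pixel_size_um: float = 1.0,
                 with_fourier: bool = False):
    """Per-scale (fa, n_maxima, density) plus optional Fourier score for one
    pixel array.  Shared inner loop of all drivers."""
    rows = []
    for s in scales_px:
        resp = cwt_px(pixels, s, wavelet_config, pixel_size_um=pixel_size_um)
        mx = detect_maxima(resp, wavelet_config)
        if len(mx) == 0:
            rows.append((s * pixel_size_um, float("nan"), 0, None))
            continue
        pdf = angle_pdf(mx, n_bins)
        rows.append((s * pixel_size_um, anisotropy_factor(pdf), len(mx),
                     pdf.density))
    r = fourier.r_computed(pixels) if with_fourier else float("nan")
    return rows, r


# --- calibration (Figs. 3 and 5 machinery) -------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Tables from one calibration run.

    scores : one row per image × scale (fa, n_maxima) plus r_computed.
    summaries : per group × scale medians and quartiles of Fa.
    fourier_summaries : per group medians and quartiles of RComputed.
    discrimination : consecutive-pair counts per diameter × scale × method.
    mean_pdfs : cohort-average angle densities per group × scale.
    """

    scores: pd.DataFrame
    summaries: pd.DataFrame
    fourier_summaries: pd.DataFrame
    discrimination: pd.DataFrame
    mean_pdfs: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.summaries.to_csv(out / "group_summaries.csv", index=False)
        self.fourier_summaries.to_csv(out / "fourier_summaries.csv",
                                      index=False)
        self.discrimination.to_csv(out / "discrimination.csv", index=False)
        self.mean_pdfs.to_csv(out / "mean_pdfs.csv", index=False)


def run_calibration(diameters_um=DIAMETERS_UM, angle_ranges=ANGLE_RANGES,
                    n_per_group: int = 100, scales_px=(NAMED_SCALES_PX[0],),
                    seed: int = 0, n_bins: int = DEFAULT_N_BINS,
                    base_config: FiberSimConfig | None = None,
                    wavelet_config: WaveletConfig | None = None,
                    alpha: float = DEFAULT_ALPHA,
                    with_fourier: bool = True,
                    out_dir=None) -> CalibrationResult:
    """Simulate the calibration design and score every image.

    For each diameter and angle range, ``n_per_group`` fiber images are
    generated (seeds derived from ``seed``), the anisotropy factor is
    computed at each requested scale, and the Fourier score per image.
    Consecutive angle-range pairs are then tested per diameter: once per
    scale for the wavelet scores and once for the Fourier scores.
    """
    base = base_config or FiberSimConfig()
    wcfg = wavelet_config or WaveletConfig(scales_px=tuple(sorted(scales_px)))
    px_um = base.pixel_size_um
    n_images = len(diameters_um) * len(angle_ranges) * n_per_group
    seeds = _derive_seeds(seed, n_images)

    rows, pdf_acc = [], {}
    i = 0
    for diam in diameters_um:
        for (tmin, tmax) in angle_ranges:
            for rep in range(n_per_group):
                cfg = replace(base, diameter_um=float(diam),
                              angle_range_deg=(float(tmin), float(tmax)),
                              seed=int(seeds[i]))
                img = simulate_fiber_image(cfg)
                per_scale, r = image_scores(img.pixels, scales_px, wcfg,
                                            n_bins, px_um, with_fourier)
                image_id = f"d{diam:g}_r{tmin:g}-{tmax:g}_{rep:04d}"
                for (s_um, fa, n_mx, dens) in per_scale:
                    rows.append({
                        "image_id": image_id, "diameter_um": diam,
                        "theta_min": tmin, "theta_max": tmax, "rep": rep,
                        "scale_um": s_um, "n_maxima": n_mx, "fa": fa,
                        "r_computed": r,
                    })
                    if dens is not None:
                        key = (diam, tmin, tmax, s_um)
                        acc = pdf_acc.setdefault(key, [np.zeros(n_bins), 0])
                        acc[0] += dens
                        acc[1] += 1
                i += 1
        log.info("calibration: diameter %g um scored", diam)

    scores = pd.DataFrame(rows)
    summaries = (scores.dropna(subset=["fa"])
                 .groupby(["diameter_um", "theta_min", "theta_max",
                           "scale_um"])["fa"]
                 .agg(median_fa="median",
                      q1=lambda x: x.quantile(0.25),
                      q3=lambda x: x.quantile(0.75), n_images="count")
                 .reset_index())
    per_image = scores.drop_duplicates("image_id")
    fourier_summaries = (per_image.dropna(subset=["r_computed"])
                         .groupby(["diameter_um", "theta_min", "theta_max"])
                         ["r_computed"]
                         .agg(median_r="median",
                              q1=lambda x: x.quantile(0.25),
                              q3=lambda x: x.quantile(0.75),
                              n_images="count")
                         .reset_index())

    disc_rows = []
    for diam in diameters_um:
        sub = scores[scores["diameter_um"] == diam]
        for s in sorted(set(sub["scale_um"])):
            groups = [sub[(sub["theta_min"] == tmin) & (sub["scale_um"] == s)]
                      ["fa"].dropna().to_numpy()
                      for (tmin, tmax) in angle_ranges]
            res = discrimination_count(groups, alpha, method="wavelet",
                                       diameter_um=float(diam),
                                       scale_um=float(s),
                                       expected_n_groups=len(angle_ranges))
            disc_rows.append(res)
        if with_fourier:
            subi = per_image[per_image["diameter_um"] == diam]
            groups = [subi[subi["theta_min"] == tmin]
                      ["r_computed"].dropna().to_numpy()
                      for (tmin, tmax) in angle_ranges]
            res = discrimination_count(groups, alpha, method="fourier",
                                       diameter_um=float(diam),
                                       expected_n_groups=len(angle_ranges))
            disc_rows.append(res)
    discrimination = pd.DataFrame([{
        "diameter_um": r.diameter_um, "scale_um": r.scale_um,
        "method": r.method, "n_pairs": r.n_pairs,
        "n_discriminated": r.n_discriminated,
    } for r in disc_rows])

    pdf_rows = []
    centers = (np.arange(n_bins) + 0.5) * (2 * np.pi / n_bins) - np.pi
    for (diam, tmin, tmax, s_um), (dens_sum, n) in pdf_acc.items():
        mean_dens = dens_sum / n
        for c, d in zip(centers, mean_dens, strict=True):
            pdf_rows.append({"diameter_um": diam, "theta_min": tmin,
                             "theta_max": tmax, "scale_um": s_um,
                             "angle_rad": c, "density": d, "n_images": n})
    mean_pdfs = pd.DataFrame(pdf_rows)

    result = CalibrationResult(scores, summaries, fourier_summaries,
                               discrimination, mean_pdfs)
    if out_dir is not None:
        result.write(out_dir)
    return result


# --- noise robustness (Fig. 6 machinery) ---------------------------------

@dataclass(frozen=True)
class NoiseResult:
    """Tables from one noise-robustness run.

    Seven groups: clean fibers, the five noise multiples, pure white noise.
    ``comparison`` is the rank-sum test of the highest noise multiple vs
    the white-noise-only group at the largest scale.
    """

    scores: pd.DataFrame
    summaries: pd.DataFrame
    mean_pdfs: pd.DataFrame
    comparison: GroupComparison

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "noise_scores.csv", index=False)
        self.summaries.to_csv(out / "noise_summaries.csv", index=False)
        self.mean_pdfs.to_csv(out / "noise_mean_pdfs.csv", index=False)
        pd.DataFrame([{
            "group_a": self.comparison.label_a,
            "group_b": self.comparison.label_b,
            "p_value": self.comparison.p_value,
            "significant": self.comparison.significant,
        }]).to_csv(out / "noise_comparison.csv", index=False)


def run_noise_experiment(n_per_group: int = 100,
                         noise_multiples=(1, 2, 5, 10, 20),
                         angle_range=(60.0, 120.0),
                         diameter_um: float = 4.0,
                         scales_px=NAMED_SCALES_PX, seed: int = 0,
                         n_bins: int = DEFAULT_N_BINS,
                         base_config: FiberSimConfig | None = None,
                         wavelet_config: WaveletConfig | None = None,
                         alpha: float = DEFAULT_ALPHA,
                         out_dir=None) -> NoiseResult:
    """Score clean, noise-degraded, and pure-noise groups across scales.

    Each replicate renders one clean fiber image, adds white noise at every
    multiple (independent fields), and generates one matched pure
    white-noise image whose mean equals the clean image mean.
    """
    base = base_config or FiberSimConfig()
    cfg0 = replace(base, diameter_um=float(diameter_um),
                   angle_range_deg=(float(angle_range[0]),
                                    float(angle_range[1])))
    wcfg = wavelet_config or WaveletConfig(scales_px=tuple(sorted(scales_px)))
    px_um = cfg0.pixel_size_um
    multiples = tuple(noise_multiples)
    # one seed per (replicate, variant): fibers + each noise field + pure noise
    seeds = _derive_seeds(seed, n_per_group * (len(multiples) + 2))
    seeds = seeds.reshape(n_per_group, len(multiples) + 2)

    groups = ["clean"] + [f"noise{m:g}x" for m in multiples] + ["whitenoise"]
    rows, pdf_acc = [], {}
    for rep in range(n_per_group):
        cfg = replace(cfg0, seed=int(seeds[rep, 0]))
        clean = simulate_fiber_image(cfg)
        variants = [("clean", clean)]
        for j, m in enumerate(multiples):
            noisy = add_white_noise(clean, NoiseConfig(
                multiple=float(m), seed=int(seeds[rep, 1 + j])))
            variants.append((f"noise{m:g}x", noisy))
        pure = white_noise_image(float(clean.pixels.mean()),
                                 clean.pixels.shape,
                                 seed=int(seeds[rep, -1]),
                                 pixel_size_um=px_um)
        variants.append(("whitenoise", pure))
        for gname, img in variants:
            per_scale, _ = image_scores(img.pixels, scales_px, wcfg,
                                        n_bins, px_um)
            for (s_um, fa, n_mx, dens) in per_scale:
                rows.append({"group": gname, "rep": rep, "scale_um": s_um,
                             "n_maxima": n_mx, "fa": fa})
                if dens is not None:
                    acc = pdf_acc.setdefault((gname, s_um),
                                             [np.zeros(n_bins), 0])
                    acc[0] += dens
                    acc[1] += 1
    scores = pd.DataFrame(rows)
    scores["group"] = pd.Categorical(scores["group"], categories=groups,
                                     ordered=True)
    summaries = (scores.dropna(subset=["fa"])
                 .groupby(["group", "scale_um"], observed=True)["fa"]
                 .agg(median_fa="median",
                      q1=lambda x: x.quantile(0.25),
                      q3=lambda x: x.quantile(0.75), n_images="count")
                 .reset_index())

    largest = max(s * px_um for s in scales_px)
    top = f"noise{multiples[-1]:g}x"
    sel = scores["scale_um"] == largest
    comparison = compare_groups(
        scores[sel & (scores["group"] == top)]["fa"].dropna(),
        scores[sel & (scores["group"] == "whitenoise")]["fa"].dropna(),
        alpha, label_a=top, label_b="whitenoise")

    centers = (np.arange(n_bins) + 0.5) * (2 * np.pi / n_bins) - np.pi
    pdf_rows = []
    for (gname, s_um), (dens_sum, n) in pdf_acc.items():
        for c, d in zip(centers, dens_sum / n, strict=True):
            pdf_rows.append({"group": gname, "scale_um": s_um,
                             "angle_rad": c, "density": d, "n_images": n})
    mean_pdfs = pd.DataFrame(pdf_rows)

    result = NoiseResult(scores, summaries, mean_pdfs, comparison)
    if out_dir is not None:
        result.write(out_dir)
    return result


# --- cohort comparison (tissue-analysis machinery) -----------------------

@dataclass(frozen=True)
class CohortResult:
    """Multiscale cohort comparison against a designated control.

    profiles : per-image anisotropy profiles by cohort label.
    comparisons : all pairwise rank-sum tests per scale.
    normalized : per-cohort (median / control median) ratio profiles.
    crossovers : scale intervals where two cohorts' normalized medians
        swap order (one row per sign change, bracketing ladder steps).
    """

    profiles: dict[str, list[AnisotropyProfile]]
    comparisons: pd.DataFrame
    normalized: dict[str, AnisotropyProfile]
    crossovers: pd.DataFrame
    control: str

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for label, profs in self.profiles.items():
            for j, p in enumerate(profs):
                for s, fa, n in zip(p.scales_um, p.fa,
                                    p.n_maxima if p.n_maxima is not None
                                    else np.full(p.fa.size, -1), strict=True):
                    rows.append({"cohort": label, "image": p.label or j,
                                 "scale_um": s, "fa": fa, "n_maxima": n})
        pd.DataFrame(rows).to_csv(out / "cohort_scores.csv", index=False)
        self.comparisons.to_csv(out / "cohort_comparisons.csv", index=False)
        norm_rows = [{"cohort": lab, "scale_um": s, "ratio": v}
                     for lab, p in self.normalized.items()
                     for s, v in zip(p.scales_um, p.fa, strict=True)]
        pd.DataFrame(norm_rows).to_csv(out / "cohort_normalized.csv",
                                       index=False)
        self.crossovers.to_csv(out / "cohort_crossovers.csv", index=False)


def _median_matrix(profiles: list[AnisotropyProfile]) -> np.ndarray:
    return np.nanmedian(np.vstack([p.fa for p in profiles]), axis=0)


def analyze_cohorts(cohorts: dict[str, list], control: str,
                    wavelet_config: WaveletConfig | None = None,
                    n_bins: int = DEFAULT_N_BINS,
                    alpha: float = DEFAULT_ALPHA,
                    out_dir=None) -> CohortResult:
    """Compare labeled image cohorts across the scale ladder.

    ``cohorts`` maps labels to lists of :class:`IntensityImage` (profiles
    are computed here) or precomputed :class:`AnisotropyProfile`.  Every
    cohort needs at least 3 images.  Produces per-scale pairwise rank-sum
    tests, control-normalised median profiles, and the scale intervals at
    which any two non-control cohorts' normalized medians cross.
    """
    if control not in cohorts:
        raise ValueError(f"control cohort {control!r} not among cohorts")
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    wcfg = wavelet_config or WaveletConfig()
    profiles: dict[str, list[AnisotropyProfile]] = {}
    for label, items in cohorts.items():
        if len(items) < 3:
            raise ValueError(f"cohort {label!r} has fewer than 3 images")
        profs = []
        for j, item in enumerate(items):
            if isinstance(item, AnisotropyProfile):
                profs.append(item)
            elif isinstance(item, IntensityImage):
                profs.append(multiscale_profile(item, wcfg, n_bins,
                                                label=item.label or
                                                f"{label}-{j}"))
            else:
                raise TypeError("cohort items must be IntensityImage or "
                                "AnisotropyProfile")
        profiles[label] = profs

    scales = profiles[control][0].scales_um
    labels = list(profiles)
    comp_rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            fa_a = np.vstack([p.fa for p in profiles[la]])
            fa_b = np.vstack([p.fa for p in profiles[lb]])
            for k, s in enumerate(scales):
                xa = fa_a[:, k]
                xb = fa_b[:, k]
                xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
                if xa.size < 2 or xb.size < 2:
                    continue
                gc = compare_groups(xa, xb, alpha, la, lb)
                comp_rows.append({"label_a": la, "label_b": lb,
                                  "scale_um": s, "p_value": gc.p_value,
                                  "significant": gc.significant})
    comparisons = pd.DataFrame(comp_rows)

    normalized = {label: normalize_profiles(profiles[label],
                                            profiles[control], label=label)
                  for label in labels}

    cross_rows = []
    noncontrol = [l for l in labels if l != control]
    for i, la in enumerate(noncontrol):
        for lb in noncontrol[i + 1:]:
            diff = normalized[la].fa - normalized[lb].fa
            sign = np.sign(diff)
            for k in range(len(scales) - 1):
                if sign[k] != 0 and sign[k + 1] != 0 and \
                        sign[k] != sign[k + 1]:
                    cross_rows.append({"label_a": la, "label_b": lb,
                                       "scale_um_below": scales[k],
                                       "scale_um_above": scales[k + 1]})
    crossovers = pd.DataFrame(cross_rows,
                              columns=["label_a", "label_b",
                                       "scale_um_below", "scale_um_above"])

    result = CohortResult(profiles, comparisons, normalized, crossovers,
                          control)
    if out_dir is not None:
        result.write(out_dir)
    return result
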