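"""Synthetic fruit cohorts for end-to-end testing of the geometry pipeline.

Real studies of this kind digitize hundreds of photographed fruits whose
coordinates are rarely deposited.  This module generates everything the
pipeline consumes — EPE parameter draws per cultivar-like preset, noisy
digitized profiles, rendered silhouette images, and simulated
water-displacement volume readings — with ground truth retained, so every
downstream stage can be scored against known answers.

Noise model
-----------
Digitization error is emulated as a radial perturbation field applied to
the exact curve points: a zero-mean periodic Gaussian process along the
boundary with standard deviation ``radial_noise_frac * a`` and correlation
length ``noise_corr_frac`` of the perimeter (default 0.10).  A traced
boundary is itself a connected curve, so its error is smooth at the scale
of the point spacing; a spatially correlated field reproduces that, and
propagates approximately one-to-one into the fit's RMSE_adj.  Observed
volume is the true solid-of-revolution volume with multiplicative Gaussian
error, rounded to the graduated-cylinder resolution.

All randomness flows through ``numpy.random.default_rng`` (PCG64), seeded
from the cohort spec, so cohorts are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from PIL import Image

from .epe_model import EPEParams, ProfileCoordinates, sample_curve
from .geometry import volume_closed_form
from .profile_pipeline import standardize_points, write_profile_csv

__all__ = [
    "CohortSpec",
    "Cohort",
    "PRESETS",
    "sample_params",
    "generate_profile",
    "simulate_v_obs",
    "render_image",
    "save_silhouette",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cultivar cohort.

    ``b_range`` is the uniform sampling interval (cm) for the half-length;
    ``w_ratio_range`` the uniform interval for the width ratio a/b (kept
    <= 1: the cultivars emulated are prolate, so the caliper-measured
    length is always the longest chord).  The shape coefficients are
    centred Gaussians truncated to valid profiles.  ``radial_noise_frac`` scales
    digitization noise as a fraction of ``a``; ``v_obs_noise_frac`` is the
    multiplicative sd of the water-displacement reading and
    ``v_obs_resolution`` its rounding step in cm^3 (1 cm^3 ~ one
    graduation of a 250 mL cylinder).
    """

    cultivar_label: str
    n_fruits: int
    b_range: tuple
    w_ratio_range: tuple
    c1_sd: float = 0.05
    c2_sd: float = 0.05
    c3_sd: float = 0.03
    radial_noise_frac: float = 0.01
    noise_corr_frac: float = 0.10
    v_obs_noise_frac: float = 0.05
    v_obs_resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise ValueError("n_fruits must be >= 1")
        for lo, hi in (self.b_range, self.w_ratio_range):
            if not (0 < lo <= hi):
                raise ValueError("b_range and w_ratio_range must be positive intervals")
        if self.w_ratio_range[1] > 1.0:
            raise ValueError("w_ratio_range must stay <= 1 (prolate shapes)")
        if min(self.c1_sd, self.c2_sd, self.c3_sd, self.radial_noise_frac,
               self.v_obs_noise_frac, self.v_obs_resolution) < 0:
            raise ValueError("noise parameters must be non-negative")


#: Cultivar-like presets. Sizes put the c=0 volume median/range near the
#: regimes reported for cherry, Qianxi and truss tomatoes (V roughly
#: 5-31 cm^3, median W/L 0.89-0.97); radial noise levels reproduce the
#: observed per-cultivar fit-quality ordering. Convenience defaults, not
#: claims about the true cultivar distributions.
PRESETS = {
    "cherry": CohortSpec(
        cultivar_label="cherry", n_fruits=297,
        b_range=(1.42, 1.87), w_ratio_range=(0.84, 0.96),
        c1_sd=0.05, c2_sd=0.05, c3_sd=0.03,
        radial_noise_frac=0.034, seed=101,
    ),
    "qianxi": CohortSpec(
        cultivar_label="qianxi", n_fruits=320,
        b_range=(1.44, 1.98), w_ratio_range=(0.83, 0.95),
        c1_sd=0.05, c2_sd=0.05, c3_sd=0.03,
        radial_noise_frac=0.048, seed=102,
    ),
    "truss": CohortSpec(
        cultivar_label="truss", n_fruits=300,
        b_range=(1.08, 1.45), w_ratio_range=(0.94, 1.00),
        c1_sd=0.03, c2_sd=0.03, c3_sd=0.02,
        radial_noise_frac=0.026, seed=103,
    ),
}


def sample_params(spec: CohortSpec, rng: np.random.Generator) -> EPEParams:
    """Draw one valid parameter set: b and a/b uniform; c's truncated Gaussian.

    Coefficient draws violating profile validity (modulation polynomial
    not strictly positive) are resampled, at most 100 times.
    """
    b = rng.uniform(*spec.b_range)
    a = b * rng.uniform(*spec.w_ratio_range)
    for _ in range(100):
        c1 = rng.normal(0.0, spec.c1_sd)
        c2 = rng.normal(0.0, spec.c2_sd)
        c3 = rng.normal(0.0, spec.c3_sd)
        params = EPEParams(a, b, c1, c2, c3)
        if params.is_valid():
            return params
    raise RuntimeError(
        f"could not draw valid shape coefficients in 100 tries for {spec}"
    )


def _smooth_periodic_noise(n: int, corr_frac: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Unit-variance periodic Gaussian field of given correlation length."""
    z = rng.normal(0.0, 1.0, n)
    w = max(1, int(round(corr_frac * n)))
    half = 3 * w
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / w) ** 2)
    if len(kern) >= n:  # very long correlation relative to n: coarse fallback
        kern = kern[: n - 1]
        half = (len(kern) - 1) // 2
    padded = np.roll(np.pad(kern, (0, n - len(kern))), -half)
    sm = np.real(np.fft.irfft(np.fft.rfft(z) * np.fft.rfft(padded), n))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_profile(params: EPEParams, n: int = 1000,
                     radial_noise_frac: float = 0.0,
                     rng: Optional[np.random.Generator] = None,
                     noise_corr_frac: float = 0.10) -> ProfileCoordinates:
    """Noisy digitized profile of one fruit, standardized.

    With zero noise this is exactly :func:`sample_curve`.  Otherwise each
    curve point is displaced along the unit vector from the centroid by the
    correlated noise field, and the perturbed boundary is re-standardized.
    """
    clean = sample_curve(params, n)
    if radial_noise_frac == 0.0:
        return clean
    if rng is None:
        raise ValueError("an rng is required when radial_noise_frac > 0")
    pts = clean.points
    centroid = pts.mean(axis=0)
    radial = pts - centroid
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    delta = (_smooth_periodic_noise(n, noise_corr_frac, rng)
             * radial_noise_frac * params.a)
    return standardize_points(pts + radial * delta[:, None], n)


def simulate_v_obs(v_true: float, spec: CohortSpec,
                   rng: np.random.Generator) -> float:
    """Water-displacement reading: multiplicative error, then rounding.

    The reading is floored at one resolution step (a displaced fruit always
    registers at least one graduation).
    """
    if v_true <= 0:
        raise ValueError("v_true must be positive")
    noisy = v_true * (1.0 + rng.normal(0.0, spec.v_obs_noise_frac))
    step = spec.v_obs_resolution
    if step > 0:
        noisy = max(step, round(noisy / step) * step)
    return float(noisy)


#: default scale, cm per pixel, of a 600-dpi scan
CM_PER_PX_600DPI = 2.54 / 600.0


def render_image(params: EPEParams, cm_per_px: float = CM_PER_PX_600DPI,
                 margin_px: int = 20, max_pixels: int = 4096) -> np.ndarray:
    """Rasterize the filled EPE silhouette; True = fruit foreground.

    Pixel centres inside the region between the lower and upper branches
    are foreground.  A white margin of at least ``margin_px`` surrounds the
    silhouette on all sides so the background phase touches the border.
    """
    if cm_per_px <= 0:
        raise ValueError("cm_per_px must be positive")
    params.validate()
    u = np.linspace(-1.0, 1.0, 2001)
    ymax = float((params.a * np.sqrt(1 - u * u) * params.poly(u)).max())
    width = int(np.ceil(2 * params.b / cm_per_px)) + 2 * margin_px
    height = int(np.ceil(2 * ymax / cm_per_px)) + 2 * margin_px
    if max(width, height) > max_pixels:
        raise ValueError(
            f"rendered image {width}x{height} exceeds the {max_pixels}px budget; "
            "increase cm_per_px or max_pixels"
        )
    cols = (np.arange(width) - (width - 1) / 2.0) * cm_per_px
    rows = ((height - 1) / 2.0 - np.arange(height)) * cm_per_px
    uu = np.clip(cols / params.b, -1.0, 1.0)
    ytop = params.a * np.sqrt(1.0 - uu * uu) * params.poly(uu)
    inside_x = np.abs(cols) <= params.b
    mask = (rows[:, None] <= ytop[None, :]) & (rows[:, None] >= -ytop[None, :])
    mask &= inside_x[None, :]
    return mask


def save_silhouette(mask: np.ndarray, path) -> None:
    """Write a foreground mask as a black-on-white 8-bit PNG/BMP."""
    img = Image.fromarray(np.where(mask, 0, 255).astype(np.uint8), mode="L")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img.save(path)


@dataclass
class Cohort:
    """One generated cohort: ground truth, profiles and simulated readings."""

    spec: CohortSpec
    params: List[EPEParams]
    profiles: List[ProfileCoordinates]
    truth: pd.DataFrame  # fruit_id, cultivar, true a..c3, v_true, v_obs


def generate_cohort(spec: CohortSpec, n_points: int = 1000) -> Cohort:
    """Generate ``spec.n_fruits`` fruits with profiles and volume readings."""
    rng = np.random.default_rng(spec.seed)
    params_list, profiles, rows = [], [], []
    for k in range(spec.n_fruits):
        params = sample_params(spec, rng)
        profile = generate_profile(params, n_points, spec.radial_noise_frac,
                                   rng, spec.noise_corr_frac)
        v_true = volume_closed_form(params)
        v_obs = simulate_v_obs(v_true, spec, rng)
        fruit_id = f"{spec.cultivar_label}_{k:04d}"
        params_list.append(params)
        profiles.append(profile)
        rows.append({
            "fruit_id": fruit_id, "cultivar": spec.cultivar_label,
            "true_a": params.a, "true_b": params.b, "true_c1": params.c1,
            "true_c2": params.c2, "true_c3": params.c3,
            "v_true": v_true, "v_obs": v_obs,
        })
    return Cohort(spec=spec, params=params_list, profiles=profiles,
                  truth=pd.DataFrame(rows))


def write_cohort(cohort: Cohort, out_dir, images: bool = False,
                 cm_per_px: float = CM_PER_PX_600DPI) -> Path:
    """Write profile CSVs (+ optional silhouette PNGs) and a manifest.

    The manifest carries the ground-truth columns alongside the derived
    file paths; numeric values use 6 significant digits.
    """
    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    manifest = cohort.truth.copy()
    paths = []
    for fid, prof in zip(manifest["fruit_id"], cohort.profiles):
        rel = f"profiles/{fid}.csv"
        write_profile_csv(prof, out / rel)
        paths.append(rel)
    manifest["profile_path"] = paths
    if images:
        (out / "images").mkdir(exist_ok=True)
        img_paths = []
        for fid, params in zip(manifest["fruit_id"], cohort.params):
            rel = f"images/{fid}.png"
            save_silhouette(render_image(params, cm_per_px), out / rel)
            img_paths.append(rel)
        manifest["image_path"] = img_paths
        manifest["measured_length_cm"] = [2.0 * p.b for p in cohort.params]
    float_cols = manifest.select_dtypes("number").columns
    manifest[float_cols] = manifest[float_cols].map(lambda v: float(f"{v:.6g}"))
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"
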