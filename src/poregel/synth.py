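"""Seeded synthetic-data generators with known ground truth.

The study's raw microscopy is not deposited, so every input the
pipeline consumes is emulated here: noisy model-generated pore-radius
traces, liposome fluorescence movies with peripheral spots / blisters /
center depletion, kymographs of advected actin with pile-up at the
moving pore edge, and traction maps with rim-localised stress of known
equivalent membrane tension.

Every generator is a pure function of (config, seed): repeated calls
are bit-identical, and each returns a machine-readable ground-truth
record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .params import GelParams, preset
from .model import simulate_pore
from .fields import FieldTrajectory
from .kinetics import TimeSeries, Kymograph
from .images import ImageFrame, TractionMap

__all__ = [
    "SceneConfig",
    "gen_pore_trace",
    "gen_liposome_movie",
    "gen_kymograph",
    "gen_traction_map",
]


@dataclass(frozen=True)
class SceneConfig:
    """Configuration for a synthetic liposome movie.

    Defaults emulate the imaging conditions of the study system:
    0.1 µm pixels, 10 µm contact radius, ~1 µm peripheral spots packed
    within ~2 µm of the contact line, µm-scale dark blisters, center
    depletion with τ_a = 100 s, and 5%-of-dynamic-range Gaussian read
    noise.
    """

    seed: int = 0
    pixel_size: float = 0.1e-6       # m/px
    frame_interval: float = 10.0     # s
    n_frames: int = 12
    R_liposome: float = 10e-6        # m
    noise_model: str = "gaussian"    # 'gaussian' | 'poisson'
    noise_sd: float = 0.05           # fraction of dynamic range
    poisson_gain: float = 100.0      # photons at unit intensity
    n_spots: int = 10
    spot_snr: float = 5.0
    spot_diameter: float = 1e-6      # m
    ring_width: float = 2e-6         # m: spots within w of contact line
    n_blisters: int = 5
    blister_radius: float = 1.5e-6   # m
    camera_offset: float = 0.2       # baseline so noise is never clipped
    psf_sigma: float = 0.15e-6       # m, Gaussian point-spread blur
    tau_a: float = 100.0             # s, center depletion
    gel: GelParams = dc_field(default_factory=lambda: preset("actin_liposome"))


def _gauss(img: np.ndarray, sigma_px: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(img, sigma_px)


def _noise(rng: np.random.Generator, img: np.ndarray, cfg: SceneConfig,
           dynamic_range: float) -> np.ndarray:
    if cfg.noise_model == "gaussian":
        out = img + rng.normal(0.0, cfg.noise_sd * dynamic_range, img.shape)
    elif cfg.noise_model == "poisson":
        out = rng.poisson(np.clip(img, 0, None) * cfg.poisson_gain
                          ) / cfg.poisson_gain
    else:
        raise ValueError(f"unknown noise model {cfg.noise_model!r}")
    return np.clip(out, 0.0, None)


def gen_pore_trace(params: GelParams, R_init: float, t_grid: np.ndarray,
                   noise_sd: float, seed: int) -> tuple[TimeSeries, dict]:
    """Model pore-radius trace + i.i.d. Gaussian noise of sd ``noise_sd``
    (meters). Ground truth carries the noise-free radii and parameters."""
    traj = simulate_pore(params, R_init, t_grid)
    rng = np.random.default_rng(seed)
    noisy = traj.radii + rng.normal(0.0, noise_sd, traj.radii.shape)
    ts = TimeSeries(traj.times, np.clip(noisy, 0.0, None),
                    label="pore_radius", units="m")
    truth = {
        "radii_true_m": traj.radii,
        "params": params.to_dict(),
        "R_init_m": R_init,
        "noise_sd_m": noise_sd,
        "seed": seed,
        "terminated": traj.terminated,
    }
    return ts, truth


def gen_liposome_movie(cfg: SceneConfig) -> tuple[list[ImageFrame], dict]:
    """Fluorescent actin movie of an adherent liposome.

    A uniform disk whose center intensity decays as exp(−t/τ_a), with
    ``n_spots`` peripheral spots turning on at uniformly drawn onset
    times via a logistic ramp, packed within ``ring_width`` of the
    contact line. Returns the frames and a ground-truth dict with the
    spot table (positions, onsets) and the depletion time constant.
    """
    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size
    R_px = cfg.R_liposome / px
    n = int(np.ceil(2.4 * R_px))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c)
    disk = rr <= R_px

    # spot geometry: uniform over the peripheral annulus, uniform angle
    r_lo = (cfg.R_liposome - cfg.ring_width) / px
    u = rng.uniform(size=cfg.n_spots)
    spot_r = np.sqrt(r_lo**2 + u * (R_px**2 - r_lo**2))
    spot_th = rng.uniform(0.0, 2.0 * np.pi, cfg.n_spots)
    spot_y = c + spot_r * np.sin(spot_th)
    spot_x = c + spot_r * np.cos(spot_th)
    total_t = cfg.frame_interval * (cfg.n_frames - 1)
    onsets = rng.uniform(0.0, 0.7 * total_t, cfg.n_spots)

    sigma_px = cfg.spot_diameter / (2.355 * px)  # FWHM = spot diameter
    base = 1.0
    spot_amp = cfg.spot_snr * cfg.noise_sd * 1.0 / 1.0  # SNR vs read noise

    frames = []
    for k in range(cfg.n_frames):
        t = k * cfg.frame_interval
        center_level = np.exp(-t / cfg.tau_a)
        img = np.where(disk, base * center_level, 0.0).astype(float)
        for j in range(cfg.n_spots):
            ramp = 1.0 / (1.0 + np.exp(-(t - onsets[j]) / 10.0))
            if ramp < 1e-3:
                continue
            blob = spot_amp * ramp * np.exp(
                -((yy - spot_y[j])**2 + (xx - spot_x[j])**2)
                / (2.0 * sigma_px**2))
            img += blob
        if cfg.psf_sigma > 0:
            img = np.ascontiguousarray(
                _gauss(img, cfg.psf_sigma / px))
        img = _noise(rng, img + cfg.camera_offset, cfg, dynamic_range=base)
        frames.append(ImageFrame(img, px, channel="actin", time=t))

    truth = {
        "center_px": (c, c),
        "center_m": (c * px, c * px),
        "R_liposome_m": cfg.R_liposome,
        "tau_a_s": cfg.tau_a,
        "ring_width_m": cfg.ring_width,
        "spots_y_m": spot_y * px,
        "spots_x_m": spot_x * px,
        "spot_onsets_s": onsets,
        "spot_amp": spot_amp,
        "seed": cfg.seed,
    }
    return frames, truth


def gen_brightfield_blisters(cfg: SceneConfig) -> tuple[ImageFrame, dict]:
    """Brightfield frame with ``n_blisters`` dark disks of radius
    ``blister_radius`` planted inside the liposome contact disk."""
    rng = np.random.default_rng(cfg.seed + 1)
    px = cfg.pixel_size
    R_px = cfg.R_liposome / px
    b_px = cfg.blister_radius / px
    n = int(np.ceil(2.4 * R_px))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]

    img = np.full((n, n), 1.0)
    centers = []
    max_r = R_px - 2.0 * b_px
    attempts = 0
    while len(centers) < cfg.n_blisters and attempts < 2000:
        attempts += 1
        r = max_r * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        y, x = c + r * np.sin(th), c + r * np.cos(th)
        if all(np.hypot(y - y0, x - x0) > 2.6 * b_px for y0, x0 in centers):
            centers.append((y, x))
    for y0, x0 in centers:
        rr = np.hypot(yy - y0, xx - x0)
        img -= 0.6 * (1.0 / (1.0 + np.exp((rr - b_px) / 0.5)))
    if cfg.psf_sigma > 0:
        img = _gauss(img, cfg.psf_sigma / px)
    img = _noise(rng, img + cfg.camera_offset, cfg, dynamic_range=1.0)
    frame = ImageFrame(img, px, channel="brightfield")
    truth = {
        "centers_m": np.array(centers) * px,
        "radius_m": cfg.blister_radius,
        "n_blisters": len(centers),
        "seed": cfg.seed + 1,
    }
    return frame, truth


def gen_kymograph(field_traj: FieldTrajectory, noise_sd: float, seed: int,
                  pixel_size: float = 0.1e-6) -> tuple[Kymograph, dict]:
    """Kymograph of an advected textured actin layer.

    Intensity ∝ ρ(r, t) modulated by a static random texture carried
    with the material (tracked by integrating the velocity field), plus
    Gaussian noise. Ground truth carries the Lagrangian displacement of
    the pore edge and of bulk tracers.
    """
    rng = np.random.default_rng(seed)
    fields = field_traj.fields
    times = field_traj.times
    R_L = fields[0].R_L
    n_x = int(np.ceil(R_L / pixel_size))
    x = (np.arange(n_x) + 0.5) * pixel_size

    # material texture: smooth random field in the initial configuration
    n_tex = 4 * n_x
    tex_raw = rng.normal(size=n_tex)
    kernel = np.exp(-0.5 * (np.arange(-5, 6) / 1.2) ** 2)
    kernel /= kernel.sum()
    texture = np.convolve(tex_raw, kernel, mode="same")
    tex_x = np.linspace(0.0, R_L, n_tex)

    # Lagrangian map: integrate tracer positions through the recorded
    # velocity snapshots (piecewise-constant in time)
    tracers0 = np.linspace(fields[0].R, R_L, 200)
    tracers = tracers0.copy()
    disp_rows = [np.zeros_like(tracers)]
    for k in range(len(fields) - 1):
        dt = times[k + 1] - times[k]
        vk = np.interp(tracers, fields[k].r, fields[k].v,
                       left=fields[k].v[0], right=fields[k].v[-1])
        tracers = np.clip(tracers + vk * dt, 0.0, R_L)
        disp_rows.append(tracers - tracers0)

    rows = []
    for k, fld in enumerate(fields):
        rho_x = np.interp(x, fld.r, fld.rho, left=0.0, right=fld.rho[-1])
        rho_x[x < fld.R] = 0.0
        # texture advected: intensity pattern carried by the material
        x0 = np.interp(x, tracers0 + disp_rows[k], tracers0,
                       left=np.nan, right=tracers0[-1])
        mod = np.interp(np.nan_to_num(x0, nan=0.0), tex_x, texture)
        row = rho_x * (1.0 + 0.3 * mod)
        row[x < fld.R] = 0.0
        rows.append(row)
    arr = np.array(rows)
    arr = np.clip(arr + rng.normal(0.0, noise_sd, arr.shape), 0.0, None)

    dt_med = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    kymo = Kymograph(arr, pixel_size=pixel_size, frame_interval=dt_med)
    truth = {
        "edge_positions_m": np.array([f.R for f in fields]),
        "times_s": times,
        "tracers0_m": tracers0,
        "tracer_displacement_m": np.array(disp_rows),
        "seed": seed,
    }
    return kymo, truth


def gen_traction_map(target_tension: float, R_contact: float,
                     rim_width: float, noise_sd_pa: float,
                     seed: int, pixel_size: float = 0.2e-6
                     ) -> tuple[TractionMap, dict]:
    """Traction map with radially inward rim stress of known equivalent
    membrane tension.

    The rim-band stress magnitude is chosen so the literal rim-tension
    readout (mean |σ| over the band × mask perimeter) returns
    ``target_tension`` exactly in the noise-free limit.
    """
    if not (0.0 < rim_width < R_contact):
        raise ValueError("need 0 < rim_width < R_contact")
    rng = np.random.default_rng(seed)
    px = pixel_size
    R_px = R_contact / px
    n = int(np.ceil(2.6 * R_px))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c)
    mask = rr <= R_px

    from scipy import ndimage as _ndi
    from skimage import measure as _measure
    dist_in = _ndi.distance_transform_edt(mask) * px
    rim = mask & (dist_in <= rim_width)
    contours = _measure.find_contours(mask.astype(float), 0.5)
    longest = max(contours, key=lambda cc: cc.shape[0])
    perimeter = float(np.hypot(*np.diff(longest, axis=0).T).sum()) * px
    stress_mag = target_tension / perimeter  # Pa so that literal readout hits

    with np.errstate(invalid="ignore", divide="ignore"):
        uy = np.where(rr > 0, -(yy - c) / rr, 0.0)
        ux = np.where(rr > 0, -(xx - c) / rr, 0.0)
    sy = np.where(rim, stress_mag * uy, 0.0)
    sx = np.where(rim, stress_mag * ux, 0.0)
    sy = sy + rng.normal(0.0, noise_sd_pa, sy.shape) * mask
    sx = sx + rng.normal(0.0, noise_sd_pa, sx.shape) * mask
    tmap = TractionMap(np.dstack([sy, sx]), px, mask)
    truth = {
        "target_tension_N_per_m": target_tension,
        "rim_stress_pa": stress_mag,
        "perimeter_m": perimeter,
        "rim_width_m": rim_width,
        "seed": seed,
    }
    return tmap, truth
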