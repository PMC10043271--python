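"""Fitting and statistics on 1-D traces.

Pore-opening timescales, actin turnover kinetics, density fold changes,
kymograph displacement gradients, fitting the active-gel model to
measured pore-radius traces, and the group-comparison statistics used
throughout (Welch two-sided t-test for distributions, Fisher's exact
test for prevalences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .params import GelParams
from . import model as _model

__all__ = [
    "TimeSeries",
    "Kymograph",
    "FitResult",
    "fit_pore_radius",
    "normalize_tau",
    "fit_center_depletion",
    "density_fold",
    "displacement_gradient",
    "fit_model_to_trace",
    "group_compare",
    "prevalence_compare",
    "significance_stars",
]


@dataclass(frozen=True)
class TimeSeries:
    """A 1-D trace y(t) with strictly increasing times."""

    t: np.ndarray
    y: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("t and y must be 1-D and equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("t and y must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "value": self.y}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "",
                 units: str = "") -> "TimeSeries":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["value"].to_numpy(),
                   label=label, units=units)


@dataclass(frozen=True)
class Kymograph:
    """Space–time intensity array: rows are time lines, columns space."""

    intensity: np.ndarray  # (n_t, n_x)
    pixel_size: float      # m/px
    frame_interval: float  # s

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("kymograph must be 2-D (time, space)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        object.__setattr__(self, "intensity", arr)


@dataclass
class FitResult:
    """Nonlinear fit outcome: estimates, standard errors, diagnostics."""

    model_name: str
    params: dict
    stderr: dict
    residual_rms: float
    converged: bool
    extra: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_name": self.model_name,
            "params": self.params,
            "stderr": self.stderr,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "extra": {k: v for k, v in self.extra.items()
                      if not isinstance(v, np.ndarray)},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _curve_fit(f, t, y, p0, bounds=(-np.inf, np.inf)):
    popt, pcov = optimize.curve_fit(f, t, y, p0=p0, bounds=bounds,
                                    maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = y - f(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    return popt, perr, rms


def fit_pore_radius(ts: TimeSeries, growing: bool = False) -> FitResult:
    """Characteristic pore-opening timescale τ from R(t).

    Default form is the saturating exponential
    R(t) = R_∞ − (R_∞ − R_0)·exp(−(t − t0)/τ) with t0 fixed at the
    first sample (pores saturate at the contact radius). ``growing``
    selects a pure growing exponential R_0·exp((t − t0)/τ) instead.
    """
    t, y = ts.t, ts.y
    if t.size < 6:
        raise ValueError("need at least 6 points to fit a timescale")
    if np.any(y < 0):
        raise ValueError("pore radii must be non-negative")
    span = y.max() - y.min()
    if span <= 0 or span < 1e-12 * max(abs(y.max()), 1e-300):
        raise RuntimeError("constant trace: pore-opening fit cannot converge")
    t0 = t[0]

    # fit in normalised units (y/ymax, t/tspan): curve_fit's bounded
    # solver stalls when parameter scales differ by many decades
    ymax = float(y.max())
    tspan = float(t[-1] - t[0])
    z = y / ymax
    u = (t - t0) / tspan

    if growing:
        def f(uu, z0, q):
            return z0 * np.exp(uu / q)
        p0 = [max(z[0], 1e-3), 1.0 / 3.0]
        try:
            popt, perr, rms = _curve_fit(f, u, z, p0)
        except RuntimeError as err:
            raise RuntimeError(f"pore-radius fit failed: {err}") from None
        popt = [popt[0] * ymax, popt[1] * tspan]
        perr = [perr[0] * ymax, perr[1] * tspan]
        rms *= ymax
        names = ("R_0", "tau")
    else:
        def f(uu, zinf, z0, q):
            return zinf - (zinf - z0) * np.exp(-uu / q)
        # anchor R_inf to the observed saturation plateau when the trace
        # has one (pores saturate at the contact radius): a free R_inf
        # correlates ~0.95 with tau under noise and inflates it badly
        plateau = float(np.median(np.sort(y)[-max(y.size // 5, 3):]))
        k = max(y.size // 10, 3)
        med_last = float(np.median(y[-k:]))
        med_prev = float(np.median(y[-2 * k:-k]))
        saturated = abs(med_last - med_prev) < 0.05 * span
        if saturated and plateau > 0:
            lo, hi = 0.95 * plateau / ymax, 1.05 * plateau / ymax
        else:
            lo, hi = 0.5, 1.5
        p0 = [min(max(z[-1], lo + 1e-9), hi - 1e-9), z[0], 1.0 / 3.0]
        try:
            popt, perr, rms = _curve_fit(
                f, u, z, p0,
                bounds=([lo, 0.0, 1e-9], [hi, 1.0, np.inf]))
        except RuntimeError as err:
            raise RuntimeError(f"pore-radius fit failed: {err}") from None
        popt = [popt[0] * ymax, popt[1] * ymax, popt[2] * tspan]
        perr = [perr[0] * ymax, perr[1] * ymax, perr[2] * tspan]
        rms *= ymax
        names = ("R_inf", "R_0", "tau")

    params = dict(zip(names, map(float, popt)))
    if params["tau"] <= 0:
        raise RuntimeError("fitted tau is non-positive")
    return FitResult(
        model_name="growing_exponential" if growing else
        "saturating_exponential",
        params=params,
        stderr=dict(zip(names, map(float, perr))),
        residual_rms=rms,
        converged=True,
    )


def normalize_tau(tau: float, tau_BL: float) -> float:
    """τ normalised to the bare-liposome (empty) reference τ_BL."""
    if tau_BL <= 0:
        raise ValueError("tau_BL must be > 0")
    return tau / tau_BL


def detect_depletion_onset(ts: TimeSeries, smooth_window: int | None = None,
                           tolerance: float = 0.02) -> float:
    """Onset of depolymerization: last time the smoothed trace is within
    ``tolerance`` (relative) of its running maximum.

    The smoothing window defaults to 5% of the trace length (at least
    5 samples) so the rule stays usable on noisy traces.
    """
    y = ts.y
    if smooth_window is None:
        smooth_window = max(5, ts.t.size // 20)
    if ts.t.size >= smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    running_max = np.maximum.accumulate(y)
    near_max = y >= (1.0 - tolerance) * running_max
    idx = np.nonzero(near_max)[0]
    return float(ts.t[idx[-1]]) if idx.size else float(ts.t[0])


def _fit_depletion_at_onset(ts: TimeSeries, t_on: float):
    """Exponential fit anchored at ``t_on``; returns (popt, perr, rms,
    whole-trace piecewise SSE with a flat plateau before the onset)."""
    sel = ts.t >= t_on
    t, y = ts.t[sel], ts.y[sel]
    if t.size < 6:
        t, y = ts.t, ts.y
        t_on = float(ts.t[0])
    scale = float(np.max(np.abs(y))) or 1.0
    tspan = float(t[-1] - t[0]) or 1.0
    z = y / scale
    u = (t - t_on) / tspan

    def f(uu, zinf, z0, q):
        return zinf + (z0 - zinf) * np.exp(-uu / q)

    p0 = [z[-1], z[0], 1.0 / 3.0]
    popt, perr, rms = _curve_fit(
        f, u, z, p0, bounds=([-np.inf, -np.inf, 1e-9],
                             [np.inf, np.inf, np.inf]))
    popt = [popt[0] * scale, popt[1] * scale, popt[2] * tspan]
    perr = [perr[0] * scale, perr[1] * scale, perr[2] * tspan]
    model = np.where(
        ts.t < t_on, popt[1],
        popt[0] + (popt[1] - popt[0]) * np.exp(
            -np.clip(ts.t - t_on, 0, None) / popt[2]))
    sse = float(np.sum((ts.y - model) ** 2))
    return popt, perr, rms * scale, sse, t_on


def fit_center_depletion(ts: TimeSeries,
                         refine_onset: bool = True) -> FitResult:
    """Characteristic depolymerization time τ_a from a center-intensity
    trace: I(t) = I_∞ + (I_0 − I_∞)·exp(−(t − t_on)/τ_a).

    The onset t_on starts from the running-maximum rule and, with
    ``refine_onset`` (default), is refined by a small changepoint grid
    search minimising the whole-trace plateau+exponential SSE — the
    running-max rule alone truncates early under noise and inflates
    τ_a.
    """
    if ts.t.size < 6:
        raise ValueError("need at least 6 points")
    if np.polyfit(ts.t, ts.y, 1)[0] > 0 and ts.y[-1] >= ts.y[0]:
        raise RuntimeError("rising trace: no depolymerization to fit")
    t_on0 = detect_depletion_onset(ts)
    candidates = [t_on0]
    if refine_onset:
        half = 0.12 * (ts.t[-1] - ts.t[0])
        candidates = np.clip(t_on0 + np.linspace(-half, half, 9),
                             ts.t[0], ts.t[-2])
    best = None
    for cand in np.atleast_1d(candidates):
        try:
            result = _fit_depletion_at_onset(ts, float(cand))
        except RuntimeError:
            continue
        if best is None or result[3] < best[3]:
            best = result
    if best is None:
        raise RuntimeError("center-depletion fit failed to converge")
    popt, perr, rms, _, t_on = best
    names = ("I_inf", "I_0", "tau_a")
    return FitResult(
        model_name="exponential_depletion",
        params=dict(zip(names, map(float, popt))),
        stderr=dict(zip(names, map(float, perr))),
        residual_rms=rms,
        converged=True,
        extra={"onset_s": t_on, "onset_rule_s": t_on0},
    )


def density_fold(ts: TimeSeries, baseline_window: float) -> TimeSeries:
    """Trace divided by its mean over the initial ``baseline_window``
    seconds — the ρ/ρ0 fold-change normalisation."""
    sel = ts.t <= ts.t[0] + baseline_window
    if not np.any(sel):
        raise ValueError("baseline window contains no samples")
    base = float(np.mean(ts.y[sel]))
    if base <= 0:
        raise ValueError("baseline mean must be > 0")
    return TimeSeries(ts.t, ts.y / base, label=ts.label, units="fold")


def _subpixel_peak(c: np.ndarray, i: int) -> float:
    """Three-point sub-pixel peak interpolation around index i.

    Gaussian (log-parabolic) interpolation when the neighbourhood is
    positive — it suffers far less peak-locking than a plain parabola
    for correlation-shaped peaks — with a parabolic fallback.
    """
    if not (0 < i < c.size - 1):
        return float(i)
    if min(c[i - 1], c[i], c[i + 1]) > 0:
        l0, l1, l2 = np.log([c[i - 1], c[i], c[i + 1]])
        denom = l0 - 2.0 * l1 + l2
        if denom < 0:
            return i + 0.5 * (l0 - l2) / denom
    denom = c[i - 1] - 2.0 * c[i] + c[i + 1]
    if denom < 0:
        return i + 0.5 * (c[i - 1] - c[i + 1]) / denom
    return float(i)


def displacement_gradient(kymo: Kymograph, window: int = 8,
                          overlap: float = 0.5, search: int = 10,
                          min_peak: float = 0.5) -> dict:
    """Cumulative displacement U(x, t) and strain ∂U/∂x from a kymograph.

    Per consecutive time pair, windowed 1-D normalised cross-correlation
    (default 8 px windows, 50% overlap, parabolic sub-pixel peak) gives
    the incremental displacement; increments are summed into U and the
    gradient taken by central differences on the window-center grid.
    Windows whose correlation peak falls below ``min_peak`` are flagged
    invalid (NaN increment, carried forward).
    """
    arr = kymo.intensity
    n_t, n_x = arr.shape
    if n_x < 16 or n_t < 3:
        raise ValueError("kymograph must be at least 3 x 16 (time x space)")
    step = max(int(window * (1.0 - overlap)), 1)
    centers = np.arange(window // 2, n_x - window // 2, step)
    n_w = centers.size
    dU = np.zeros((n_t - 1, n_w))
    valid = np.ones((n_t - 1, n_w), dtype=bool)

    for k in range(n_t - 1):
        a, b = arr[k], arr[k + 1]
        for j, c in enumerate(centers):
            lo, hi = c - window // 2, c + window // 2
            tpl = a[lo:hi]
            s_lo, s_hi = max(lo - search, 0), min(hi + search, n_x)
            seg = b[s_lo:s_hi]
            tpl0 = tpl - tpl.mean()
            n_lag = seg.size - window + 1
            if n_lag < 3 or np.allclose(tpl0, 0):
                valid[k, j] = False
                continue
            corr = np.empty(n_lag)
            for m in range(n_lag):
                win = seg[m:m + window]
                w0 = win - win.mean()
                denom = np.sqrt((tpl0**2).sum() * (w0**2).sum())
                corr[m] = (tpl0 * w0).sum() / denom if denom > 0 else 0.0
            i_pk = int(np.argmax(corr))
            if corr[i_pk] < min_peak:
                valid[k, j] = False
                continue
            if corr[i_pk] > 1.0 - 1e-9:
                # exact match (e.g. static or integer shift): no refinement
                shift = float(i_pk) + s_lo - lo
            else:
                shift = _subpixel_peak(corr, i_pk) + s_lo - lo
            dU[k, j] = shift

    # median vector validation: reject increments deviating > 1 px from
    # the local (5-window) median, then infill from valid neighbours
    # (standard PIV practice; zeroing them would bias U and spike dU/dx)
    for k in range(n_t - 1):
        med = ndimage.median_filter(dU[k], size=5, mode="nearest")
        valid[k] &= np.abs(dU[k] - med) <= 1.0
    for k in range(n_t - 1):
        if valid[k].all():
            continue
        good = np.nonzero(valid[k])[0]
        if good.size == 0:
            dU[k] = 0.0
            continue
        bad = np.nonzero(~valid[k])[0]
        dU[k, bad] = np.interp(centers[bad], centers[good], dU[k, good])
    U = np.vstack([np.zeros(n_w), np.cumsum(dU, axis=0)])
    x = centers * kymo.pixel_size
    # light spatial smoothing before differentiating (strain from PIV is
    # always computed on a regularised field)
    U_s = ndimage.uniform_filter1d(U, size=3, axis=1, mode="nearest")
    dUdx = np.gradient(U_s * kymo.pixel_size, x, axis=1)
    return {
        "x_m": x,
        "t_s": np.arange(n_t) * kymo.frame_interval,
        "U_px": U,
        "U_m": U * kymo.pixel_size,
        "dU_dx": dUdx,
        "valid": valid,
    }


def fit_model_to_trace(ts: TimeSeries, params: GelParams,
                       free: tuple[str, ...] = ("sigma0", "zeta"),
                       R_init: float | None = None) -> FitResult:
    """Fit the active-gel pore equation to a measured R(t) trace.

    Nonlinear least squares over ``model.simulate_pore`` outputs with the
    chosen free parameters; remaining parameters are held at ``params``.
    Reports the myosin tension contribution σ0·d and the fluidisation
    curve η_eff(t)/η_eff(ζ=0) along the fitted trajectory.
    """
    allowed = {"eta", "sigma0", "zeta", "f_adh", "gamma"}
    if not set(free) <= allowed:
        raise ValueError(f"free parameters must be within {sorted(allowed)}")
    if R_init is None:
        R_init = float(ts.y[0])
    t_rel = ts.t - ts.t[0]
    scales = {name: max(abs(getattr(params, name)), 1e-12) for name in free}

    def build(theta):
        kw = {name: theta[i] * scales[name] for i, name in enumerate(free)}
        return params.replace(**kw)

    def resid(theta):
        try:
            p = build(theta)
            traj = _model.simulate_pore(p, R_init, t_rel)
        except (ValueError, _model.EffectiveViscosityFloorError,
                RuntimeError):
            return np.full(ts.y.size, 1e3 * params.R_L)
        return traj.radii - ts.y

    x0 = np.ones(len(free))
    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12,
                                 ftol=1e-12)
    fitted = build(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))

    # asymptotic covariance; singular => non-identifiable combination
    J = sol.jac
    dof = max(ts.y.size - len(free), 1)
    s2 = float(sol.fun @ sol.fun) / dof
    JTJ = J.T @ J
    identifiable = np.linalg.cond(JTJ) < 1e12
    if identifiable:
        cov = np.linalg.inv(JTJ) * s2
        stderr = {
            name: float(np.sqrt(max(cov[i, i], 0.0)) * scales[name])
            for i, name in enumerate(free)
        }
    else:
        stderr = {name: float("nan") for name in free}

    traj = _model.simulate_pore(fitted, R_init, t_rel)
    eta_eff = np.array([_model.effective_viscosity(fitted, R)
                        for R in traj.radii])
    eta_eff_z0 = np.array(
        [_model.effective_viscosity(fitted.replace(zeta=0.0), R)
         for R in traj.radii])
    return FitResult(
        model_name="activegel_pore",
        params={name: float(getattr(fitted, name)) for name in free},
        stderr=stderr,
        residual_rms=rms,
        converged=bool(sol.success and identifiable),
        extra={
            "sigma_a_d_N_per_m": float(fitted.sigma0 * fitted.d),
            "eta_eff_ratio": eta_eff / eta_eff_z0,
            "t_s": t_rel,
            "identifiable": bool(identifiable),
            "fitted_params": fitted.to_dict(),
        },
    )


def group_compare(a, b) -> dict:
    """Welch two-sided t-test between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: identical constants => no evidence of difference
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "stars": significance_stars(1.0)}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "stars": significance_stars(p)}


def prevalence_compare(table) -> dict:
    """Fisher's exact two-sided test on a 2x2 count table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab_f = np.asarray(table, dtype=float)
        if np.any(tab_f < 0) or np.any(tab_f != np.round(tab_f)):
            raise ValueError("counts must be non-negative integers")
        tab = tab_f.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p),
            "stars": significance_stars(p)}


def significance_stars(p: float) -> str:
    """The *, **, *** convention for p < 0.05, 0.01, 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
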