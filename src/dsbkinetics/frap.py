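"""FRAP trace normalization, model fitting, and fit diagnostics.

The raw observables are three intensity traces on a common time grid: the
mean intensity of the bleached region of interest, a reference region used to
correct for acquisition photobleaching (the whole nucleus, or the unbleached
part of the damaged region for bleaches placed inside a micro-irradiated
area), and a background region. Normalization is

    value(t) = [(roi - bg) / (ref - bg)] / prebleach_mean_of_that_ratio

so any multiplicative intensity drift common to roi and reference (laser
decay, acquisition bleaching) cancels exactly, and the pre-bleach level is 1.

Fitting supports the two limiting kinetic models: the diffusion-limited
recovery (tau_D plus a bleach-depth scale) and the reaction-limited recovery
(k'_on, k_off exactly as written, with no extra amplitude — the implied
bleach depth is k'_on/(k'_on + k_off)). The reaction fit defaults to a fit
window starting 3 s post bleach, which isolates the slowly exchanging bound
population from fast diffusive recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .models import (
    DiffusionFrapParams,
    ReactionFrapParams,
    reaction_frap,
    soumpasis_frap,
)

__all__ = [
    "FrapRecord",
    "NormalizedFrapCurve",
    "FrapFit",
    "AdequacyReport",
    "HalfRecoveryNotReached",
    "DegenerateDenominatorError",
    "normalize_frap",
    "half_recovery_time",
    "fit_frap",
    "assess_single_population_adequacy",
    "koff_area_independence",
]


class DegenerateDenominatorError(ValueError):
    """Reference minus background is non-positive at some frame."""


class HalfRecoveryNotReached(Exception):
    """The recovery curve never crosses the half-recovery level."""


@dataclass
class FrapRecord:
    """Raw FRAP traces with bleach metadata.

    ``bleach_index`` is the index of the first post-bleach frame (so at least
    one pre-bleach frame precedes it). ``protocol_tag`` records which
    reference-region semantics the caller used; the arithmetic is identical.
    """

    time: np.ndarray
    roi_trace: np.ndarray
    reference_trace: np.ndarray
    background_trace: np.ndarray
    bleach_index: int
    bleach_area: float | None = None  # µm²
    protocol_tag: Literal[
        "whole-nucleus-correction", "damage-region-correction"
    ] = "whole-nucleus-correction"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.roi_trace = np.asarray(self.roi_trace, dtype=float)
        self.reference_trace = np.asarray(self.reference_trace, dtype=float)
        bg = np.asarray(self.background_trace, dtype=float)
        if bg.ndim == 0:
            bg = np.full_like(self.time, float(bg))
        self.background_trace = bg
        n = self.time.size
        for name in ("roi_trace", "reference_trace", "background_trace"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != time length {n}")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index must leave >= 1 pre-bleach frame and be in range")


@dataclass
class NormalizedFrapCurve:
    """Background-corrected, bleaching-corrected, pre-bleach-normalized recovery.

    ``time_post_bleach`` starts at 0 at the first post-bleach frame; the
    pre-bleach level is 1 by construction.
    """

    time_post_bleach: np.ndarray
    value: np.ndarray
    bleach_area: float | None = None
    prebleach_mean: float = 1.0

    def __post_init__(self) -> None:
        self.time_post_bleach = np.asarray(self.time_post_bleach, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_post_bleach.size != self.value.size:
            raise ValueError("time and value must have equal length")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("curve values must be finite")


@dataclass
class AdequacyReport:
    """Goodness-of-fit diagnostics for one fitted model on one curve."""

    model_id: str
    runs_test_p: float
    reduced_chi_square: float | None
    recovery_span: float
    adequate: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class FrapFit:
    """Result of fitting one kinetic model to a normalized FRAP curve."""

    model_id: Literal["diffusion", "reaction"]
    params: DiffusionFrapParams | ReactionFrapParams
    param_se: dict[str, float]
    fit_window: tuple[float, float]
    rss: float
    n_points: int
    success: bool
    bleach_depth_scale: float | None = None  # diffusion model only
    residuals: np.ndarray | None = None
    bleach_area: float | None = None
    message: str = ""

    @property
    def n_free_params(self) -> int:
        return 2  # both models fit exactly two free parameters

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model_id == "diffusion":
            s = self.bleach_depth_scale if self.bleach_depth_scale is not None else 1.0
            return 1.0 - s * (1.0 - soumpasis_frap(t, self.params))
        return reaction_frap(t, self.params)

    def to_json(self) -> dict:
        from .models import params_to_json

        return {
            "model_id": self.model_id,
            "params": params_to_json(self.params),
            "param_se": {k: float(v) for k, v in self.param_se.items()},
            "fit_window": [float(self.fit_window[0]), float(self.fit_window[1])],
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "success": bool(self.success),
            "bleach_depth_scale": None
            if self.bleach_depth_scale is None
            else float(self.bleach_depth_scale),
            "bleach_area_um2": None if self.bleach_area is None else float(self.bleach_area),
            "message": self.message,
        }


def normalize_frap(
    record: FrapRecord, prebleach_frames: int | Literal["all"] = "all"
) -> NormalizedFrapCurve:
    """Normalize raw FRAP traces to a dimensionless recovery curve.

    Per frame the background is subtracted from both the ROI and the
    reference, the ratio is taken (cancelling acquisition photobleaching and
    illumination drift), and the ratio is divided by its mean over the last
    ``prebleach_frames`` pre-bleach frames (all of them by default). Only
    post-bleach frames are returned, with t = 0 at the first post-bleach
    frame.

    Raises
    ------
    DegenerateDenominatorError
        If reference - background <= 0 at any frame (the offending frame is
        named).
    """
    denom = record.reference_trace - record.background_trace
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise DegenerateDenominatorError(
            f"reference - background <= 0 at frame {int(bad[0])} "
            f"(value {denom[bad[0]]:.6g})"
        )
    ratio = (record.roi_trace - record.background_trace) / denom

    b = record.bleach_index
    if prebleach_frames == "all":
        pre = ratio[:b]
    else:
        k = int(prebleach_frames)
        if k < 1:
            raise ValueError("prebleach_frames must be >= 1 or 'all'")
        pre = ratio[max(0, b - k) : b]
    if pre.size == 0:
        raise ValueError("no pre-bleach frames available for normalization")
    pre_mean = float(np.mean(pre))
    if pre_mean <= 0:
        raise DegenerateDenominatorError("pre-bleach mean of corrected ratio is <= 0")

    value = ratio[b:] / pre_mean
    t = record.time[b:] - record.time[b]
    return NormalizedFrapCurve(
        time_post_bleach=t, value=value, bleach_area=record.bleach_area, prebleach_mean=pre_mean
    )


def half_recovery_time(curve: NormalizedFrapCurve) -> float:
    """Time to recover half of the fluorescence lost upon photobleaching.

    With ``v0`` the first post-bleach value, the lost signal is ``1 - v0`` and
    the half level is ``v0 + (1 - v0)/2``; the first crossing is located by
    linear interpolation between the bracketing frames.

    Raises
    ------
    HalfRecoveryNotReached
        If the curve never reaches the half level.
    """
    t, v = curve.time_post_bleach, curve.value
    if v.size < 2:
        raise ValueError("need at least 2 post-bleach points")
    v0 = v[0]
    if v0 >= 1.0:
        raise ValueError("first post-bleach value must be < 1 (no bleach depth)")
    half = v0 + (1.0 - v0) / 2.0
    above = np.nonzero(v >= half)[0]  # v[0] < half by construction
    if above.size == 0:
        raise HalfRecoveryNotReached(
            f"curve never reaches the half-recovery level {half:.4g}"
        )
    i = int(above[0])
    # linear interpolation in [i-1, i]
    t0, t1, v0_, v1_ = t[i - 1], t[i], v[i - 1], v[i]
    if v1_ == v0_:
        return float(t1)
    return float(t0 + (half - v0_) * (t1 - t0) / (v1_ - v0_))


def _fit_window_slice(curve: NormalizedFrapCurve, start: float) -> np.ndarray:
    return np.nonzero(curve.time_post_bleach >= start)[0]


def _reaction_residual(p, t, y):
    model = 1.0 - (p["k_on_prime"] / (p["k_on_prime"] + p["k_off"])) * np.exp(-p["k_off"] * t)
    return model - y


def _diffusion_residual(p, t, y):
    rec = soumpasis_frap(t, DiffusionFrapParams(tau_D=p["tau_D"].value))
    model = 1.0 - p["depth"] * (1.0 - rec)
    return model - y


def fit_frap(
    curve: NormalizedFrapCurve,
    model_id: Literal["diffusion", "reaction"],
    fit_window_start: float | None = None,
    weights: np.ndarray | None = None,
    n_restarts: int = 4,
) -> FrapFit:
    """Fit a kinetic model to a normalized FRAP curve by bounded least squares.

    The reaction model fits ``k'_on`` and ``k_off`` with no extra amplitude
    (window start defaults to 3 s post bleach); the diffusion model fits
    ``tau_D`` and a bleach-depth scale (window start defaults to 0).
    Initialization is multi-start: ``k_off`` from the half-recovery time,
    ``k'_on`` from the initial bleach depth, plus a small deterministic grid
    around them; the restart with the lowest residual sum of squares wins, so
    the fit is deterministic given the curve.
    """
    if fit_window_start is None:
        fit_window_start = 3.0 if model_id == "reaction" else 0.0
    idx = _fit_window_slice(curve, fit_window_start)
    if idx.size == 0:
        raise ValueError("fit window excludes all data")
    if idx.size < 10:
        raise ValueError(f"need >= 10 points inside the fit window, have {idx.size}")
    t = curve.time_post_bleach[idx]
    y = curve.value[idx]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)[idx]

    v0 = float(curve.value[0])
    depth0 = min(max(1.0 - v0, 1e-3), 1.0)
    try:
        th = half_recovery_time(curve)
        k_off0 = np.log(2.0) / max(th, 1e-6)
    except (HalfRecoveryNotReached, ValueError):
        k_off0 = 1.0 / max(t[-1], 1e-6)

    best = None
    if model_id == "reaction":
        # k'_on such that depth = k'_on/(k'_on+k_off) matches the observed depth
        k_on0 = k_off0 * depth0 / max(1.0 - depth0, 1e-3)
        starts = [(k_on0, k_off0)]
        for fk in (0.2, 1.0, 5.0):
            for fo in (0.2, 5.0):
                starts.append((max(k_on0 * fk, 1e-4), max(k_off0 * fo, 1e-4)))
        starts = starts[: 1 + 2 * n_restarts]
        for k_on_i, k_off_i in starts:
            p = Parameters()
            p.add("k_on_prime", value=k_on_i, min=0.0, max=1e4)
            p.add("k_off", value=k_off_i, min=1e-8, max=1e4)
            try:
                res = minimize(
                    lambda pp: w * _reaction_residual(pp, t, y), p, method="least_squares"
                )
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("reaction fit failed to converge from any start")
        params = ReactionFrapParams(
            k_on_prime=float(best.params["k_on_prime"].value),
            k_off=float(best.params["k_off"].value),
        )
        se = {
            name: float(best.params[name].stderr)
            if best.params[name].stderr is not None
            else float("nan")
            for name in ("k_on_prime", "k_off")
        }
        depth_scale = None
    else:
        tau0 = np.log(2.0) / k_off0  # same timescale heuristic as the reaction start
        starts = [tau0 * f for f in (1.0, 0.1, 10.0, 0.01, 100.0)][: 1 + n_restarts]
        for tau_i in starts:
            p = Parameters()
            p.add("tau_D", value=max(tau_i, 1e-8), min=1e-8, max=1e6)
            p.add("depth", value=depth0, min=1e-6, max=1.5)
            try:
                res = minimize(
                    lambda pp: w * _diffusion_residual(pp, t, y), p, method="least_squares"
                )
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("diffusion fit failed to converge from any start")
        params = DiffusionFrapParams(tau_D=float(best.params["tau_D"].value))
        se = {
            "tau_D": float(best.params["tau_D"].stderr)
            if best.params["tau_D"].stderr is not None
            else float("nan"),
            "depth": float(best.params["depth"].stderr)
            if best.params["depth"].stderr is not None
            else float("nan"),
        }
        depth_scale = float(best.params["depth"].value)

    resid = np.asarray(best.residual, dtype=float)
    return FrapFit(
        model_id=model_id,
        params=params,
        param_se=se,
        fit_window=(float(t[0]), float(t[-1])),
        rss=float(np.sum(resid**2)),
        n_points=int(t.size),
        success=bool(best.success),
        bleach_depth_scale=depth_scale,
        residuals=resid,
        bleach_area=curve.bleach_area,
        message=str(best.message),
    )


def _runs_test_p(residuals: np.ndarray) -> float:
    """Wald–Wolfowitz runs test on residual signs (two-sided p-value)."""
    from statsmodels.sandbox.stats.runs import runstest_1samp

    r = residuals[residuals != 0]
    if r.size < 10 or np.all(r > 0) or np.all(r < 0):
        return 0.0  # fully one-sided residuals: maximally structured
    _, p = runstest_1samp(np.sign(r), cutoff=0, correction=True)
    return float(p)


def assess_single_population_adequacy(
    curve: NormalizedFrapCurve,
    fits: Sequence[FrapFit],
    noise_scale: float | None = None,
    runs_p_threshold: float = 0.01,
    chi2_threshold: float = 2.0,
    min_recovery_span: float = 0.05,
) -> list[AdequacyReport]:
    """Judge whether single-population fits describe the curve adequately.

    Each fit gets a runs test on the signs of its residuals (structured,
    sign-correlated residuals reject the model) and, when a noise scale is
    supplied, a reduced chi-square. A fit is flagged inadequate when the runs
    test p-value falls below ``runs_p_threshold`` or reduced chi-square
    exceeds ``chi2_threshold``. Curves whose total recovery span is below
    ``min_recovery_span`` are flagged as degenerate (nothing to fit) whatever
    the residual diagnostics say. Reports are returned ranked by residual sum
    of squares, best first.
    """
    reports: list[AdequacyReport] = []
    span = float(np.max(curve.value) - np.min(curve.value))
    for fit in fits:
        if fit.residuals is None:
            raise ValueError("fit carries no residuals; refit with fit_frap")
        p = _runs_test_p(fit.residuals)
        red_chi2 = None
        if noise_scale is not None and noise_scale > 0:
            dof = max(fit.n_points - fit.n_free_params, 1)
            red_chi2 = float(fit.rss / (noise_scale**2 * dof))
        flags: list[str] = []
        adequate = True
        if p < runs_p_threshold:
            adequate = False
            flags.append("structured-residuals")
        if red_chi2 is not None and red_chi2 > chi2_threshold:
            adequate = False
            flags.append("chi-square-excess")
        if span < min_recovery_span:
            adequate = False
            flags.append("no-recovery-signal")
        reports.append(
            AdequacyReport(
                model_id=fit.model_id,
                runs_test_p=p,
                reduced_chi_square=red_chi2,
                recovery_span=span,
                adequate=adequate,
                flags=flags,
            )
        )
    order = np.argsort([f.rss for f in fits])
    return [reports[i] for i in order]


@dataclass
class AreaInvarianceReport:
    """Outcome of the k_off-vs-bleach-area invariance check."""

    per_area: dict[float, dict[str, float]]
    slope: float
    slope_ci: tuple[float, float]
    passed: bool


def koff_area_independence(
    fits: Sequence[FrapFit], confidence: float = 0.95, min_per_group: int = 3
) -> AreaInvarianceReport:
    """Check that fitted ``k_off`` does not depend on the bleach-spot area.

    A reaction-limited dissociation rate is a molecular property, so its
    estimate must not vary with the size of the bleached region (a dependence
    would indicate diffusion contamination). An ordinary least-squares slope
    of ``k_off`` against area is computed with its confidence interval; the
    check passes when the interval covers zero.
    """
    areas = np.array([f.bleach_area for f in fits], dtype=float)
    if np.any(~np.isfinite(areas)):
        raise ValueError("every fit must carry a bleach_area")
    koffs = np.array(
        [f.params.k_off for f in fits if isinstance(f.params, ReactionFrapParams)], dtype=float
    )
    if koffs.size != len(fits):
        raise ValueError("all fits must be reaction-model fits")
    uniq = np.unique(areas)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct bleach areas")
    per_area: dict[float, dict[str, float]] = {}
    for a in uniq:
        sel = koffs[areas == a]
        if sel.size < min_per_group:
            raise ValueError(f"need >= {min_per_group} fits for area {a} µm², have {sel.size}")
        per_area[float(a)] = {
            "n": int(sel.size),
            "mean": float(np.mean(sel)),
            "sd": float(np.std(sel, ddof=1)),
        }
    lr = stats.linregress(areas, koffs)
    dof = koffs.size - 2
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    ci = (lr.slope - tcrit * lr.stderr, lr.slope + tcrit * lr.stderr)
    return AreaInvarianceReport(
        per_area=per_area,
        slope=float(lr.slope),
        slope_ci=(float(ci[0]), float(ci[1])),
        passed=bool(ci[0] <= 0.0 <= ci[1]),
    )
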