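"""FCS: intensity-trace detrending, autocorrelation, and model fitting.

A fluorescence-correlation measurement records photon counts in a tiny
confocal focal volume at fixed sample intervals (acquisitions of ~30 s keep
the correlation curves quiet). Slow drifts — acquisition photobleaching,
stage creep — add spurious long-lag correlation, so traces are first
detrended by local-mean normalization. The autocorrelation

    G(tau) = <dF(t) dF(t+tau)> / <F>^2,   dF = F - <F>

is then computed either by the direct O(N^2) definition (the oracle) or by
the multi-tau scheme: logarithmically spaced lags with pairwise binning of
the signal at each octave, the standard estimator for correlations spanning
many decades. Curves are fitted with the one- or two-population models
(structural parameter omega fixed to 6), and the population structure is
decided by a conservative double gate: corrected AIC difference AND an
F-test on the residual sums of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .models import (
    DEFAULT_OMEGA,
    FcsOnePopParams,
    FcsTwoPopParams,
    fcs_g,
)

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "FcsFit",
    "ModelSelectionReport",
    "detrend_trace",
    "autocorrelate",
    "fit_fcs",
    "compare_fcs_models",
    "residence_time_report",
]


@dataclass
class IntensityTrace:
    """Binned photon counts (or analog intensity) at a fixed sample interval."""

    sample_interval: float  # seconds
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def duration(self) -> float:
        return self.counts.size * self.sample_interval

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass
class CorrelationCurve:
    """Autocorrelation amplitude G at strictly increasing positive lags."""

    lag: np.ndarray
    g: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.size != self.g.size:
            raise ValueError("lag and g must have equal length")
        if np.any(self.lag <= 0) or not np.all(np.diff(self.lag) > 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.size != self.lag.size:
                raise ValueError("se must match lag length")


@dataclass
class FcsFit:
    """Fitted FCS model with uncertainties and information criterion."""

    model_id: Literal["one_pop", "two_pop"]
    params: FcsOnePopParams | FcsTwoPopParams
    param_se: dict[str, float]
    rss: float
    n_points: int
    aicc: float
    success: bool
    curve_id: int = 0  # identity token used to guard model comparisons
    weighted_residuals: np.ndarray | None = None
    message: str = ""

    @property
    def n_free_params(self) -> int:
        return 2 if self.model_id == "one_pop" else 4

    @property
    def g0(self) -> float:
        """Zero-lag amplitude implied by the fit, 1/(2^{3/2} N)."""
        return 1.0 / (2.0**1.5 * self.params.N)

    def predict(self, lag) -> np.ndarray:
        return fcs_g(lag, self.params)

    def to_json(self) -> dict:
        from .models import params_to_json

        return {
            "model_id": self.model_id,
            "params": params_to_json(self.params),
            "param_se": {k: float(v) for k, v in self.param_se.items()},
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "aicc": float(self.aicc),
            "success": bool(self.success),
            "message": self.message,
        }


def detrend_trace(trace: IntensityTrace, window: float = 2.0) -> IntensityTrace:
    """Remove slow intensity drifts by local-mean normalization.

    Each bin is divided by a centered moving average of the counts over
    ``window`` seconds and rescaled by the global mean, so the output
    preserves the input's mean while fluctuations slower than the window are
    flattened. Stationary traces pass through essentially unchanged.
    """
    n_win = int(round(window / trace.sample_interval))
    if n_win < 10:
        raise ValueError("window must span >= 10 sample intervals")
    if n_win > trace.n_bins:
        raise ValueError("window longer than the trace")
    # centered moving average via cumulative sums (edges use shrinking windows)
    half = n_win // 2
    c = trace.counts
    csum = np.concatenate(([0.0], np.cumsum(c)))
    idx = np.arange(c.size)
    lo = np.clip(idx - half, 0, c.size)
    hi = np.clip(idx + half + 1, 0, c.size)
    local = (csum[hi] - csum[lo]) / (hi - lo)
    if np.any(local <= 0):
        raise ValueError("local mean is non-positive; cannot detrend")
    out = c / local
    out *= float(np.mean(c)) / float(np.mean(out))  # preserve the global mean exactly
    return IntensityTrace(sample_interval=trace.sample_interval, counts=out)


def _direct_autocorrelation(c: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """O(N^2) reference estimator: G(k) = mean(dF_t dF_{t+k}) / mean(F)^2."""
    mean = c.mean()
    d = c - mean
    lags = np.arange(1, max_lag + 1)
    g = np.empty(lags.size)
    for j, k in enumerate(lags):
        g[j] = np.mean(d[:-k] * d[k:]) / mean**2
    return lags.astype(float), g


def _multi_tau_lags_g(d: np.ndarray, norm: float, dt: float, m: int):
    """Multi-tau ladder on mean-subtracted data ``d``; returns (lags, g)."""
    lags: list[float] = []
    g: list[float] = []
    # level 0: lags 1..2m at full resolution (matches the direct estimator)
    for k in range(1, 2 * m + 1):
        if k >= d.size:
            break
        lags.append(k * dt)
        g.append(float(np.mean(d[:-k] * d[k:])) / norm)
    # higher levels: pairwise binning, lags m+1..2m in binned units
    level_dt = dt
    dd = d
    while True:
        n2 = dd.size // 2
        if n2 < 2 * m + 1:
            break
        dd = 0.5 * (dd[: 2 * n2 : 2] + dd[1 : 2 * n2 : 2])
        level_dt *= 2.0
        for k in range(m + 1, 2 * m + 1):
            if k >= dd.size:
                break
            lags.append(k * level_dt)
            g.append(float(np.mean(dd[:-k] * dd[k:])) / norm)
    return np.asarray(lags), np.asarray(g)


def autocorrelate(
    trace: IntensityTrace,
    scheme: Literal["multi_tau", "direct"] = "multi_tau",
    m: int = 16,
    max_lag: int | None = None,
    n_segments: int = 8,
) -> CorrelationCurve:
    """Autocorrelate an intensity trace.

    ``direct`` evaluates the O(N^2) definition at every integer lag up to
    ``max_lag`` (default n_bins // 4) and serves as the oracle. ``multi_tau``
    evaluates the first ``2m`` lags at full resolution — identical to the
    direct estimator there — then repeatedly halves the time resolution by
    pairwise binning and adds ``m`` lags per octave, yielding logarithmic lag
    coverage out to roughly a quarter of the trace at O(N log N) cost.

    With ``n_segments >= 2`` (multi-tau only) a per-lag standard error is
    attached, estimated from the scatter of the correlation over that many
    disjoint sub-traces; lags longer than a sub-trace can resolve inherit
    the last resolved error scaled linearly with lag. Fitting with these
    weights keeps the strongly correlated long-lag estimator noise from
    masquerading as kinetic structure.
    """
    c = trace.counts.astype(float)
    if c.size < 1024:
        raise ValueError("need >= 1024 bins to autocorrelate")
    mean = c.mean()
    if mean == 0:
        raise ValueError("zero-mean trace: normalization undefined")
    dt = trace.sample_interval

    if scheme == "direct":
        ml = max_lag if max_lag is not None else c.size // 4
        lags, g = _direct_autocorrelation(c, ml)
        return CorrelationCurve(lag=lags * dt, g=g)

    if scheme != "multi_tau":
        raise ValueError(f"unknown scheme {scheme!r}")
    if m < 2 or m % 2:
        raise ValueError("m must be an even integer >= 2")

    d = c - mean
    lags, g = _multi_tau_lags_g(d, mean**2, dt, m)

    se = None
    if n_segments >= 2 and c.size // n_segments >= 4 * m:
        seg_len = c.size // n_segments
        seg_g = []
        for s in range(n_segments):
            seg = c[s * seg_len : (s + 1) * seg_len]
            sl, sg = _multi_tau_lags_g(seg - seg.mean(), seg.mean() ** 2, dt, m)
            seg_g.append(sg)
        n_shared = min(len(sg) for sg in seg_g)
        block = np.asarray([sg[:n_shared] for sg in seg_g])
        se_shared = block.std(axis=0, ddof=1) / math.sqrt(n_segments)
        # the per-lag scatter of only n_segments values is itself noisy; a
        # moving median across ~one octave of lags stabilizes the weights
        half_w = m // 2
        se_smooth = np.array(
            [
                np.median(se_shared[max(0, i - half_w) : i + half_w + 1])
                for i in range(n_shared)
            ]
        )
        se = np.empty_like(g)
        n_shared = min(n_shared, se.size)
        se[:n_shared] = se_smooth[:n_shared]
        if n_shared < se.size:  # extrapolate: estimator noise grows with lag
            se[n_shared:] = se_smooth[n_shared - 1] * (
                lags[n_shared:] / lags[n_shared - 1]
            )
        se = np.maximum(se, 1e-12)
    return CorrelationCurve(lag=lags, g=g, se=se)


def _model_eval(p, lag, n_components, omega):
    amp = 1.0 / (2.0**1.5 * p["N"])
    if n_components == 1:
        shape = (1.0 + lag / p["tau1"]) ** -1.0 * (1.0 + lag / (omega**2 * p["tau1"])) ** -0.5
    else:
        s1 = (1.0 + lag / p["tau1"]) ** -1.0 * (1.0 + lag / (omega**2 * p["tau1"])) ** -0.5
        s2 = (1.0 + lag / p["tau2"]) ** -1.0 * (1.0 + lag / (omega**2 * p["tau2"])) ** -0.5
        shape = p["f1"] * s1 + (1.0 - p["f1"]) * s2
    return amp * shape


def _finite_window_offset(p, n_components, omega, T, _grid={}):
    """First-order finite-acquisition bias of the correlation estimator.

    Estimating <F> from a record of length T depresses the measured
    correlation by approximately (2/T) * int_0^T (1 - s/T) G(s) ds at every
    lag; the offset is evaluated on the model itself (no free parameter).
    """
    key = round(float(T), 9)
    if key not in _grid:
        s = np.geomspace(T * 1e-7, T, 512)
        _grid[key] = s
    s = _grid[key]
    gs = _model_eval(p, s, n_components, omega) * (1.0 - s / T)
    integral = np.trapezoid(gs, s) + gs[0] / (1.0 - s[0] / T) * s[0]
    return 2.0 * integral / T


def _fcs_residual(p, lag, g, n_components, omega, window_s=None):
    model = _model_eval(p, lag, n_components, omega)
    if window_s is not None:
        model = model - _finite_window_offset(p, n_components, omega, window_s)
    return model - g


def _aicc(rss: float, n: int, k: int) -> float:
    # least-squares AIC with small-sample correction; k counts the noise variance
    kk = k + 1
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * kk
    if n - kk - 1 > 0:
        aic += 2 * kk * (kk + 1) / (n - kk - 1)
    return float(aic)


def fit_fcs(
    curve: CorrelationCurve,
    n_components: Literal[1, 2] = 1,
    omega: float = DEFAULT_OMEGA,
    weights: np.ndarray | None = None,
    acquisition_window_s: float | None = None,
) -> FcsFit:
    """Fit the one- or two-population autocorrelation model to a curve.

    ``omega`` is held fixed during the fit. Initialization uses the measured
    zero-lag amplitude for ``N`` and a deterministic grid of residence-time
    starts spanning the lag range; the best restart by residual sum of
    squares is kept, so the fit is deterministic given the curve. Two-
    population results are reported with ``tau1 <= tau2``.

    When ``acquisition_window_s`` (the trace duration T) is given, the fitted
    model includes the first-order finite-acquisition offset
    ``-(2/T) * int (1 - s/T) G(s) ds``: estimating the mean intensity from the
    same finite record depresses the measured correlation by that amount at
    every lag, which otherwise biases the slow residence time and fractions
    downward. The correction adds no free parameter.
    """
    lag, g = curve.lag, curve.g
    if lag.size < 15:
        raise ValueError("need >= 15 lag points")
    if np.log10(lag[-1] / lag[0]) < 2.0:
        raise ValueError("lags must span >= 2 decades")
    g0 = float(np.mean(g[: max(3, lag.size // 50)]))
    if g0 <= 0:
        raise ValueError("non-positive G(0) estimate; no correlation amplitude")
    n0 = 1.0 / (2.0**1.5 * g0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif curve.se is not None:
        w = 1.0 / curve.se
    else:
        w = np.ones_like(g)

    tau_grid = np.geomspace(lag[0] * 2, lag[-1] / 2, 6)
    if n_components == 1:
        starts = [(tau_a, None, None) for tau_a in tau_grid]
    else:
        # pairs spanning well-separated scales plus fraction variants: the
        # two-population surface has collapse basins (f1 -> 0 or 1) that a
        # single fraction start falls into on noisy curves
        starts = []
        for tau_a in tau_grid[:-1]:
            for sep in (8.0, 30.0):
                for f1_0 in (0.3, 0.6):
                    starts.append((tau_a, min(tau_a * sep, lag[-1] * 1e2), f1_0))
    best = None
    for tau_a, tau_b, f1_0 in starts:
        p = Parameters()
        p.add("N", value=n0, min=1e-6, max=1e9)
        p.add("tau1", value=tau_a, min=lag[0] * 1e-3, max=lag[-1] * 1e3)
        if n_components == 2:
            p.add("tau2", value=tau_b, min=lag[0] * 1e-3, max=lag[-1] * 1e3)
            p.add("f1", value=f1_0, min=0.0, max=1.0)
        try:
            res = minimize(
                lambda pp: w * _fcs_residual(pp, lag, g, n_components, omega, acquisition_window_s),
                p,
                method="least_squares",
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("FCS fit failed to converge from any start")

    rss = float(np.sum(np.asarray(best.residual) ** 2))

    def _se(name):
        s = best.params[name].stderr
        return float(s) if s is not None else float("nan")

    if n_components == 1:
        params = FcsOnePopParams(
            N=float(best.params["N"].value), tau=float(best.params["tau1"].value), omega=omega
        )
        se = {"N": _se("N"), "tau": _se("tau1")}
        model_id = "one_pop"
        k = 2
    else:
        t1, t2 = float(best.params["tau1"].value), float(best.params["tau2"].value)
        f1 = float(best.params["f1"].value)
        se1, se2, sef = _se("tau1"), _se("tau2"), _se("f1")
        if t1 > t2:  # canonical ordering; FcsTwoPopParams relabels too
            se1, se2, sef = se2, se1, sef
        params = FcsTwoPopParams(N=float(best.params["N"].value), tau1=t1, tau2=t2, f1=f1, omega=omega)
        se = {"N": _se("N"), "tau1": se1, "tau2": se2, "f1": sef}
        model_id = "two_pop"
        k = 4
    return FcsFit(
        model_id=model_id,
        params=params,
        param_se=se,
        rss=rss,
        n_points=int(lag.size),
        aicc=_aicc(rss, lag.size, k),
        success=bool(best.success),
        curve_id=id(curve),
        weighted_residuals=np.asarray(best.residual, dtype=float),
        message=str(best.message),
    )


@dataclass
class ModelSelectionReport:
    """One- vs two-population decision with both gate statistics."""

    selected: Literal["one_pop", "two_pop"]
    delta_aicc: float  # AICc(one_pop) - AICc(two_pop); large positive favors two_pop
    f_statistic: float
    f_p_value: float
    aicc_threshold: float
    f_p_threshold: float


def compare_fcs_models(
    fit1: FcsFit,
    fit2: FcsFit,
    aicc_threshold: float = 10.0,
    f_p_threshold: float = 0.01,
    min_component_fraction: float = 0.1,
    residual_thinning: int = 4,
) -> ModelSelectionReport:
    """Decide between one- and two-population fits of the same curve.

    The two-population model is selected only when BOTH the corrected-AIC
    difference exceeds ``aicc_threshold`` AND the nested-model F-test on the
    residual sums of squares rejects the one-population model at
    ``f_p_threshold``; ties and marginal evidence default to the simpler
    model (parsimony). A second population whose fitted fraction is below
    ``min_component_fraction`` is not considered resolved — fits that
    "detect" a few-percent component are almost always absorbing correlated
    estimator noise rather than kinetics — and the simpler model is kept.

    Neighboring multi-tau lags share data, so their residuals are strongly
    correlated; feeding all of them to AICc/F overstates the evidence.
    Both statistics are therefore evaluated on every ``residual_thinning``-th
    residual (roughly one independent point per quarter octave); the fits
    themselves always use the full grid.
    """
    one = fit1 if fit1.model_id == "one_pop" else fit2
    two = fit2 if fit2.model_id == "two_pop" else fit1
    if one.model_id != "one_pop" or two.model_id != "two_pop":
        raise ValueError("need exactly one one_pop and one two_pop fit")
    if one.curve_id != two.curve_id or one.n_points != two.n_points:
        raise ValueError("fits were not computed on the same curve")
    if (
        residual_thinning > 1
        and one.weighted_residuals is not None
        and two.weighted_residuals is not None
    ):
        r1 = one.weighted_residuals[::residual_thinning]
        r2 = two.weighted_residuals[::residual_thinning]
        rss_one, rss_two, n = float(np.sum(r1**2)), float(np.sum(r2**2)), r1.size
    else:
        rss_one, rss_two, n = one.rss, two.rss, one.n_points
    d_aicc = _aicc(rss_one, n, one.n_free_params) - _aicc(rss_two, n, two.n_free_params)
    df1 = two.n_free_params - one.n_free_params
    df2 = n - two.n_free_params
    if rss_two <= 0 or df2 <= 0:
        f_stat, f_p = np.inf, 0.0
    elif rss_one > rss_two:
        f_stat = ((rss_one - rss_two) / df1) / (rss_two / df2)
        f_p = float(stats.f.sf(f_stat, df1, df2))
    else:  # two-pop fit no better than one-pop: no evidence at all
        f_stat, f_p = 0.0, 1.0
    resolved = (
        isinstance(two.params, FcsTwoPopParams)
        and min(two.params.f1, 1.0 - two.params.f1) >= min_component_fraction
    )
    selected = (
        "two_pop"
        if (d_aicc >= aicc_threshold and f_p < f_p_threshold and resolved)
        else "one_pop"
    )
    return ModelSelectionReport(
        selected=selected,
        delta_aicc=float(d_aicc),
        f_statistic=float(f_stat),
        f_p_value=float(f_p),
        aicc_threshold=aicc_threshold,
        f_p_threshold=f_p_threshold,
    )


def _slow_tau(fit: FcsFit) -> float:
    return fit.params.tau2 if isinstance(fit.params, FcsTwoPopParams) else fit.params.tau


def residence_time_report(groups: dict[str, Sequence[FcsFit]]) -> dict:
    """Summarize residence times per condition and compare conditions pairwise.

    For two-population fits the slow residence time ``tau2`` (the bound,
    chromatin-engaged pool) is the compared quantity, alongside summaries of
    ``tau1`` and ``f1``; one-population fits contribute their single ``tau``.
    Pairwise comparisons are Welch two-tailed t-tests on the slow residence
    time.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    summary: dict[str, dict] = {}
    slow: dict[str, np.ndarray] = {}
    for label, fits in groups.items():
        if len(fits) == 0:
            raise ValueError(f"empty group {label!r}")
        taus = np.array([_slow_tau(f) for f in fits])
        slow[label] = taus
        entry = {
            "n": int(taus.size),
            "tau_slow_mean": float(np.mean(taus)),
            "tau_slow_sd": float(np.std(taus, ddof=1)) if taus.size > 1 else float("nan"),
        }
        two = [f.params for f in fits if isinstance(f.params, FcsTwoPopParams)]
        if two:
            entry["tau_fast_mean"] = float(np.mean([p.tau1 for p in two]))
            entry["f1_mean"] = float(np.mean([p.f1 for p in two]))
        summary[label] = entry
    pairwise = []
    labels = list(groups)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            if slow[a].size < 2 or slow[b].size < 2:
                raise ValueError("pairwise comparison needs >= 2 fits per group")
            t, p = stats.ttest_ind(slow[a], slow[b], equal_var=False)
            pairwise.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": float(np.mean(slow[a]) - np.mean(slow[b])),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return {"per_condition": summary, "pairwise": pairwise}
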