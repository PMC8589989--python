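"""Closed-form kinetic models for FRAP recovery and FCS autocorrelation.

Two limiting FRAP regimes are provided: a diffusion-limited recovery for a
uniform circular bleach (Soumpasis-type, written in terms of the characteristic
diffusion time ``tau_D`` across the bleached area) and a reaction-limited
recovery for first-order exchange at binding sites, parameterized by the
pseudo-first-order association rate ``k_on_prime`` (intrinsic on-rate times the
local binding-site concentration) and the dissociation rate ``k_off``.

FCS autocorrelation is modeled with one or two freely mixing populations of
mean occupancy ``N`` in the focal volume, each with a residence time ``tau``;
the structural parameter of the detection volume ``omega`` is a fixed shape
constant (default 6, never fitted). The zero-lag amplitude is
``G(0) = 1 / (2**1.5 * N)`` for both models.

All evaluators are pure, vectorized over time/lag grids, and validate their
parameters on construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "DiffusionFrapParams",
    "ReactionFrapParams",
    "FcsOnePopParams",
    "FcsTwoPopParams",
    "soumpasis_frap",
    "reaction_frap",
    "fcs_g",
    "params_to_json",
    "params_from_json",
]

#: Fixed structural parameter of the confocal focal volume.
DEFAULT_OMEGA = 6.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DiffusionFrapParams:
    """Diffusion-limited FRAP: characteristic diffusion time across the bleach ROI.

    Parameters
    ----------
    tau_D : float
        Characteristic diffusion time within the bleached area, seconds (> 0).
    """

    tau_D: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.tau_D) and self.tau_D > 0, "tau_D must be finite and > 0")


@dataclass(frozen=True)
class ReactionFrapParams:
    """Reaction-limited FRAP: first-order binding/unbinding at damage sites.

    Parameters
    ----------
    k_on_prime : float
        Pseudo-first-order association rate k_on * [BS], 1/s (>= 0).
    k_off : float
        Dissociation rate, 1/s (> 0). Its inverse is the bound residence time.
    """

    k_on_prime: float
    k_off: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.k_on_prime) and self.k_on_prime >= 0, "k_on_prime must be >= 0")
        _require(np.isfinite(self.k_off) and self.k_off > 0, "k_off must be > 0")

    @property
    def bound_fraction(self) -> float:
        """Equilibrium bound fraction k'_on / (k'_on + k_off)."""
        return self.k_on_prime / (self.k_on_prime + self.k_off)


@dataclass(frozen=True)
class FcsOnePopParams:
    """Single-population FCS autocorrelation parameters.

    ``N`` is the mean number of tagged molecules in the focal volume, ``tau``
    their residence time in seconds, ``omega`` the structural parameter of the
    focal volume (fixed shape constant, default 6).
    """

    N: float
    tau: float
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        _require(np.isfinite(self.N) and self.N > 0, "N must be > 0")
        _require(np.isfinite(self.tau) and self.tau > 0, "tau must be > 0")
        _require(np.isfinite(self.omega) and self.omega > 0, "omega must be > 0")


@dataclass(frozen=True)
class FcsTwoPopParams:
    """Two-population FCS autocorrelation parameters.

    Canonical ordering ``tau1 <= tau2`` is enforced on construction: if the
    supplied residence times are reversed, they are swapped and ``f1`` is
    relabeled to ``1 - f1`` so the parameter vector is unique (no label
    switching in fits).
    """

    N: float
    tau1: float
    tau2: float
    f1: float
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        _require(np.isfinite(self.N) and self.N > 0, "N must be > 0")
        _require(np.isfinite(self.tau1) and self.tau1 > 0, "tau1 must be > 0")
        _require(np.isfinite(self.tau2) and self.tau2 > 0, "tau2 must be > 0")
        _require(0.0 <= self.f1 <= 1.0, "f1 must lie in [0, 1]")
        _require(np.isfinite(self.omega) and self.omega > 0, "omega must be > 0")
        if self.tau1 > self.tau2:
            t1, t2 = self.tau2, self.tau1
            object.__setattr__(self, "tau1", t1)
            object.__setattr__(self, "tau2", t2)
            object.__setattr__(self, "f1", 1.0 - self.f1)


def soumpasis_frap(t, params: DiffusionFrapParams):
    """Diffusion-limited FRAP recovery fraction at time(s) ``t`` after the bleach.

    Evaluates ``exp(-x) * (I0(x) + I1(x))`` with ``x = tau_D / (2 t)`` and
    ``I0, I1`` the modified Bessel functions of the first kind. The scaled
    Bessel functions ``i0e``/``i1e`` are used so the product with ``exp(-x)``
    never overflows, however small ``t`` is. ``t = 0`` returns the limit 0.

    Parameters
    ----------
    t : array_like
        Time since bleach, seconds (>= 0).
    params : DiffusionFrapParams

    Returns
    -------
    ndarray or float
        Recovery fraction in (0, 1]; 0 exactly at t = 0.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    x = params.tau_D / (2.0 * t[pos])
    # i0e(x) + i1e(x) == exp(-x) * (I0(x) + I1(x))
    out[pos] = i0e(x) + i1e(x)
    if out.ndim == 0:
        return float(out)
    return out


def reaction_frap(t, params: ReactionFrapParams):
    """Reaction-limited FRAP recovery fraction at time(s) ``t`` after the bleach.

    ``frap(t) = 1 - (k'_on / (k'_on + k_off)) * exp(-k_off * t)``.
    At ``t = 0`` this equals the equilibrium free fraction
    ``k_off / (k'_on + k_off)`` (the bound, bleached pool has not yet
    exchanged); it relaxes to 1 with rate ``k_off``.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    out = 1.0 - params.bound_fraction * np.exp(-params.k_off * t)
    if out.ndim == 0:
        return float(out)
    return out


def _fcs_component(t: np.ndarray, tau: float, omega: float) -> np.ndarray:
    return (1.0 + t / tau) ** -1.0 * (1.0 + t / (omega**2 * tau)) ** -0.5


def fcs_g(t, params: FcsOnePopParams | FcsTwoPopParams):
    """FCS autocorrelation amplitude ``G`` at lag time(s) ``t``.

    One population::

        G(t) = (1 / (2**1.5 N)) (1 + t/tau)^-1 (1 + t/(omega^2 tau))^-1/2

    Two populations: the same zero-lag amplitude times the ``f1``-weighted sum
    of the two component shapes. ``G(0) = 1 / (2**1.5 N)`` in both cases.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "lag t must be >= 0")
    amp = 1.0 / (2.0**1.5 * params.N)
    if isinstance(params, FcsOnePopParams):
        shape = _fcs_component(t, params.tau, params.omega)
    elif isinstance(params, FcsTwoPopParams):
        shape = params.f1 * _fcs_component(t, params.tau1, params.omega) + (
            1.0 - params.f1
        ) * _fcs_component(t, params.tau2, params.omega)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported FCS parameter type: {type(params)!r}")
    out = amp * shape
    if out.ndim == 0:
        return float(out)
    return out


_MODEL_TAGS = {
    DiffusionFrapParams: "diffusion",
    ReactionFrapParams: "reaction",
    FcsOnePopParams: "fcs_one_pop",
    FcsTwoPopParams: "fcs_two_pop",
}
_TAG_MODELS = {v: k for k, v in _MODEL_TAGS.items()}


def params_to_json(params) -> dict:
    """Serialize any parameter set to a flat ``{model, params, omega}`` object."""
    tag = _MODEL_TAGS[type(params)]
    d = {k: float(v) for k, v in params.__dict__.items() if k != "omega"}
    obj = {"model": tag, "params": d}
    if hasattr(params, "omega"):
        obj["omega"] = float(params.omega)
    return obj


def params_from_json(obj: dict):
    """Inverse of :func:`params_to_json`."""
    cls = _TAG_MODELS[obj["model"]]
    kwargs = dict(obj["params"])
    if "omega" in obj and "omega" not in kwargs and hasattr(cls, "omega"):
        kwargs["omega"] = obj["omega"]
    return cls(**kwargs)
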