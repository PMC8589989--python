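"""Ground-truth particle simulator for FRAP, FCS, and imaging pipelines.

Brownian-dynamics particles diffuse in a 2D nuclear mid-plane (a reflecting
disk). Inside a damage region, free particles bind immobile sites according
to the first-order exchange scheme

    Free + BS  <-- k_off / k_on -->  Bound

with pseudo-first-order association rate ``k'_on = k_on * [BS]`` (the
binding-site field is unsaturable, matching the pseudo-first-order
assumption of the reaction-limited FRAP model). Per timestep the update
order is fixed: move, then bind/unbind with exact two-state probabilities
``1 - exp(-rate * dt)``, then detect. Photobleaching switches fluorophores
irreversibly dark inside a region of interest; photoactivation renders a
marker channel. Detection is either region-mean intensity traces (FRAP),
confocal point detection with a Gaussian lateral profile (FCS), or camera
rendering with Poisson and read noise (imaging stacks).

Every simulation is reproducible from ``(config, seed)``; the
:class:`GroundTruth` record derived from the config carries the values each
downstream fit is scored against.

Default parameters emulate the study conditions this package targets:
GFP-tagged Ku70-like mobility (D ~ 15 µm²/s) in a large flat nucleus
(U2OS-like, radius 7 µm), a 6 x 2 µm micro-irradiated stripe, exchange rates
k'_on = 0.3 /s and k_off = 0.1 /s, bleach spots of 1-4 µm² inside the
stripe, and 30 s FCS acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fcs import IntensityTrace
from .frap import FrapRecord
from .imaging import ImageStack, RoiMasks

__all__ = [
    "Disk",
    "Rect",
    "BleachEvent",
    "GaussianDetection",
    "CameraDetection",
    "SimulationConfig",
    "GroundTruth",
    "ParticleTrajectories",
    "simulate_particles",
    "simulate_frap_record",
    "simulate_fcs_trace",
    "simulate_track_stack",
    "frap_study_config",
    "fcs_study_config",
    "track_study_config",
    "config_to_json",
    "config_from_json",
]


# --------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class Disk:
    """Disk of radius ``radius`` centered at (cx, cy), µm."""

    cx: float
    cy: float
    radius: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        return (xy[..., 0] - self.cx) ** 2 + (xy[..., 1] - self.cy) ** 2 <= self.radius**2

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def bounding_radius(self) -> float:
        return math.hypot(self.cx, self.cy) + self.radius


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: |x - cx| <= half_x, |y - cy| <= half_y, µm."""

    cx: float
    cy: float
    half_x: float
    half_y: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        return (np.abs(xy[..., 0] - self.cx) <= self.half_x) & (
            np.abs(xy[..., 1] - self.cy) <= self.half_y
        )

    @property
    def area(self) -> float:
        return 4.0 * self.half_x * self.half_y

    @property
    def bounding_radius(self) -> float:
        return math.hypot(abs(self.cx) + self.half_x, abs(self.cy) + self.half_y)


Geometry = Disk | Rect


@dataclass(frozen=True)
class BleachEvent:
    """Instantaneous photobleach (or photoactivation) of a region at a time."""

    roi: Geometry
    time: float


@dataclass(frozen=True)
class GaussianDetection:
    """Confocal detection volume: 3D Gaussian profile.

    The weight of a molecule at (x, y, z) relative to the focus is
    ``exp(-2 (x² + y²) / waist² - 2 z² / (omega · waist)²)``: ``waist`` is the
    lateral 1/e² radius and ``omega`` the structural parameter (axial/lateral
    ratio) of the focal volume, matching its role in the correlation models.
    """

    waist: float = 0.25  # µm, lateral 1/e² radius
    omega: float = 6.0  # axial elongation of the focal volume
    brightness: float = 20000.0  # detected counts per second per molecule at focus
    background_rate: float = 1000.0  # counts per second
    sample_interval: float = 1e-3  # seconds per bin


@dataclass(frozen=True)
class CameraDetection:
    """Widefield/spinning-disk camera rendering parameters."""

    pixel_size: float = 0.1  # µm per pixel
    shape: tuple[int, int] = (120, 120)  # (Y, X)
    base_intensity: float = 400.0  # mean nuclear counts per pixel (SNR ~ sqrt of this)
    offset: float = 10.0  # camera offset, counts
    read_noise: float = 2.0  # Gaussian read noise sd, counts
    marker_amplitude: float = 100.0  # activated-marker counts per pixel


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation; ``seed`` is mandatory.

    ``k_on`` is the intrinsic association rate per binding-site concentration
    and ``binding_site_density`` the (dimensionless) site concentration
    inside the damage region, so the operative rate is
    ``k_on_prime = k_on * binding_site_density``.

    ``species``: optional mixture for FCS, a sequence of (fraction,
    diffusion_coefficient) pairs summing to 1; when absent, all particles
    share ``diffusion_coefficient``.
    """

    seed: int
    nucleus_radius: float = 7.0
    n_particles: int = 6000
    diffusion_coefficient: float = 15.0  # µm²/s
    damage_region: Geometry = Rect(0.0, 0.0, 3.0, 1.0)  # 6 x 2 µm stripe
    k_on: float = 0.3
    binding_site_density: float = 1.0
    k_off: float = 0.1
    dt: float = 0.025
    duration: float = 65.0
    frame_interval: float = 0.25
    bleach: BleachEvent | None = None
    activation: BleachEvent | None = None
    detection: GaussianDetection | CameraDetection | None = None
    acquisition_bleach_rate: float = 0.0  # 1/s, per-fluorophore dark conversion
    species: tuple[tuple[float, float], ...] | None = None
    binding_enabled: bool = True
    enrichment: float | None = None  # imaging stacks only
    intensity_scale: float = 1.0  # AU per (particle / µm²) for trace detection
    trace_offset: float = 10.0  # AU, added to every trace
    trace_read_noise: float = 1.0  # AU

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        kmax = max(self.k_on_prime, self.k_off)
        if self.binding_enabled and kmax > 0 and self.dt > 0.1 / kmax:
            raise ValueError(
                f"dt={self.dt} too coarse for rates: need dt <= {0.1 / kmax:.4g}"
            )
        if self.damage_region.bounding_radius > self.nucleus_radius + 1e-9:
            raise ValueError("damage_region must lie inside the nucleus")
        if self.species is not None:
            total = sum(f for f, _ in self.species)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("species fractions must sum to 1")
        if self.enrichment is not None and self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")

    @property
    def k_on_prime(self) -> float:
        return self.k_on * self.binding_site_density


@dataclass(frozen=True)
class GroundTruth:
    """True parameters a downstream fit should recover, derived from the config."""

    k_on_prime: float
    k_off: float
    diffusion_coefficient: float
    bound_fraction_eq: float
    fcs_residence_time: float | None = None
    enrichment: float | None = None
    bleach_area: float | None = None

    @staticmethod
    def from_config(cfg: SimulationConfig) -> "GroundTruth":
        kon, koff = cfg.k_on_prime, cfg.k_off
        bound = kon / (kon + koff) if (kon + koff) > 0 else 0.0
        tau = None
        if isinstance(cfg.detection, GaussianDetection):
            tau = cfg.detection.waist**2 / (4.0 * cfg.diffusion_coefficient)
        return GroundTruth(
            k_on_prime=kon,
            k_off=koff,
            diffusion_coefficient=cfg.diffusion_coefficient,
            bound_fraction_eq=bound,
            fcs_residence_time=tau,
            enrichment=cfg.enrichment,
            bleach_area=cfg.bleach.roi.area if cfg.bleach is not None else None,
        )


# --------------------------------------------------------------------------
# core Brownian stepper


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack((r * np.cos(th), r * np.sin(th)))


def _uniform_in(rng: np.random.Generator, n: int, geom: Geometry) -> np.ndarray:
    if isinstance(geom, Disk):
        xy = _uniform_disk(rng, n, geom.radius)
        xy[:, 0] += geom.cx
        xy[:, 1] += geom.cy
        return xy
    xy = rng.uniform(-1.0, 1.0, size=(n, 2))
    xy[:, 0] = geom.cx + xy[:, 0] * geom.half_x
    xy[:, 1] = geom.cy + xy[:, 1] * geom.half_y
    return xy


def _reflect_disk(xy: np.ndarray, radius: float) -> None:
    """Radially fold positions outside the nucleus back inside, in place."""
    r2 = xy[:, 0] ** 2 + xy[:, 1] ** 2
    out = r2 > radius**2
    if not out.any():
        return
    r = np.sqrt(r2[out])
    scale = (2.0 * radius - r) / r
    # a pathologically long step could over-fold; clamp to the boundary
    scale = np.where(scale < 0, radius / r, scale)
    xy[out, 0] *= scale
    xy[out, 1] *= scale


def _equilibrium_init(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and bound states sampled from the binding steady state.

    At equilibrium free particles are uniform over the nucleus at density
    ``c_f`` and bound particles uniform over the damage region at density
    ``c_f * k'_on / k_off``; the split of ``n_particles`` follows.
    """
    n = cfg.n_particles
    a_nuc = math.pi * cfg.nucleus_radius**2
    if cfg.binding_enabled and cfg.k_on_prime > 0 and cfg.k_off > 0:
        a_d = cfg.damage_region.area
        ratio = cfg.k_on_prime / cfg.k_off
        n_bound = int(round(n * (a_d * ratio) / (a_nuc + a_d * ratio)))
    else:
        n_bound = 0
    pos = np.empty((n, 2))
    bound = np.zeros(n, dtype=bool)
    if n_bound:
        pos[:n_bound] = _uniform_in(rng, n_bound, cfg.damage_region)
        bound[:n_bound] = True
    pos[n_bound:] = _uniform_disk(rng, n - n_bound, cfg.nucleus_radius)
    return pos, bound


def _step_sigma(cfg: SimulationConfig) -> np.ndarray:
    """Per-particle per-axis step standard deviation sqrt(2 D dt)."""
    n = cfg.n_particles
    if cfg.species is None:
        return np.full(n, math.sqrt(2.0 * cfg.diffusion_coefficient * cfg.dt))
    sig = np.empty(n)
    start = 0
    for frac, d in cfg.species:
        cnt = int(round(frac * n))
        sig[start : start + cnt] = math.sqrt(2.0 * d * cfg.dt)
        start += cnt
    sig[start:] = sig[start - 1] if start else sig[0]
    return sig


def _advance(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    pos: np.ndarray,
    bound: np.ndarray,
    sigma: np.ndarray,
    p_bind: float,
    p_unbind: float,
) -> None:
    """One timestep in place: move free particles, then bind/unbind."""
    steps = rng.standard_normal(pos.shape) * sigma[:, None]
    free = ~bound
    pos[free] += steps[free]
    _reflect_disk(pos, cfg.nucleus_radius)
    if p_bind > 0 or p_unbind > 0:
        u = rng.uniform(size=bound.size)
        in_region = cfg.damage_region.contains(pos)
        newly_bound = free & in_region & (u < p_bind)
        u2 = rng.uniform(size=bound.size)
        released = bound & (u2 < p_unbind)
        bound[newly_bound] = True
        bound[released] = False


@dataclass
class ParticleTrajectories:
    """Recorded particle positions and binding states at sampled steps."""

    times: np.ndarray  # (S,)
    positions: np.ndarray  # (S, n, 2)
    bound: np.ndarray  # (S, n)


def simulate_particles(cfg: SimulationConfig, record_every: int = 1) -> ParticleTrajectories:
    """Run the Brownian-dynamics binding simulation and record trajectories.

    Particle count is conserved; the run is bit-reproducible from the seed.
    ``record_every`` subsamples the stored steps (the dynamics always run at
    ``cfg.dt``).
    """
    rng = np.random.default_rng(cfg.seed)
    pos, bound = _equilibrium_init(rng, cfg)
    sigma = _step_sigma(cfg)
    p_bind = 1.0 - math.exp(-cfg.k_on_prime * cfg.dt) if cfg.binding_enabled else 0.0
    p_unbind = 1.0 - math.exp(-cfg.k_off * cfg.dt) if cfg.binding_enabled else 0.0
    n_steps = int(round(cfg.duration / cfg.dt))
    rec_t, rec_p, rec_b = [], [], []
    for i in range(n_steps):
        _advance(rng, cfg, pos, bound, sigma, p_bind, p_unbind)
        if i % record_every == 0:
            rec_t.append((i + 1) * cfg.dt)
            rec_p.append(pos.copy())
            rec_b.append(bound.copy())
    return ParticleTrajectories(
        times=np.asarray(rec_t), positions=np.asarray(rec_p), bound=np.asarray(rec_b)
    )


# --------------------------------------------------------------------------
# FRAP


def simulate_frap_record(cfg: SimulationConfig) -> tuple[FrapRecord, GroundTruth]:
    """Simulate a FRAP acquisition and return the raw traces plus ground truth.

    The bleach switches every fluorophore inside ``cfg.bleach.roi``
    irreversibly dark at the bleach time. Traces are region-mean intensities
    in arbitrary units (particle surface density times ``intensity_scale``
    plus a camera offset and Gaussian read noise): the bleached ROI, the
    reference (the unbleached remainder of the damage region when the bleach
    sits inside it — the damage-site protocol — otherwise the whole
    nucleus), and a background region outside the cell. Optional acquisition
    photobleaching darkens each fluorophore with rate
    ``acquisition_bleach_rate``.
    """
    if cfg.bleach is None:
        raise ValueError("config must define a bleach event")
    if cfg.bleach.time < cfg.frame_interval:
        raise ValueError("bleach must occur after at least one recorded pre-frame")
    rng = np.random.default_rng(cfg.seed)
    pos, bound = _equilibrium_init(rng, cfg)
    fluor = np.ones(cfg.n_particles, dtype=bool)
    sigma = _step_sigma(cfg)
    p_bind = 1.0 - math.exp(-cfg.k_on_prime * cfg.dt) if cfg.binding_enabled else 0.0
    p_unbind = 1.0 - math.exp(-cfg.k_off * cfg.dt) if cfg.binding_enabled else 0.0
    p_acq = 1.0 - math.exp(-cfg.acquisition_bleach_rate * cfg.dt)

    roi = cfg.bleach.roi
    damage_protocol = bool(
        np.all(cfg.damage_region.contains(_uniform_in(np.random.default_rng(0), 256, roi)))
    )
    steps_per_frame = max(int(round(cfg.frame_interval / cfg.dt)), 1)
    n_steps = int(round(cfg.duration / cfg.dt))
    bleach_step = int(round(cfg.bleach.time / cfg.dt))

    times, roi_tr, ref_tr, bg_tr = [], [], [], []
    roi_area = roi.area
    if damage_protocol:
        ref_area = cfg.damage_region.area - roi_area
    else:
        ref_area = math.pi * cfg.nucleus_radius**2 - roi_area
    bleach_index = None

    def record(step: int) -> None:
        t = step * cfg.dt
        in_roi = roi.contains(pos)
        n_roi = int(np.count_nonzero(fluor & in_roi))
        if damage_protocol:
            in_ref = cfg.damage_region.contains(pos) & ~in_roi
        else:
            in_ref = ~in_roi
        n_ref = int(np.count_nonzero(fluor & in_ref))
        noise = rng.normal(0.0, cfg.trace_read_noise, size=3)
        times.append(t)
        roi_tr.append(cfg.trace_offset + cfg.intensity_scale * n_roi / roi_area + noise[0])
        ref_tr.append(cfg.trace_offset + cfg.intensity_scale * n_ref / ref_area + noise[1])
        bg_tr.append(cfg.trace_offset + noise[2])

    record(0)
    for i in range(1, n_steps + 1):
        _advance(rng, cfg, pos, bound, sigma, p_bind, p_unbind)
        if p_acq > 0:
            fluor &= rng.uniform(size=fluor.size) >= p_acq
        if i == bleach_step:
            fluor &= ~roi.contains(pos)
            bleach_index = len(times)  # next recorded frame is first post-bleach
        if i % steps_per_frame == 0:
            record(i)
    if bleach_index is None:
        raise ValueError("bleach time lies outside the simulated duration")

    record_out = FrapRecord(
        time=np.asarray(times),
        roi_trace=np.asarray(roi_tr),
        reference_trace=np.asarray(ref_tr),
        background_trace=np.asarray(bg_tr),
        bleach_index=bleach_index,
        bleach_area=roi_area,
        protocol_tag="damage-region-correction" if damage_protocol else "whole-nucleus-correction",
    )
    return record_out, GroundTruth.from_config(cfg)


# --------------------------------------------------------------------------
# FCS


def simulate_fcs_trace(cfg: SimulationConfig) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate a confocal FCS acquisition and return the binned count trace.

    Particles diffuse in a periodic box: laterally area-matched to the
    nucleus, axially a few focal depths tall (the focal spot is far from any
    boundary, so the wrap-around geometry is statistically equivalent and
    fully vectorizable). The detector at the box center weights each
    particle by the 3D Gaussian profile of :class:`GaussianDetection` and
    the per-bin expected count (signal plus background rate) is Poisson
    sampled. The lateral residence time of species with diffusion
    coefficient D is ``waist² / (4 D)``.
    """
    det = cfg.detection
    if not isinstance(det, GaussianDetection):
        raise ValueError("config must carry a GaussianDetection")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_particles
    dt = det.sample_interval
    n_bins = int(round(cfg.duration / dt))
    box_xy = cfg.nucleus_radius * math.sqrt(math.pi)  # side of area-matched box
    w_z = det.omega * det.waist
    box_z = 3.2 * w_z  # tall enough that axial wrap-around images are negligible

    if cfg.species is None:
        sigma = np.full(n, math.sqrt(2.0 * cfg.diffusion_coefficient * dt))
    else:
        sigma = np.empty(n)
        start = 0
        for frac, d in cfg.species:
            cnt = int(round(frac * n))
            sigma[start : start + cnt] = math.sqrt(2.0 * d * dt)
            start += cnt
        sigma[start:] = sigma[start - 1] if start else sigma[0]

    if n == 0 and det.background_rate == 0:
        raise ValueError("degenerate config: zero particles and zero background")
    box = np.array([box_xy, box_xy, box_z])
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    center = box / 2.0
    inv_w2 = 2.0 / det.waist**2
    inv_wz2 = 2.0 / w_z**2
    counts = np.empty(n_bins)
    chunk = 2048
    done = 0
    while done < n_bins:
        m = min(chunk, n_bins - done)
        steps = rng.standard_normal(size=(m, n, 3)) * sigma[None, :, None]
        traj = np.mod(pos[None, :, :] + np.cumsum(steps, axis=0), box[None, None, :])
        dx = traj[..., 0] - center[0]
        dy = traj[..., 1] - center[1]
        dz = traj[..., 2] - center[2]
        w = np.exp(-inv_w2 * (dx * dx + dy * dy) - inv_wz2 * dz * dz)
        rate = det.brightness * w.sum(axis=1) + det.background_rate
        counts[done : done + m] = rng.poisson(rate * dt)
        pos = traj[-1]
        done += m
    return IntensityTrace(sample_interval=dt, counts=counts), GroundTruth.from_config(cfg)


# --------------------------------------------------------------------------
# imaging stacks


def simulate_track_stack(cfg: SimulationConfig) -> tuple[ImageStack, RoiMasks, GroundTruth]:
    """Render a two-channel micro-irradiation time-lapse with known truth.

    The protein channel shows a uniform nucleus whose damage region rises to
    the configured ``enrichment`` factor after the activation frame while the
    nucleoplasm is depleted so the nuclear total is conserved (protein
    redistributes, it is not created); the marker channel shows the
    photoactivated stripe appearing at the same frame. Pixels carry Poisson
    shot noise plus Gaussian read noise. Identical configs give identical
    stacks (and identical TIFF bytes when written).
    """
    det = cfg.detection if isinstance(cfg.detection, CameraDetection) else CameraDetection()
    if cfg.activation is None:
        raise ValueError("config must define an activation event")
    if cfg.enrichment is None:
        raise ValueError("config must set the enrichment factor")
    rng = np.random.default_rng(cfg.seed)
    ny, nx = det.shape
    # pixel-center coordinates, origin at image center, µm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * det.pixel_size
    xs = (np.arange(nx) - (nx - 1) / 2.0) * det.pixel_size
    xy = np.stack(np.meshgrid(xs, ys), axis=-1)  # (ny, nx, 2) -> (x, y)
    nucleus = Disk(0.0, 0.0, cfg.nucleus_radius).contains(xy)
    damage = cfg.activation.roi.contains(xy) & nucleus
    background = ~Disk(0.0, 0.0, cfg.nucleus_radius + 1.0).contains(xy)

    n_frames = int(round(cfg.duration / cfg.frame_interval))
    damage_frame = int(round(cfg.activation.time / cfg.frame_interval))
    if not 0 < damage_frame < n_frames:
        raise ValueError("activation time must leave pre- and post-activation frames")

    e = float(cfg.enrichment)
    phi = damage.sum() / nucleus.sum()
    depleted = 1.0 - phi * (e - 1.0) / (1.0 - phi)  # conserves the nuclear total
    if depleted < 0:
        raise ValueError("enrichment too large for mass conservation in this geometry")
    b = det.base_intensity
    protein = np.full((n_frames, ny, nx), det.offset, dtype=float)
    marker = np.full((n_frames, ny, nx), det.offset, dtype=float)
    protein[:, nucleus] += b
    for f in range(damage_frame, n_frames):
        protein[f][nucleus] = det.offset + b * depleted
        protein[f][damage] = det.offset + b * e
        marker[f][damage] += det.marker_amplitude

    for arr in (protein, marker):
        arr[:] = rng.poisson(arr).astype(float)
        arr += rng.normal(0.0, det.read_noise, size=arr.shape)

    stack = ImageStack(
        channels={"protein": protein, "marker": marker},
        pixel_size=det.pixel_size,
        frame_interval=cfg.frame_interval,
        damage_frame=damage_frame,
    )
    masks = RoiMasks(damage=damage, nucleus=nucleus, background=background)
    return stack, masks, GroundTruth.from_config(cfg)


# --------------------------------------------------------------------------
# study-condition constructors


def frap_study_config(seed: int, bleach_area: float = 1.0, **overrides) -> SimulationConfig:
    """Damage-site FRAP under the study conditions: a square bleach ROI of
    ``bleach_area`` µm² (1-4 µm² range) inside the 6 x 2 µm damaged stripe,
    k'_on = 0.3 /s, k_off = 0.1 /s, fast diffusion, 5 s of pre-bleach frames
    and 60 s of recovery at 4 frames/s."""
    half = math.sqrt(bleach_area) / 2.0
    base = dict(
        seed=seed,
        bleach=BleachEvent(roi=Rect(0.0, 0.0, half, half), time=5.0),
        duration=65.0,
        frame_interval=0.25,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def fcs_study_config(
    seed: int, two_species: bool = False, f1: float = 0.6, d_ratio: float = 20.0, **overrides
) -> SimulationConfig:
    """Confocal FCS under the study conditions: 30 s acquisition, 1 ms bins,
    0.25 µm waist, fast nuclear diffusion (D = 4 µm²/s). ``two_species``
    adds a slow population (D reduced by ``d_ratio``) at fraction ``1 - f1``,
    emulating a chromatin-bound pool."""
    d_fast = 4.0
    species = ((f1, d_fast), (1.0 - f1, d_fast / d_ratio)) if two_species else None
    base = dict(
        seed=seed,
        nucleus_radius=2.5,  # lateral extent of the simulated region around the spot
        n_particles=700,
        diffusion_coefficient=d_fast,
        species=species,
        detection=GaussianDetection(),
        duration=30.0,
        binding_enabled=False,
        damage_region=Rect(0.0, 0.0, 0.5, 0.5),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def track_study_config(seed: int, enrichment: float = 2.0, **overrides) -> SimulationConfig:
    """Micro-irradiation track imaging under the study conditions: a 6 x 1.5 µm
    activation stripe, frames every 5 s for 5 min, damage at 25 s, camera
    rendering at SNR ~ 20."""
    base = dict(
        seed=seed,
        nucleus_radius=5.0,
        activation=BleachEvent(roi=Rect(0.0, 0.0, 3.0, 0.75), time=25.0),
        enrichment=enrichment,
        detection=CameraDetection(),
        duration=300.0,
        frame_interval=5.0,
        binding_enabled=False,
        damage_region=Rect(0.0, 0.0, 3.0, 0.75),
    )
    base.update(overrides)
    return SimulationConfig(**base)


# --------------------------------------------------------------------------
# JSON round-trip for configs


def _geom_to_json(g: Geometry | None):
    if g is None:
        return None
    if isinstance(g, Disk):
        return {"shape": "disk", "cx": g.cx, "cy": g.cy, "radius": g.radius}
    return {"shape": "rect", "cx": g.cx, "cy": g.cy, "half_x": g.half_x, "half_y": g.half_y}


def _geom_from_json(obj):
    if obj is None:
        return None
    kind = obj["shape"]
    if kind == "disk":
        return Disk(obj["cx"], obj["cy"], obj["radius"])
    if kind == "rect":
        return Rect(obj["cx"], obj["cy"], obj["half_x"], obj["half_y"])
    raise ValueError(f"unknown geometry shape {kind!r}")


def config_to_json(cfg: SimulationConfig) -> dict:
    d = {
        "seed": int(cfg.seed),
        "nucleus_radius": cfg.nucleus_radius,
        "n_particles": cfg.n_particles,
        "diffusion_coefficient": cfg.diffusion_coefficient,
        "damage_region": _geom_to_json(cfg.damage_region),
        "k_on": cfg.k_on,
        "binding_site_density": cfg.binding_site_density,
        "k_off": cfg.k_off,
        "dt": cfg.dt,
        "duration": cfg.duration,
        "frame_interval": cfg.frame_interval,
        "acquisition_bleach_rate": cfg.acquisition_bleach_rate,
        "binding_enabled": cfg.binding_enabled,
        "enrichment": cfg.enrichment,
        "intensity_scale": cfg.intensity_scale,
        "trace_offset": cfg.trace_offset,
        "trace_read_noise": cfg.trace_read_noise,
        "species": None if cfg.species is None else [list(s) for s in cfg.species],
    }
    if cfg.bleach is not None:
        d["bleach"] = {"roi": _geom_to_json(cfg.bleach.roi), "time": cfg.bleach.time}
    if cfg.activation is not None:
        d["activation"] = {"roi": _geom_to_json(cfg.activation.roi), "time": cfg.activation.time}
    if isinstance(cfg.detection, GaussianDetection):
        d["detection"] = {"kind": "gaussian", **cfg.detection.__dict__}
    elif isinstance(cfg.detection, CameraDetection):
        d["detection"] = {"kind": "camera", **cfg.detection.__dict__, "shape": list(cfg.detection.shape)}
    return d


def config_from_json(obj: dict) -> SimulationConfig:
    obj = dict(obj)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "damage_region" in obj:
        obj["damage_region"] = _geom_from_json(obj["damage_region"])
    for key in ("bleach", "activation"):
        if obj.get(key) is not None:
            obj[key] = BleachEvent(roi=_geom_from_json(obj[key]["roi"]), time=obj[key]["time"])
    det = obj.get("detection")
    if det is not None:
        det = dict(det)
        kind = det.pop("kind")
        if kind == "gaussian":
            obj["detection"] = GaussianDetection(**det)
        elif kind == "camera":
            det["shape"] = tuple(det["shape"])
            obj["detection"] = CameraDetection(**det)
        else:
            raise ValueError(f"unknown detection kind {kind!r}")
    if obj.get("species") is not None:
        obj["species"] = tuple(tuple(s) for s in obj["species"])
    return SimulationConfig(**obj)
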