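"""Synthetic HS-AFM movies of nucleosome disassembly with full ground truth.

This module is the forward model for the whole pipeline: it renders
time-lapse height images (nm) of single nucleosomes / partially assembled
nucleosomal structures (PANS) on a Widom-601 construct with asymmetric
flanking DNA arms, undergoing stochastic stepwise disassembly

    chromatosome -> nucleosome -> hexasome -> tetrasome -> disome -> bare DNA

Every frame comes with a per-pixel class mask (background / NCP / DNA), the
exact event log, and the planted per-frame volumes and arm angles, so every
downstream stage can be tested against ground truth without real data.

Rendering model
---------------
* Histone core: spherical-cap height profile (apparent height ~4-6 nm).
  The cap's sphere radius is solved so that the *rendered, tip-convolved*
  particle integrates to the requested nominal volume — the volume scale of
  liquid-AFM imaging, which is what the species volume bands describe.
* DNA arms: discretised 2D worm-like chains (0.33 nm/bp) rendered as tubes
  of ~2 nm apparent height.
* Tip convolution: grayscale dilation with a spherical tip apex.
* Artifacts: per-scanline offsets, additive Gaussian height noise,
  frame-to-frame drift, and intermittent arm-segment dropout emulating
  transient desorption of the DNA from the mica.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

__all__ = [
    "SPECIES_LADDER",
    "DEFAULT_SPECIES_VOLUMES",
    "ConstructSpec",
    "MoleculeState",
    "DisassemblyEvent",
    "DisassemblySchedule",
    "TipModel",
    "NoiseModel",
    "SimulatedMovie",
    "NUC_200W100",
    "TET_100W50",
    "build_construct",
    "sample_schedule",
    "planted_schedule",
    "render_frame",
    "simulate_movie",
    "simulate_field",
    "cap_volume",
    "cap_sphere_radius",
    "schedule_to_volume_trace",
]

#: Disassembly ladder, heaviest species first.
SPECIES_LADDER = (
    "chromatosome",
    "nucleosome",
    "hexasome",
    "tetrasome",
    "disome",
    "bareDNA",
)

#: Apparent (liquid-imaging) volume scale per species, nm^3.  The first four
#: are measured band means; the disome value is a configurable placeholder
#: (no published mean exists for it).
DEFAULT_SPECIES_VOLUMES = {
    "chromatosome": 673.7,
    "nucleosome": 594.8,
    "hexasome": 470.2,
    "tetrasome": 351.7,
    "disome": 200.0,
    "bareDNA": 0.0,
}

#: nm of DNA released from the core per heterodimer ejection (~35 bp/side).
DEFAULT_RELEASED_BP = 35

#: Planted arm rotation (degrees) applied to the released side at each of
#: the first two ejections: ~90 deg on the short arm, then ~55 deg on the
#: long arm.
DEFAULT_ROTATIONS_DEG = (90.0, 55.0, 0.0, 0.0, 0.0)

BACKGROUND, NCP, DNA = 0, 1, 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructSpec:
    """DNA construct: a 601 positioning sequence with two flanking arms."""

    arm_bp_long: int = 200
    arm_bp_short: int = 100
    nps_bp: int = 147
    rise: float = 0.33          # nm per bp
    core_radius: float = 5.0    # histone core radius r, nm

    def __post_init__(self):
        if self.arm_bp_long < 0 or self.arm_bp_short < 0:
            raise ValueError("arm bp counts must be non-negative")
        if self.nps_bp <= 0 or self.rise <= 0 or self.core_radius <= 0:
            raise ValueError("nps_bp, rise and core_radius must be positive")

    @property
    def total_bp(self) -> int:
        return self.arm_bp_long + self.nps_bp + self.arm_bp_short

    @property
    def full_length_nm(self) -> float:
        """Contour length of the fully unwrapped DNA."""
        return self.total_bp * self.rise

    def arm_lengths_nm(self) -> tuple[float, float]:
        """(long, short) flanking-arm contour lengths, nm."""
        return self.arm_bp_long * self.rise, self.arm_bp_short * self.rise


NUC_200W100 = ConstructSpec(arm_bp_long=200, arm_bp_short=100)
TET_100W50 = ConstructSpec(arm_bp_long=100, arm_bp_short=50)


@dataclass
class MoleculeState:
    """Instantaneous geometry of one molecule."""

    species: str
    construct: ConstructSpec
    core_center: np.ndarray            # (y, x) nm
    core_height: float                 # apparent height, nm
    nominal_volume: float              # apparent volume, nm^3
    wrapped_bp_per_side: tuple[int, int]   # (long side, short side) still wrapped
    arm_paths: tuple[np.ndarray, np.ndarray] | None = None  # (long, short), (n,2) nm
    tetramer_offset: int = 0           # signed bp along the NPS


@dataclass(frozen=True)
class DisassemblyEvent:
    time_s: float
    transition: tuple[str, str]        # (from_species, to_species)
    mode: str                          # "sudden" | "gradual"
    side: str                          # "short" | "long" — which arm gains DNA


@dataclass
class DisassemblySchedule:
    events: list[DisassemblyEvent] = field(default_factory=list)

    def __post_init__(self):
        times = [e.time_s for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        ladder = list(SPECIES_LADDER)
        for e in self.events:
            i, j = ladder.index(e.transition[0]), ladder.index(e.transition[1])
            if j != i + 1:
                raise ValueError(f"transition {e.transition} violates the species ladder")

    def species_at(self, t: float, start: str) -> str:
        s = start
        for e in self.events:
            if t >= e.time_s:
                s = e.transition[1]
        return s


@dataclass(frozen=True)
class TipModel:
    """Spherical tip apex used for grayscale-dilation convolution."""

    tip_radius: float = 2.0  # nm

    def __post_init__(self):
        if self.tip_radius < 0:
            raise ValueError("tip_radius must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    height_sigma: float = 0.15       # additive pixel noise, nm
    line_offset_sigma: float = 0.05  # per-scanline offset, nm
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx) nm/frame
    arm_dropout_prob: float = 0.0    # per-arm, per-frame segment invisibility

    def __post_init__(self):
        if self.height_sigma < 0 or self.line_offset_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0.0 <= self.arm_dropout_prob <= 1.0:
            raise ValueError("arm_dropout_prob must be in [0, 1]")


NOISELESS = NoiseModel(0.0, 0.0, (0.0, 0.0), 0.0)


@dataclass
class SimulatedMovie:
    """Synthetic stack plus complete ground truth."""

    frames: np.ndarray          # (T, H, W) float32 heights, nm
    truth_masks: np.ndarray     # (T, H, W) uint8, 0/1/2
    pixel_size: float           # nm / px
    fps: float
    event_log: DisassemblySchedule
    true_volumes: np.ndarray    # nm^3 per frame (planted, noiseless)
    true_angles: np.ndarray     # (T, 2) degrees: (theta_long, theta_short)
    construct: ConstructSpec
    start_species: str = "nucleosome"
    seed: int | None = None

    def __post_init__(self):
        if self.frames.shape != self.truth_masks.shape:
            raise ValueError("stack and truth masks must have equal shapes")


# ---------------------------------------------------------------------------
# construct / schedule
# ---------------------------------------------------------------------------

def build_construct(
    spec: ConstructSpec,
    species: str = "nucleosome",
    core_center=(0.0, 0.0),
    core_height: float = 5.0,
    species_volumes: dict | None = None,
) -> MoleculeState:
    """Assemble the initial molecule geometry for a construct.

    Arm contour lengths are exactly ``arm_bp * rise``; the nominal volume is
    taken from the species volume table (apparent liquid-AFM scale).
    """
    if species not in SPECIES_LADDER:
        raise ValueError(f"unknown species {species!r}")
    vols = dict(DEFAULT_SPECIES_VOLUMES)
    if species_volumes:
        vols.update(species_volumes)
    half = spec.nps_bp // 2
    return MoleculeState(
        species=species,
        construct=spec,
        core_center=np.asarray(core_center, dtype=float),
        core_height=core_height,
        nominal_volume=vols[species],
        wrapped_bp_per_side=(half, spec.nps_bp - half),
        tetramer_offset=0,
    )


def sample_schedule(
    rates,
    seed=None,
    start_species: str = "nucleosome",
    gradual_prob: float = 0.5,
    t_max: float = math.inf,
) -> DisassemblySchedule:
    """Draw a stochastic disassembly schedule with exponential dwell times.

    Parameters
    ----------
    rates : mapping or sequence
        Per-transition rate constants (1/s), either a mapping
        ``{species: rate_of_leaving}`` or a sequence aligned with the ladder
        starting at ``start_species``.  A zero rate stops the ladder there.
    seed : int or numpy Generator
    start_species : first species on the ladder.
    gradual_prob : probability an ejection proceeds in the gradual mode.
    t_max : truncate events beyond this time.

    The first dimer release happens on the short-arm (rigid 601) side, the
    second on the long (flexible) side; later events alternate.
    """
    rng = np.random.default_rng(seed)
    ladder = list(SPECIES_LADDER)
    idx = ladder.index(start_species)
    chain = ladder[idx:]
    if isinstance(rates, dict):
        rate_list = [rates.get(s, 0.0) for s in chain[:-1]]
    else:
        rate_list = list(rates) + [0.0] * (len(chain) - 1 - len(rates))
    if any(r < 0 for r in rate_list):
        raise ValueError("rates must be >= 0")

    sides = ["short", "long"] * 3
    events, t = [], 0.0
    for k, (frm, to) in enumerate(zip(chain[:-1], chain[1:])):
        r = rate_list[k]
        if r == 0:
            break
        t += rng.exponential(1.0 / r)
        if t > t_max:
            break
        mode = "gradual" if rng.random() < gradual_prob else "sudden"
        events.append(DisassemblyEvent(t, (frm, to), mode, sides[k]))
    return DisassemblySchedule(events)


def planted_schedule(times_s, start_species="nucleosome", modes=None) -> DisassemblySchedule:
    """Deterministic schedule with events at the given times (ladder order)."""
    ladder = list(SPECIES_LADDER)
    idx = ladder.index(start_species)
    sides = ["short", "long"] * 3
    modes = list(modes) if modes is not None else ["sudden"] * len(times_s)
    events = [
        DisassemblyEvent(t, (ladder[idx + k], ladder[idx + k + 1]), modes[k], sides[k])
        for k, t in enumerate(times_s)
    ]
    return DisassemblySchedule(events)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def cap_volume(sphere_radius: float, h: float) -> float:
    """Closed-form spherical-cap volume, V = pi h^2 (3R - h) / 3."""
    return math.pi * h * h * (3.0 * sphere_radius - h) / 3.0


def cap_sphere_radius(volume: float, h: float) -> float:
    """Invert the closed form: sphere radius giving the requested cap volume."""
    return (3.0 * volume / (math.pi * h * h) + h) / 3.0


def _tip_structure(tip_radius: float, pixel_size: float):
    """Non-positive spherical tip apex sampled on the pixel grid."""
    if tip_radius <= 0:
        return None
    n = int(math.ceil(tip_radius / pixel_size))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1] * pixel_size
    rho2 = yy * yy + xx * xx
    tip = np.full(rho2.shape, -np.inf)
    inside = rho2 <= tip_radius**2
    tip[inside] = np.sqrt(tip_radius**2 - rho2[inside]) - tip_radius
    return tip


def _dilate(surface: np.ndarray, tip: TipModel, pixel_size: float) -> np.ndarray:
    """Grayscale dilation of the surface by the spherical tip apex:
    out[x] = max_u (surface[x - u] + tip[u])."""
    s = _tip_structure(tip.tip_radius, pixel_size)
    if s is None:
        return surface
    n = s.shape[0] // 2
    padded = np.pad(surface, n, mode="constant")
    out = surface.copy()
    H, W = surface.shape
    for di in range(-n, n + 1):
        for dj in range(-n, n + 1):
            t = s[di + n, dj + n]
            if not np.isfinite(t) or (di == 0 and dj == 0):
                continue
            shifted = padded[n + di:n + di + H, n + dj:n + dj + W]
            np.maximum(out, shifted + t, out=out)
    return np.maximum(out, 0.0)


def _cap_surface(shape, center_px, sphere_radius, h, pixel_size):
    """Height profile of a spherical cap (h <= R, i.e. at most a hemisphere)."""
    yy, xx = np.indices(shape)
    rho2 = ((yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2) * pixel_size**2
    a2 = h * (2.0 * sphere_radius - h)   # cap base radius squared
    z = np.sqrt(np.maximum(sphere_radius**2 - rho2, 0.0)) - (sphere_radius - h)
    z[rho2 > a2] = 0.0
    return np.maximum(z, 0.0)


@lru_cache(maxsize=512)
def _calibrated_cap(volume, h_max, tip_radius, pixel_size):
    """(sphere_radius, height) so the rendered, tip-dilated cap integrates
    to `volume` on the pixel grid.

    At the nominal height ``h_max`` the sphere radius is solved for the
    target volume; small volumes that cannot be reached even by a
    hemisphere of that height fall back to a hemisphere (R = h) of reduced
    height.  With a zero tip the closed form is used directly.
    """
    if volume <= 0:
        return 0.0, 0.0
    if tip_radius <= 0:
        r0 = cap_sphere_radius(volume, h_max)
        if r0 >= h_max:
            return r0, h_max
        h = (3.0 * volume / (2.0 * math.pi)) ** (1.0 / 3.0)  # hemisphere
        return h, h

    tip = TipModel(tip_radius)

    def rendered(r, h):
        a = math.sqrt(max(h * (2 * r - h), 0.0)) + tip_radius
        n = int(math.ceil(a / pixel_size)) + 3
        shape = (2 * n + 1, 2 * n + 1)
        surf = _cap_surface(shape, (n, n), r, h, pixel_size)
        return _dilate(surf, tip, pixel_size).sum() * pixel_size**2

    if rendered(h_max, h_max) <= volume:
        hi = max(cap_sphere_radius(volume, h_max), h_max) + 1.0
        while rendered(hi, h_max) < volume:
            hi *= 1.5
        r = brentq(lambda rr: rendered(rr, h_max) - volume,
                   h_max, hi, xtol=1e-3)
        return r, h_max
    # hemisphere of reduced height
    lo, hi = 2 * pixel_size, h_max
    if rendered(lo, lo) > volume:
        return lo, lo
    h = brentq(lambda hh: rendered(hh, hh) - volume, lo, hi, xtol=1e-3)
    return h, h


def _sample_wlc(rng, start, heading_deg, contour_nm, persistence_nm=50.0,
                step_nm=1.0, bounds=None, margin=4.0):
    """Discretised 2D worm-like chain from `start` (y, x nm) with initial
    heading (deg, CCW from +x with y = row axis).  Reflects at field bounds."""
    n = max(int(round(contour_nm / step_nm)), 1)
    pts = np.empty((n + 1, 2))
    pts[0] = start
    theta = math.radians(heading_deg)
    sigma = math.sqrt(step_nm / persistence_nm)
    for i in range(n):
        if rng is not None:
            theta += sigma * rng.standard_normal()
        step = np.array([math.sin(theta), math.cos(theta)]) * step_nm
        nxt = pts[i] + step
        if bounds is not None:
            for ax in (0, 1):
                if nxt[ax] < margin or nxt[ax] > bounds[ax] - margin:
                    if ax == 0:
                        theta = -theta
                    else:
                        theta = math.pi - theta
                    step = np.array([math.sin(theta), math.cos(theta)]) * step_nm
                    nxt = pts[i] + step
            nxt = np.clip(nxt, 0.5, np.array(bounds) - 0.5)
        pts[i + 1] = nxt
    return pts


def _tube_surface(shape, path_nm, pixel_size, height=2.0, half_width=2.0):
    """Render a DNA tube (semicircular cross-section) along a polyline."""
    canvas = np.zeros(shape, dtype=bool)
    if len(path_nm) >= 2:
        seg = np.diff(path_nm, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        n_dense = np.maximum((seglen / (0.4 * pixel_size)).astype(int), 1)
        dense = [path_nm[:1]]
        for i, m in enumerate(n_dense):
            t = np.linspace(0, 1, m + 1)[1:, None]
            dense.append(path_nm[i] + t * seg[i])
        dense = np.vstack(dense)
    else:
        dense = np.asarray(path_nm)
    ij = np.round(dense / pixel_size).astype(int)
    ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1])]
    if len(ij) == 0:
        return np.zeros(shape)
    canvas[ij[:, 0], ij[:, 1]] = True
    d_nm = ndimage.distance_transform_edt(~canvas) * pixel_size
    z = np.zeros(shape)
    inside = d_nm < half_width
    z[inside] = height * np.sqrt(1.0 - (d_nm[inside] / half_width) ** 2)
    return z


def render_frame(
    state: MoleculeState,
    tip: TipModel = TipModel(),
    noise: NoiseModel = NOISELESS,
    pixel_size: float = 1.9,
    shape=(200, 200),
    seed=None,
    dna_height: float = 2.0,
    dna_half_width: float = 2.0,
):
    """Render one molecule into a height frame plus its truth mask.

    Returns ``(frame, mask)`` where the mask labels every rendered pixel
    (0 background, 1 NCP, 2 DNA; NCP wins where both surfaces overlap).
    The noiseless maximum height equals ``state.core_height`` exactly when
    the core center sits on a grid point.
    """
    rng = np.random.default_rng(seed)
    center_px = np.asarray(state.core_center) / pixel_size
    if not (0 <= center_px[0] < shape[0] and 0 <= center_px[1] < shape[1]):
        raise ValueError("molecule core lies outside the frame")

    ncp, dna = _render_surfaces(state, tip, noise, pixel_size, shape, rng,
                                dna_height, dna_half_width)
    frame = np.maximum(ncp, dna)
    mask = np.zeros(shape, dtype=np.uint8)
    thresh = 0.05
    mask[(dna > thresh)] = DNA
    mask[(ncp > thresh) & (ncp >= dna)] = NCP
    frame = _apply_noise(frame, noise, rng)
    return frame.astype(np.float32), mask


def _render_surfaces(state, tip, noise, pixel_size, shape, rng,
                     dna_height=2.0, dna_half_width=2.0):
    """NCP and DNA height surfaces (tip-convolved, noiseless)."""
    ncp = np.zeros(shape)
    if state.nominal_volume > 0 and state.species != "bareDNA":
        R, h = _calibrated_cap(
            round(float(state.nominal_volume), 1), round(state.core_height, 3),
            round(tip.tip_radius, 3), round(pixel_size, 4))
        center_px = np.asarray(state.core_center) / pixel_size
        ncp = _cap_surface(shape, center_px, R, h, pixel_size)
        ncp = _dilate(ncp, tip, pixel_size)

    dna = np.zeros(shape)
    paths = state.arm_paths or ()
    for path in paths:
        if path is None or len(path) < 2:
            continue
        path = np.asarray(path, float)
        if noise.arm_dropout_prob > 0 and rng.random() < noise.arm_dropout_prob:
            # transient desorption: a random contiguous segment vanishes
            n = len(path)
            i0 = rng.integers(0, n - 1)
            i1 = min(n, i0 + max(2, int(0.3 * n)))
            path = np.delete(path, slice(i0, i1), axis=0)
            if len(path) < 2:
                continue
        tube = _tube_surface(shape, path, pixel_size, dna_height, dna_half_width)
        dna = np.maximum(dna, _dilate(tube, tip, pixel_size))
    return ncp, dna


def _apply_noise(frame, noise: NoiseModel, rng):
    if noise.line_offset_sigma > 0:
        frame = frame + rng.normal(0, noise.line_offset_sigma, (frame.shape[0], 1))
    if noise.height_sigma > 0:
        frame = frame + rng.normal(0, noise.height_sigma, frame.shape)
    return frame


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def schedule_to_volume_trace(
    schedule: DisassemblySchedule,
    fps: float,
    n_frames: int,
    start_species: str = "nucleosome",
    species_volumes: dict | None = None,
    gradual_duration_s: float = 1.5,
):
    """Planted per-frame nominal volume implied by a schedule.

    Sudden events drop between two consecutive frames; gradual events ramp
    linearly over ``gradual_duration_s``.  Returns ``(volumes, species)``.
    """
    vols = dict(DEFAULT_SPECIES_VOLUMES)
    if species_volumes:
        vols.update(species_volumes)
    t = np.arange(n_frames) / fps
    V = np.full(n_frames, vols[start_species], dtype=float)
    species = np.array([start_species] * n_frames, dtype=object)
    for e in schedule.events:
        v0, v1 = vols[e.transition[0]], vols[e.transition[1]]
        after = t >= e.time_s
        V[after] = v1
        species[after] = e.transition[1]
        if e.mode == "gradual" and gradual_duration_s > 0:
            ramp = after & (t < e.time_s + gradual_duration_s)
            frac = (t[ramp] - e.time_s) / gradual_duration_s
            V[ramp] = v0 + frac * (v1 - v0)
    return V, species


def simulate_movie(
    spec: ConstructSpec = NUC_200W100,
    schedule: DisassemblySchedule | None = None,
    fps: float = 1.0,
    n_frames: int = 100,
    tip: TipModel = TipModel(),
    noise: NoiseModel = NoiseModel(),
    seed=None,
    pixel_size: float = 1.9,
    shape=(200, 200),
    start_species: str = "nucleosome",
    species_volumes: dict | None = None,
    released_bp_per_event: int = DEFAULT_RELEASED_BP,
    rotations_deg=DEFAULT_ROTATIONS_DEG,
    gradual_duration_s: float = 1.5,
    core_height: float = 5.0,
    persistence_nm: float = 50.0,
    angle_jitter_deg: float = 5.0,
) -> SimulatedMovie:
    """Simulate a full labeled disassembly movie.

    The event log is the exact ground truth; ``true_volumes`` follows the
    schedule (gradual events interpolate over ``gradual_duration_s``) and
    ``true_angles`` records the planted (long, short) arm headings per frame.
    """
    rng = np.random.default_rng(seed)
    schedule = schedule or DisassemblySchedule([])
    duration = n_frames / fps
    if schedule.events and schedule.events[-1].time_s > duration:
        warnings.warn("schedule extends beyond the movie duration; truncating")
        schedule = DisassemblySchedule(
            [e for e in schedule.events if e.time_s <= duration])

    V, species_per_frame = schedule_to_volume_trace(
        schedule, fps, n_frames, start_species, species_volumes, gradual_duration_s)

    center0 = np.array([shape[0] * pixel_size / 2.0, shape[1] * pixel_size / 2.0])
    base_long = rng.uniform(0, 360)
    base_short = base_long + rng.uniform(120, 240)  # arms leave on roughly opposite sides

    frames = np.empty((n_frames,) + tuple(shape), dtype=np.float32)
    masks = np.empty((n_frames,) + tuple(shape), dtype=np.uint8)
    true_angles = np.empty((n_frames, 2))
    bounds_nm = (shape[0] * pixel_size, shape[1] * pixel_size)
    drift = np.asarray(noise.drift_per_frame, float)

    long0, short0 = spec.arm_lengths_nm()
    state = build_construct(spec, start_species, center0, core_height, species_volumes)
    event_times = [e.time_s for e in schedule.events]

    for f in range(n_frames):
        t = f / fps
        n_done = sum(1 for et in event_times if t >= et)
        rot_long = sum(r for k, r in enumerate(rotations_deg[:n_done])
                       if schedule.events[k].side == "long")
        rot_short = sum(r for k, r in enumerate(rotations_deg[:n_done])
                        if schedule.events[k].side == "short")
        rel_long = released_bp_per_event * sum(
            1 for k in range(n_done) if schedule.events[k].side == "long")
        rel_short = released_bp_per_event * sum(
            1 for k in range(n_done) if schedule.events[k].side == "short")

        th_long = base_long + rot_long + angle_jitter_deg * rng.standard_normal()
        th_short = base_short + rot_short + angle_jitter_deg * rng.standard_normal()
        true_angles[f] = (th_long % 360.0, th_short % 360.0)

        center = center0 + f * drift
        center = np.clip(center, 10.0, np.array(bounds_nm) - 10.0)
        sp = species_per_frame[f]
        if sp == "bareDNA":
            # one continuous free DNA molecule rendered as a single tube
            full = _sample_wlc(rng, center, th_long, spec.full_length_nm,
                               persistence_nm, bounds=bounds_nm)
            st = replace(state, species=sp, nominal_volume=0.0,
                         core_center=center, arm_paths=(full, None))
        else:
            r0 = spec.core_radius - 0.5
            start_l = center + r0 * np.array([math.sin(math.radians(th_long)),
                                              math.cos(math.radians(th_long))])
            start_s = center + r0 * np.array([math.sin(math.radians(th_short)),
                                              math.cos(math.radians(th_short))])
            path_l = _sample_wlc(rng, start_l, th_long,
                                 long0 + rel_long * spec.rise, persistence_nm,
                                 bounds=bounds_nm)
            path_s = _sample_wlc(rng, start_s, th_short,
                                 short0 + rel_short * spec.rise, persistence_nm,
                                 bounds=bounds_nm)
            st = replace(state, species=sp, nominal_volume=float(V[f]),
                         core_center=center, arm_paths=(path_l, path_s))
        frames[f], masks[f] = render_frame(
            st, tip, noise, pixel_size, shape, seed=rng.integers(2**31))

    return SimulatedMovie(frames, masks, pixel_size, fps, schedule,
                          V, true_angles, spec, start_species, seed)


# ---------------------------------------------------------------------------
# multi-molecule training fields
# ---------------------------------------------------------------------------

def simulate_field(
    n_molecules: int = 20,
    shape=(200, 200),
    pixel_size: float = 1.9,
    spec: ConstructSpec = NUC_200W100,
    tip: TipModel = TipModel(),
    noise: NoiseModel = NoiseModel(height_sigma=0.3, line_offset_sigma=0.0),
    seed=None,
    species_pool=("nucleosome", "hexasome", "tetrasome"),
    min_separation_nm: float = 50.0,
    core_height: float = 5.0,
):
    """Render a field of several molecules, as in a crowded AFM micrograph.

    With ~20 nucleosome-scale molecules on a 200x200 px field at 1.9 nm/px
    the class proportions land near the 89 / 3 / 7 % background / NCP / DNA
    balance of manually segmented training data.  Returns ``(frame, mask)``.
    """
    rng = np.random.default_rng(seed)
    bounds_nm = (shape[0] * pixel_size, shape[1] * pixel_size)
    margin = 25.0
    centers = []
    attempts = 0
    while len(centers) < n_molecules and attempts < 2000:
        attempts += 1
        c = rng.uniform([margin, margin],
                        [bounds_nm[0] - margin, bounds_nm[1] - margin])
        if all(np.hypot(*(c - p)) >= min_separation_nm for p in centers):
            centers.append(c)

    ncp_all = np.zeros(shape)
    dna_all = np.zeros(shape)
    long0, short0 = spec.arm_lengths_nm()
    for c in centers:
        sp = species_pool[rng.integers(len(species_pool))]
        th_l = rng.uniform(0, 360)
        th_s = th_l + rng.uniform(120, 240)
        r0 = spec.core_radius - 0.5
        paths = []
        for th, L in ((th_l, long0), (th_s, short0)):
            start = c + r0 * np.array([math.sin(math.radians(th)),
                                       math.cos(math.radians(th))])
            paths.append(_sample_wlc(rng, start, th, L, bounds=bounds_nm))
        st = MoleculeState(
            species=sp, construct=spec, core_center=c,
            core_height=core_height + rng.uniform(-0.5, 0.5),
            nominal_volume=DEFAULT_SPECIES_VOLUMES[sp],
            wrapped_bp_per_side=(spec.nps_bp // 2, spec.nps_bp - spec.nps_bp // 2),
            arm_paths=tuple(paths))
        ncp, dna = _render_surfaces(st, tip, NOISELESS, pixel_size, shape, rng)
        ncp_all = np.maximum(ncp_all, ncp)
        dna_all = np.maximum(dna_all, dna)

    frame = np.maximum(ncp_all, dna_all)
    mask = np.zeros(shape, dtype=np.uint8)
    thresh = 0.05
    mask[dna_all > thresh] = DNA
    mask[(ncp_all > thresh) & (ncp_all >= dna_all)] = NCP
    frame = _apply_noise(frame, noise, rng)
    return frame.astype(np.float32), mask
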