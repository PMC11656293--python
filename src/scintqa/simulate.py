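"""Synthetic pencil-beam-scanning delivery and two-view scintillation camera model.

This module is the stand-in for the physical measurement chain: a spot plan is
broken into low-intensity pulses (emulating a vendor feedback strategy that
delivers each pencil beam as several non-consecutive pulses spread over repeated
layer scans), and each pulse is rendered as one 16-bit camera frame showing a
direct view and a mirror view of the scintillation track, with perspective,
vignetting, shot/read noise, hot pixels and interleaved dark frames.

Coordinate conventions
----------------------
Isocenter frame: right-handed, beam travels vertically downward (-Z); the
scintillator cube is centered on the isocenter.  Image arrays are indexed
(row, column), 0-based; the row index increases with depth in the cube.  The
direct view occupies the right side of the sensor (column ~ Y), the mirror view
the left side (column ~ X), and the leftmost ``dark_margin_pixels`` columns see
only background.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpotPlan",
    "Spot",
    "Layer",
    "DeliveryConfig",
    "GeometryConfig",
    "Misalignment",
    "PulseRecord",
    "Frame",
    "FrameStack",
    "make_calibration_plan",
    "deliver",
    "render",
    "bragg_depth",
    "project_pulse",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spot:
    """One planned pencil beam: lateral position (mm), energy (MeV), intensity (MU)."""

    spot_id: int
    X: float
    Y: float
    E: float
    I: float


@dataclass(frozen=True)
class Layer:
    E: float
    spot_ids: tuple[int, ...]


@dataclass
class SpotPlan:
    """A spot plan: spots grouped into energy layers, in delivery order.

    Invariants (checked by :meth:`validate`): spot ids unique, every spot in
    exactly one layer, intensities positive, layer energies strictly monotone.
    """

    name: str
    range_shifter_wet_cm: float
    spots: list[Spot]
    layers: list[Layer]

    def validate(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spot ids in plan")
        layer_ids = [sid for lay in self.layers for sid in lay.spot_ids]
        if sorted(layer_ids) != sorted(ids):
            raise ValueError("spots and layer membership disagree")
        if len(set(layer_ids)) != len(layer_ids):
            raise ValueError("a spot belongs to more than one layer")
        if any(s.I <= 0 for s in self.spots):
            raise ValueError("spot intensities must be > 0")
        energies = [lay.E for lay in self.layers]
        if len(energies) > 1:
            diffs = np.diff(energies)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError("layer energies must be strictly monotone")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def spot_by_id(self, spot_id: int) -> Spot:
        for s in self.spots:
            if s.spot_id == spot_id:
                return s
        raise KeyError(spot_id)


@dataclass(frozen=True)
class DeliveryConfig:
    """Parameters of the pulsed delivery emulation.

    ``pulses_per_pb_range`` bounds the number of pulses one pencil beam is
    split into; ``pulse_intensity_cap`` is the hard per-pulse MU ceiling of the
    machine; ``dark_frame_fraction`` is the expected fraction of camera
    triggers that contain no beam; ``pulse_jitter`` (mm) and
    ``energy_jitter_mev`` are per-pulse Gaussian delivery scatter.
    """

    pulses_per_pb_range: tuple[int, int] = (3, 11)
    scans_per_layer: tuple[int, int] = (3, 4)
    pulse_intensity_cap: float = 0.13
    min_pulse_intensity: float = 1.5e-3
    dark_frame_fraction: float = 0.25
    pulse_jitter: float = 0.15
    energy_jitter_mev: float = 0.05
    frame_period: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pulses_per_pb_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("pulses_per_pb_range must lie within [1, 20]")
        if self.pulse_intensity_cap <= 0:
            raise ValueError("pulse_intensity_cap must be > 0")
        if not 0.0 <= self.dark_frame_fraction <= 1.0:
            raise ValueError("dark_frame_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry and optics of the cube + mirror + camera assembly.

    The cube has side ``cube_side`` mm; the camera sits ``camera_distance`` mm
    from its closest face.  The direct view spans ``direct_view_pixels`` pixels
    over one cube side at the closest face (apparent pixel ~435 um by default),
    the mirror view ``mirror_view_pixels`` (~600 um: the folded optical path is
    longer).  ``range_alpha``/``range_p`` are the Bragg-Kleeman range-energy
    constants (range [mm] = alpha * E^p in water) and
    ``range_shifter_wet_cm`` the water-equivalent slab pulling the peak into
    the cube.
    """

    cube_side: float = 100.0
    camera_distance: float = 320.0
    mirror_extra_path: float = 110.0
    direct_view_pixels: int = 230
    mirror_view_pixels: int = 167
    sensor_shape: tuple[int, int] = (256, 480)
    mirror_angle_deg: float = 45.0
    dark_margin_pixels: int = 30
    gaussian_psf_sd: float = 0.7
    vignetting_strength: float = 0.3
    perspective_strength: float = 1.0
    range_alpha: float = 0.022
    range_p: float = 1.77
    range_shifter_wet_cm: float = 7.4
    entrance_plateau_fraction: float = 0.35
    peak_sd_long: float = 4.0
    peak_sd_lat: float = 3.5
    counts_per_mu: float = 3.0e5
    mirror_reflectivity: float = 0.82
    pedestal: float = 100.0
    read_noise_sd: float = 2.0
    hot_pixel_rate: float = 1.0e-4
    noiseless: bool = False  # skip shot/read noise and hot pixels (diagnostics)

    def __post_init__(self) -> None:
        if min(self.cube_side, self.camera_distance) <= 0:
            raise ValueError("lengths must be > 0")
        if self.direct_view_pixels <= self.mirror_view_pixels:
            raise ValueError("direct view must have more pixels than mirror view")
        if self.dark_margin_pixels < 1:
            raise ValueError("dark_margin_pixels must be >= 1")

    # --- derived quantities -------------------------------------------------
    @property
    def direct_pixel_mm(self) -> float:
        """Apparent pixel size (mm) of the direct view at the closest cube face."""
        return self.cube_side / self.direct_view_pixels

    @property
    def mirror_pixel_mm(self) -> float:
        """Apparent pixel size (mm) of the mirror view at the closest cube face."""
        return self.cube_side / self.mirror_view_pixels

    @property
    def direct_bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) of the direct view region, half-open."""
        nrow, ncol = self.sensor_shape
        r0 = (nrow - self.direct_view_pixels) // 2
        c1 = ncol - 5
        return (r0, r0 + self.direct_view_pixels, c1 - self.direct_view_pixels, c1)

    @property
    def mirror_bounds(self) -> tuple[int, int, int, int]:
        nrow, ncol = self.sensor_shape
        r0 = (nrow - self.mirror_view_pixels) // 2
        direct_c0 = self.direct_bounds[2]
        free = direct_c0 - self.dark_margin_pixels - self.mirror_view_pixels
        if free < 2:
            raise ValueError("sensor too narrow for both views and the margin")
        c0 = self.dark_margin_pixels + free // 2  # centered in the free span
        return (r0, r0 + self.mirror_view_pixels, c0, c0 + self.mirror_view_pixels)

    def scaled(self, factor: float) -> "GeometryConfig":
        """Return a geometry with the sensor scaled by ``factor`` (same physics).

        Used to run the full chain at reduced resolution when the full-size
        sensor is not needed.
        """
        nrow, ncol = self.sensor_shape
        return replace(
            self,
            direct_view_pixels=max(2, round(self.direct_view_pixels * factor)),
            mirror_view_pixels=max(1, round(self.mirror_view_pixels * factor)),
            sensor_shape=(max(8, round(nrow * factor)), max(8, round(ncol * factor))),
            dark_margin_pixels=max(1, round(self.dark_margin_pixels * factor)),
        )

    def hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class Misalignment:
    """Rigid misplacement of the detector table relative to the machine.

    ``rotation_deg`` is a yaw about the vertical (beam) axis, ``pitch_deg`` a
    rotation about the lateral horizontal X axis, ``translation`` (dX, dY, dZ)
    in mm.  The identity misalignment is all zeros.
    """

    rotation_deg: float = 0.0
    pitch_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.pitch_deg == 0.0
            and self.translation == (0.0, 0.0, 0.0)
        )

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Rotation matrix and translation vector mapping machine -> table frame
        of a point, i.e. the transform applied rigidly to the irradiated scene
        as seen by the detector."""
        a = math.radians(self.rotation_deg)
        b = math.radians(self.pitch_deg)
        yaw = np.array(
            [[math.cos(a), -math.sin(a), 0.0],
             [math.sin(a), math.cos(a), 0.0],
             [0.0, 0.0, 1.0]]
        )
        pitch = np.array(
            [[1.0, 0.0, 0.0],
             [0.0, math.cos(b), -math.sin(b)],
             [0.0, math.sin(b), math.cos(b)]]
        )
        return yaw @ pitch, np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the rigid transform to an (n, 3) array of isocenter-frame points."""
        R, t = self.matrix()
        return points @ R.T + t


@dataclass(frozen=True)
class PulseRecord:
    """One machine log-file entry: a single delivered pulse."""

    timestamp: float  # ms
    X: float  # mm
    Y: float  # mm
    E: float  # MeV
    I: float  # MU
    pb_id: int
    layer_index: int
    scan_index: int


@dataclass(frozen=True)
class Frame:
    pixels: np.ndarray  # (H, W) uint16
    timestamp: float  # ms


@dataclass
class FrameStack:
    """A stack of 16-bit camera frames with per-frame timestamps."""

    pixels: np.ndarray  # (n, H, W) uint16
    timestamps: np.ndarray  # (n,) ms
    exposure_us: float = 990.0
    frequency_hz: float = 1000.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n, H, W)")
        if len(self.timestamps) != len(self.pixels):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def frames(self) -> list[Frame]:
        return [Frame(p, t) for p, t in zip(self.pixels, self.timestamps)]


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def make_calibration_plan(
    n_layers: int,
    spots_per_side: int,
    extent: float,
    energy_range: tuple[float, float],
    intensity: float = 1.0,
    range_shifter_wet_cm: float = 7.4,
    name: str = "calibration-grid",
) -> SpotPlan:
    """Build a uniform calibration grid: per layer, ``spots_per_side**2`` spots
    on a square grid over [-extent, +extent] mm; energies evenly spaced over
    ``energy_range`` (low to high in delivery order).
    """
    if n_layers < 1 or spots_per_side < 2:
        raise ValueError("need n_layers >= 1 and spots_per_side >= 2")
    if extent <= 0:
        raise ValueError("extent must be > 0")
    e_lo, e_hi = energy_range
    if e_hi < e_lo:
        raise ValueError("empty energy range")
    if n_layers == 1:
        energies = [0.5 * (e_lo + e_hi)]
    else:
        energies = list(np.linspace(e_lo, e_hi, n_layers))
    positions = np.linspace(-extent, extent, spots_per_side)
    spots: list[Spot] = []
    layers: list[Layer] = []
    sid = 0
    for E in energies:
        ids = []
        for y in positions:
            for x in positions:
                spots.append(Spot(sid, float(x), float(y), float(E), float(intensity)))
                ids.append(sid)
                sid += 1
        layers.append(Layer(float(E), tuple(ids)))
    plan = SpotPlan(name, range_shifter_wet_cm, spots, layers)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# pulsed delivery
# ---------------------------------------------------------------------------

def _split_intensity(
    I: float, cfg: DeliveryConfig, rng: np.random.Generator
) -> np.ndarray:
    """Partition a planned spot intensity into per-pulse intensities.

    The pulse count emulates the machine's feedback splitting: roughly
    ceil(I / cap_draw) with a randomized effective cap, clipped to the
    configured range but never so few that the hard per-pulse cap is violated,
    nor so many that pulses fall below the minimum deliverable intensity.
    """
    lo, hi = cfg.pulses_per_pb_range
    cap = cfg.pulse_intensity_cap
    if I <= cfg.min_pulse_intensity:
        return np.array([I])
    n_max_by_min = max(1, int(I / cfg.min_pulse_intensity))
    cap_draw = cap * rng.uniform(0.6, 1.0)
    n = int(np.clip(math.ceil(I / cap_draw), lo, hi))
    n = max(n, math.ceil(I / cap))  # hard cap wins over the range
    n = min(n, n_max_by_min)
    if n == 1:
        return np.array([I])
    # stick-breaking weights, rescaled to conserve I exactly
    w = rng.dirichlet(np.full(n, 8.0))
    parts = I * w
    # redistribute any excess above the hard cap
    for _ in range(100):
        over = parts > cap
        if not over.any():
            break
        excess = float(np.sum(parts[over] - cap))
        parts[over] = cap
        free = ~over
        parts[free] += excess * parts[free] / max(parts[free].sum(), 1e-300)
    # exact conservation: absorb rounding in the smallest pulse
    k = int(np.argmin(parts))
    parts[k] += I - parts.sum()
    return parts


def deliver(
    plan: SpotPlan,
    cfg: DeliveryConfig,
    mis: Misalignment | None = None,
) -> list[PulseRecord]:
    """Simulate the pulsed delivery of a plan and return the machine log.

    Each spot is split into pulses (intensity conserved to 1e-9 MU, each pulse
    at most ``pulse_intensity_cap``), spread round-robin over the repeated
    scans of its layer so that a pencil beam's pulses are not all consecutive.
    Timestamps advance on the ``frame_period`` grid; ticks are skipped at the
    dark-frame rate so that rendering one frame per tick reproduces the
    configured fraction of dark triggers.

    ``mis`` rigidly displaces the delivered spot positions (machine-side
    errors).  Table misplacement relative to the detector is instead modelled
    at render time (see :func:`render`), which leaves the log nominal as a real
    log-file would be.
    """
    plan.validate()
    cfg.validate()
    if not plan.spots:
        raise ValueError("plan is empty")
    rng = np.random.default_rng(cfg.rng_seed)
    mis = mis or Misalignment()

    records: list[PulseRecord] = []
    tick = 0
    d = cfg.dark_frame_fraction
    p_dark = min(d, 0.999)

    for layer_index, layer in enumerate(plan.layers):
        n_scans = int(rng.integers(cfg.scans_per_layer[0], cfg.scans_per_layer[1] + 1))
        # per-spot pulse intensities, assigned round-robin to scan passes
        per_scan: list[list[tuple[int, float]]] = [[] for _ in range(n_scans)]
        for sid in layer.spot_ids:
            spot = plan.spot_by_id(sid)
            parts = _split_intensity(spot.I, cfg, rng)
            order = rng.permutation(n_scans)
            for i, part in enumerate(parts):
                per_scan[order[i % n_scans]].append((sid, float(part)))
        for scan_index in range(n_scans):
            for sid, part in per_scan[scan_index]:
                spot = plan.spot_by_id(sid)
                pos = mis.apply(np.array([[spot.X, spot.Y, 0.0]]))[0]
                x = pos[0] + rng.normal(0.0, cfg.pulse_jitter)
                y = pos[1] + rng.normal(0.0, cfg.pulse_jitter)
                e = spot.E + rng.normal(0.0, cfg.energy_jitter_mev)
                # geometric number of dark ticks before this pulse
                while rng.random() < p_dark:
                    tick += 1
                records.append(
                    PulseRecord(
                        timestamp=tick * cfg.frame_period,
                        X=float(x),
                        Y=float(y),
                        E=float(e),
                        I=part,
                        pb_id=sid,
                        layer_index=layer_index,
                        scan_index=scan_index,
                    )
                )
                tick += 1
    return records


# ---------------------------------------------------------------------------
# optical forward model
# ---------------------------------------------------------------------------

def bragg_depth(E: float | np.ndarray, geom: GeometryConfig,
                range_shifter_wet_cm: float | None = None) -> float | np.ndarray:
    """Depth of the Bragg peak below the cube top face (mm) for energy E (MeV),
    from the Bragg-Kleeman power law minus the range-shifter water-equivalent
    thickness."""
    wet = geom.range_shifter_wet_cm if range_shifter_wet_cm is None else range_shifter_wet_cm
    return geom.range_alpha * np.asarray(E, dtype=float) ** geom.range_p - 10.0 * wet


def _magnification(dist_to_face: float, geom: GeometryConfig, extra: float) -> float:
    """Perspective magnification relative to the closest cube face."""
    L = geom.camera_distance + extra
    return L / (L + geom.perspective_strength * dist_to_face)


def project_pulse(
    X: float, Y: float, E: float, geom: GeometryConfig,
    mis: Misalignment | None = None,
) -> dict:
    """Project one pulse into sensor coordinates.

    Returns the direct-view and mirror-view (row, col) of the Bragg peak, the
    entry points, per-view magnification at the peak, and a ``shoot_through``
    flag when the peak falls beyond the cube.  ``mis`` is the table
    misplacement applied to the scene in the detector frame.
    """
    half = geom.cube_side / 2.0
    depth = float(bragg_depth(E, geom))
    shoot_through = not (0.0 < depth < geom.cube_side)
    depth_c = float(np.clip(depth, 0.0, geom.cube_side))
    # machine-frame track: entry at cube top (z=+half), peak at depth below it
    entry = np.array([X, Y, half])
    peak = np.array([X, Y, half - depth_c])
    if mis is not None and not mis.is_identity:
        entry, peak = mis.apply(np.vstack([entry, peak]))

    dr0, _, dc0, _ = geom.direct_bounds
    mr0, _, mc0, _ = geom.mirror_bounds

    def to_view(p: np.ndarray, view: str) -> tuple[float, float, float]:
        x, y, z = p
        d = half - z  # depth below the top face, mm
        if view == "D":
            m = _magnification(half - x, geom, 0.0)
            row = dr0 + (d * m) / geom.direct_pixel_mm
            col = dc0 + (geom.direct_view_pixels / 2.0) + (y * m) / geom.direct_pixel_mm
        else:
            m = _magnification(half - y, geom, geom.mirror_extra_path)
            row = mr0 + (d * m) / geom.mirror_pixel_mm
            col = mc0 + (geom.mirror_view_pixels / 2.0) + (x * m) / geom.mirror_pixel_mm
        return row, col, m

    rowD, colD, mD = to_view(peak, "D")
    rowD0, colD0, _ = to_view(entry, "D")
    rowM, colM, mM = to_view(peak, "M")
    rowM0, colM0, _ = to_view(entry, "M")
    return {
        "direct_peak": (rowD, colD),
        "direct_entry": (rowD0, colD0),
        "mirror_peak": (rowM, colM),
        "mirror_entry": (rowM0, colM0),
        "mag_direct": mD,
        "mag_mirror": mM,
        "depth": depth,
        "shoot_through": shoot_through,
    }


def _vignette(row: float, col: float, geom: GeometryConfig) -> float:
    nrow, ncol = geom.sensor_shape
    r2 = ((row - nrow / 2) / (nrow / 2)) ** 2 + ((col - ncol / 2) / (ncol / 2)) ** 2
    return 1.0 - geom.vignetting_strength * min(r2, 1.0) * 0.5 - 0.0


def _render_track(
    canvas: np.ndarray,
    bounds: tuple[int, int, int, int],
    entry: tuple[float, float],
    peak: tuple[float, float],
    amplitude: float,
    sd_long_px: float,
    sd_lat_px: float,
    plateau: float,
    shoot_through: bool,
    n_samples: int = 48,
) -> None:
    """Accumulate one scintillation track (plateau + Bragg peak) into a view.

    The track is sampled along the entry->peak segment; each sample deposits a
    2-D Gaussian of lateral sd ``sd_lat_px``.  The longitudinal weight is a
    plateau rising into a Gaussian peak at the end of range (suppressed for
    shoot-through pulses).
    """
    r0, r1, c0, c1 = bounds
    er, ec = entry
    pr, pc = peak
    track_len = math.hypot(pr - er, pc - ec)
    end_r = pr + (0.0 if shoot_through else 2.5 * sd_long_px) * (
        (pr - er) / max(track_len, 1e-9)
    )
    end_c = pc + (0.0 if shoot_through else 2.5 * sd_long_px) * (
        (pc - ec) / max(track_len, 1e-9)
    )
    ts = np.linspace(0.0, 1.0, n_samples)
    rows_s = er + ts * (end_r - er)
    cols_s = ec + ts * (end_c - ec)
    # longitudinal profile vs distance from the peak position
    dist_to_peak = np.hypot(rows_s - pr, cols_s - pc)
    w = np.full(n_samples, plateau)
    if not shoot_through:
        w = w + (1.0 - plateau) * np.exp(-0.5 * (dist_to_peak / sd_long_px) ** 2)
    # normalize so the deposited peak value ~ amplitude
    step = math.hypot(end_r - er, end_c - ec) / max(n_samples - 1, 1)
    w *= amplitude * step / (math.sqrt(2.0 * math.pi) * sd_lat_px)

    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    gr = np.exp(-0.5 * ((rows[None, :] - rows_s[:, None]) / sd_lat_px) ** 2)
    gc = np.exp(-0.5 * ((cols[None, :] - cols_s[:, None]) / sd_lat_px) ** 2)
    canvas[r0:r1, c0:c1] += np.einsum("k,kr,kc->rc", w, gr, gc)


def render(
    pulses: list[PulseRecord],
    geom: GeometryConfig,
    cfg: DeliveryConfig,
    mis: Misalignment | None = None,
    range_shifter_wet_cm: float | None = None,
) -> FrameStack:
    """Render one camera frame per trigger tick spanned by the pulse train.

    Ticks carrying a pulse get the two-view scintillation image; skipped ticks
    become dark frames.  ``mis`` is the table misplacement seen by the
    detector: the scene (not the log) is rigidly transformed.  Noise model:
    Poisson shot noise on signal + pedestal, Gaussian read noise, sparse hot
    pixels, clipped to 16 bits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0x5EED]))
    nrow, ncol = geom.sensor_shape
    geom_use = geom if range_shifter_wet_cm is None else replace(
        geom, range_shifter_wet_cm=range_shifter_wet_cm
    )

    if pulses:
        t0 = pulses[0].timestamp
        t1 = pulses[-1].timestamp
        n_ticks = int(round((t1 - t0) / cfg.frame_period)) + 1
        tick_times = t0 + cfg.frame_period * np.arange(n_ticks)
        pulse_at: dict[int, PulseRecord] = {
            int(round((p.timestamp - t0) / cfg.frame_period)): p for p in pulses
        }
    else:
        # pure dark acquisition: a short stack of noise frames
        n_ticks = 32
        tick_times = cfg.frame_period * np.arange(n_ticks)
        pulse_at = {}

    frames = np.empty((n_ticks, nrow, ncol), dtype=np.uint16)
    shoot_through_ts: list[float] = []

    sd_lat_D = geom_use.peak_sd_lat / geom_use.direct_pixel_mm
    sd_long_D = geom_use.peak_sd_long / geom_use.direct_pixel_mm
    sd_lat_M = geom_use.peak_sd_lat / geom_use.mirror_pixel_mm
    sd_long_M = geom_use.peak_sd_long / geom_use.mirror_pixel_mm

    for k in range(n_ticks):
        signal = np.zeros((nrow, ncol), dtype=float)
        p = pulse_at.get(k)
        if p is not None:
            proj = project_pulse(p.X, p.Y, p.E, geom_use, mis)
            if proj["shoot_through"]:
                shoot_through_ts.append(p.timestamp)
            amp = p.I * geom_use.counts_per_mu
            ampD = amp * proj["mag_direct"] ** 2 * _vignette(
                *proj["direct_peak"], geom_use
            )
            ampM = (
                amp
                * geom_use.mirror_reflectivity
                * proj["mag_mirror"] ** 2
                * _vignette(*proj["mirror_peak"], geom_use)
            )
            _render_track(
                signal, geom_use.direct_bounds, proj["direct_entry"],
                proj["direct_peak"], ampD, sd_long_D, sd_lat_D,
                geom_use.entrance_plateau_fraction, proj["shoot_through"],
            )
            _render_track(
                signal, geom_use.mirror_bounds, proj["mirror_entry"],
                proj["mirror_peak"], ampM, sd_long_M, sd_lat_M,
                geom_use.entrance_plateau_fraction, proj["shoot_through"],
            )
            if geom_use.gaussian_psf_sd > 0:
                from scipy.ndimage import gaussian_filter

                signal = gaussian_filter(signal, geom_use.gaussian_psf_sd)
        # margin columns carry background only
        signal[:, : geom_use.dark_margin_pixels] = 0.0
        if geom_use.noiseless:
            img = signal + geom_use.pedestal
        else:
            with np.errstate(over="ignore"):
                img = rng.poisson(signal + geom_use.pedestal).astype(float)
            img += rng.normal(0.0, geom_use.read_noise_sd, size=img.shape)
            # hot pixels from scattered radiation, anywhere on the sensor
            n_hot = rng.poisson(geom_use.hot_pixel_rate * nrow * ncol)
            if n_hot > 0:
                hr = rng.integers(0, nrow, n_hot)
                hc = rng.integers(0, ncol, n_hot)
                peak_scale = max(signal.max(), 50.0)
                img[hr, hc] = np.minimum(
                    rng.uniform(10.0, 50.0, n_hot) * peak_scale, 65535.0
                )
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    return FrameStack(
        pixels=frames,
        timestamps=tick_times,
        exposure_us=990.0,
        frequency_hz=1000.0 / cfg.frame_period,
        metadata={
            "geometry_hash": geom_use.hash(),
            "direct_bounds": list(geom_use.direct_bounds),
            "mirror_bounds": list(geom_use.mirror_bounds),
            "dark_margin_pixels": geom_use.dark_margin_pixels,
            "shoot_through_timestamps": shoot_through_ts,
            "n_pulse_triggers": len(pulse_at),
            "n_dark_triggers": n_ticks - len(pulse_at),
        },
    )
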