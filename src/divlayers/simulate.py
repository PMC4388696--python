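"""Ground-truth synthetic data generators for every analysis in the package.

Each generator emulates the statistical structure one of the measurements
assumes: cylindrical-shell "band" localizations for ring morphometry, paired
two-color channels with a known short-axis shift and registration error,
chromosome-anchored cluster radii under a Gaussian-radius or uniform-disk
model, axially resolved molecule layers above a dye-coated coverslip for
surface-referenced z estimation, fiducial-bead control points for channel
registration, and two-ROI fluorescence recovery traces.

All generators are deterministic given their ``seed`` (or an explicit
``numpy.random.Generator``); defaults are the study conditions of the
analyses they feed (ring FWHM 115 nm / diameter 689 nm, 20 nm lateral and
17 nm axial localization precision, 18 nm registration error, 2 s frame
interval with 120 frames and the bleach during frame 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locio import LocalizationTable

__all__ = [
    "FWHM_FACTOR",
    "RingSimParams",
    "TwoColorSimParams",
    "RadialSimParams",
    "FrapSimParams",
    "simulate_ring_band",
    "simulate_two_color",
    "simulate_radial_clusters",
    "simulate_ipalm_layers",
    "simulate_beads",
    "simulate_frap",
]

#: FWHM of a Gaussian = FWHM_FACTOR * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class RingSimParams:
    """Parameters of a band/ring localization sample.

    diameter and band_width are the ground-truth ring diameter d and the FWHM
    w of the molecule density along the cell's long axis; loc_precision and
    z_precision are the lateral and axial localization error s.d. (nm);
    background_density is a uniform background rate in counts per um^2 over
    ``field`` (nm x nm).
    """

    diameter: float = 689.0
    band_width: float = 115.0
    n_molecules: int = 600
    loc_precision: float = 20.0
    z_precision: float = 17.0
    background_density: float = 0.0
    field: tuple[float, float] = (2000.0, 2000.0)
    seed: int | None = None

    def __post_init__(self):
        if self.diameter <= 0 or self.band_width <= 0:
            raise ValueError("diameter and band_width must be positive")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.loc_precision < 0 or self.z_precision < 0:
            raise ValueError("precisions must be >= 0")


@dataclass
class TwoColorSimParams:
    """Two-color pair: channel 2 re-detects the channel-1 molecules, shifted
    by ``shift_y`` along the short axis with extra registration noise."""

    base: RingSimParams = field(default_factory=RingSimParams)
    shift_y: float = 0.0
    registration_sd: float = 18.0
    detection_efficiency: float = 1.0

    def __post_init__(self):
        if not (0 < self.detection_efficiency <= 1):
            raise ValueError("detection_efficiency must be in (0, 1]")
        if self.registration_sd < 0:
            raise ValueError("registration_sd must be >= 0")


@dataclass
class RadialSimParams:
    """Radial cluster placement model: ``gaussian`` (radius ~ N(mu_r, sigma_r),
    negative draws rejected) or ``disk`` (uniform over a disk of radius
    r_max); the angular position is uniform on [0, 2 pi)."""

    mode: str = "gaussian"
    mu_r: float = 280.0
    sigma_r: float = 120.0
    r_max: float = 419.0
    n_clusters: int = 613
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("gaussian", "disk"):
            raise ValueError("mode must be 'gaussian' or 'disk'")
        if self.mode == "gaussian" and self.sigma_r <= 0:
            raise ValueError("sigma_r must be > 0 in gaussian mode")
        if self.mode == "disk" and self.r_max <= 0:
            raise ValueError("r_max must be > 0 in disk mode")


@dataclass
class FrapSimParams:
    """FRAP acquisition and recovery parameters (defaults: 120 frames at 2 s,
    i.e. 30 frames/min for 4 min, photobleach during frame 2)."""

    halftime: float = 19.8
    frame_interval: float = 2.0
    n_frames: int = 120
    bleach_frame: int = 2
    bleach_depth: float = 0.8
    plateau: float = 0.8
    noise_sd: float = 0.05
    n_traces: int = 59
    seed: int | None = None

    def __post_init__(self):
        if self.halftime <= 0:
            raise ValueError("halftime must be > 0")
        if not (0 < self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.n_frames <= self.bleach_frame:
            raise ValueError("n_frames must exceed bleach_frame")


# ---------------------------------------------------------------------------
# ring / two-color


def _shell_positions(p: RingSimParams, rng: np.random.Generator):
    """True molecule positions on a cylindrical shell of radius d/2 about the
    long (x) axis: x ~ Gaussian with FWHM = band_width, (y, z) on the circle."""
    sigma_x = p.band_width / FWHM_FACTOR
    x = rng.normal(0.0, sigma_x, p.n_molecules)
    phi = rng.uniform(0.0, 2.0 * math.pi, p.n_molecules)
    radius = p.diameter / 2.0
    y = radius * np.cos(phi)
    z = radius * np.sin(phi)
    return x, y, z


def _background(p: RingSimParams, rng: np.random.Generator):
    area_um2 = (p.field[0] / 1000.0) * (p.field[1] / 1000.0)
    n_bg = rng.poisson(p.background_density * area_um2)
    bx = rng.uniform(-p.field[0] / 2, p.field[0] / 2, n_bg)
    by = rng.uniform(-p.field[1] / 2, p.field[1] / 2, n_bg)
    return bx, by


def simulate_ring_band(
    p: RingSimParams, dims: int = 2, seed=None, return_truth: bool = False
):
    """Simulate localizations of a band/ring structure in the cell frame.

    ``dims=2`` projects out z (wide-field PALM geometry) and adds lateral
    localization noise; ``dims=3`` keeps z and adds axial noise as well.
    Background localizations (if any) are uniform over the field.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    rng = _rng(p.seed if seed is None else seed)
    x, y, z = _shell_positions(p, rng)
    truth = pd.DataFrame({"x_nm": x, "y_nm": y, "z_nm": z})
    ox = x + rng.normal(0.0, p.loc_precision, len(x)) if p.loc_precision else x.copy()
    oy = y + rng.normal(0.0, p.loc_precision, len(y)) if p.loc_precision else y.copy()
    bx, by = _background(p, rng)
    cols = {
        "x_nm": np.concatenate([ox, bx]),
        "y_nm": np.concatenate([oy, by]),
    }
    if dims == 3:
        oz = z + rng.normal(0.0, p.z_precision, len(z)) if p.z_precision else z.copy()
        bz = rng.uniform(-p.diameter / 2, p.diameter / 2, len(bx))
        cols["z_nm"] = np.concatenate([oz, bz])
    n_total = len(cols["x_nm"])
    cols["frame"] = np.arange(n_total)
    cols["channel"] = np.full(n_total, "ch1")
    if p.loc_precision > 0:
        cols["precision_nm"] = np.full(n_total, p.loc_precision)
    table = LocalizationTable(pd.DataFrame(cols))
    if return_truth:
        return table, truth
    return table


def simulate_two_color(p: TwoColorSimParams, seed=None) -> LocalizationTable:
    """Simulate a two-color pair of the same underlying band structure.

    Channel 1 and channel 2 are independent detections (each molecule kept
    with ``detection_efficiency`` per channel, each with its own localization
    noise); channel 2 is additionally shifted by ``shift_y`` along the short
    axis and perturbed by isotropic registration noise of s.d.
    ``registration_sd``.
    """
    rng = _rng(p.base.seed if seed is None else seed)
    x, y, _ = _shell_positions(p.base, rng)
    prec = p.base.loc_precision
    frames = []
    for ch, (dy, extra_sd) in (
        ("ch1", (0.0, 0.0)),
        ("ch2", (p.shift_y, p.registration_sd)),
    ):
        if p.detection_efficiency < 1.0:
            keep = rng.random(len(x)) < p.detection_efficiency
        else:
            keep = np.ones(len(x), dtype=bool)
        cx = x[keep]
        cy = y[keep] + dy
        if prec > 0:
            cx = cx + rng.normal(0.0, prec, len(cx))
            cy = cy + rng.normal(0.0, prec, len(cy))
        if extra_sd > 0:
            cx = cx + rng.normal(0.0, extra_sd, len(cx))
            cy = cy + rng.normal(0.0, extra_sd, len(cy))
        df = pd.DataFrame(
            {
                "x_nm": cx,
                "y_nm": cy,
                "frame": np.flatnonzero(keep),
                "channel": ch,
            }
        )
        if prec > 0:
            df["precision_nm"] = prec
        frames.append(df)
    return LocalizationTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# radial cluster placement


def sample_rejected_gaussian_radius(
    mu: float, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n radii from N(mu, sigma) rejecting (redrawing) negative values."""
    r = rng.normal(mu, sigma, n)
    bad = r < 0
    while bad.any():
        r[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = r < 0
    return r


def simulate_radial_clusters(p: RadialSimParams, seed=None) -> pd.DataFrame:
    """Simulate cluster radial positions and their 2D-projected displacements.

    Returns a DataFrame with the true radius ``r_nm``, angular position
    ``phi_rad`` and the observable projected short-axis displacement
    ``r_prime_nm``.  In gaussian mode r' = |r cos(phi)|; in disk mode the
    cross-section point (y, z) is uniform on the disk and r' = |y|.
    """
    rng = _rng(p.seed if seed is None else seed)
    n = p.n_clusters
    if p.mode == "gaussian":
        r = sample_rejected_gaussian_radius(p.mu_r, p.sigma_r, n, rng)
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        r_prime = np.abs(r * np.cos(phi))
    else:
        # uniform over the disk: radius ~ R sqrt(u), angle uniform
        r = p.r_max * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        y = r * np.cos(phi)
        r_prime = np.abs(y)
    return pd.DataFrame({"r_nm": r, "phi_rad": phi, "r_prime_nm": r_prime})


# ---------------------------------------------------------------------------
# iPALM layers


def simulate_ipalm_layers(
    depths,
    z_precision: float = 17.0,
    surface_n: int = 1000,
    surface_fwhm: float = 10.0,
    field: tuple[float, float] = (2000.0, 2000.0),
    seed=None,
) -> LocalizationTable:
    """Simulate 3D localizations of molecule layers above a dye-coated surface.

    ``depths`` is a sequence of (z_nm, n) pairs; each layer is Gaussian about
    its depth with s.d. ``z_precision``.  The surface dye channel sits at
    z = 0 with a Gaussian spread of the given FWHM.  Channels are named
    ``surface`` and ``layer0``, ``layer1``, ...
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depths must be nonempty")
    if surface_fwhm <= 0:
        raise ValueError("surface_fwhm must be > 0")
    rng = _rng(seed)
    parts = []

    def _xy(n):
        return (
            rng.uniform(-field[0] / 2, field[0] / 2, n),
            rng.uniform(-field[1] / 2, field[1] / 2, n),
        )

    sx, sy = _xy(surface_n)
    parts.append(
        pd.DataFrame(
            {
                "x_nm": sx,
                "y_nm": sy,
                "z_nm": rng.normal(0.0, surface_fwhm / FWHM_FACTOR, surface_n),
                "channel": "surface",
            }
        )
    )
    for i, (depth, n) in enumerate(depths):
        lx, ly = _xy(int(n))
        lz = np.full(int(n), float(depth))
        if z_precision > 0:
            lz = lz + rng.normal(0.0, z_precision, int(n))
        parts.append(
            pd.DataFrame({"x_nm": lx, "y_nm": ly, "z_nm": lz, "channel": f"layer{i}"})
        )
    return LocalizationTable(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# fiducial beads


def simulate_beads(
    matrix=((1.0, 0.0), (0.0, 1.0)),
    offset=(0.0, 0.0),
    n_points: int = 300,
    noise_sd: float = 0.0,
    field: tuple[float, float] = (40000.0, 40000.0),
    seed=None,
) -> pd.DataFrame:
    """Simulate fiducial-bead control-point pairs across the field of view.

    Channel-1 positions are uniform over ``field``; channel-2 positions are
    the affine image (``matrix`` @ p + ``offset``) plus isotropic Gaussian
    noise of s.d. ``noise_sd`` added independently to both channels.
    Returns a DataFrame with columns x1, y1, x2, y2 (nm).
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = _rng(seed)
    matrix = np.asarray(matrix, dtype=float)
    offset = np.asarray(offset, dtype=float)
    p1 = np.column_stack(
        [
            rng.uniform(-field[0] / 2, field[0] / 2, n_points),
            rng.uniform(-field[1] / 2, field[1] / 2, n_points),
        ]
    )
    p2 = p1 @ matrix.T + offset
    if noise_sd > 0:
        p1 = p1 + rng.normal(0.0, noise_sd, p1.shape)
        p2 = p2 + rng.normal(0.0, noise_sd, p2.shape)
    return pd.DataFrame(
        {"x1": p1[:, 0], "y1": p1[:, 1], "x2": p2[:, 0], "y2": p2[:, 1]}
    )


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap(p: FrapSimParams, seed=None):
    """Simulate two-ROI FRAP traces.

    The bleach-ROI trace sits at the prebleach level (1.0) through the bleach
    frame, drops to ``1 - bleach_depth`` at the first post-bleach frame and
    recovers as floor + (plateau - floor) * (1 - exp(-k t')) with
    k = ln 2 / halftime and t' measured from the first post-bleach frame.
    The midcell-ROI trace is constant at the prebleach level.  Gaussian noise
    of s.d. ``noise_sd`` (fraction of prebleach) is added per frame to both.

    Returns a list of :class:`divlayers.frap.FrapTrace`.
    """
    from .frap import FrapTrace

    rng = _rng(p.seed if seed is None else seed)
    k = math.log(2.0) / p.halftime
    floor = 1.0 - p.bleach_depth
    frames = np.arange(1, p.n_frames + 1)
    first_post = p.bleach_frame + 1
    t_prime = (frames - first_post) * p.frame_interval
    clean = np.where(
        frames <= p.bleach_frame,
        1.0,
        floor + (p.plateau - floor) * (1.0 - np.exp(-k * np.maximum(t_prime, 0.0))),
    )
    traces = []
    for _ in range(p.n_traces):
        bleach = clean.copy()
        midcell = np.ones(p.n_frames)
        if p.noise_sd > 0:
            bleach = bleach + rng.normal(0.0, p.noise_sd, p.n_frames)
            midcell = midcell + rng.normal(0.0, p.noise_sd, p.n_frames)
        traces.append(
            FrapTrace(
                i_bleach=bleach,
                i_midcell=midcell,
                frame_interval=p.frame_interval,
                bleach_frame=p.bleach_frame,
            )
        )
    return traces
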