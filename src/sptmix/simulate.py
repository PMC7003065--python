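"""Synthetic single-molecule localization data for PALM tracking analysis.

Emulates sparse photoactivated emitters diffusing inside rod-shaped
(spherocylindrical) bacterial cells: each emitter belongs to one of a small
number of diffusive species, performs 2-D Brownian motion reflected at the
cell boundary, is observed with isotropic Gaussian localization noise, and
survives photobleaching for a geometrically distributed number of frames.

All lengths are in micrometres, times in seconds, diffusion coefficients in
um^2/s; frames are 0-based integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "SpeciesModel",
    "CellGeometry",
    "GroundTruth",
    "CONTROL_SPECIES",
    "DART_SPECIES",
    "sample_track_length",
    "reflect_at_boundary",
    "point_in_cell",
    "simulate_movie",
    "sample_tracks",
]

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/photophysics parameters of a simulated movie.

    Parameters
    ----------
    frame_interval
        Time between consecutive frames, seconds. Default 0.015 (15 ms).
    n_frames
        Movie length in frames. Default 10,000.
    localization_sigma
        Per-axis standard deviation of the localization error, micrometres.
        Default 0.035 (35 nm, typical for PAmCherry).
    activations_per_cell_per_frame
        Expected number of newly photoactivated emitters per cell per frame.
        The default 0.01 keeps at most ~1 emitter active per cell at a time,
        so frame-to-frame linking is unambiguous.
    survival_prob
        Per-frame probability that an active emitter remains visible
        (photobleaching survival). Default 0.6, giving a mean track length
        of 1/(1-0.6) = 2.5 frames.
    """

    frame_interval: float = 0.015
    n_frames: int = 10_000
    localization_sigma: float = 0.035
    activations_per_cell_per_frame: float = 0.01
    survival_prob: float = 0.6

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.activations_per_cell_per_frame < 0:
            raise ValueError("activations_per_cell_per_frame must be >= 0")
        if not (0 <= self.survival_prob < 1):
            raise ValueError("survival_prob must lie in [0, 1)")


@dataclass(frozen=True)
class SpeciesModel:
    """One diffusive species: mobility and population fraction."""

    diffusion_coefficient: float
    occupancy: float

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not (0 <= self.occupancy <= 1):
            raise ValueError("occupancy must lie in [0, 1]")


#: Three-species model of UvrB mobility under control conditions
#: (inactive toxin): immobile / slow / fast apparent mobilities with a
#: 16% immobile fraction.
CONTROL_SPECIES = (
    SpeciesModel(0.11, 0.16),
    SpeciesModel(0.41, 0.42),
    SpeciesModel(1.24, 0.42),
)

#: Same mobilities after active DarT expression: the immobile fraction rises
#: to 35%; the mobile remainder is split equally between slow and fast, as
#: in the control.
DART_SPECIES = (
    SpeciesModel(0.11, 0.35),
    SpeciesModel(0.41, 0.325),
    SpeciesModel(1.24, 0.325),
)


def _species_arrays(species: Sequence[SpeciesModel]) -> tuple[np.ndarray, np.ndarray]:
    if len(species) == 0:
        raise ValueError("species set must be non-empty")
    d = np.asarray([s.diffusion_coefficient for s in species], dtype=float)
    f = np.asarray([s.occupancy for s in species], dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"species occupancies must sum to 1, got {f.sum()!r}")
    return d, f


@dataclass(frozen=True)
class CellGeometry:
    """2-D spherocylinder (projected rod-shaped cell).

    The cell is a rectangle of half-length ``length/2`` and half-width
    ``radius``, capped by semicircles of the same radius, centred at the
    origin of its local frame with the long axis along x. Defaults are
    typical E. coli dimensions.
    """

    length: float = 2.0
    radius: float = 0.45
    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class GroundTruth:
    """Per-emitter truth emitted alongside a simulated localization table.

    ``emitters`` has one row per emitter
    (emitter_id, species_index, cell_id, activation_frame, bleach_frame);
    ``positions`` holds the true (noise-free) field coordinates, one row per
    emitter per observed frame.
    """

    emitters: pd.DataFrame
    positions: pd.DataFrame


def sample_track_length(
    survival_prob: float, rng: RngLike = None, size: Optional[int] = None
) -> Union[int, np.ndarray]:
    """Draw photobleaching-limited track lengths (frames), geometric with
    support >= 1.

    P(L = k) = (1 - q) * q**(k-1) with q = ``survival_prob``, so
    E[L] = 1/(1-q); the default acquisition q = 0.6 gives a mean of 2.5
    frames and P(L >= 5) = 0.6**4 ~ 13%.
    """
    if not (0 <= survival_prob < 1):
        raise ValueError("survival_prob must lie in [0, 1)")
    gen = _as_rng(rng)
    if survival_prob == 0:
        out = np.ones(size if size is not None else 1, dtype=np.int64)
    else:
        out = gen.geometric(1.0 - survival_prob, size=size if size is not None else 1)
    return out if size is not None else int(out[0])


def point_in_cell(points: np.ndarray, geometry: CellGeometry, atol: float = 0.0) -> np.ndarray:
    """Boolean point-in-spherocylinder test in the cell's local frame.

    ``points`` is (..., 2); returns a boolean array of the leading shape.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[..., 0], p[..., 1]
    half = geometry.length / 2.0
    r = geometry.radius + atol
    dx = np.abs(x) - half
    in_body = (dx <= 0) & (np.abs(y) <= r)
    in_cap = (dx > 0) & (dx**2 + y**2 <= r**2)
    return in_body | in_cap


def reflect_at_boundary(position: np.ndarray, geometry: CellGeometry) -> np.ndarray:
    """Mirror a point (or array of points) back inside the spherocylinder.

    Points already inside are returned unchanged; outside points are
    reflected across the nearest boundary segment, iterating until inside
    (one pass almost always suffices for diffusive step sizes).
    """
    p = np.array(position, dtype=float, copy=True)
    scalar = p.ndim == 1
    pts = p.reshape(-1, 2)
    half = geometry.length / 2.0
    r = geometry.radius

    for _ in range(64):
        inside = point_in_cell(pts, geometry)
        if inside.all():
            break
        out = ~inside
        x, y = pts[out, 0], pts[out, 1]
        body = np.abs(x) <= half
        # cylindrical wall: reflect across y = +/- r
        y[body] = np.sign(y[body]) * (2 * r - np.abs(y[body]))
        # hemispherical caps: reflect radially about the cap circle
        cap = ~body
        cx = np.sign(x[cap]) * half
        vx, vy = x[cap] - cx, y[cap]
        d = np.hypot(vx, vy)
        d = np.where(d == 0, 1e-300, d)
        scale = np.abs(2 * r - d) / d
        x[cap] = cx + vx * scale
        y[cap] = vy * scale
        pts[out, 0] = x
        pts[out, 1] = y
    else:  # pragma: no cover - pathological step sizes only
        bad = ~point_in_cell(pts, geometry)
        pts[bad] *= (r * 0.99) / np.hypot(pts[bad, 0], pts[bad, 1])[:, None]

    return pts[0] if scalar else pts.reshape(np.shape(position))


def _uniform_in_cell(n: int, geometry: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the spherocylinder, by rejection from the
    bounding box."""
    half = geometry.length / 2.0
    r = geometry.radius
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        cand = rng.uniform([-half - r, -r], [half + r, r], size=(m, 2))
        ok = cand[point_in_cell(cand, geometry)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def cell_offsets(geometry: CellGeometry) -> np.ndarray:
    """Field-frame origin of each cell: cells laid out on a grid with 1 um
    clearance, so cells never overlap."""
    n = geometry.n_cells
    ncols = max(1, int(math.ceil(math.sqrt(n))))
    pitch_x = geometry.length + 2 * geometry.radius + 1.0
    pitch_y = 2 * geometry.radius + 1.0
    idx = np.arange(n)
    return np.column_stack(((idx % ncols) * pitch_x, (idx // ncols) * pitch_y))


def simulate_movie(
    acq: AcquisitionConfig,
    species: Sequence[SpeciesModel],
    geometry: CellGeometry,
    rng: RngLike = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one PALM movie: a localization table plus ground truth.

    Emitters photoactivate at Poisson-distributed times in each cell, are
    assigned a species by occupancy, diffuse by reflected 2-D Brownian steps
    with per-axis step s.d. sqrt(2*D*dt), and bleach after a geometric
    lifetime. Reported positions add isotropic Gaussian localization noise.

    Returns
    -------
    locs : DataFrame
        Columns ``frame, cell_id, x_um, y_um, sigma_um``, sorted by frame
        then cell.
    truth : GroundTruth
    """
    gen = _as_rng(rng)
    d_arr, f_arr = _species_arrays(species)

    n_per_cell = gen.poisson(
        acq.activations_per_cell_per_frame * acq.n_frames, size=geometry.n_cells
    )
    total = int(n_per_cell.sum())
    cell_id = np.repeat(np.arange(geometry.n_cells), n_per_cell)
    activation = gen.integers(0, acq.n_frames, size=total)
    lifetime = sample_track_length(acq.survival_prob, gen, size=total) if total else np.empty(0, int)
    bleach = np.minimum(activation + lifetime - 1, acq.n_frames - 1)
    species_idx = gen.choice(len(species), size=total, p=f_arr)
    offsets = cell_offsets(geometry)

    step_sd = np.sqrt(2.0 * d_arr * acq.frame_interval)
    rows_true: list[np.ndarray] = []
    rec_emitter: list[np.ndarray] = []
    rec_frame: list[np.ndarray] = []
    starts = _uniform_in_cell(total, geometry, gen) if total else np.empty((0, 2))
    for e in range(total):
        n_obs = int(bleach[e] - activation[e] + 1)
        pos = np.empty((n_obs, 2))
        pos[0] = starts[e]
        sd = step_sd[species_idx[e]]
        if n_obs > 1:
            steps = gen.normal(0.0, sd, size=(n_obs - 1, 2)) if sd > 0 else np.zeros((n_obs - 1, 2))
            for i in range(1, n_obs):
                pos[i] = reflect_at_boundary(pos[i - 1] + steps[i - 1], geometry)
        rows_true.append(pos + offsets[cell_id[e]])
        rec_emitter.append(np.full(n_obs, e))
        rec_frame.append(np.arange(activation[e], bleach[e] + 1))

    if rows_true:
        true_xy = np.concatenate(rows_true)
        emitter_col = np.concatenate(rec_emitter)
        frame_col = np.concatenate(rec_frame)
    else:
        true_xy = np.empty((0, 2))
        emitter_col = np.empty(0, int)
        frame_col = np.empty(0, int)

    noise = (
        gen.normal(0.0, acq.localization_sigma, size=true_xy.shape)
        if acq.localization_sigma > 0
        else np.zeros_like(true_xy)
    )
    obs_xy = true_xy + noise

    locs = pd.DataFrame(
        {
            "frame": frame_col,
            "cell_id": cell_id[emitter_col] if total else np.empty(0, int),
            "x_um": obs_xy[:, 0],
            "y_um": obs_xy[:, 1],
            "sigma_um": np.full(len(frame_col), acq.localization_sigma),
        }
    )
    order = np.lexsort((emitter_col, locs["cell_id"].to_numpy(), locs["frame"].to_numpy()))
    locs = locs.iloc[order].reset_index(drop=True)

    truth = GroundTruth(
        emitters=pd.DataFrame(
            {
                "emitter_id": np.arange(total),
                "species_index": species_idx,
                "cell_id": cell_id,
                "activation_frame": activation,
                "bleach_frame": bleach,
            }
        ),
        positions=pd.DataFrame(
            {
                "emitter_id": emitter_col,
                "frame": frame_col,
                "x_um": true_xy[:, 0],
                "y_um": true_xy[:, 1],
            }
        ),
    )
    return locs, truth


def sample_tracks(
    n_tracks: int,
    species: Sequence[SpeciesModel],
    *,
    n_steps: int = 4,
    frame_interval: float = 0.015,
    localization_sigma: float = 0.0,
    geometry: Optional[CellGeometry] = None,
    rng: RngLike = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Directly generate ``n_tracks`` tracks of exactly ``n_steps`` steps.

    This is the fast path for studying the apparent-diffusion estimator and
    the mixture fit: it skips movie assembly and linking and produces tracks
    of the exact length the downstream analysis consumes. With
    ``geometry=None`` motion is unconfined (free Brownian); otherwise steps
    are reflected inside the cell as in :func:`simulate_movie`.

    Returns a track table (``track_id, cell_id, frame, x_um, y_um``) and the
    ground-truth species index per track.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    gen = _as_rng(rng)
    d_arr, f_arr = _species_arrays(species)
    labels = gen.choice(len(species), size=n_tracks, p=f_arr)
    sd = np.sqrt(2.0 * d_arr * frame_interval)[labels]

    n_loc = n_steps + 1
    steps = gen.normal(0.0, 1.0, size=(n_tracks, n_steps, 2)) * sd[:, None, None]
    pos = np.empty((n_tracks, n_loc, 2))
    if geometry is None:
        pos[:, 0] = 0.0
        pos[:, 1:] = np.cumsum(steps, axis=1)
    else:
        pos[:, 0] = _uniform_in_cell(n_tracks, geometry, gen)
        for i in range(n_steps):
            pos[:, i + 1] = reflect_at_boundary(pos[:, i] + steps[:, i], geometry)
    if localization_sigma > 0:
        pos = pos + gen.normal(0.0, localization_sigma, size=pos.shape)

    flat = pos.reshape(-1, 2)
    tracks = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_tracks), n_loc),
            "cell_id": np.zeros(n_tracks * n_loc, dtype=int),
            "frame": np.tile(np.arange(n_loc), n_tracks),
            "x_um": flat[:, 0],
            "y_um": flat[:, 1],
        }
    )
    return tracks, labels
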