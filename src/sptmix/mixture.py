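"""Apparent diffusion coefficients and finite-mixture decomposition.

For a track with consecutive-frame positions r_0..r_n, the apparent
diffusion coefficient is

    D* = MSD / (4 dt),   MSD = (1/n) * sum_i |r_{i+1} - r_i|^2,

using exactly the first ``n`` single-frame steps (n = 4 by default). For a
single freely diffusing species with true apparent mobility D, each squared
step is exponential with mean 4*D*dt, so D* — the mean of n such estimates
scaled by 1/(4 dt) — follows a gamma law with shape n and scale D/n:

    f(x | D, n) = (n/D)^n x^(n-1) exp(-n x / D) / (n-1)!

A population containing several species therefore yields a finite mixture
of such gamma densities; the fitter below maximizes the mixture
log-likelihood over species mobilities D_i and occupancies f_i by
expectation-maximization with multiple restarts. A constrained variant
holds the D_i fixed (e.g. to a reference condition's fit) and refits only
the occupancies, whose likelihood is concave, making that fit convex and
restart-free.

Localization noise is not subtracted from D* by default: an immobile
molecule localized with precision sigma has apparent mobility ~ sigma^2/dt,
which is how an "immobile" species acquires a small positive mobility. An
optional correction (subtracting sigma^2/dt) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .linking import Track

__all__ = [
    "ApparentDiffusion",
    "ClassificationThresholds",
    "MixtureFit",
    "compute_dstar",
    "compute_dstars",
    "dstar_density",
    "fit_mixture",
    "classify_dstar",
    "immobile_fraction",
]


@dataclass(frozen=True)
class ApparentDiffusion:
    """Per-track apparent diffusion estimate."""

    track_id: int
    d_star: float
    n_steps_used: int


@dataclass(frozen=True)
class ClassificationThresholds:
    """D* cut-offs separating immobile / slow / fast molecules (um^2/s)."""

    immobile_max: float = 0.2
    fast_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.immobile_max < self.fast_min):
            raise ValueError("need 0 < immobile_max < fast_min")


@dataclass
class MixtureFit:
    """Result of a gamma-mixture fit of a D* population.

    ``species`` is ordered by ascending mobility; ``fixed_d`` records the
    mobilities held constant during a constrained (occupancy-only) fit, or
    None for a free fit. ``loglik_history`` is the per-iteration
    log-likelihood trace of the winning restart.
    """

    species: List[Tuple[float, float]]
    n_steps: int
    log_likelihood: float
    n_tracks: int
    converged: bool
    fixed_d: Optional[List[float]] = None
    loglik_history: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        occ = np.array([f for _, f in self.species])
        if np.any(occ < -1e-9) or abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError("occupancies must lie in [0,1] and sum to 1")

    @property
    def diffusion_coefficients(self) -> np.ndarray:
        return np.array([d for d, _ in self.species])

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([f for _, f in self.species])


def compute_dstar(
    track: Track, frame_interval: float, n_steps: int = 4
) -> ApparentDiffusion:
    """Apparent diffusion coefficient of one track from its first
    ``n_steps`` consecutive-frame steps.

    Raises if the track is shorter than ``n_steps`` steps or if the frames
    used are not consecutive.
    """
    if track.n_steps < n_steps:
        raise ValueError(
            f"track {track.track_id} has {track.n_steps} steps; {n_steps} required"
        )
    frames = track.frames[: n_steps + 1]
    if np.any(np.diff(frames) != 1):
        raise ValueError(f"track {track.track_id}: frames are not consecutive")
    disp = np.diff(track.positions[: n_steps + 1], axis=0)
    msd = float(np.mean(np.sum(disp**2, axis=1)))
    return ApparentDiffusion(
        track_id=track.track_id,
        d_star=msd / (4.0 * frame_interval),
        n_steps_used=n_steps,
    )


def compute_dstars(
    tracks: Union[Sequence[Track], pd.DataFrame],
    frame_interval: float,
    n_steps: int = 4,
    sigma_correction: float = 0.0,
) -> pd.DataFrame:
    """Vectorized D* for a collection of tracks.

    Accepts a list of :class:`Track` or a long-form track table
    (``track_id, frame, x_um, y_um``). Every track must have at least
    ``n_steps`` consecutive-frame steps. ``sigma_correction`` (um) optionally
    subtracts the localization-noise floor sigma^2/dt from each estimate
    (clipped at zero).

    Returns a DataFrame ``track_id, d_star_um2_s, n_steps``.
    """
    if isinstance(tracks, pd.DataFrame):
        df = tracks.sort_values(["track_id", "frame"], kind="stable")
        tid = df["track_id"].to_numpy()
        frames = df["frame"].to_numpy()
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        tid = np.concatenate([np.full(len(t.frames), t.track_id) for t in tracks])
        frames = np.concatenate([t.frames for t in tracks])
        xy = np.concatenate([t.positions for t in tracks])

    ids, starts, counts = np.unique(tid, return_index=True, return_counts=True)
    if np.any(counts < n_steps + 1):
        short = ids[counts < n_steps + 1][0]
        raise ValueError(f"track {short} has fewer than {n_steps} steps")
    # index of each row within its track
    within = np.arange(len(tid)) - np.repeat(starts, counts)
    use = (within[:-1] < n_steps) & (tid[:-1] == tid[1:])
    if np.any(np.diff(frames)[use] != 1):
        raise ValueError("non-consecutive frames within the first steps of a track")
    sq = np.sum(np.diff(xy, axis=0) ** 2, axis=1)
    sq = np.where(use, sq, 0.0)
    msd = np.add.reduceat(np.append(sq, 0.0), starts) / n_steps
    d_star = msd / (4.0 * frame_interval)
    if sigma_correction > 0:
        d_star = np.clip(d_star - sigma_correction**2 / frame_interval, 0.0, None)
    return pd.DataFrame(
        {"track_id": ids, "d_star_um2_s": d_star, "n_steps": n_steps}
    )


def dstar_density(
    x: Union[float, np.ndarray], d: float, n_steps: int
) -> Union[float, np.ndarray]:
    """Sampling density of D* for one species: gamma with shape ``n_steps``
    and scale ``d / n_steps`` (mean d, variance d^2/n)."""
    if not d > 0:
        raise ValueError("d must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return stats.gamma.pdf(x, a=n_steps, scale=d / n_steps)


def _em_pass(
    x: np.ndarray, const: np.ndarray, d: np.ndarray, w: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """One E-step over R parallel restarts.

    ``x`` is (m,), ``const`` the data-dependent part of the log density
    ((n-1) log x - log (n-1)!), ``d``/``w`` are (R, k). Returns the
    responsibilities (R, m, k) and the per-restart log-likelihood (R,).
    """
    head = n * (math.log(n) - np.log(d)) + np.log(np.maximum(w, 1e-300))  # (R, k)
    log_joint = x[None, :, None] * (-n / d)[:, None, :]
    log_joint += head[:, None, :]
    log_joint += const[None, :, None]
    mx = log_joint.max(axis=2, keepdims=True)
    np.exp(log_joint - mx, out=log_joint)
    s = log_joint.sum(axis=2, keepdims=True)
    resp = log_joint / s
    ll = (np.log(s[:, :, 0]) + mx[:, :, 0]).sum(axis=1)
    return resp, ll


def fit_mixture(
    dstars: Union[pd.DataFrame, np.ndarray, Sequence[ApparentDiffusion]],
    k: int = 3,
    n_steps: int = 4,
    fixed_d: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Maximum-likelihood gamma-mixture fit of a D* population by EM.

    Parameters
    ----------
    dstars
        D* values: an array, a DataFrame with a ``d_star_um2_s`` column, or
        a sequence of :class:`ApparentDiffusion`.
    k
        Number of species.
    n_steps
        Gamma shape (number of steps used per track).
    fixed_d
        If given (length k), species mobilities are held at these values and
        only occupancies are fitted — the "constrained fit" used to compare
        conditions on a common set of species.
    seed, n_restarts
        The first restart initializes mobilities at k evenly spaced sample
        quantiles with equal occupancies; the remaining restarts draw
        mobilities log-uniformly in [0.01, 5] um^2/s. The best final
        likelihood wins.

    Convergence: log-likelihood improvement below ``tol`` for 3 consecutive
    iterations. Non-convergence is reported via ``converged=False``, never
    silently.
    """
    if isinstance(dstars, pd.DataFrame):
        x = dstars["d_star_um2_s"].to_numpy(dtype=float)
    elif len(dstars) and isinstance(dstars[0], ApparentDiffusion):
        x = np.array([a.d_star for a in dstars], dtype=float)
    else:
        x = np.asarray(dstars, dtype=float)
    m = len(x)
    if m < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for k={k}, got {m}")
    if np.any(x < 0):
        raise ValueError("d_star values must be >= 0")
    x = np.maximum(x, np.finfo(float).eps)  # jitter exact zeros

    if fixed_d is not None:
        if len(fixed_d) != k:
            raise ValueError("fixed_d must have length k")
        if np.any(np.asarray(fixed_d) <= 0):
            raise ValueError("fixed_d values must be > 0")
        # occupancy-only likelihood is concave: one restart suffices
        d = np.sort(np.asarray(fixed_d, dtype=float))[None, :]
        R = 1
    else:
        rng = np.random.default_rng(seed)
        R = max(1, n_restarts)
        d = np.empty((R, k))
        d[0] = np.quantile(x, (np.arange(k) + 0.5) / k)
        if R > 1:
            d[1:] = np.sort(
                np.exp(rng.uniform(math.log(0.01), math.log(5.0), size=(R - 1, k))),
                axis=1,
            )
        d = np.maximum(d, 1e-6)
    w = np.full((R, k), 1.0 / k)
    const = (n_steps - 1) * np.log(x) - gammaln(n_steps)

    prev_ll = np.full(R, -np.inf)
    slow_count = np.zeros(R, dtype=int)
    active = np.ones(R, dtype=bool)
    history: list[np.ndarray] = []
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        resp, ll_a = _em_pass(x, const, d[idx], w[idx], n_steps)
        nk = resp.sum(axis=1)  # (len(idx), k)
        w[idx] = nk / m
        if fixed_d is None:
            d_new = (resp * x[None, :, None]).sum(axis=1) / np.maximum(nk, 1e-300)
            d[idx] = np.maximum(np.where(nk > 0, d_new, d[idx]), 1e-9)
        slow_count[idx] = np.where(ll_a - prev_ll[idx] < tol, slow_count[idx] + 1, 0)
        prev_ll[idx] = ll_a
        history.append(prev_ll.copy())
        active[idx] = slow_count[idx] < 3
        if not active.any():
            break

    # final likelihood at the last parameter values
    _, ll = _em_pass(x, const, d, w, n_steps)
    best = int(np.argmax(ll))  # ties: first found
    order = np.argsort(d[best], kind="stable")
    species = [(float(d[best, i]), float(w[best, i])) for i in order]
    return MixtureFit(
        species=species,
        n_steps=n_steps,
        log_likelihood=float(ll[best]),
        n_tracks=m,
        converged=bool(slow_count[best] >= 3),
        fixed_d=list(np.sort(np.asarray(fixed_d, dtype=float))) if fixed_d is not None else None,
        loglik_history=np.array([h[best] for h in history]),
    )


def classify_dstar(
    d_star: float, thresholds: ClassificationThresholds = ClassificationThresholds()
) -> str:
    """Classify one D* value as ``immobile`` (< immobile_max), ``fast``
    (> fast_min) or ``slow`` (otherwise; thresholds themselves are slow)."""
    if d_star < thresholds.immobile_max:
        return "immobile"
    if d_star > thresholds.fast_min:
        return "fast"
    return "slow"


def immobile_fraction(
    source: Union[MixtureFit, pd.DataFrame, np.ndarray],
    method: str = "mixture",
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> float:
    """Percentage of immobile molecules.

    ``method="mixture"`` (default): 100 x the occupancy of the lowest-
    mobility species of a converged :class:`MixtureFit`. ``method=
    "threshold"``: 100 x the fraction of tracks with D* below
    ``thresholds.immobile_max`` (the per-track colouring rule).
    """
    if method == "mixture":
        if not isinstance(source, MixtureFit):
            raise TypeError("method='mixture' requires a MixtureFit")
        if not source.converged:
            raise ValueError(
                "mixture fit did not converge; refit or use method='threshold'"
            )
        return 100.0 * source.species[0][1]
    if method == "threshold":
        if isinstance(source, MixtureFit):
            raise TypeError("method='threshold' requires raw d_star values")
        x = (
            source["d_star_um2_s"].to_numpy(dtype=float)
            if isinstance(source, pd.DataFrame)
            else np.asarray(source, dtype=float)
        )
        if len(x) == 0:
            raise ValueError("no d_star values")
        return 100.0 * float(np.mean(x < thresholds.immobile_max))
    raise ValueError(f"unknown method {method!r}")
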