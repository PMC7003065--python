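"""Frame-to-frame linking of sparse localizations into tracks.

At PALM activation densities (at most ~1 active emitter per cell per frame)
a conservative greedy mutual-nearest-neighbour scheme with a hard
displacement gate is sufficient: a localization in frame f+1 is linked to a
track head in frame f only when each is the other's nearest candidate and
the displacement does not exceed ``max_displacement``. Links never cross
cell boundaries when ``restrict_to_cell`` is on. Singleton localizations
(never linked) are discarded; tracks have at least two localizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "LinkingConfig",
    "link_localizations",
    "filter_tracks_min_steps",
    "tracks_to_table",
    "table_to_tracks",
]


@dataclass
class Track:
    """Time-ordered positions of one molecule.

    ``frames`` is strictly increasing; ``positions`` is an (n, 2) array in
    micrometres with one row per frame.
    """

    track_id: int
    cell_id: int
    frames: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.frames) != len(self.positions) or len(self.frames) < 2:
            raise ValueError("a track needs >= 2 localizations, one position per frame")
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1


@dataclass(frozen=True)
class LinkingConfig:
    """Linking parameters.

    ``max_displacement`` (um/frame) defaults to 0.9, about three times the
    r.m.s. frame-to-frame displacement of the fastest species
    (3*sqrt(4*1.24*0.015) ~ 0.82 um). ``max_gap`` is the number of missed
    frames tolerated inside a track (0 = consecutive frames only).
    """

    max_displacement: float = 0.9
    max_gap: int = 0
    restrict_to_cell: bool = True

    def __post_init__(self) -> None:
        if not self.max_displacement > 0:
            raise ValueError("max_displacement must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def _link_group(
    frames: np.ndarray, xy: np.ndarray, cell: np.ndarray, cfg: LinkingConfig
) -> List[tuple[int, list[int]]]:
    """Link one cell's localizations; returns (cell_id, row-index list) per
    track candidate (including singletons, filtered by the caller)."""
    order = np.argsort(frames, kind="stable")
    frames, xy, cell = frames[order], xy[order], cell[order]
    # open tracks: list of [last_frame, row_indices]
    open_tracks: list[list] = []
    done: list[tuple[int, list[int]]] = []
    unique_frames = np.unique(frames)
    for f in unique_frames:
        sel = np.flatnonzero(frames == f)
        # retire tracks that can no longer be extended
        still = []
        for t in open_tracks:
            if f - t[0] > 1 + cfg.max_gap:
                done.append((int(cell[t[1][0]]), t[1]))
            else:
                still.append(t)
        open_tracks = still
        if not open_tracks:
            for i in sel:
                open_tracks.append([f, [int(i)]])
            continue
        heads = np.array([xy[t[1][-1]] for t in open_tracks])
        pts = xy[sel]
        dist = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=-1)
        dist[dist > cfg.max_displacement] = np.inf
        # mutual nearest neighbours; np.argmin breaks ties at the lowest
        # index, i.e. the earliest input row
        nearest_pt = dist.argmin(axis=1)
        nearest_head = dist.argmin(axis=0)
        matched_pts = set()
        for h, j in enumerate(nearest_pt):
            if np.isinf(dist[h, j]) or nearest_head[j] != h:
                continue
            open_tracks[h][0] = f
            open_tracks[h][1].append(int(sel[j]))
            matched_pts.add(j)
        for j, i in enumerate(sel):
            if j not in matched_pts:
                open_tracks.append([f, [int(i)]])
    done.extend((int(cell[t[1][0]]), t[1]) for t in open_tracks)
    return done


def link_localizations(locs: pd.DataFrame, cfg: LinkingConfig | None = None) -> List[Track]:
    """Assemble a localization table into tracks.

    ``locs`` must be sorted by frame and contain columns
    ``frame, x_um, y_um`` (and ``cell_id`` unless ``restrict_to_cell`` is
    off, in which case a missing column defaults to cell 0). Returns tracks
    with >= 2 localizations, numbered in order of first appearance.
    """
    cfg = cfg or LinkingConfig()
    frames = locs["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise ValueError("localization table must be sorted by frame")
    xy = locs[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("localization coordinates must be finite")
    cell = (
        locs["cell_id"].to_numpy()
        if "cell_id" in locs.columns
        else np.zeros(len(locs), dtype=int)
    )

    candidates: list[tuple[int, list[int]]] = []
    if cfg.restrict_to_cell:
        for c in np.unique(cell):
            m = cell == c
            idx = np.flatnonzero(m)
            got = _link_group(frames[m], xy[m], cell[m], cfg)
            candidates.extend((cid, [int(idx[i]) for i in rows]) for cid, rows in got)
    else:
        candidates = _link_group(frames, xy, cell, cfg)

    # deterministic numbering: by first localization row
    candidates.sort(key=lambda t: t[1][0])
    tracks: List[Track] = []
    for cid, rows in candidates:
        if len(rows) < 2:
            continue
        tracks.append(
            Track(
                track_id=len(tracks),
                cell_id=cid,
                frames=frames[rows],
                positions=xy[rows],
            )
        )
    return tracks


def filter_tracks_min_steps(tracks: Iterable[Track], min_steps: int = 4) -> List[Track]:
    """Keep tracks with at least ``min_steps`` steps (min_steps + 1
    localizations); order preserved."""
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    return [t for t in tracks if t.n_steps >= min_steps]


def tracks_to_table(tracks: Sequence[Track]) -> pd.DataFrame:
    """Long-form track table: ``track_id, cell_id, frame, x_um, y_um``."""
    if not tracks:
        return pd.DataFrame(
            {"track_id": [], "cell_id": [], "frame": [], "x_um": [], "y_um": []}
        ).astype({"track_id": int, "cell_id": int, "frame": int})
    return pd.DataFrame(
        {
            "track_id": np.concatenate([np.full(len(t.frames), t.track_id) for t in tracks]),
            "cell_id": np.concatenate([np.full(len(t.frames), t.cell_id) for t in tracks]),
            "frame": np.concatenate([t.frames for t in tracks]),
            "x_um": np.concatenate([t.positions[:, 0] for t in tracks]),
            "y_um": np.concatenate([t.positions[:, 1] for t in tracks]),
        }
    )


def table_to_tracks(table: pd.DataFrame) -> List[Track]:
    """Inverse of :func:`tracks_to_table`."""
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                cell_id=int(grp["cell_id"].iloc[0]),
                frames=grp["frame"].to_numpy(),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return tracks
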