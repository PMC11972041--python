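"""Front/back cluster coincidence matching and fragment-track building.

A fragment track is the straight line through the two interaction points of
one particle in the front and back detection layers.  Requiring a two-layer
coincidence within |dt| <= 75 ns strongly suppresses background from
particles other than charged nuclear fragments.  When more than two clusters
fall in a coincidence group, pairs with the smallest |dt| are matched first
(greedy, deterministic: ties broken by earlier front then back timestamp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Line3, TrackerGeometry, unit_vector

TRACK_COLUMNS = [
    "front_idx",
    "back_idx",
    "t_track_ns",
    "delta_t_ns",
    "fx",
    "fy",
    "fz",
    "bx",
    "by",
    "bz",
    "dx",
    "dy",
    "dz",
    "wide_angle",
]


def match_coincidences(
    front: pd.DataFrame, back: pd.DataFrame, window_ns: float = 75.0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One-to-one front/back cluster matching within a coincidence window.

    Clusters are merged into one time-sorted stream and split into
    coincidence groups wherever consecutive timestamps are more than
    ``window_ns`` apart; within each group pairs are taken greedily by
    smallest |dt|.  Returns ``(pairs, unmatched_front, unmatched_back)``
    where ``pairs`` has columns ``front_idx, back_idx, delta_t_ns`` indexing
    the input tables, and the matching is invariant under global time shifts.
    """
    nf, nb = len(front), len(back)
    pairs_empty = pd.DataFrame(columns=["front_idx", "back_idx", "delta_t_ns"])
    if nf == 0 or nb == 0:
        return pairs_empty, np.arange(nf), np.arange(nb)
    tf = front["t_ns"].to_numpy(dtype=float)
    tb = back["t_ns"].to_numpy(dtype=float)
    t_all = np.concatenate([tf, tb])
    is_front = np.concatenate([np.ones(nf, bool), np.zeros(nb, bool)])
    idx_all = np.concatenate([np.arange(nf), np.arange(nb)])
    order = np.argsort(t_all, kind="stable")
    t_s = t_all[order]
    group = np.zeros(len(t_s), dtype=np.int64)
    group[1:] = np.cumsum(np.diff(t_s) > window_ns)

    fi_out, bi_out, dt_out = [], [], []
    matched_f = np.zeros(nf, bool)
    matched_b = np.zeros(nb, bool)
    bounds = np.flatnonzero(np.diff(group)) + 1
    for members in np.split(order, bounds):
        f_members = members[is_front[members]]
        b_members = members[~is_front[members]]
        if len(f_members) == 0 or len(b_members) == 0:
            continue
        f_idx = idx_all[f_members]
        b_idx = idx_all[b_members]
        if len(f_idx) == 1 and len(b_idx) == 1:
            dt = tb[b_idx[0]] - tf[f_idx[0]]
            if abs(dt) <= window_ns:
                matched_f[f_idx[0]] = matched_b[b_idx[0]] = True
                fi_out.append(f_idx[0])
                bi_out.append(b_idx[0])
                dt_out.append(dt)
            continue
        dt = tb[b_idx][None, :] - tf[f_idx][:, None]
        ii, jj = np.nonzero(np.abs(dt) <= window_ns)
        if len(ii) == 0:
            continue
        cand = sorted(
            zip(np.abs(dt[ii, jj]), tf[f_idx[ii]], tb[b_idx[jj]], f_idx[ii], b_idx[jj]),
            key=lambda c: (c[0], c[1], c[2]),
        )
        for _, _, _, fi, bi in cand:
            if matched_f[fi] or matched_b[bi]:
                continue
            matched_f[fi] = matched_b[bi] = True
            fi_out.append(fi)
            bi_out.append(bi)
            dt_out.append(tb[bi] - tf[fi])
    pairs = pd.DataFrame(
        {
            "front_idx": np.array(fi_out, dtype=np.int64),
            "back_idx": np.array(bi_out, dtype=np.int64),
            "delta_t_ns": np.array(dt_out, dtype=float),
        }
    )
    pairs = pairs.sort_values("front_idx", kind="stable", ignore_index=True)
    return pairs, np.flatnonzero(~matched_f), np.flatnonzero(~matched_b)


@dataclass(frozen=True)
class FragmentTrack:
    """A fragment line through its front- and back-layer interaction points."""

    front_point: np.ndarray
    back_point: np.ndarray
    line: Line3  # directed front -> back, i.e. away from the phantom
    t_track_ns: float
    delta_t_ns: float
    wide_angle: bool


def build_track(
    front_cluster: pd.Series,
    back_cluster: pd.Series,
    geom: TrackerGeometry,
    wide_angle_deg: float = 45.0,
) -> FragmentTrack:
    """Build one track from a matched front/back cluster pair.

    Raises ``ValueError`` if the mapped 3D points coincide (degenerate).
    Tracks at a polar angle to the focus line beyond ``wide_angle_deg`` are
    flagged as likely accidental coincidences but kept.
    """
    p_f = geom.sensor_to_room(
        front_cluster["centroid_col"], front_cluster["centroid_row"], "front"
    )
    p_b = geom.sensor_to_room(
        back_cluster["centroid_col"], back_cluster["centroid_row"], "back"
    )
    if np.linalg.norm(p_b - p_f) < 1e-9:
        raise ValueError("degenerate pair: identical front/back points")
    d = unit_vector(p_b - p_f)
    cos_focus = float(np.dot(d, geom.focus_direction))
    wide = cos_focus < np.cos(np.radians(wide_angle_deg))
    return FragmentTrack(
        front_point=p_f,
        back_point=p_b,
        line=Line3(p_f, d),
        t_track_ns=float(front_cluster["t_ns"]),
        delta_t_ns=float(back_cluster["t_ns"] - front_cluster["t_ns"]),
        wide_angle=wide,
    )


def build_tracks(
    pairs: pd.DataFrame,
    front: pd.DataFrame,
    back: pd.DataFrame,
    geom: TrackerGeometry,
    wide_angle_deg: float = 45.0,
) -> tuple[pd.DataFrame, int]:
    """Vectorised track building for a matched-pair table.

    Returns ``(tracks, n_degenerate)``; degenerate pairs (identical mapped
    points) are dropped and counted.
    """
    if len(pairs) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS), 0
    f = front.iloc[pairs["front_idx"].to_numpy()]
    b = back.iloc[pairs["back_idx"].to_numpy()]
    p_f = geom.sensor_to_room(
        f["centroid_col"].to_numpy(), f["centroid_row"].to_numpy(), "front"
    )
    p_b = geom.sensor_to_room(
        b["centroid_col"].to_numpy(), b["centroid_row"].to_numpy(), "back"
    )
    diff = p_b - p_f
    norm = np.linalg.norm(diff, axis=1)
    ok = norm >= 1e-9
    n_degenerate = int((~ok).sum())
    d = diff[ok] / norm[ok, None]
    cos_focus = d @ geom.focus_direction
    tracks = pd.DataFrame(
        {
            "front_idx": pairs["front_idx"].to_numpy()[ok],
            "back_idx": pairs["back_idx"].to_numpy()[ok],
            "t_track_ns": f["t_ns"].to_numpy()[ok],
            "delta_t_ns": pairs["delta_t_ns"].to_numpy()[ok],
            "fx": p_f[ok, 0],
            "fy": p_f[ok, 1],
            "fz": p_f[ok, 2],
            "bx": p_b[ok, 0],
            "by": p_b[ok, 1],
            "bz": p_b[ok, 2],
            "dx": d[:, 0],
            "dy": d[:, 1],
            "dz": d[:, 2],
            "wide_angle": cos_focus < np.cos(np.radians(wide_angle_deg)),
        }
    )
    return tracks, n_degenerate
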