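"""Readers and writers for pixel-hit lists, beam logs and voxel grids.

File dialects
-------------
* Pixel hits: TSV with header ``layer chip col row toa_ns energy_kev``.
  ``toa_ns`` values are multiples of the 1.5625 ns timestamp quantum (the
  Timepix3 time binning); the quantum is exactly representable in binary
  floating point, so times round-trip bit-exactly.  An HDF5 mirror with the
  same column names is selected by a ``.h5``/``.hdf5`` suffix.
* Beam log: TSV ``spot_id energy_mev_u x_mm y_mm sigma_mm n_primaries
  t_start_ns t_end_ns`` — one row per pencil-beam spot, time-ordered and
  non-overlapping.
* Voxel grids: sparse TSV of ``(ix, iy, iz, count)`` with a JSON sidecar
  carrying origin, voxel size, shape and out-of-grid counts, so test
  fixtures stay human-diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Timepix3 timestamp quantum in nanoseconds (exact in binary floating point).
TOA_QUANTUM_NS = 1.5625

HIT_COLUMNS = ["layer", "chip", "col", "row", "toa_ns", "energy_kev"]
BEAM_COLUMNS = [
    "spot_id",
    "energy_mev_u",
    "x_mm",
    "y_mm",
    "sigma_mm",
    "n_primaries",
    "t_start_ns",
    "t_end_ns",
]

#: Soft validation bounds for the default treatment field (MeV/u).
DEFAULT_ENERGY_RANGE = (153.0, 250.0)


class LoadError(ValueError):
    """Raised when an input file fails validation; names the offending line."""


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5"}


def quantize_toa(toa_ns):
    """Snap times to the nearest multiple of the 1.5625 ns quantum."""
    return np.round(np.asarray(toa_ns, dtype=float) / TOA_QUANTUM_NS) * TOA_QUANTUM_NS


def read_pixel_hits(path: str | Path) -> pd.DataFrame:
    """Load a pixel-hit list, validated and sorted by time of arrival.

    Raises :class:`LoadError` (naming the data line) for missing columns,
    non-positive energies, negative times, or times off the timestamp grid.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{path}: no such file")
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as fh:
            missing = [c for c in HIT_COLUMNS if c not in fh]
            if missing:
                raise LoadError(f"{path}: missing column(s) {missing}")
            df = pd.DataFrame({c: fh[c][:] for c in HIT_COLUMNS})
            df["layer"] = df["layer"].astype(str)
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype={"layer": str})
        except Exception as exc:  # malformed table
            raise LoadError(f"{path}: cannot parse ({exc})") from exc
        missing = [c for c in HIT_COLUMNS if c not in df.columns]
        if missing:
            raise LoadError(f"{path}: missing column(s) {missing}")
        df = df[HIT_COLUMNS]
    if df.empty:
        return df.astype(
            {"chip": int, "col": int, "row": int, "toa_ns": float, "energy_kev": float}
        )

    def _fail(mask: np.ndarray, what: str):
        line = int(np.flatnonzero(mask)[0]) + 2  # 1-based, after the header
        raise LoadError(f"{path}: {what} at line {line}")

    bad_layer = ~df["layer"].isin(["front", "back"]).to_numpy()
    if bad_layer.any():
        _fail(bad_layer, "unknown layer id")
    for col in ("chip", "col", "row", "toa_ns", "energy_kev"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().to_numpy().any():
            _fail(vals.isna().to_numpy(), f"malformed value in column {col!r}")
        df[col] = vals
    if (df["energy_kev"] <= 0).to_numpy().any():
        _fail((df["energy_kev"] <= 0).to_numpy(), "non-positive energy")
    if (df["toa_ns"] < 0).to_numpy().any():
        _fail((df["toa_ns"] < 0).to_numpy(), "negative time of arrival")
    off_grid = np.abs(df["toa_ns"].to_numpy() - quantize_toa(df["toa_ns"])) > 1e-3
    if off_grid.any():
        _fail(off_grid, "time of arrival off the 1.5625 ns grid")
    df["toa_ns"] = quantize_toa(df["toa_ns"])
    df = df.astype({"chip": int, "col": int, "row": int})
    return df.sort_values("toa_ns", kind="stable", ignore_index=True)


def write_pixel_hits(hits: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df = hits[HIT_COLUMNS] if len(hits) else pd.DataFrame(columns=HIT_COLUMNS)
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "w") as fh:
            for c in HIT_COLUMNS:
                data = df[c].to_numpy()
                if c == "layer":
                    data = data.astype("S8")
                fh.create_dataset(c, data=data)
        return
    out = df.copy()
    if len(out):
        out["toa_ns"] = [repr(float(v)) for v in out["toa_ns"]]
        out["energy_kev"] = [f"{v:.6f}" for v in out["energy_kev"]]
    out.to_csv(path, sep="\t", index=False)


def read_beam_log(path: str | Path, energy_range=DEFAULT_ENERGY_RANGE) -> pd.DataFrame:
    """Load a pencil-beam delivery log, time-ordered, overlap-checked.

    Energies outside ``energy_range`` produce a logged warning but are kept
    (soft validation for non-default plans).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise LoadError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in BEAM_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    df = df[BEAM_COLUMNS]
    if df.empty:
        return df
    if (df["t_start_ns"] >= df["t_end_ns"]).any():
        bad = int(np.flatnonzero((df["t_start_ns"] >= df["t_end_ns"]).to_numpy())[0]) + 2
        raise LoadError(f"{path}: t_start >= t_end at line {bad}")
    df = df.sort_values("t_start_ns", kind="stable", ignore_index=True)
    if (df["t_start_ns"].to_numpy()[1:] <= df["t_end_ns"].to_numpy()[:-1]).any():
        raise LoadError(f"{path}: overlapping spot intervals")
    if energy_range is not None:
        lo, hi = energy_range
        n_out = int(((df["energy_mev_u"] < lo) | (df["energy_mev_u"] > hi)).sum())
        if n_out:
            log.warning(
                "%s: %d spot(s) outside the default plan energy range [%g, %g] MeV/u",
                path,
                n_out,
                lo,
                hi,
            )
    df["spot_id"] = df["spot_id"].astype(int)
    df["n_primaries"] = df["n_primaries"].astype(int)
    return df


def write_beam_log(beam_log: pd.DataFrame, path: str | Path) -> None:
    df = beam_log[BEAM_COLUMNS] if len(beam_log) else pd.DataFrame(columns=BEAM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_distribution(dist, base_path: str | Path) -> None:
    """Write a voxelised fragment distribution as sparse TSV + JSON sidecar.

    ``base_path`` without suffix produces ``<base>.tsv`` and ``<base>.json``.
    """
    base = Path(base_path)
    tsv = base.with_suffix(".tsv")
    meta = base.with_suffix(".json")
    idx = np.argwhere(dist.counts > 0)
    counts = dist.counts[tuple(idx.T)] if len(idx) else np.array([], dtype=int)
    pd.DataFrame(
        {
            "ix": idx[:, 0] if len(idx) else [],
            "iy": idx[:, 1] if len(idx) else [],
            "iz": idx[:, 2] if len(idx) else [],
            "count": counts,
        }
    ).to_csv(tsv, sep="\t", index=False)
    meta.write_text(
        json.dumps(
            {
                "origin_mm": list(dist.grid.origin),
                "voxel_size_mm": list(dist.grid.voxel_size),
                "shape": list(dist.grid.shape),
                "n_outside": int(dist.n_outside),
                "n_total": int(dist.counts.sum() + dist.n_outside),
            },
            indent=2,
        )
        + "\n"
    )


def read_distribution(base_path: str | Path):
    """Inverse of :func:`write_distribution`."""
    from .compare import FragmentDistribution, GridSpec

    base = Path(base_path)
    meta = json.loads(base.with_suffix(".json").read_text())
    grid = GridSpec(
        origin=tuple(meta["origin_mm"]),
        voxel_size=tuple(meta["voxel_size_mm"]),
        shape=tuple(meta["shape"]),
    )
    counts = np.zeros(grid.shape, dtype=np.int64)
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    if len(df):
        counts[df["ix"].to_numpy(), df["iy"].to_numpy(), df["iz"].to_numpy()] = df[
            "count"
        ].to_numpy()
    return FragmentDistribution(grid=grid, counts=counts, n_outside=meta["n_outside"])


VERTEX_COLUMNS = ["x_mm", "y_mm", "z_mm", "miss_mm", "spot_id", "t_track_ns"]


def write_vertices(vertices: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VERTEX_COLUMNS if c in vertices.columns] or VERTEX_COLUMNS
    df = vertices[cols] if len(vertices) else pd.DataFrame(columns=VERTEX_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_vertices(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("x_mm", "y_mm", "z_mm") if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df
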