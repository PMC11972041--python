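"""Orchestration: simulate -> reconstruct -> compare, with run reports.

Each stage is a pure function over in-memory tables; the CLI wraps these
with file I/O.  Reports carry per-stage counts (hits, clusters, tracks,
vertices) and comparison summaries in a machine-readable form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, compare, tracking, vertexing
from .config import RunConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    config_hash: str
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "counts": self.counts,
            "warnings": self.warnings,
        }


def run_reconstruction(
    config: RunConfig,
    hits_front: pd.DataFrame,
    hits_back: pd.DataFrame,
    beam_log: pd.DataFrame,
) -> tuple[pd.DataFrame, RunReport]:
    """Full post-processing chain from pixel hits to reconstructed vertices.

    Clusters each layer, matches front/back coincidences, builds fragment
    tracks in room coordinates, associates each track with the pencil beam
    delivered at its timestamp, and projects it onto that beam line.
    Deterministic given its inputs.
    """
    report = RunReport(config_hash=config.config_hash())
    geom = config.geometry.to_tracker()
    c = report.counts
    c["n_hits_front"] = len(hits_front)
    c["n_hits_back"] = len(hits_back)
    try:
        cl_f, _ = clustering.cluster_hits(
            hits_front, config.clustering.time_window_ns, config.clustering.adjacency
        )
        cl_b, _ = clustering.cluster_hits(
            hits_back, config.clustering.time_window_ns, config.clustering.adjacency
        )
    except Exception as exc:
        raise StageError("clustering", str(exc)) from exc
    c["n_clusters_front"] = len(cl_f)
    c["n_clusters_back"] = len(cl_b)
    if len(cl_b) == 0 and len(cl_f) > 0:
        report.warnings.append("no back-layer clusters: zero tracks")
    try:
        pairs, _, _ = tracking.match_coincidences(cl_f, cl_b, config.tracking.window_ns)
        tracks, n_deg = tracking.build_tracks(
            pairs, cl_f, cl_b, geom, config.tracking.wide_angle_deg
        )
    except Exception as exc:
        raise StageError("tracking", str(exc)) from exc
    c["n_tracks"] = len(tracks)
    c["n_degenerate_pairs"] = n_deg
    c["n_wide_angle"] = int(tracks["wide_angle"].sum()) if len(tracks) else 0
    try:
        vertices, qc = vertexing.reconstruct_vertices(
            tracks, beam_log, config.grid.miss_distance_cut_mm
        )
    except Exception as exc:
        raise StageError("vertexing", str(exc)) from exc
    c["n_unassociated"] = qc["n_unassociated"]
    c["n_degenerate_projections"] = qc["n_degenerate"]
    c["n_vertices"] = len(vertices)
    return vertices, report


def run_reconstruction_multi(
    config: RunConfig,
    hits_front: list,
    hits_back: list,
    beam_log: pd.DataFrame,
) -> tuple[pd.DataFrame, RunReport]:
    """Reconstruct several delivery repetitions and pool the vertices.

    Repetitions are processed independently (each reuses the same beam log)
    and their vertex tables concatenated — the summed-repetition emulation
    of a larger multi-tracker monitoring system.
    """
    parts, reports = [], []
    for hf, hb in zip(hits_front, hits_back):
        v, r = run_reconstruction(config, hf, hb, beam_log)
        parts.append(v)
        reports.append(r)
    vertices = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    merged = RunReport(config_hash=config.config_hash())
    for r in reports:
        for k, v in r.counts.items():
            merged.counts[k] = merged.counts.get(k, 0) + v
        merged.warnings.extend(r.warnings)
    merged.counts["n_repetitions"] = len(reports)
    return vertices, merged


@dataclass
class ComparisonResult:
    diff_map: compare.DifferenceMap
    n_eligible: int
    n_significant: int
    significant_voxels: pd.DataFrame
    expected_chance: float
    expected_chance_se: float
    profile_ref: compare.DepthProfile
    profile_test: compare.DepthProfile
    region_deltas: dict
    report: RunReport

    def summary(self) -> dict:
        return {
            "n_eligible": self.n_eligible,
            "n_significant": self.n_significant,
            "expected_chance": self.expected_chance,
            "expected_chance_se": self.expected_chance_se,
            "region_deltas": self.region_deltas,
        }


def run_comparison(
    config: RunConfig,
    vertices_ref: pd.DataFrame,
    vertices_test: pd.DataFrame,
    chance_draws: int = 10_000,
    chance_seed: int | None = 0,
) -> ComparisonResult:
    """Compare two fragment distributions on the configured voxel grid.

    Produces the voxel difference map with the Poisson significance mask,
    the expected number of chance exceedances (plug-in calibration on the
    reference distribution), transverse-integrated depth profiles, and
    region-integrated count changes for the configured z regions.
    """
    g = config.grid
    grid = compare.GridSpec(tuple(g.origin_mm), tuple(g.voxel_size_mm), tuple(g.shape))
    report = RunReport(config_hash=config.config_hash())
    d_ref = compare.voxelize(vertices_ref, grid)
    d_test = compare.voxelize(vertices_test, grid)
    report.counts["n_vertices_ref"] = int(d_ref.n_total_in_grid + d_ref.n_outside)
    report.counts["n_vertices_test"] = int(d_test.n_total_in_grid + d_test.n_outside)
    dmap = compare.difference_map(d_ref, d_test, g.min_count, g.k_sigma, g.eligibility)
    n_sig, table = compare.count_significant(dmap)
    n_elig = int(dmap.eligible.sum())
    if n_elig:
        exp, exp_se = compare.expected_chance_exceedances(
            d_ref.counts[dmap.eligible].astype(float),
            g.k_sigma,
            n_draws=chance_draws,
            seed=chance_seed,
        )
    else:
        exp, exp_se = 0.0, 0.0
        report.warnings.append("no eligible voxels for chance calibration")
    z_lo = min(g.origin_mm[2], *(r[0] for r in g.regions.values()))
    z_hi = max(g.origin_mm[2] + g.voxel_size_mm[2] * g.shape[2], *(r[1] for r in g.regions.values()))
    p_ref = compare.depth_profile(vertices_ref, g.depth_bin_mm, (z_lo, z_hi), g.regions)
    p_test = compare.depth_profile(vertices_test, g.depth_bin_mm, (z_lo, z_hi), g.regions)
    region_deltas = {
        name: compare.region_delta(p_ref, p_test, span) for name, span in g.regions.items()
    }
    report.counts["n_eligible"] = n_elig
    report.counts["n_significant"] = n_sig
    return ComparisonResult(
        dmap,
        n_elig,
        n_sig,
        table,
        exp,
        exp_se,
        p_ref,
        p_test,
        region_deltas,
        report,
    )
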