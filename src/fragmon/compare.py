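"""Fragment-distribution comparison: voxel maps, Poisson significance, depth profiles.

Two fragment distributions (voxelised collections of reconstructed
fragmentation vertices) are subtracted voxel by voxel.  A voxel difference
is called significant when it exceeds a 2-sigma Poisson threshold,

    |N2 - N1| >= k * sqrt(N1 + N2),        k = 2  (95.4% confidence)

restricted to voxels with more than ``min_count`` events (the visualization
threshold, 100 by default).  No multiple-testing correction is applied;
instead the analysis is calibrated by the number of voxels expected to pass
the threshold by chance under paired Poisson counting noise, which this
module estimates by Monte Carlo with plug-in per-voxel means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: origin corner, voxel size, voxel counts."""

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float] = (8.0, 8.0, 10.0)
    shape: tuple[int, int, int] = (10, 10, 18)

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_size) or any(n <= 0 for n in self.shape):
            raise ValueError("voxel sizes and shape must be positive")

    @property
    def z_centers(self) -> np.ndarray:
        o, d, n = self.origin[2], self.voxel_size[2], self.shape[2]
        return o + d * (np.arange(n) + 0.5)


@dataclass(frozen=True)
class FragmentDistribution:
    """3D voxel histogram of reconstructed vertices with grid metadata."""

    grid: GridSpec
    counts: np.ndarray  # int64, shape == grid.shape
    n_outside: int = 0

    @property
    def n_total_in_grid(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DifferenceMap:
    grid: GridSpec
    n1: np.ndarray
    n2: np.ndarray
    delta: np.ndarray  # N2 - N1
    eligible: np.ndarray  # count-threshold mask
    significant: np.ndarray  # Poisson-threshold mask, subset of eligible


def _positions(vertices) -> np.ndarray:
    if isinstance(vertices, pd.DataFrame):
        return vertices[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(vertices, dtype=float))


def voxelize(vertices, grid: GridSpec) -> FragmentDistribution:
    """Histogram vertices onto the grid with half-open voxels [edge, edge+size).

    Conserves counts: in-grid counts plus ``n_outside`` equal the number of
    input vertices.
    """
    pos = _positions(vertices)
    if pos.size == 0:
        return FragmentDistribution(grid, np.zeros(grid.shape, dtype=np.int64), 0)
    idx = np.floor(
        (pos - np.asarray(grid.origin)) / np.asarray(grid.voxel_size)
    ).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    flat = np.ravel_multi_index(tuple(idx[inside].T), grid.shape)
    counts = np.bincount(flat, minlength=int(np.prod(grid.shape))).reshape(grid.shape)
    return FragmentDistribution(grid, counts.astype(np.int64), int((~inside).sum()))


def poisson_threshold_mask(n1, n2, k_sigma: float = 2.0) -> np.ndarray:
    """Elementwise |N2 - N1| >= k * sqrt(N1 + N2) (symmetric in N1, N2)."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    return np.abs(n2 - n1) >= k_sigma * np.sqrt(n1 + n2)


def difference_map(
    d1: FragmentDistribution,
    d2: FragmentDistribution,
    min_count: int = 100,
    k_sigma: float = 2.0,
    eligibility: str = "both",
) -> DifferenceMap:
    """Voxel difference N2 - N1 with count-eligibility and Poisson masks.

    ``eligibility`` controls which distribution the "more than min_count
    events" rule applies to: ``"both"`` (default), ``"either"``, or
    ``"first"`` (the reference only).
    """
    if d1.grid != d2.grid:
        raise ValueError("distributions are on different grids")
    n1 = d1.counts
    n2 = d2.counts
    if eligibility == "both":
        eligible = (n1 > min_count) & (n2 > min_count)
    elif eligibility == "either":
        eligible = (n1 > min_count) | (n2 > min_count)
    elif eligibility == "first":
        eligible = n1 > min_count
    else:
        raise ValueError("eligibility must be 'both', 'either' or 'first'")
    significant = eligible & poisson_threshold_mask(n1, n2, k_sigma)
    return DifferenceMap(d1.grid, n1, n2, (n2 - n1).astype(np.int64), eligible, significant)


def count_significant(dmap: DifferenceMap) -> tuple[int, pd.DataFrame]:
    """Number of significant voxels plus their list, sorted by |delta| descending."""
    idx = np.argwhere(dmap.significant)
    delta = dmap.delta[dmap.significant]
    order = np.argsort(-np.abs(delta), kind="stable")
    table = pd.DataFrame(
        {
            "ix": idx[order, 0] if len(idx) else [],
            "iy": idx[order, 1] if len(idx) else [],
            "iz": idx[order, 2] if len(idx) else [],
            "n1": dmap.n1[dmap.significant][order] if len(idx) else [],
            "n2": dmap.n2[dmap.significant][order] if len(idx) else [],
            "delta": delta[order] if len(idx) else [],
        }
    )
    return int(dmap.significant.sum()), table


def expected_chance_exceedances(
    means,
    k_sigma: float = 2.0,
    n_draws: int = 10_000,
    seed=None,
    min_count: int | None = None,
) -> tuple[float, float]:
    """Expected number of voxels passing the Poisson threshold by chance.

    For each voxel mean ``mu`` the pass probability
    ``P(|X - Y| >= k * sqrt(X + Y))`` with independent ``X, Y ~ Poisson(mu)``
    is estimated from ``n_draws`` Monte Carlo pairs; the expectation is the
    sum over voxels.  ``means`` may be a :class:`FragmentDistribution`
    (plug-in: observed counts of voxels above ``min_count`` serve as means)
    or an explicit array of per-voxel means.  Returns ``(expected,
    mc_standard_error)``.
    """
    if isinstance(means, FragmentDistribution):
        if min_count is None:
            min_count = 100
        mu = means.counts[means.counts > min_count].astype(float)
    else:
        mu = np.asarray(means, dtype=float).ravel()
    if mu.size == 0:
        raise ValueError("no eligible voxels")
    rng = np.random.default_rng(seed)
    expected = 0.0
    var = 0.0
    chunk = max(1, int(2e6) // n_draws)
    for lo in range(0, mu.size, chunk):
        m = mu[lo : lo + chunk]
        x = rng.poisson(m, size=(n_draws, m.size))
        y = rng.poisson(m, size=(n_draws, m.size))
        p = poisson_threshold_mask(x, y, k_sigma).mean(axis=0)
        expected += float(p.sum())
        var += float((p * (1.0 - p)).sum() / n_draws)
    return expected, float(np.sqrt(var))


@dataclass(frozen=True)
class DepthProfile:
    """Transverse-integrated histogram of vertices along the beam axis (z)."""

    bin_edges: np.ndarray  # len n_bins + 1, multiples of the bin size
    counts: np.ndarray  # int64, len n_bins
    regions: dict = field(default_factory=dict)  # label -> (z0, z1)

    @property
    def bin_size(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def depth_profile(
    vertices,
    bin_size_mm: float = 5.0,
    z_range: tuple[float, float] | None = None,
    regions: dict | None = None,
) -> DepthProfile:
    """Histogram vertex z positions in fixed-size bins anchored at z = 0.

    ``z_range`` is expanded outward to bin-size multiples; by default it
    covers the data.
    """
    if bin_size_mm <= 0:
        raise ValueError("bin_size_mm must be positive")
    pos = _positions(vertices)
    z = pos[:, 2] if pos.size else np.array([0.0])
    if z_range is None:
        z_range = (float(z.min()), float(z.max()) + 1e-9)
    lo = np.floor(z_range[0] / bin_size_mm) * bin_size_mm
    hi = np.ceil(z_range[1] / bin_size_mm) * bin_size_mm
    if hi <= lo:
        hi = lo + bin_size_mm
    edges = lo + bin_size_mm * np.arange(int(round((hi - lo) / bin_size_mm)) + 1)
    if pos.size == 0:
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
    else:
        idx = np.floor((pos[:, 2] - lo) / bin_size_mm).astype(np.int64)
        inside = (idx >= 0) & (idx < len(edges) - 1)
        counts = np.bincount(idx[inside], minlength=len(edges) - 1).astype(np.int64)
    return DepthProfile(edges, counts, dict(regions or {}))


def profile_difference(p1: DepthProfile, p2: DepthProfile) -> np.ndarray:
    """Per-bin count difference p2 - p1 (requires identical binning)."""
    if len(p1.bin_edges) != len(p2.bin_edges) or not np.allclose(
        p1.bin_edges, p2.bin_edges
    ):
        raise ValueError("depth profiles use different binning")
    return (p2.counts - p1.counts).astype(np.int64)


def region_delta(
    p1: DepthProfile, p2: DepthProfile, region: tuple[float, float]
) -> float:
    """Integrated count change of p2 relative to p1 over a z interval.

    Bins partially covered by the region contribute in proportion to their
    overlap fraction.
    """
    z0, z1 = region
    if z1 <= z0:
        raise ValueError("region must satisfy z0 < z1")
    if z0 < p1.bin_edges[0] - 1e-9 or z1 > p1.bin_edges[-1] + 1e-9:
        raise ValueError("region extends beyond the profile range")
    diff = profile_difference(p1, p2).astype(float)
    lo = p1.bin_edges[:-1]
    hi = p1.bin_edges[1:]
    overlap = np.clip(np.minimum(hi, z1) - np.maximum(lo, z0), 0.0, None)
    return float(np.sum(diff * overlap / (hi - lo)))


def model_shortfall(measured_deltas, simulated_deltas) -> float:
    """Relative shortfall of a model's integrated count change vs measurement.

    Both arguments are iterables of region-integrated count changes (e.g.
    reductions upstream and downstream of an insert).  Returns
    ``1 - |sum(simulated)| / |sum(measured)|``: the fraction of the measured
    change that the model fails to reproduce.
    """
    meas = float(np.sum(np.abs(measured_deltas)))
    sim = float(np.sum(np.abs(simulated_deltas)))
    if meas == 0:
        raise ValueError("measured change is zero")
    return 1.0 - sim / meas
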