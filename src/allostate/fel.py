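"""Free-energy landscape reconstruction on periodic CV grids.

Two reconstruction routes are supported:

* population-based: F(bin) = -kT ln(count/N), min-shifted, with
  never-visited bins masked rather than given a pseudo-count;
* well-tempered metadynamics: the accumulated bias V(s) is summed from the
  deposited Gaussian hills of all walkers (shared-bias multiple-walkers
  scheme) and converted with the well-tempered estimator
  F(s) = -(γ/(γ-1)) V(s).

Also provided: the 2D → 1D Boltzmann marginal profile (the free-energy
profile along one CV computed from the populations of the other) and the
minimax path barrier between two basins (lowest pass on the 4-connected
periodic grid graph; masked bins are impassable).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import KB_KCAL, kt_kcal, periodic_delta, wrap_angle
from .trajio import HillSeries

__all__ = [
    "GridSpec",
    "LandscapeGrid",
    "BiasPotential",
    "BarrierResult",
    "landscape_from_samples",
    "marginal_profile",
    "bias_from_hills",
    "fel_from_bias",
    "barrier_between",
]


@dataclass(frozen=True)
class GridSpec:
    """Per-axis bin layout for a (possibly periodic) CV grid."""

    cv_names: tuple[str, ...]
    bins: tuple[int, ...]
    periods: tuple[float | None, ...]        # None = aperiodic
    ranges: tuple[tuple[float, float], ...]

    @classmethod
    def dihedral(cls, cv_names: Sequence[str], bins: int = 72) -> "GridSpec":
        """Default periodic grid over (-180°, 180°] per named dihedral CV."""
        n = len(cv_names)
        return cls(
            cv_names=tuple(cv_names),
            bins=(bins,) * n,
            periods=(360.0,) * n,
            ranges=((-180.0, 180.0),) * n,
        )

    @property
    def ndim(self) -> int:
        return len(self.bins)

    def edges(self, axis: int) -> np.ndarray:
        lo, hi = self.ranges[axis]
        return np.linspace(lo, hi, self.bins[axis] + 1)

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges(axis)
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class LandscapeGrid:
    """Free energy (kcal/mol) on a CV grid at a stated temperature.

    Masked bins were never visited and carry NaN in ``values``; the minimum
    over unmasked bins is shifted to zero.
    """

    spec: GridSpec
    values: np.ndarray               # NaN at masked bins
    temperature: float
    mask: np.ndarray = field(default=None)   # True where unvisited

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != tuple(self.spec.bins):
            raise ValueError("values shape does not match grid spec")

    @property
    def kt(self) -> float:
        return kt_kcal(self.temperature)

    def min_shift(self) -> "LandscapeGrid":
        if np.all(self.mask):
            raise ValueError("landscape has no visited bins")
        vals = self.values.copy()
        vals[~self.mask] -= np.nanmin(vals[~self.mask])
        return LandscapeGrid(self.spec, vals, self.temperature,
                             mask=self.mask.copy())

    def to_frame(self):
        import pandas as pd

        grids = np.meshgrid(
            *[self.spec.centers(a) for a in range(self.spec.ndim)],
            indexing="ij")
        data = {n: g.ravel() for n, g in zip(self.spec.cv_names, grids)}
        data["free_energy"] = self.values.ravel()
        data["unvisited"] = self.mask.ravel()
        return pd.DataFrame(data)


@dataclass
class BiasPotential:
    """Accumulated metadynamics bias V(s) >= 0 on a CV grid."""

    spec: GridSpec
    values: np.ndarray
    gamma: float
    hills_per_walker: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9):
            raise ValueError("bias potential must be non-negative")


def _bin_indices(samples: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Map samples (n, d) to integer bin indices, wrapping periodic axes."""
    idx = np.empty(samples.shape, dtype=int)
    for a in range(spec.ndim):
        x = samples[:, a]
        if spec.periods[a]:
            x = wrap_angle(x) if spec.periods[a] == 360.0 else x % spec.periods[a]
        e = spec.edges(a)
        k = np.searchsorted(e, x, side="left") - 1
        # value exactly at the lower range edge belongs to bin 0; value at
        # the upper edge (e.g. +180°) belongs to the last bin
        k = np.clip(k, 0, spec.bins[a] - 1)
        idx[:, a] = k
    return idx


def landscape_from_samples(samples, spec: GridSpec | None = None,
                           temperature: float = 300.0) -> LandscapeGrid:
    """Population free energy F = -kT ln(count/N), min-shifted.

    ``samples`` is (n, d) (or 1D for a single CV).  Empty bins are masked.
    Invariant to duplicating the sample set: only proportions matter.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    samples = samples[np.all(np.isfinite(samples), axis=1)]
    if samples.size == 0:
        raise ValueError("empty sample set")
    if spec is None:
        spec = GridSpec.dihedral([f"cv{i+1}" for i in range(samples.shape[1])])
    if samples.shape[1] != spec.ndim:
        raise ValueError("sample dimensionality does not match grid spec")
    idx = _bin_indices(samples, spec)
    counts = np.zeros(spec.bins, dtype=float)
    np.add.at(counts, tuple(idx.T), 1.0)
    kt = kt_kcal(temperature)
    with np.errstate(divide="ignore"):
        f = -kt * np.log(counts / len(samples))
    f[counts == 0] = np.nan
    grid = LandscapeGrid(spec, f, temperature, mask=(counts == 0))
    return grid.min_shift()


def marginal_profile(grid2d: LandscapeGrid, axis: int = 0) -> LandscapeGrid:
    """1D profile along ``axis`` from Boltzmann populations of the other CV.

    P(x) = Σ_y exp(-F(x,y)/kT) over unmasked bins; F1(x) = -kT ln P(x),
    min-shifted.  Columns that are entirely masked stay masked.
    """
    if grid2d.spec.ndim != 2:
        raise ValueError("marginal_profile needs a 2D grid")
    if np.all(grid2d.mask):
        raise ValueError("all bins masked; nothing to marginalize")
    kt = grid2d.kt
    other = 1 - axis
    w = np.where(grid2d.mask, 0.0, np.exp(-np.nan_to_num(grid2d.values) / kt))
    p = w.sum(axis=other)
    spec1 = GridSpec(
        cv_names=(grid2d.spec.cv_names[axis],),
        bins=(grid2d.spec.bins[axis],),
        periods=(grid2d.spec.periods[axis],),
        ranges=(grid2d.spec.ranges[axis],),
    )
    with np.errstate(divide="ignore"):
        f1 = -kt * np.log(p)
    f1[p == 0] = np.nan
    grid = LandscapeGrid(spec1, f1, grid2d.temperature, mask=(p == 0))
    return grid.min_shift()


def _hill_factors_1d(centers_a, sigmas_a, grid_centers, period):
    """Gaussian factors exp(-Δ²/2σ²) of each hill on one axis's centers."""
    if period:
        d = periodic_delta(grid_centers[None, :], centers_a[:, None], period)
    else:
        d = grid_centers[None, :] - centers_a[:, None]
    return np.exp(-0.5 * (d / sigmas_a[:, None]) ** 2)


def bias_from_hills(hill_series: HillSeries | Sequence[HillSeries],
                    spec: GridSpec | None = None,
                    chunk: int = 512) -> BiasPotential:
    """Sum deposited Gaussians from one or more walkers onto a grid.

    All series must share CV names, periods and bias factor γ; walkers are
    merged by concatenating their hills sorted by deposition time (shared
    bias, no per-walker reweighting).  Δ uses the minimum-image periodic
    difference on periodic axes.
    """
    series = [hill_series] if isinstance(hill_series, HillSeries) else list(hill_series)
    if not series:
        raise ValueError("no hill series given")
    ref = series[0]
    for s in series[1:]:
        if s.cv_names != ref.cv_names or s.cv_periods != ref.cv_periods:
            raise ValueError("hill series have mismatched CVs")
        if s.bias_factor != ref.bias_factor:
            raise ValueError(
                f"mixed bias factors across walkers: "
                f"{s.bias_factor} vs {ref.bias_factor}")
    if spec is None:
        spec = GridSpec.dihedral(ref.cv_names)
    if spec.ndim != ref.n_cv:
        raise ValueError("grid spec dimensionality does not match hills")

    order = []
    for s in series:
        for i in range(len(s)):
            order.append((s.times[i], s.walker_id, s.centers[i], s.sigmas[i],
                          s.heights[i]))
    order.sort(key=lambda r: (r[0], r[1]))
    hills_per_walker = {s.walker_id: len(s) for s in series}

    v = np.zeros(spec.bins)
    if order:
        centers = np.array([r[2] for r in order])
        sigmas = np.array([r[3] for r in order])
        heights = np.array([r[4] for r in order])
        axes_centers = [spec.centers(a) for a in range(spec.ndim)]
        for start in range(0, len(order), chunk):
            sl = slice(start, start + chunk)
            factors = [
                _hill_factors_1d(centers[sl, a], sigmas[sl, a],
                                 axes_centers[a], spec.periods[a])
                for a in range(spec.ndim)
            ]
            if spec.ndim == 1:
                v += heights[sl] @ factors[0]
            elif spec.ndim == 2:
                v += np.einsum("k,ki,kj->ij", heights[sl],
                               factors[0], factors[1])
            else:
                raise NotImplementedError("grids beyond 2D not supported")
    return BiasPotential(spec=spec, values=v, gamma=ref.bias_factor,
                         hills_per_walker=hills_per_walker)


def fel_from_bias(bias: BiasPotential, gamma: float | None = None,
                  temperature: float = 300.0) -> LandscapeGrid:
    """Well-tempered estimator F(s) = -(γ/(γ-1)) V(s), min-shifted."""
    gamma = bias.gamma if gamma is None else gamma
    if gamma <= 1:
        raise ValueError("bias factor γ must be > 1")
    f = -(gamma / (gamma - 1.0)) * bias.values
    grid = LandscapeGrid(bias.spec, f, temperature,
                         mask=np.zeros(bias.values.shape, dtype=bool))
    return grid.min_shift()


@dataclass(frozen=True)
class BarrierResult:
    """Minimax-path barrier between two basins."""

    barrier: float                   # pass height - min F in region A
    pass_height: float               # absolute F of the lowest pass
    saddle: tuple[float, ...]        # CV location of the connecting bin
    min_a: float
    min_b: float


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _region_mask(grid: LandscapeGrid, region: dict) -> np.ndarray:
    """Boolean bin mask of a CV box {cv_name: (lo, hi)} on the grid."""
    spec = grid.spec
    sel = np.ones(spec.bins, dtype=bool)
    for a, name in enumerate(spec.cv_names):
        if name not in region:
            continue
        lo, hi = region[name]
        c = spec.centers(a)
        if spec.periods[a]:
            d = (c - wrap_angle(lo)) % spec.periods[a]
            width = (wrap_angle(hi) - wrap_angle(lo)) % spec.periods[a]
            if width == 0 and lo != hi:
                width = spec.periods[a]
            axis_sel = (d >= 0) & (d <= width)
        else:
            axis_sel = (c >= lo) & (c <= hi)
        shape = [1] * spec.ndim
        shape[a] = spec.bins[a]
        sel &= axis_sel.reshape(shape)
    return sel


def barrier_between(grid: LandscapeGrid, region_a: dict,
                    region_b: dict) -> BarrierResult:
    """Lowest-pass barrier from basin A to basin B on the grid graph.

    The pass height is the minimum over all 4-connected grid paths A → B of
    the maximum F along the path (periodic wrap on periodic axes; masked
    bins are impassable).  The barrier is pass height minus the minimum F
    inside region A.  Computed by union-find over bins inserted in order of
    increasing F: the F at which the two basin minima first connect is
    exactly the lowest pass.
    """
    vals = grid.values
    mask = grid.mask
    spec = grid.spec
    sel_a = _region_mask(grid, region_a) & ~mask
    sel_b = _region_mask(grid, region_b) & ~mask
    if not sel_a.any() or not sel_b.any():
        raise ValueError("each region must contain at least one visited bin")
    flat_vals = vals.ravel()
    unmasked = ~mask.ravel()
    min_a = float(np.nanmin(vals[sel_a]))
    min_b = float(np.nanmin(vals[sel_b]))
    seed_a = int(np.nanargmin(np.where(sel_a, vals, np.nan).ravel()))
    seed_b = int(np.nanargmin(np.where(sel_b, vals, np.nan).ravel()))

    shape = tuple(spec.bins)
    n = int(np.prod(shape))
    uf = _UnionFind(n)
    added = np.zeros(n, dtype=bool)

    # precompute flat indices of the 2*ndim neighbours of every bin
    # (periodic wrap on periodic axes, -1 where the neighbour falls off)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    nb_cols = []
    for a in range(len(shape)):
        for step in (-1, 1):
            j = [g.copy() for g in grids]
            j[a] = j[a] + step
            if spec.periods[a]:
                j[a] %= shape[a]
                nb_cols.append(np.ravel_multi_index(j, shape).ravel())
            else:
                valid = (j[a] >= 0) & (j[a] < shape[a])
                j[a] = np.clip(j[a], 0, shape[a] - 1)
                col = np.ravel_multi_index(j, shape).ravel()
                col[~valid.ravel()] = -1
                nb_cols.append(col)
    nb_table = np.stack(nb_cols, axis=1)

    order = np.argsort(flat_vals[unmasked], kind="stable")
    candidates = np.flatnonzero(unmasked)[order]
    for flat in candidates:
        flat = int(flat)
        added[flat] = True
        for nb in nb_table[flat]:
            if nb >= 0 and added[nb]:
                uf.union(flat, int(nb))
        if uf.find(seed_a) == uf.find(seed_b):
            pass_height = float(flat_vals[flat])
            saddle_idx = np.unravel_index(flat, shape)
            saddle = tuple(float(spec.centers(a)[k])
                           for a, k in enumerate(saddle_idx))
            return BarrierResult(
                barrier=pass_height - min_a,
                pass_height=pass_height,
                saddle=saddle,
                min_a=min_a,
                min_b=min_b,
            )
    raise ValueError("no path: regions are disconnected through visited bins")
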