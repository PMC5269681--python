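"""Periodic WHAM: free-energy profile from biased umbrella windows.

The weighted-histogram analysis method combines the histograms of all biased
windows into one unbiased probability profile by self-consistent iteration of
the window free-energy constants ``f_i``:

    P_j  ~  ( sum_i n_ij )  /  ( sum_i N_i f_i exp(-beta U_i(theta_j)) )
    1/f_i = sum_j P_j exp(-beta U_i(theta_j))

with the harmonic bias evaluated with the *periodic* angular distance.  The
iteration is carried out entirely in log space so that windows far from a bin
(bias energies of thousands of kT) cause no under/overflow.

The module also extracts minima, barriers and state free-energy differences
from a profile and measures convergence between profiles of data segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from flipkin.constants import DEG2RAD, PERIOD_DEG, kt_kcal
from flipkin.umbrella import WindowSet


class WhamConvergenceError(RuntimeError):
    """Self-consistent iteration failed to reach tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e} kcal/mol)"
        )


@dataclass
class FreeEnergyProfile:
    """F(xi) on a uniform periodic angular grid, kcal/mol, minimum at zero.

    Unoccupied bins are NaN (undefined), never infinite, so downstream
    integrals restrict themselves to the occupied range.
    """

    bin_centers: np.ndarray   # deg, strictly increasing, uniform, one period
    values: np.ndarray        # kcal/mol, NaN where unoccupied
    occupancy: np.ndarray     # raw counts per bin
    temperature: float        # K
    period: float = PERIOD_DEG

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        widths = np.diff(self.bin_centers)
        if len(self.bin_centers) < 2 or np.any(widths <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bin width must be uniform")
        occ = self.occupied
        if occ.any():
            finite = self.values[occ]
            if not np.all(np.isfinite(finite)):
                raise ValueError("occupied bins must carry finite free energy")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0

    def interp(self, xi: np.ndarray) -> np.ndarray:
        """Linear interpolation of F at angles ``xi`` (deg, same branch as the
        grid); raises if any query falls on an undefined bin."""
        occ = self.occupied
        xi = np.asarray(xi, dtype=float)
        lo, hi = self.bin_centers[occ][0], self.bin_centers[occ][-1]
        if np.any(xi < lo - 1e-9) or np.any(xi > hi + 1e-9):
            raise ValueError(
                f"query outside occupied range [{lo}, {hi}] deg"
            )
        # Guard against interior undefined bins inside the query range.
        inner = (self.bin_centers >= xi.min()) & (self.bin_centers <= xi.max())
        if np.any(~occ & inner):
            raise ValueError("undefined profile bins inside the requested range")
        return np.interp(xi, self.bin_centers[occ], self.values[occ])

    def write(self, path: str | Path) -> None:
        """Three-column text: bin center (deg), F (kcal/mol), occupancy."""
        with open(path, "w") as fh:
            fh.write(
                f"# free-energy profile, T {self.temperature:.17g} K, "
                f"period {self.period:.17g} deg, min-referenced\n"
            )
            fh.write("# center[deg]  F[kcal/mol]  occupancy\n")
            for c, v, o in zip(self.bin_centers, self.values, self.occupancy):
                fh.write(f"{c:.17g} {v:.17g} {o:.17g}\n")

    @classmethod
    def read(cls, path: str | Path, temperature: float,
             period: float = PERIOD_DEG) -> "FreeEnergyProfile":
        data = np.loadtxt(path, comments="#")
        return cls(
            bin_centers=data[:, 0], values=data[:, 1], occupancy=data[:, 2],
            temperature=temperature, period=period,
        )


@dataclass
class StateRegion:
    """A named angular region (one or more intervals on the profile branch)."""

    label: str
    intervals: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("a state region needs at least one interval")
        for lo, hi in self.intervals:
            if hi <= lo:
                raise ValueError(f"empty interval ({lo}, {hi}) in {self.label}")

    def mask(self, bin_centers: np.ndarray) -> np.ndarray:
        m = np.zeros(len(bin_centers), dtype=bool)
        for lo, hi in self.intervals:
            m |= (bin_centers >= lo) & (bin_centers <= hi)
        return m


@dataclass
class Extremum:
    position: float   # deg
    value: float      # kcal/mol
    kind: str         # "min" | "max"


def wham(
    window_set: WindowSet,
    n_bins: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    inefficiencies: np.ndarray | None = None,
    bias_offsets: np.ndarray | None = None,
    grid_origin: float | None = None,
) -> FreeEnergyProfile:
    """Periodic WHAM estimate of F(xi) from a set of umbrella windows.

    Parameters
    ----------
    window_set:
        Biased windows sharing one temperature; series already on their
        centers' branches.
    n_bins:
        Histogram bins over one full period.  Default: one bin per 2 degrees.
    tol:
        Convergence tolerance on the window constants, kcal/mol.
    max_iter:
        Iteration cap; exceeded -> :class:`WhamConvergenceError` carrying the
        last residual.
    inefficiencies:
        Optional per-window statistical inefficiency ``g = 2 tau_int/dt + 1``;
        each window's sample count is divided by its ``g`` when weighting the
        histograms (correlated samples carry less information).
    bias_offsets:
        Optional per-window constant added to each bias energy (kcal/mol),
        e.g. Hamiltonian offsets of an extended-ensemble setup.  The profile
        is exactly invariant under any choice (gauge freedom absorbed by the
        window constants).
    grid_origin:
        Lower edge (deg) of the first histogram bin; default anchors the grid
        half a bin below the first window center.  Shifting the origin by an
        integer number of bins cyclically rotates the profile.
    """
    period = window_set.period
    temperature = window_set.temperature
    kt = kt_kcal(temperature)
    if n_bins is None:
        n_bins = int(round(period / 2.0))
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n_win = len(window_set)
    if inefficiencies is None:
        g = np.ones(n_win)
    else:
        g = np.asarray(inefficiencies, dtype=float)
        if g.shape != (n_win,) or np.any(g < 1):
            raise ValueError("inefficiencies must be one value >= 1 per window")

    # Common periodic grid anchored at the first window center.
    width = period / n_bins
    edge0 = (window_set.centers[0] - width / 2 if grid_origin is None
             else float(grid_origin))
    bin_centers = edge0 + width * (np.arange(n_bins) + 0.5)

    counts = np.zeros((n_win, n_bins))
    for i, w in enumerate(window_set):
        idx = np.floor(np.mod(w.series.values - edge0, period) / width).astype(int)
        np.add.at(counts[i], np.clip(idx, 0, n_bins - 1), 1.0)
    n_eff = counts.sum(axis=1) / g                      # effective samples
    counts_eff = counts / g[:, None]
    total = counts_eff.sum(axis=0)
    occupied = total > 0

    # beta * U_i(theta_j) with the periodic angular distance, radians.
    delta = np.mod(
        bin_centers[None, :] - window_set.centers[:, None] + period / 2, period
    ) - period / 2
    k_arr = np.array([w.force_constant for w in window_set])
    beta_u = 0.5 * k_arr[:, None] * (delta * DEG2RAD) ** 2 / kt
    if bias_offsets is not None:
        beta_u = beta_u + np.asarray(bias_offsets, dtype=float)[:, None] / kt

    log_total = np.full(n_bins, -np.inf)
    log_total[occupied] = np.log(total[occupied])
    log_n = np.log(n_eff)

    log_f = np.zeros(n_win)
    residual = np.inf
    for _ in range(max_iter):
        # log P_j (unnormalized), occupied bins only
        log_den = logsumexp(log_n[:, None] + log_f[:, None] - beta_u, axis=0)
        log_p = log_total - log_den
        log_p -= logsumexp(log_p[occupied])
        new_log_f = -logsumexp(log_p[None, occupied] - beta_u[:, occupied], axis=1)
        new_log_f -= new_log_f[0]
        residual = float(np.max(np.abs(new_log_f - log_f))) * kt
        log_f = new_log_f
        if residual < tol:
            break
    else:
        raise WhamConvergenceError(residual, max_iter)

    values = np.full(n_bins, np.nan)
    values[occupied] = -kt * log_p[occupied]
    values[occupied] -= values[occupied].min()
    if np.any(~occupied):
        lo = int(np.flatnonzero(occupied)[0])
        hi = int(np.flatnonzero(occupied)[-1])
        if np.any(~occupied[lo:hi + 1]):
            warnings.warn(
                "empty bins inside the sampled range; marked undefined",
                stacklevel=2,
            )
    return FreeEnergyProfile(
        bin_centers=bin_centers, values=values, occupancy=total,
        temperature=temperature, period=period,
    )


def state_delta_f(
    profile: FreeEnergyProfile, region_a: StateRegion, region_b: StateRegion
) -> float:
    """Free-energy difference ``F_B - F_A`` (kcal/mol) between two regions.

    Each state's free energy is the Boltzmann integral of the profile over the
    region: ``F_X = -kT ln sum_{j in X} w e^{-F_j/kT}``; antisymmetric by
    construction.
    """
    kt = kt_kcal(profile.temperature)
    occ = profile.occupied
    out = []
    for region in (region_a, region_b):
        m = region.mask(profile.bin_centers) & occ
        if not m.any():
            raise ValueError(f"region {region.label!r} has no occupied bins")
        out.append(
            -kt * logsumexp(-profile.values[m] / kt)
            - kt * np.log(profile.bin_width)
        )
    return out[1] - out[0]


def _largest_occupied_arc(occupied: np.ndarray) -> np.ndarray:
    """Mask of the largest contiguous occupied run on the periodic grid.

    Sparse stray samples (e.g. window tails wrapped to the far side of the
    period) form small disconnected islands with very noisy free energies;
    feature extraction is restricted to the main sampled arc.
    """
    if occupied.all() or not occupied.any():
        return occupied.copy()
    n = occupied.size
    # rotate so position 0 is unoccupied, then find runs linearly
    start = int(np.argmin(occupied))
    rolled = np.roll(occupied, -start)
    best_len = best_at = cur_len = 0
    for i, o in enumerate(rolled):
        if o:
            cur_len += 1
            if cur_len > best_len:
                best_len, best_at = cur_len, i - cur_len + 1
        else:
            cur_len = 0
    mask = np.zeros(n, dtype=bool)
    mask[(np.arange(best_at, best_at + best_len) + start) % n] = True
    return mask


def locate_extrema(
    profile: FreeEnergyProfile, smoothing_window: int = 1
) -> list[Extremum]:
    """Local minima and maxima of the (optionally smoothed) profile.

    ``smoothing_window`` is the odd length of a moving-average filter (1 =
    no smoothing).  Neighbor comparisons are periodic when the whole period is
    occupied, otherwise restricted to the largest contiguous occupied arc.  A
    flat profile has no extrema.  Plateau points count once (at their center).
    """
    occ = _largest_occupied_arc(profile.occupied)
    n_occ = int(occ.sum())
    if n_occ < 3:
        raise ValueError("need at least 3 occupied bins to locate extrema")
    periodic = bool(occ.all())
    nbin = occ.size
    if periodic:
        order = np.arange(nbin)
    else:
        # walk the arc in circular order starting where it begins (the bin
        # whose cyclic predecessor is unoccupied), so a wrap-around arc is
        # traversed as one contiguous stretch
        starts = np.flatnonzero(occ & ~np.roll(occ, 1))
        order = (int(starts[0]) + np.arange(nbin)) % nbin
        order = order[occ[order]]
    x = profile.bin_centers[order].astype(float)
    # unwrap so positions increase monotonically along the arc
    wraps = np.flatnonzero(np.diff(x) < 0)
    for w in wraps:
        x[w + 1:] += profile.period
    y = profile.values[order]
    if smoothing_window > 1:
        if smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        kernel = np.ones(smoothing_window) / smoothing_window
        if periodic:
            y = np.convolve(
                np.concatenate([y[-(smoothing_window // 2):], y,
                                y[:smoothing_window // 2]]),
                kernel, mode="valid",
            )
        else:
            pad = smoothing_window // 2
            y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")

    # Run-length compress equal neighbors so a plateau counts once, at its
    # center; then compare each run against its distinct neighbors.
    eps = 1e-12
    n = len(y)
    runs: list[list[int]] = [[0, 0]]
    for i in range(1, n):
        if abs(y[i] - y[runs[-1][0]]) <= eps:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    if periodic and len(runs) > 1 and abs(y[0] - y[runs[-1][0]]) <= eps:
        runs[0][0] = runs.pop()[0] - n      # wrap the boundary plateau
    out: list[Extremum] = []
    if len(runs) < 3 and not (periodic and len(runs) == 2):
        return out                          # flat or monotone: no extrema
    m = len(runs)
    idx = range(m) if periodic else range(1, m - 1)
    for j in idx:
        val = y[runs[j][0]]
        left = y[runs[(j - 1) % m][0]]
        right = y[runs[(j + 1) % m][0]]
        mid = (runs[j][0] + runs[j][1]) / 2.0
        pos = float(np.interp(mid % n, np.arange(n), x)) if mid % 1 else x[int(mid) % n]
        if val < left - eps and val < right - eps:
            kind = "min"
        elif val > left + eps and val > right + eps:
            kind = "max"
        else:
            continue
        # wrap the (possibly arc-unwrapped) position back onto the grid branch
        grid_lo = profile.bin_centers[0] - profile.bin_width / 2
        pos = grid_lo + float(np.mod(pos - grid_lo, profile.period))
        out.append(Extremum(float(pos), float(val), kind))
    out.sort(key=lambda e: e.position)
    return out


def _arc_order(occupied: np.ndarray) -> np.ndarray:
    """Indices of the largest occupied arc in circular traversal order."""
    occ = _largest_occupied_arc(occupied)
    n = occ.size
    if occ.all():
        return np.arange(n)
    starts = np.flatnonzero(occ & ~np.roll(occ, 1))
    order = (int(starts[0]) + np.arange(n)) % n
    return order[occ[order]]


def basin_regions(
    profile: FreeEnergyProfile, smoothing_window: int = 1
) -> tuple[Extremum, Extremum, Extremum, StateRegion, StateRegion]:
    """Split the sampled arc into the basins of the two deepest minima.

    Returns ``(intra_min, extra_min, saddle, intra_region, extra_region)``
    where *intra* is the higher-angle minimum of the two deepest ones (the
    intra-helical state of the flipping landscape) and the saddle is the
    highest maximum on the branch segment between them.  Basin membership is
    decided along the occupied arc in circular order: bins beyond the saddle
    on the intra side belong to the intra basin up to the complementary
    maximum (when coverage closes the period) or to the arc end.
    """
    ext = locate_extrema(profile, smoothing_window)
    minima = sorted([e for e in ext if e.kind == "min"], key=lambda e: e.value)
    if len(minima) < 2:
        raise ValueError("profile has fewer than two minima; specify regions")
    extra_min, intra_min = sorted(minima[:2], key=lambda e: e.position)
    between = [e for e in ext if e.kind == "max"
               and extra_min.position < e.position < intra_min.position]
    if not between:
        raise ValueError("no barrier between the two minima")
    saddle = max(between, key=lambda e: e.value)
    outside = [e for e in ext if e.kind == "max" and e not in between]

    order = _arc_order(profile.occupied)
    centers = profile.bin_centers
    period = profile.period
    pos = centers[order].astype(float)
    wraps = np.flatnonzero(np.diff(pos) < 0)
    for w in wraps:
        pos[w + 1:] += period          # arc coordinate, monotone

    def to_arc(p: float) -> float:
        # place a branch position onto the monotone arc coordinate
        k = np.round((p - pos[0]) / period)
        cand = p - k * period
        while cand < pos[0] - 1e-9:
            cand += period
        return cand

    if outside:
        # Two maxima split the circle into two cyclic arcs; the intra basin
        # is the arc (possibly wrapping the branch edge) holding the intra
        # minimum.
        second = max(outside, key=lambda e: e.value)

        def in_cyclic(p, a, b):
            return np.mod(p - a, period) < np.mod(b - a, period)

        s, t = saddle.position, second.position
        branch_pos = centers[order]
        if in_cyclic(intra_min.position, s, t):
            intra_sel = in_cyclic(branch_pos, s, t)
        else:
            intra_sel = in_cyclic(branch_pos, t, s)
    else:
        # single saddle on a non-closing arc: split the line at the saddle
        saddle_arc = to_arc(saddle.position)
        intra_arc = to_arc(intra_min.position)
        if intra_arc > saddle_arc:
            intra_sel = pos > saddle_arc
        else:
            intra_sel = pos < saddle_arc
    intra_mask = np.zeros(centers.size, dtype=bool)
    extra_mask = np.zeros(centers.size, dtype=bool)
    intra_mask[order[intra_sel]] = True
    extra_mask[order[~intra_sel]] = True
    return (
        intra_min, extra_min, saddle,
        StateRegion("intra", _mask_to_intervals(intra_mask, centers,
                                                profile.bin_width)),
        StateRegion("extra", _mask_to_intervals(extra_mask, centers,
                                                profile.bin_width)),
    )


def _mask_to_intervals(mask: np.ndarray, centers: np.ndarray, width: float
                       ) -> list[tuple[float, float]]:
    intervals = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return intervals
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((centers[run_start] - width / 2,
                              centers[prev] + width / 2))
            run_start = i
        prev = i
    intervals.append((centers[run_start] - width / 2, centers[prev] + width / 2))
    return intervals


def barrier_between(
    profile: FreeEnergyProfile, min_a: float, min_b: float
) -> float:
    """Barrier height (kcal/mol): highest profile point strictly between the
    two minima positions (deg, on the profile branch) minus the lower
    minimum value."""
    lo, hi = sorted((min_a, min_b))
    m = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.occupied
    if not m.any():
        raise ValueError("no occupied bins between the two minima")
    seg = profile.values[m]
    ends = [profile.interp(np.array([min_a]))[0], profile.interp(np.array([min_b]))[0]]
    return float(seg.max() - min(ends))


def convergence_rmsd(profiles: Sequence[FreeEnergyProfile]) -> np.ndarray:
    """Pairwise RMSD matrix (kcal/mol) between segment profiles.

    Each pair is compared over mutually occupied bins after re-referencing
    both profiles to zero mean on that bin set, so a constant offset between
    segments does not count as disagreement."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    grid = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.allclose(p.bin_centers, grid):
            raise ValueError("profiles must share one bin grid")
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = profiles[i].occupied & profiles[j].occupied
            if not m.any():
                raise ValueError(f"profiles {i} and {j} share no occupied bins")
            a = profiles[i].values[m]
            b = profiles[j].values[m]
            d = (a - a.mean()) - (b - b.mean())
            out[i, j] = out[j, i] = float(np.sqrt(np.mean(d * d)))
    return out
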