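"""Observables and scaling analyses of self-assembly trajectories.

Covers the quantities used to characterize the morphology and dynamics of
the assembling peptides:

* per-residue energy and mobility profiles over an equilibrated window;
* mean radius of gyration and RMS centre-of-mass displacement R_c(t) with
  the anomalous-diffusion exponent gamma from R_c ~ t^gamma (gamma = 1/2 is
  ordinary diffusion, gamma < 1/2 sub-diffusion inside aggregates);
* the radial residue-count profile about the aggregate's centre of mass;
* the static structure factor S(q) = |sum_j exp(i q.r_j)|^2 / N on the
  reciprocal lattice, and the effective (mass-scaling) dimension
  D = 1/nu from the power law S(q) ~ q^(-1/nu); D ~ 3 marks a compact
  solid, D ~ 2 an ideal-chain mass distribution, and any fitted D > 3 is
  flagged as a probable fit-window artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .energetics import Trajectory


def radius_of_gyration(coords: np.ndarray) -> float:
    """RMS distance of nodes from their centroid; coords unwrapped, (n, 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("expected (n, 3) coordinates")
    c = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - c) ** 2, axis=1))))


def mean_rg(traj: Trajectory) -> np.ndarray:
    """Mean radius of gyration over chains at every checkpoint."""
    cc = traj.chain_coords().astype(float)
    cen = cc.mean(axis=2, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((cc - cen) ** 2, axis=3), axis=2))
    return rg.mean(axis=1)


@dataclass
class PowerLawFit:
    exponent: float
    stderr: float
    window: tuple[float, float]
    n_points: int
    r_value: float = np.nan


@dataclass
class DynamicsSeries:
    """R_c(t) and Rg(t), averaged over chains (and trajectories)."""

    times: np.ndarray
    r_c: np.ndarray
    r_g: np.ndarray
    n_chains: int
    fit: PowerLawFit | None = None


def rms_com_displacement(trajs: Trajectory | list[Trajectory]) -> DynamicsSeries:
    """RMS displacement of chain centres of mass from their t=0 positions.

    R_c(t) = sqrt(<|com(t) - com(0)|^2>), the average running over chains and,
    when several replicate trajectories are given, over replicates as well.
    Requires unwrapped coordinates (as stored by the simulation driver).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    times = trajs[0].times
    sq, rg, n_tot = 0.0, 0.0, 0
    for t in trajs:
        if not np.array_equal(t.times, times):
            raise ValueError("trajectories have different checkpoint times")
        coms = t.coms().astype(float)
        disp = coms - coms[0]
        sq = sq + np.sum(np.sum(disp**2, axis=2), axis=1)
        rg = rg + mean_rg(t) * t.n_chains
        n_tot += t.n_chains
    return DynamicsSeries(times=times, r_c=np.sqrt(sq / n_tot),
                          r_g=rg / n_tot, n_chains=n_tot)


def fit_power_exponent(times, values, window: tuple[float, float] | None = None,
                       min_points: int = 5) -> PowerLawFit:
    """Least-squares slope of log(value) vs log(time) inside a time window.

    Defaults to the last decade of the series (asymptotic regime).  Raises
    if fewer than ``min_points`` strictly positive points fall in the window.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is None:
        tmax = times.max()
        window = (tmax / 10.0, tmax)
    lo, hi = window
    sel = (times >= lo) & (times <= hi) & (times > 0)
    if np.count_nonzero(sel) < min_points:
        raise ValueError(f"need >= {min_points} points in window {window}")
    if np.any(values[sel] <= 0):
        raise ValueError("power-law fit requires positive values in window")
    res = stats.linregress(np.log(times[sel]), np.log(values[sel]))
    return PowerLawFit(exponent=float(res.slope), stderr=float(res.stderr),
                       window=(float(lo), float(hi)),
                       n_points=int(np.count_nonzero(sel)),
                       r_value=float(res.rvalue))


@dataclass
class ProfileSeries:
    """Per-position profile along the chain (1-based positions)."""

    positions: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    observable: str
    T: float

    @property
    def argmax_position(self) -> int:
        return int(self.positions[np.argmax(self.mean)])

    @property
    def argmin_position(self) -> int:
        return int(self.positions[np.argmin(self.mean)])


def _window_indices(traj: Trajectory, window):
    if window is None:
        lo, hi = traj.times[-1] / 2.0, traj.times[-1]
    else:
        lo, hi = window
    idx = np.flatnonzero((traj.times >= lo) & (traj.times <= hi))
    if len(idx) == 0:
        raise ValueError(f"window {window} contains no checkpoints "
                         f"(times span {traj.times[0]}..{traj.times[-1]})")
    return idx


def energy_profile(trajs: Trajectory | list[Trajectory],
                   window: tuple[float, float] | None = None) -> ProfileSeries:
    """Mean per-position residue energy over the equilibrated window.

    Averages the per-node contact energy over checkpoints in the window
    (default: second half of the run), over all chains, and over replicate
    trajectories; the standard error is taken over chain means.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n = trajs[0].chain_length
    chain_means = []
    for t in trajs:
        idx = _window_indices(t, window)
        e = t.node_energy[idx].reshape(len(idx), t.n_chains, n)
        chain_means.append(e.mean(axis=0))
    cm = np.concatenate(chain_means, axis=0)        # (chains_total, n)
    return ProfileSeries(positions=np.arange(1, n + 1), mean=cm.mean(axis=0),
                         stderr=cm.std(axis=0, ddof=1) / np.sqrt(len(cm)),
                         observable="energy", T=trajs[0].config.T)


def mobility_profile(trajs: Trajectory | list[Trajectory],
                     window: tuple[float, float] | None = None) -> ProfileSeries:
    """Mean successful hops per residue per MCS over the window."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n = trajs[0].chain_length
    chain_means = []
    for t in trajs:
        idx = _window_indices(t, window)
        if len(idx) < 2 or t.times[idx[-1]] == t.times[idx[0]]:
            # zero-length window (e.g. an n_mcs = 0 run): mobility is zero
            chain_means.append(np.zeros((t.n_chains, n)))
            continue
        dh = (t.hops[idx[-1]] - t.hops[idx[0]]).astype(float)
        dt = float(t.times[idx[-1]] - t.times[idx[0]])
        chain_means.append((dh / dt).reshape(t.n_chains, n))
    cm = np.concatenate(chain_means, axis=0)
    return ProfileSeries(positions=np.arange(1, n + 1), mean=cm.mean(axis=0),
                         stderr=cm.std(axis=0, ddof=1) / np.sqrt(len(cm)),
                         observable="mobility", T=trajs[0].config.T)


@dataclass
class RadialProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    center: np.ndarray


def minimum_image_center(wrapped: np.ndarray, L: int) -> np.ndarray:
    """Centre of mass of a periodic point cloud via the circular mean."""
    theta = np.asarray(wrapped, dtype=float) * (2 * np.pi / L)
    c = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(c / (2 * np.pi / L), L)


def radial_distribution(positions: np.ndarray, L: int, bin_width: float = 1.0,
                        center: np.ndarray | None = None) -> RadialProfile:
    """Unnormalized residue counts in spherical shells about the cloud centre.

    ``positions`` may be wrapped or unwrapped; they are wrapped into the box
    and displacements are taken under the minimum-image convention.  The
    default centre is the minimum-image centre of mass of the residue cloud.
    """
    w = np.mod(np.asarray(positions, dtype=float), L)
    if center is None:
        center = minimum_image_center(w, L)
    d = w - center
    d -= L * np.round(d / L)
    r = np.sqrt(np.sum(d * d, axis=1))
    edges = np.arange(0.0, r.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(r, bins=edges)
    return RadialProfile(bin_edges=edges, counts=counts,
                         center=np.asarray(center))


@dataclass
class StructureFactorProfile:
    """Direction-averaged S(|q|) with an optional mass-scaling fit."""

    q: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    n_particles: float
    fit: "DimensionFit | None" = None


@dataclass
class DimensionFit:
    D: float
    stderr: float
    window: tuple[float, float]
    n_points: int
    flagged: bool    # True when D > 3: probable fit-window artifact


def _sq_grid(wrapped: np.ndarray, L: int) -> np.ndarray:
    """|FFT of the occupancy field|^2 / N on the full reciprocal lattice."""
    grid = np.zeros((L, L, L))
    idx = np.mod(np.round(wrapped).astype(np.int64), L)
    np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    F = np.fft.fftn(grid)
    return (F * F.conj()).real / len(wrapped)


def structure_factor(configs: np.ndarray | list[np.ndarray], L: int,
                     rel_bin_width: float = 0.05,
                     q_max: float | None = None) -> StructureFactorProfile:
    """S(q) on the reciprocal lattice, averaged over directions and samples.

    Each configuration is an (N, 3) array of lattice coordinates (wrapped
    internally).  q vectors are (2*pi/L) * (n_x, n_y, n_z); magnitudes are
    binned in logarithmic bins of 5% relative width by default.
    """
    if isinstance(configs, np.ndarray) and configs.ndim == 2:
        configs = [configs]
    acc = None
    n_part = 0.0
    for cfg in configs:
        s = _sq_grid(np.mod(np.asarray(cfg), L), L)
        acc = s if acc is None else acc + s
        n_part += len(cfg)
    acc /= len(configs)
    n_part /= len(configs)

    freq = 2 * np.pi * np.fft.fftfreq(L)
    qx, qy, qz = np.meshgrid(freq, freq, freq, indexing="ij")
    qmag = np.sqrt(qx**2 + qy**2 + qz**2).ravel()
    sval = acc.ravel()
    if q_max is None:
        q_max = np.pi  # Nyquist magnitude per axis
    sel = (qmag > 0) & (qmag <= q_max)
    qmag, sval = qmag[sel], sval[sel]

    qmin = 2 * np.pi / L
    n_bins = int(np.ceil(np.log(q_max / qmin) / np.log1p(rel_bin_width))) + 1
    edges = qmin * (1 + rel_bin_width) ** np.arange(-0.5, n_bins + 0.5)
    which = np.digitize(qmag, edges) - 1
    counts = np.bincount(which, minlength=n_bins + 1)[:n_bins]
    ssum = np.bincount(which, weights=sval, minlength=n_bins + 1)[:n_bins]
    qsum = np.bincount(which, weights=qmag, minlength=n_bins + 1)[:n_bins]
    nz = counts > 0
    return StructureFactorProfile(q=qsum[nz] / counts[nz],
                                  s=ssum[nz] / counts[nz],
                                  counts=counts[nz], n_particles=n_part)


def structure_factor_free(positions: np.ndarray | list[np.ndarray],
                          q_values: np.ndarray, n_directions: int = 24,
                          rng: np.random.Generator | None = None
                          ) -> StructureFactorProfile:
    """Direction-averaged S(|q|) for non-periodic (free) configurations.

    Evaluates the direct sum S(q) = |sum_j exp(i q.r_j)|^2 / N over
    ``n_directions`` random unit vectors per magnitude; appropriate for
    synthetic fixtures and closed-boundary states, where the reciprocal
    lattice of a periodic box does not apply.
    """
    if isinstance(positions, np.ndarray) and positions.ndim == 2:
        positions = [positions]
    rng = rng or np.random.default_rng(12345)
    v = rng.normal(size=(n_directions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    q_values = np.asarray(q_values, dtype=float)
    s = np.zeros(len(q_values))
    n_part = 0.0
    for pos in positions:
        pos = np.asarray(pos, dtype=float)
        proj = pos @ v.T                                    # (N, ndir)
        for k, q in enumerate(q_values):
            ph = np.exp(1j * q * proj)
            s[k] += float(np.mean(np.abs(ph.sum(axis=0)) ** 2)) / len(pos)
        n_part += len(pos)
    return StructureFactorProfile(q=q_values, s=s / len(positions),
                                  counts=np.full(len(q_values), n_directions),
                                  n_particles=n_part / len(positions))


def fit_effective_dimension(profile: StructureFactorProfile,
                            window: tuple[float, float],
                            min_points: int = 5) -> DimensionFit:
    """Effective dimension D = 1/nu from the power law S(q) ~ q^(-1/nu).

    D is minus the log-log slope of S(q) over the window.  Fits with D > 3
    are flagged: mass cannot scale faster than the embedding dimension, so
    such a value indicates fitting across the wrong q regime.
    """
    lo, hi = window
    sel = (profile.q >= lo) & (profile.q <= hi) & (profile.s > 0)
    if np.count_nonzero(sel) < min_points:
        raise ValueError(f"need >= {min_points} S(q) bins in window {window}")
    res = stats.linregress(np.log(profile.q[sel]), np.log(profile.s[sel]))
    D = -float(res.slope)
    fit = DimensionFit(D=D, stderr=float(res.stderr),
                       window=(float(lo), float(hi)),
                       n_points=int(np.count_nonzero(sel)),
                       flagged=D > 3.0 + 1e-6)
    profile.fit = fit
    return fit


def generate_fixture(kind: str, rng: np.random.Generator | None = None,
                     **params) -> np.ndarray:
    """Synthetic configurations with known analytic properties.

    kinds: ``rod`` (n, spacing), ``random_walk`` (n, unit lattice steps),
    ``point_cluster`` (n, all coincident), ``uniform_gas`` (n, L).
    """
    rng = rng or np.random.default_rng(0)
    if kind == "rod":
        n, spacing = params.get("n", 12), params.get("spacing", 2)
        out = np.zeros((n, 3))
        out[:, 0] = spacing * np.arange(n)
        return out
    if kind == "random_walk":
        n = params.get("n", 10_000)
        steps = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)])
        picks = rng.integers(0, 6, size=n - 1)
        return np.vstack([[0, 0, 0], np.cumsum(steps[picks], axis=0)])
    if kind == "point_cluster":
        n = params.get("n", 100)
        return np.zeros((n, 3))
    if kind == "uniform_gas":
        n, L = params.get("n", 1000), params.get("L", 32)
        return rng.integers(0, L, size=(n, 3)).astype(float)
    raise ValueError(f"unknown fixture kind {kind!r}")
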