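"""Stochastic single-mother-cell volume model for budding yeast.

A mother cell grows linearly in volume during each cell cycle and loses the
bud volume ``Vd`` at cytokinesis.  Cycle parameters — duration ``T`` (min),
growth rate ``mu`` (fL/min) and bud volume at division ``Vd`` (fL) — are drawn
per cycle from a multivariate log-normal distribution fitted to tracked-cell
records, subject to the aging constraint ``mu*T > Vd`` (the volume gained in a
cycle exceeds the volume lost at its end, so mother cells grow over
consecutive divisions).  Initial volumes are normal-distributed, and each cell
starts at a uniformly random phase of its first cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellCycleRecord",
    "CellCycleParams",
    "CellCycleDistribution",
    "VolumeTrajectory",
    "InvalidDataError",
    "InsufficientDataError",
    "ConstraintInfeasibleError",
    "fit_cell_cycle_distribution",
    "sample_cell_cycle",
    "simulate_volume",
    "read_cycle_annotations",
    "read_tracks",
]


class InvalidDataError(ValueError):
    """A record contains a non-positive or non-finite entry."""


class InsufficientDataError(ValueError):
    """Too few records to estimate the requested distribution."""


class ConstraintInfeasibleError(RuntimeError):
    """Rejection sampling failed to satisfy ``mu*T > Vd`` within the cap."""


@dataclass(frozen=True)
class CellCycleRecord:
    """One observed cell cycle: duration T (min), growth rate mu (fL/min),
    bud volume at division Vd (fL)."""

    T: float
    mu: float
    Vd: float


# sampled parameters share the record's shape; alias keeps intent clear
CellCycleParams = CellCycleRecord


@dataclass(frozen=True)
class CellCycleDistribution:
    """Multivariate log-normal over (T, mu, Vd) plus a normal initial-volume law.

    ``log_mean`` and ``log_cov`` are the mean vector and covariance matrix of
    ``(ln T, ln mu, ln Vd)``; ``v0_mean``/``v0_sd`` parameterise the normal
    distribution of mother-cell volume at t = 0 (fL).
    """

    log_mean: np.ndarray
    log_cov: np.ndarray
    v0_mean: float
    v0_sd: float

    def __post_init__(self) -> None:
        lm = np.asarray(self.log_mean, dtype=float)
        lc = np.asarray(self.log_cov, dtype=float)
        if lm.shape != (3,) or lc.shape != (3, 3):
            raise ValueError("log_mean must be a 3-vector and log_cov 3x3")
        if not np.allclose(lc, lc.T, atol=1e-10):
            raise ValueError("log_cov must be symmetric")
        if np.min(np.linalg.eigvalsh((lc + lc.T) / 2)) < -1e-10:
            raise ValueError("log_cov must be positive semidefinite")
        if self.v0_sd < 0:
            raise ValueError("v0_sd must be non-negative")
        object.__setattr__(self, "log_mean", lm)
        object.__setattr__(self, "log_cov", lc)

    @classmethod
    def degenerate(cls, T: float, mu: float, Vd: float,
                   v0_mean: float, v0_sd: float = 0.0) -> "CellCycleDistribution":
        """Point mass at (T, mu, Vd) — handy for analytic checks."""
        return cls(np.log([T, mu, Vd]), np.zeros((3, 3)), v0_mean, v0_sd)


@dataclass
class VolumeTrajectory:
    """Piecewise-linear mother+bud volume with division events.

    ``times``/``volume`` give the trajectory on a regular grid
    (right-continuous at divisions).  ``division_times``, ``f_per_cycle`` and
    ``cycle_params`` record the exact events: at division ``i`` the volume
    drops from ``V1 = seg_v0[i] + seg_mu[i]*(division_times[i]-seg_start[i])``
    to ``V1 - Vd``, i.e. is multiplied by the retained fraction
    ``f = (V1 - Vd)/V1``.
    """

    times: np.ndarray
    volume: np.ndarray
    division_times: np.ndarray
    f_per_cycle: np.ndarray
    cycle_params: list[CellCycleParams]
    seg_start: np.ndarray = field(repr=False, default=None)
    seg_v0: np.ndarray = field(repr=False, default=None)
    seg_mu: np.ndarray = field(repr=False, default=None)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def value(self, t, side: str = "right") -> np.ndarray:
        """Exact V(t); ``side`` picks the limit at division times (matched
        with a 1e-6 min tolerance to absorb float round-off)."""
        t = np.asarray(t, dtype=float)
        flat = np.atleast_1d(t)
        # nudge queries a hair above segment boundaries (right-continuous)
        idx = np.searchsorted(self.seg_start, flat + 1e-9, side="right") - 1
        idx = np.clip(idx, 0, len(self.seg_start) - 1)
        if side == "left" and self.division_times.size:
            near = np.min(np.abs(flat[:, None] - self.division_times[None, :]),
                          axis=1) < 1e-6
            idx = np.where(near & (idx > 0), idx - 1, idx)
        out = self.seg_v0[idx] + self.seg_mu[idx] * (flat - self.seg_start[idx])
        return out.reshape(t.shape) if t.shape else float(out[0])


def _validate_records(records) -> np.ndarray:
    arr = np.array([[r.T, r.mu, r.Vd] for r in records], dtype=float)
    for j, name in enumerate(("T", "mu", "Vd")):
        col = arr[:, j]
        if not np.all(np.isfinite(col)) or np.any(col <= 0):
            i = int(np.flatnonzero(~np.isfinite(col) | (col <= 0))[0])
            raise InvalidDataError(
                f"record {i}: field '{name}' must be finite and > 0, got {col[i]!r}"
            )
    return arr


def fit_cell_cycle_distribution(records, v0_samples) -> CellCycleDistribution:
    """Fit the log-normal cycle-parameter law and the normal initial-volume law.

    ``log_mean``/``log_cov`` are the empirical mean and (n-1)-normalised
    covariance of ``(ln T, ln mu, ln Vd)`` over the records; ``v0_mean``/
    ``v0_sd`` are the sample mean and SD of ``v0_samples``.
    """
    records = list(records)
    if len(records) < 3:
        raise InsufficientDataError(
            f"need at least 3 cycle records, got {len(records)}"
        )
    v0 = np.asarray(list(v0_samples), dtype=float)
    if v0.size < 2:
        raise InsufficientDataError(
            f"need at least 2 initial-volume samples, got {v0.size}"
        )
    if not np.all(np.isfinite(v0)) or np.any(v0 <= 0):
        raise InvalidDataError("v0_samples must be finite and > 0")
    logs = np.log(_validate_records(records))
    log_mean = logs.mean(axis=0)
    log_cov = np.cov(logs, rowvar=False, ddof=1)
    return CellCycleDistribution(
        log_mean=log_mean,
        log_cov=log_cov,
        v0_mean=float(v0.mean()),
        v0_sd=float(v0.std(ddof=1)),
    )


def sample_cell_cycle(dist: CellCycleDistribution, rng,
                      max_attempts: int = 10_000) -> CellCycleParams:
    """Draw (T, mu, Vd) from the log-normal law, rejecting draws with
    ``mu*T <= Vd`` so that every simulated cycle gains net volume."""
    rng = _as_rng(rng)
    for _ in range(max_attempts):
        z = rng.multivariate_normal(dist.log_mean, dist.log_cov,
                                    check_valid="ignore")
        T, mu, Vd = np.exp(z)
        if mu * T > Vd:
            return CellCycleParams(T=float(T), mu=float(mu), Vd=float(Vd))
    raise ConstraintInfeasibleError(
        f"mu*T > Vd not satisfied in {max_attempts} draws; "
        "the fitted cycle-parameter distribution looks pathological"
    )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_v0(dist: CellCycleDistribution, rng, max_attempts: int = 1000) -> float:
    for _ in range(max_attempts):
        v0 = rng.normal(dist.v0_mean, dist.v0_sd)
        if v0 > 0:
            return float(v0)
    raise ConstraintInfeasibleError("could not draw a positive initial volume")


def simulate_volume(dist: CellCycleDistribution, t_end: float, dt: float = 1.0,
                    rng=None, phase: float | None = None) -> VolumeTrajectory:
    """Simulate one mother cell's volume over ``[0, t_end]``.

    The cell starts a uniformly random phase ``tau`` into its first cycle:
    its volume at t=0 is ``V0 + mu_1*tau`` and the first division occurs at
    ``T_1 - tau``.  Each subsequent cycle draws fresh (T, mu, Vd).  ``phase``
    overrides the random phase (as a time in minutes) for deterministic tests.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    rng = _as_rng(rng)

    first = sample_cell_cycle(dist, rng)
    v0_birth = _draw_v0(dist, rng)
    tau = rng.uniform(0.0, first.T) if phase is None else float(phase)

    seg_start, seg_v0, seg_mu = [0.0], [v0_birth + first.mu * tau], [first.mu]
    division_times, f_per_cycle, cycle_params = [], [], [first]
    t_cur, remaining = 0.0, first.T - tau
    params = first
    while t_cur + remaining < t_end:
        t_div = t_cur + remaining
        v1 = seg_v0[-1] + params.mu * (t_div - seg_start[-1])
        f = (v1 - params.Vd) / v1
        division_times.append(t_div)
        f_per_cycle.append(f)
        params = sample_cell_cycle(dist, rng)
        cycle_params.append(params)
        seg_start.append(t_div)
        seg_v0.append(v1 * f)
        seg_mu.append(params.mu)
        t_cur, remaining = t_div, params.T

    traj = VolumeTrajectory(
        times=None, volume=None,
        division_times=np.asarray(division_times),
        f_per_cycle=np.asarray(f_per_cycle),
        cycle_params=cycle_params,
        seg_start=np.asarray(seg_start),
        seg_v0=np.asarray(seg_v0),
        seg_mu=np.asarray(seg_mu),
    )
    grid = np.arange(0.0, t_end + dt * 0.5, dt)
    traj.times = grid
    traj.volume = traj.value(grid)
    return traj


# ---------------------------------------------------------------------------
# Tabular I/O: BudJ-like cell-track and cycle-annotation tables

TRACK_COLUMNS = ("cell_id", "time_min", "volume_fL", "fluorescence_au")
CYCLE_COLUMNS = ("cell_id", "cycle_index", "T_min", "mu_fL_per_min", "Vd_fL")


def _read_table(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidDataError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_tracks(path) -> pd.DataFrame:
    """Read a cell-track table (one row per cell_id, time_min)."""
    return _read_table(path, TRACK_COLUMNS)


def read_cycle_annotations(path) -> list[CellCycleRecord]:
    """Read a cycle-annotation table into per-cycle records."""
    df = _read_table(path, CYCLE_COLUMNS)
    return [
        CellCycleRecord(T=float(r.T_min), mu=float(r.mu_fL_per_min),
                        Vd=float(r.Vd_fL))
        for r in df.itertuples()
    ]


def fit_from_tables(tracks: pd.DataFrame, records) -> CellCycleDistribution:
    """Fit the distribution from a track table (volumes at t = 0 provide the
    initial-volume samples) and cycle annotations."""
    if isinstance(tracks, (str, bytes)) or hasattr(tracks, "__fspath__"):
        tracks = read_tracks(tracks)
    if not isinstance(records, list) or (records and not
                                         isinstance(records[0], CellCycleRecord)):
        records = read_cycle_annotations(records)
    t0 = tracks["time_min"].min()
    v0 = tracks.loc[tracks["time_min"] == t0].sort_values("cell_id")["volume_fL"]
    return fit_cell_cycle_distribution(records, v0.to_numpy())
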