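"""Ground-truthed synthetic datasets with the structure of single-cell
time-lapse microscopy of light-induced FP expression in yeast mother cells.

The generator reproduces the study design the analysis assumes: a few dozen
mother cells tracked from induction, fluorescence concentration sampled every
5 min up to 200 min, cell-cycle parameters drawn per cycle from a right-skewed
multivariate log-normal, additive Gaussian noise with
``sigma = 0.02 * max(signal)`` on the population mean, and autofluorescence
removal emulated by forcing the t = 0 value to zero.  Every dataset records
its generating parameters, distribution and seed, and can emit the same
delimited track / cycle-annotation tables the volume module reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    AbundanceParams,
    CycleTrace,
    HistonePulseSpec,
    ShutoffTrace,
    forward_volumes,
    simulate_chx_shutoff,
    simulate_single_cell,
    _pulse_matrices,
)
from .volume import CellCycleDistribution, CYCLE_COLUMNS, TRACK_COLUMNS
from scipy.linalg import expm

__all__ = [
    "FluorescenceDataset",
    "default_cell_cycle",
    "preset_params",
    "PRESETS",
    "generate_dataset",
    "generate_chx_dataset",
    "generate_histone_dataset",
]

LN2 = math.log(2.0)


def default_cell_cycle() -> CellCycleDistribution:
    """Fixture cell-cycle law: mean cycle 80 min (fast glucose medium),
    growth 0.2 fL/min, bud volume 12 fL, with 20/20/30% log-scale CVs and
    initial mother volumes N(30, 5^2) fL."""
    return CellCycleDistribution(
        log_mean=np.log([80.0, 0.2, 12.0]),
        log_cov=np.diag([0.04, 0.04, 0.09]),
        v0_mean=30.0,
        v0_sd=5.0,
    )


#: ground-truth kinetic presets; maturation half-times follow the estimates
#: for the corresponding FPs (amplitude and mRNA turnover are nuisance
#: parameters: k_p = k_r = 1, mRNA half-life 10 min).
PRESETS = {
    "sfgfp": dict(kind="one_step", t50=6.9),
    "mvenus": dict(kind="one_step", t50=20.8),
    "two_step_22": dict(kind="two_step", t50=22.0),   # per-step half-time
}


def preset_params(name: str, tau1: float = 2.0, tau2: float = 4.0) -> AbundanceParams:
    try:
        spec = PRESETS[name.lower().replace("-", "_")]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    k = LN2 / spec["t50"]
    common = dict(k_r=1.0, k_dr=LN2 / 10.0, k_p=1.0, tau1=tau1, tau2=tau2)
    if spec["kind"] == "one_step":
        return AbundanceParams(kind="one_step", k_m=k, **common)
    return AbundanceParams(kind="two_step", k_m1=k, k_m2=k, **common)


@dataclass
class FluorescenceDataset:
    """Per-cell and population-averaged FP concentration time series.

    ``mean_trace`` is the observed (noisy, baseline-subtracted) population
    mean that estimation consumes; ``cell_traces`` holds the per-cell traces
    (noiseless unless per-cell noise was requested).  ``cell_cycle`` is the
    distribution driving the forward model and ``ground_truth`` records the
    generating parameters and seed.
    """

    t_grid: np.ndarray
    cell_traces: np.ndarray | None
    mean_trace: np.ndarray
    sigma: float
    cell_cycle: CellCycleDistribution
    ground_truth: dict = field(default_factory=dict)
    volumes: list = field(default_factory=list, repr=False)

    @property
    def n_cells(self) -> int:
        return 0 if self.cell_traces is None else self.cell_traces.shape[0]

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Emit the BudJ-like track table (cell_id, time_min, volume_fL,
        fluorescence_au) and the cycle-annotation table."""
        track_rows, cycle_rows = [], []
        for i, vol in enumerate(self.volumes):
            cid = f"cell_{i:03d}"
            v = vol.value(self.t_grid)
            f = self.cell_traces[i]
            for t, vv, ff in zip(self.t_grid, v, f):
                track_rows.append((cid, t, vv, ff))
            for ci, cp in enumerate(vol.cycle_params):
                cycle_rows.append((cid, ci, cp.T, cp.mu, cp.Vd))
        tracks = pd.DataFrame(track_rows, columns=list(TRACK_COLUMNS))
        cycles = pd.DataFrame(cycle_rows, columns=list(CYCLE_COLUMNS))
        return tracks, cycles


def generate_dataset(truth: AbundanceParams,
                     dist: CellCycleDistribution | None = None,
                     n_cells: int = 50,
                     noise_rule: str | None = "mean",
                     seed: int = 0,
                     t_grid=None,
                     sigma_frac: float = 0.02,
                     dt: float = 0.05) -> FluorescenceDataset:
    """Simulate a tracked mother-cell fluorescence dataset.

    ``noise_rule`` is ``"mean"`` (Gaussian noise on the population mean, the
    observation model used for fitting), ``"per_cell"`` (noise on every
    single-cell trace) or ``None`` (noise-free).  The t = 0 value of the
    observed series is forced to zero, emulating the subtraction of each
    cell's pre-induction autofluorescence.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_rule not in ("mean", "per_cell", None):
        raise ValueError("noise_rule must be 'mean', 'per_cell' or None")
    dist = dist or default_cell_cycle()
    t_grid = (np.arange(0.0, 200.0 + 2.5, 5.0) if t_grid is None
              else np.asarray(t_grid, dtype=float))

    ss = np.random.SeedSequence(seed)
    ss_cells, ss_noise = ss.spawn(2)
    noise_rng = np.random.default_rng(ss_noise)
    vols = forward_volumes(dist, n_cells, ss_cells, float(t_grid.max()))
    traces = np.empty((n_cells, t_grid.size))
    for i, vol in enumerate(vols):
        traces[i] = simulate_single_cell(truth, vol, t_grid, dt=dt).conc

    clean_mean = traces.mean(axis=0)
    sigma = sigma_frac * float(np.max(np.abs(clean_mean)))
    if noise_rule == "per_cell":
        traces = traces + noise_rng.normal(0.0, sigma, traces.shape)
        traces = traces - traces[:, :1]
        y = traces.mean(axis=0)
    elif noise_rule == "mean":
        y = clean_mean + noise_rng.normal(0.0, sigma, clean_mean.shape)
        y[0] = 0.0          # baseline subtraction pins the t = 0 sample
    else:
        y = clean_mean.copy()

    truth_record = {
        "params": truth,
        "dist": dist,
        "seed": seed,
        "sigma": sigma,
        "noise_rule": noise_rule,
        "half_time_truth": None,
    }
    from .kinetics import maturation_half_time
    truth_record["half_time_truth"] = maturation_half_time(
        truth.kind, truth.maturation_rates)
    return FluorescenceDataset(
        t_grid=t_grid, cell_traces=traces, mean_trace=y, sigma=sigma,
        cell_cycle=dist, ground_truth=truth_record, volumes=vols,
    )


#: four-FP shutoff fixture: half-times ordered sfGFP < mVenus < mCherry <
#: mKate2 (one-step for the avGFP-derived pair, tied two-step for the RFPs;
#: the mKate2 step half-time of 40 min encodes only "slower than mCherry").
CHX_PRESETS = {
    "sfGFP": ("one_step", 6.9),
    "mVenus": ("one_step", 20.8),
    "mCherry": ("two_step", 22.0),
    "mKate2": ("two_step", 40.0),
}


def _chx_params(kind: str, step_t50: float) -> AbundanceParams:
    k = LN2 / step_t50
    common = dict(k_r=1.0, k_dr=LN2 / 10.0, k_p=1.0)
    if kind == "one_step":
        return AbundanceParams(kind="one_step", k_m=k, **common)
    return AbundanceParams(kind="two_step", k_m1=k, k_m2=k, **common)


def generate_chx_dataset(truths: dict[str, AbundanceParams] | None = None,
                         growth_rate: float = LN2 / 80.0,
                         seed: int = 0,
                         t_grid=None,
                         noise_frac: float = 0.01) -> dict[str, ShutoffTrace]:
    """Noisy normalised translation-shutoff traces for a panel of FPs, each
    starting from balanced-growth steady state."""
    t_grid = (np.arange(0.0, 121.0, 5.0) if t_grid is None
              else np.asarray(t_grid, dtype=float))
    if truths is None:
        truths = {name: _chx_params(kind, t50)
                  for name, (kind, t50) in CHX_PRESETS.items()}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = {}
    for name, params in truths.items():
        clean = simulate_chx_shutoff(params, growth_rate, t_grid)
        noisy = clean.rel_fluorescence + rng.normal(
            0.0, noise_frac * clean.plateau, t_grid.shape)
        out[name] = ShutoffTrace(times=t_grid, rel_fluorescence=noisy,
                                 plateau=clean.plateau)
    return out


def _histone_boundary_state(spec: HistonePulseSpec, fp: AbundanceParams,
                            T: float, n_cycles: int = 400,
                            rtol: float = 1e-9) -> np.ndarray:
    A_on, A_off = _pulse_matrices(spec, fp)
    ts, te = spec.pulse_start * T, spec.pulse_end * T
    segs = [(a, b, A) for a, b, A in
            ((0.0, ts, A_off), (ts, te, A_on), (te, T, A_off)) if b > a]
    props = [expm(A * (b - a)) for a, b, A in segs]
    z = np.zeros(A_on.shape[0])
    z[0] = 1.0
    for _ in range(n_cycles):
        z_prev = z.copy()
        for P in props:
            z = P @ z
        z[1:] *= spec.retained_fraction
        scale = max(np.abs(z[1:]).max(), 1e-300)
        if np.abs(z[1:] - z_prev[1:]).max() <= rtol * scale:
            break
    return z


def _histone_eval(spec: HistonePulseSpec, fp: AbundanceParams, T: float,
                  z0: np.ndarray, t: float) -> float:
    """Total fluorescence at time t in [0, T] of a cycle starting at z0."""
    A_on, A_off = _pulse_matrices(spec, fp)
    ts, te = spec.pulse_start * T, spec.pulse_end * T
    zi = z0.copy()
    for a, b, A in ((0.0, ts, A_off), (ts, te, A_on), (te, T, A_off)):
        if t <= a or b <= a:
            break
        zi = expm(A * (min(t, b) - a)) @ zi
    return float(zi[-1])


def generate_histone_dataset(spec: HistonePulseSpec,
                             fp_params: AbundanceParams,
                             n_cells: int = 10,
                             seed: int = 0,
                             T_mean: float = 100.0,
                             T_log_sd: float = 0.1,
                             sample_dt: float = 5.0,
                             noise_frac: float = 0.02,
                             n_cycles: int = 2) -> list[CycleTrace]:
    """Per-cycle histone-FP fluorescence traces with budding/karyokinesis
    annotations, sampled every ``sample_dt`` min over ``n_cycles`` periodic
    cycles per cell (cycle durations log-normal around ``T_mean``)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    traces = []
    for i in range(n_cells):
        T = float(np.exp(rng.normal(np.log(T_mean), T_log_sd)))
        z = _histone_boundary_state(spec, fp_params, T)
        scale = max(abs(_histone_eval(spec, fp_params, T, z, T)), 1e-300)
        for cyc in range(n_cycles):
            t_local = np.append(np.arange(0.0, T - 1e-9, sample_dt), T)
            vals = np.array([_histone_eval(spec, fp_params, T, z, t)
                             for t in t_local])
            if noise_frac > 0:
                vals = vals + rng.normal(0.0, noise_frac * scale, vals.shape)
            offset = cyc * T
            traces.append(CycleTrace(
                time=t_local + offset, value=vals,
                budding_time=spec.budding * T + offset,
                cell_id=f"cell_{i:03d}/cycle_{cyc}",
            ))
            # z is the cycle-periodic boundary state: every cycle repeats it
    return traces
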