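"""Delayed gene-expression kinetics of fluorescent-protein (FP) maturation.

The abundance model is a linear delay-differential cascade driven by a step
light input: transcription switches on a delay ``tau1`` after induction, each
mRNA is translated with a delay ``tau2`` (reading the mRNA *history*), and the
dark FP precursor matures into the fluorescent form through one or two
first-order steps::

    one-step                          two-step
    dm/dt   = k_r s(t-tau1) - k_dr m  dm/dt    = k_r s(t-tau1) - k_dr m
    dPd/dt  = k_p m(t-tau2) - k_m Pd  dPd1/dt  = k_p m(t-tau2) - k_m1 Pd1
    dPm/dt  = k_m Pd                  dPd2/dt  = k_m1 Pd1 - k_m2 Pd2
                                      dPm/dt   = k_m2 Pd2

All states are zero for ``t < tau1``.  When the cascade is driven over a
dividing mother-cell volume trajectory, every species is multiplied by the
retained fraction ``f_c`` at each division; the delayed translation term reads
the pre-reset mRNA history for arguments before a division (ribosome loading
reflects past mRNA levels).  The measured quantity is the mature-FP
concentration ``P_m(t)/V(t)``, which is continuous across divisions because
abundance and volume are rescaled by the same factor.

Integration uses the method of steps: fixed-step RK4 on a mesh that contains
every discontinuity point (``tau1``, ``tau1+tau2``, division times and their
``tau2``-shifted images), with cubic-Hermite interpolation of the stored mRNA
history for the delayed argument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .volume import VolumeTrajectory, CellCycleDistribution, simulate_volume

__all__ = [
    "AbundanceParams",
    "AbundanceState",
    "ConcentrationTrace",
    "HistonePulseSpec",
    "HistoneProfile",
    "ShutoffTrace",
    "AlignedProfiles",
    "CycleTrace",
    "NumericalError",
    "AnnotationError",
    "simulate_single_cell",
    "closed_form_onestep",
    "population_average",
    "maturation_half_time",
    "two_step_lower_bound",
    "simulate_chx_shutoff",
    "simple_concentration_model",
    "dilution_rate_from_distribution",
    "histone_pulse_model",
    "align_cell_cycle_traces",
    "half_time_to_rate",
    "rate_to_half_time",
]

LN2 = math.log(2.0)


class NumericalError(RuntimeError):
    """Integration failure (negative state / blow-up)."""


class AnnotationError(ValueError):
    """Missing or misordered cell-cycle event annotations."""


def half_time_to_rate(t50: float) -> float:
    """First-order half-time (min) -> rate constant (1/min)."""
    if t50 <= 0:
        raise ValueError("half-time must be positive")
    return LN2 / t50


def rate_to_half_time(k: float) -> float:
    """First-order rate constant (1/min) -> half-time (min)."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return LN2 / k


@dataclass(frozen=True)
class AbundanceParams:
    """Kinetic parameters of the FP abundance model.

    Rates are per minute; ``k_r`` is the promoter-on transcription rate
    (molecules/min), ``k_dr`` the mRNA degradation rate, ``k_p`` the
    per-mRNA translation rate.  ``kind`` selects one-step (``k_m``) or
    two-step (``k_m1``, ``k_m2``) maturation; for the two-step model
    ``k_m2`` defaults to ``k_m1`` (the tied-rate convention used during
    inference).  ``tau1`` is the light-to-promoter delay and ``tau2`` the
    mRNA-to-immature-protein delay (min).
    """

    kind: str
    k_r: float
    k_dr: float
    k_p: float
    k_m: float | None = None
    k_m1: float | None = None
    k_m2: float | None = None
    tau1: float = 2.0
    tau2: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("one_step", "two_step"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "one_step":
            if self.k_m is None:
                raise ValueError("one-step model requires k_m")
        else:
            if self.k_m1 is None:
                raise ValueError("two-step model requires k_m1")
            if self.k_m2 is None:
                object.__setattr__(self, "k_m2", self.k_m1)
        for name in ("k_r", "k_dr", "k_p", "k_m", "k_m1", "k_m2",
                     "tau1", "tau2"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def maturation_rates(self) -> tuple[float, ...]:
        if self.kind == "one_step":
            return (self.k_m,)
        return (self.k_m1, self.k_m2)

    def replace(self, **kw) -> "AbundanceParams":
        d = {f: getattr(self, f) for f in
             ("kind", "k_r", "k_dr", "k_p", "k_m", "k_m1", "k_m2",
              "tau1", "tau2")}
        d.update(kw)
        return AbundanceParams(**d)


@dataclass
class AbundanceState:
    """Species abundances at one or more time points."""

    m: np.ndarray
    Pm: np.ndarray
    Pd: np.ndarray | None = None
    Pd1: np.ndarray | None = None
    Pd2: np.ndarray | None = None


@dataclass
class ConcentrationTrace:
    """Mature-FP concentration ``P_m/V`` (au/fL) on a time grid, with
    left/right concentration limits at division events for continuity
    diagnostics."""

    times: np.ndarray
    conc: np.ndarray
    division_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    conc_pre: np.ndarray = field(default_factory=lambda: np.empty(0))
    conc_post: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Method-of-steps integrator


def _build_mesh(t_end: float, dt: float, critical: np.ndarray) -> np.ndarray:
    base = np.arange(0.0, t_end, dt)
    pts = np.concatenate([base, [t_end], critical])
    pts = pts[(pts >= 0.0) & (pts <= t_end)]
    pts = np.sort(pts)
    keep = np.concatenate([[True], np.diff(pts) > 1e-9])
    return pts[keep]


def _integrate_cascade(params: AbundanceParams,
                       t_end: float,
                       dt: float,
                       div_times: np.ndarray,
                       div_factors: np.ndarray,
                       dilution: float = 0.0,
                       rates_override: dict | None = None,
                       extra_times=None):
    """Integrate the delayed cascade; kinetic rates may be 1-D arrays of a
    common length M (vectorised parameter sweeps share the division events).

    Returns ``(mesh, states, div_records)`` where ``states`` maps species name
    to an ``(n_mesh, M)`` array (post-reset values at division mesh points)
    and ``div_records`` is a list of ``(t_div, pre, post)`` state snapshots.
    """
    ro = rates_override or {}

    def _rate(name):
        v = ro.get(name, getattr(params, name))
        return np.atleast_1d(np.asarray(v, dtype=float))

    two = params.kind == "two_step"
    k_r, k_dr, k_p = _rate("k_r"), _rate("k_dr"), _rate("k_p")
    if two:
        k1, k2 = _rate("k_m1"), _rate("k_m2")
        kmax = max(k_dr.max(), k1.max(), k2.max())
    else:
        km = _rate("k_m")
        kmax = max(k_dr.max(), km.max())
    M = max(a.size for a in ([k_r, k_dr, k_p] + ([k1, k2] if two else [km])))
    tau1, tau2 = params.tau1, params.tau2

    # explicit RK4 stability cap; delayed argument must stay in the past
    dt_eff = min(dt, 2.0 / (kmax + dilution + 1e-12))
    if tau2 > 0:
        dt_eff = min(dt_eff, tau2)

    div_times = np.asarray(div_times, dtype=float)
    div_factors = np.asarray(div_factors, dtype=float)
    critical = np.concatenate([
        [tau1, tau1 + tau2], div_times, div_times + tau2,
        np.asarray(extra_times, dtype=float).ravel()
        if extra_times is not None else np.empty(0),
    ])
    mesh = _build_mesh(t_end, dt_eff, critical)
    n_mesh = mesh.size
    n_div = div_times.size

    # mRNA history with duplicated entries at divisions (pre/post reset);
    # Hermite interpolation needs values and slopes
    cap = n_mesh + 2 * n_div + 2
    ht = np.empty(cap)
    hm = np.empty((cap, M))
    hd = np.empty((cap, M))
    n_h = 0
    kdr_eff = k_dr + dilution

    def _push(t, m):
        nonlocal n_h
        ht[n_h] = t
        hm[n_h] = m
        hd[n_h] = k_r * (1.0 if t >= tau1 else 0.0) - kdr_eff * m
        n_h += 1

    def _m_delayed(q):
        if q <= tau1:
            return 0.0
        i = np.searchsorted(ht[:n_h], q, side="left")
        if i <= 0:
            return 0.0
        if i >= n_h:
            return hm[n_h - 1]
        if ht[i] == q:
            return hm[i]
        t0, t1 = ht[i - 1], ht[i]
        h = t1 - t0
        s = (q - t0) / h
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return (h00 * hm[i - 1] + h01 * hm[i]
                + h * (h10 * hd[i - 1] + h11 * hd[i]))

    zeros = np.zeros(M)
    m = zeros.copy()
    if two:
        p1, p2 = zeros.copy(), zeros.copy()
    else:
        pd = zeros.copy()
    pm = zeros.copy()

    names = ("m", "Pd1", "Pd2", "Pm") if two else ("m", "Pd", "Pm")
    out = {nm: np.empty((n_mesh, M)) for nm in names}

    def _record(i):
        out["m"][i] = m
        out["Pm"][i] = pm
        if two:
            out["Pd1"][i], out["Pd2"][i] = p1, p2
        else:
            out["Pd"][i] = pd

    def _snapshot():
        if two:
            return {"m": m.copy(), "Pd1": p1.copy(), "Pd2": p2.copy(),
                    "Pm": pm.copy()}
        return {"m": m.copy(), "Pd": pd.copy(), "Pm": pm.copy()}

    _push(mesh[0], m)
    _record(0)
    div_records = []
    div_idx = np.clip(np.searchsorted(mesh, div_times), 1, n_mesh - 1)
    for j in range(div_idx.size):       # snap to the nearest mesh point
        i = div_idx[j]
        if abs(mesh[i - 1] - div_times[j]) < abs(mesh[i] - div_times[j]):
            div_idx[j] = i - 1
    div_at = {int(i): f for i, f in zip(div_idx, div_factors)}

    for i in range(1, n_mesh):
        t0, t1 = mesh[i - 1], mesh[i]
        h = t1 - t0
        s_on = 1.0 if (t0 + t1) * 0.5 >= tau1 else 0.0
        trans = k_r * s_on
        d0 = k_p * _m_delayed(t0 - tau2)
        dh = k_p * _m_delayed(t0 + 0.5 * h - tau2)
        d1 = k_p * _m_delayed(t1 - tau2)

        if two:
            def deriv(mm, q1, q2, qm, dly):
                return (trans - kdr_eff * mm,
                        dly - (k1 + dilution) * q1,
                        k1 * q1 - (k2 + dilution) * q2,
                        k2 * q2 - dilution * qm)

            a = deriv(m, p1, p2, pm, d0)
            b = deriv(m + 0.5 * h * a[0], p1 + 0.5 * h * a[1],
                      p2 + 0.5 * h * a[2], pm + 0.5 * h * a[3], dh)
            c = deriv(m + 0.5 * h * b[0], p1 + 0.5 * h * b[1],
                      p2 + 0.5 * h * b[2], pm + 0.5 * h * b[3], dh)
            d = deriv(m + h * c[0], p1 + h * c[1],
                      p2 + h * c[2], pm + h * c[3], d1)
            m = m + (h / 6) * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
            p1 = p1 + (h / 6) * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
            p2 = p2 + (h / 6) * (a[2] + 2 * b[2] + 2 * c[2] + d[2])
            pm = pm + (h / 6) * (a[3] + 2 * b[3] + 2 * c[3] + d[3])
        else:
            def deriv(mm, qd, qm, dly):
                return (trans - kdr_eff * mm,
                        dly - (km + dilution) * qd,
                        km * qd - dilution * qm)

            a = deriv(m, pd, pm, d0)
            b = deriv(m + 0.5 * h * a[0], pd + 0.5 * h * a[1],
                      pm + 0.5 * h * a[2], dh)
            c = deriv(m + 0.5 * h * b[0], pd + 0.5 * h * b[1],
                      pm + 0.5 * h * b[2], dh)
            d = deriv(m + h * c[0], pd + h * c[1], pm + h * c[2], d1)
            m = m + (h / 6) * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
            pd = pd + (h / 6) * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
            pm = pm + (h / 6) * (a[2] + 2 * b[2] + 2 * c[2] + d[2])

        if i in div_at:
            pre = _snapshot()
            _push(t1, m)          # pre-reset history entry
            f = div_at[i]
            m = m * f
            pm = pm * f
            if two:
                p1, p2 = p1 * f, p2 * f
            else:
                pd = pd * f
            _push(t1, m)          # post-reset history entry
            div_records.append((t1, pre, _snapshot()))
        else:
            _push(t1, m)
        _record(i)

    floor = -1e-9 * max(out["Pm"].max(), 1.0)
    if min(arr.min() for arr in out.values()) < floor:
        raise NumericalError(
            "negative state encountered during integration; "
            "reduce the integration step dt"
        )
    return mesh, out, div_records


def _sample_mesh(mesh: np.ndarray, arr: np.ndarray, t) -> np.ndarray:
    """Read an (n_mesh, M) mesh array at times t (mesh points or between)."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(mesh, t)
    idx = np.clip(idx, 0, mesh.size - 1)
    exact = np.abs(mesh[idx] - t) <= 1e-9
    if np.all(exact):
        return arr[idx]
    lo = np.clip(idx - 1, 0, mesh.size - 1)
    w = np.where(exact, 1.0,
                 (t - mesh[lo]) / np.maximum(mesh[idx] - mesh[lo], 1e-300))
    return arr[lo] * (1 - w[:, None]) + arr[idx] * w[:, None]


def simulate_single_cell(params: AbundanceParams, vol: VolumeTrajectory,
                         t_grid, dt: float = 0.05) -> ConcentrationTrace:
    """Integrate the abundance cascade over one mother-cell volume trajectory
    and return the mature-FP concentration ``P_m/V`` on ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.min() < -1e-9 or t_grid.max() > vol.t_end + 1e-9:
        raise ValueError(
            f"t_grid spans [{t_grid.min()}, {t_grid.max()}] but the volume "
            f"trajectory only covers [0, {vol.t_end}]"
        )
    t_end = float(t_grid.max())
    within = vol.division_times[(vol.division_times > 0)
                                & (vol.division_times < t_end)]
    factors = vol.f_per_cycle[: within.size]
    mesh, out, div_records = _integrate_cascade(
        params, t_end, dt, within, factors, extra_times=t_grid)
    pm = _sample_mesh(mesh, out["Pm"], t_grid)[:, 0]
    # stored abundances are post-reset at divisions inside the window, so
    # pair them with the right volume limit there; elsewhere (including a
    # division falling exactly on the final grid point) use the left limit
    v = vol.value(t_grid, side="left")
    if within.size:
        at_div = np.min(np.abs(t_grid[:, None] - within[None, :]),
                        axis=1) < 1e-6
        if at_div.any():
            v = np.where(at_div, vol.value(t_grid, side="right"), v)
    conc = pm / v
    pre = np.array([rec[1]["Pm"][0] for rec in div_records])
    post = np.array([rec[2]["Pm"][0] for rec in div_records])
    v_pre = vol.value(within, side="left")
    v_post = vol.value(within, side="right")
    return ConcentrationTrace(
        times=t_grid, conc=conc, division_times=within,
        conc_pre=pre / v_pre if pre.size else pre,
        conc_post=post / v_post if post.size else post,
    )


def population_average(params: AbundanceParams, dist: CellCycleDistribution,
                       n_cells: int, t_grid, rng_seed, dt: float = 0.05,
                       return_cells: bool = False):
    """Average the single-cell concentration over ``n_cells`` independent
    volume trajectories (500 cells by default in the fitting forward model).
    Deterministic given the seed: cell ``i`` uses the ``i``-th spawned
    child stream."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t_grid = np.asarray(t_grid, dtype=float)
    vols = forward_volumes(dist, n_cells, rng_seed, float(t_grid.max()))
    traces = np.empty((n_cells, t_grid.size))
    for i, vol in enumerate(vols):
        traces[i] = simulate_single_cell(params, vol, t_grid, dt=dt).conc
    mean = traces.mean(axis=0)
    trace = ConcentrationTrace(times=t_grid, conc=mean)
    if return_cells:
        return trace, traces
    return trace


def forward_volumes(dist: CellCycleDistribution, n_cells: int, seed,
                    t_end: float) -> list[VolumeTrajectory]:
    """The volume trajectories underlying a seeded forward simulation.

    Shared by :func:`population_average` and the grid-based likelihood so
    that both evaluate the identical stochastic realisation (common random
    numbers across parameter values).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_cells)
    return [simulate_volume(dist, t_end + 1e-9, dt=t_end,
                            rng=np.random.default_rng(c)) for c in children]


def population_mean_vectorized(template: AbundanceParams,
                               vols: list[VolumeTrajectory],
                               t_grid, dt: float,
                               rates_override: dict) -> np.ndarray:
    """Population-mean concentration for many kinetic parameter values at
    once.

    ``rates_override`` maps rate names to scalars or length-M arrays; every
    cell in ``vols`` is integrated once with all M parameter vectors sharing
    its division events.  Returns an ``(len(t_grid), M)`` array — identical,
    value for value, to averaging :func:`simulate_single_cell` over the same
    trajectories at each parameter vector.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_end = float(t_grid.max())
    accum = None
    for vol in vols:
        within = vol.division_times[(vol.division_times > 0)
                                    & (vol.division_times < t_end)]
        factors = vol.f_per_cycle[: within.size]
        mesh, out, _ = _integrate_cascade(
            template, t_end, dt, within, factors,
            rates_override=rates_override, extra_times=t_grid)
        pm = _sample_mesh(mesh, out["Pm"], t_grid)
        v = vol.value(t_grid, side="left")
        if within.size:
            at_div = np.min(np.abs(t_grid[:, None] - within[None, :]),
                            axis=1) < 1e-6
            if at_div.any():
                v = np.where(at_div, vol.value(t_grid, side="right"), v)
        contrib = pm / v[:, None]
        accum = contrib if accum is None else accum + contrib
    return accum / len(vols)


# ---------------------------------------------------------------------------
# Closed-form oracle (no divisions, one-step)


def closed_form_onestep(params: AbundanceParams, t) -> AbundanceState:
    """Exact solution of the one-step cascade with constant volume and no
    divisions, via the matrix exponential of the augmented linear system
    (valid for any rate combination, including coincident rates)."""
    if params.kind != "one_step":
        raise ValueError("closed_form_onestep requires a one-step model")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k_r, k_dr, k_p, k_m = params.k_r, params.k_dr, params.k_p, params.k_m
    tau1, tau2 = params.tau1, params.tau2

    m = np.zeros_like(t)
    u = t - tau1
    pos = u > 0
    if k_dr > 0:
        m[pos] = (k_r / k_dr) * (1.0 - np.exp(-k_dr * u[pos]))
    else:
        m[pos] = k_r * u[pos]

    # augmented state z = (1, m(t - tau2), Pd, Pm) in w = t - tau1 - tau2
    A = np.array([
        [0.0, 0.0, 0.0, 0.0],
        [k_r, -k_dr, 0.0, 0.0],
        [0.0, k_p, -k_m, 0.0],
        [0.0, 0.0, k_m, 0.0],
    ])
    pd = np.zeros_like(t)
    pm = np.zeros_like(t)
    z0 = np.array([1.0, 0.0, 0.0, 0.0])
    for i, w in enumerate(t - tau1 - tau2):
        if w > 0:
            z = expm(A * w) @ z0
            pd[i], pm[i] = z[2], z[3]
    return AbundanceState(m=m, Pd=pd, Pm=pm)


# ---------------------------------------------------------------------------
# Maturation half-times


def _mature_fraction_two_step(k1: float, k2: float, t) -> np.ndarray:
    """Mature fraction of a closed Pd1 -> Pd2 -> Pm system starting from
    pure Pd1 (sequential first-order kinetics)."""
    t = np.asarray(t, dtype=float)
    if abs(k1 - k2) <= 1e-9 * max(k1, k2):
        k = 0.5 * (k1 + k2)
        return 1.0 - np.exp(-k * t) * (1.0 + k * t)
    return 1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)


def maturation_half_time(kind: str, rates) -> float:
    """Time (min) for half of an initially dark FP pool to become fluorescent.

    One-step: ``ln 2 / k_m``.  Two-step: the 50%-mature time of the closed
    sequential system starting from pure first precursor, found by
    root-finding (absolute tolerance 1e-6 min) — the "equivalent"
    half-time, which exceeds the sum-of-step-half-times lower bound.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("maturation rates must be positive and finite")
    if kind == "one_step":
        if rates.size != 1:
            raise ValueError("one-step model has a single maturation rate")
        return LN2 / float(rates[0])
    if kind != "two_step":
        raise ValueError(f"unknown model kind {kind!r}")
    if rates.size != 2:
        raise ValueError("two-step model has two maturation rates")
    k1, k2 = float(rates[0]), float(rates[1])

    def g(t):
        return _mature_fraction_two_step(k1, k2, t) - 0.5

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise NumericalError("half-time bracket expansion failed")
    return float(brentq(g, 0.0, hi, xtol=1e-6))


def two_step_lower_bound(rates) -> float:
    """Sum of the step half-times ``ln2/k_m1 + ln2/k_m2`` — a lower bound on
    the equivalent two-step maturation half-time."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if rates.size != 2 or np.any(rates <= 0):
        raise ValueError("expected two positive rates")
    return float(LN2 / rates[0] + LN2 / rates[1])


# ---------------------------------------------------------------------------
# Translation-shutoff (CHX) prediction


@dataclass
class ShutoffTrace:
    """Relative fluorescence after translation shutoff, normalised to 1 at
    t = 0; ``plateau`` is the asymptotic relative level."""

    times: np.ndarray
    rel_fluorescence: np.ndarray
    plateau: float


def simulate_chx_shutoff(params: AbundanceParams, growth_rate: float,
                         t_grid) -> ShutoffTrace:
    """Fluorescence rise after cycloheximide addition at t = 0.

    The cell is at balanced-growth steady state before shutoff (constitutive
    production, dilution at rate ``growth_rate``); shutoff stops both
    production and dilution, so the dark pool matures into the fluorescent
    pool.  For one-step maturation the plateau is ``1 + growth_rate/k_m`` —
    slow maturers show a larger relative rise.
    """
    lam = float(growth_rate)
    if lam <= 0:
        raise ValueError("growth_rate must be positive")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("shutoff trace is defined for t >= 0")
    if min(params.maturation_rates) <= 0:
        raise NumericalError(
            "zero maturation rate with a nonzero precursor pool: "
            "fluorescence never plateaus"
        )
    if params.kind == "one_step":
        km = params.k_m
        r = lam / km
        rel = 1.0 + r * (1.0 - np.exp(-km * t))
        return ShutoffTrace(times=t, rel_fluorescence=rel, plateau=1.0 + r)
    k1, k2 = params.k_m1, params.k_m2
    r2 = lam / k2                                   # Pd2 / Pm at steady state
    r1 = lam * (k2 + lam) / (k1 * k2)               # Pd1 / Pm at steady state
    rel = (1.0 + r2 * (1.0 - np.exp(-k2 * t))
           + r1 * _mature_fraction_two_step(k1, k2, t))
    return ShutoffTrace(times=t, rel_fluorescence=rel,
                        plateau=1.0 + r1 + r2)


# ---------------------------------------------------------------------------
# Simplified deterministic concentration model


def dilution_rate_from_distribution(dist: CellCycleDistribution,
                                    mode: str = "mother") -> float:
    """Average concentration-dilution rate implied by the fitted volume data.

    ``"mother"`` (default): tracked mother cells retain the fraction ``f_c``
    of volume and contents at division, so their concentration is diluted
    only by within-cycle volume growth — on average
    ``ln(1 + mu*T/V0) / T`` per cycle.  ``"doubling"``: the population
    doubling rate ``ln 2 / E[T]``, appropriate when total (mother+progeny)
    volume is followed.  Log-normal means are used for T and mu.
    """
    mean_T = math.exp(dist.log_mean[0] + 0.5 * dist.log_cov[0, 0])
    if mode == "doubling":
        return LN2 / mean_T
    if mode != "mother":
        raise ValueError("mode must be 'mother' or 'doubling'")
    mean_mu = math.exp(dist.log_mean[1] + 0.5 * dist.log_cov[1, 1])
    v0 = max(dist.v0_mean, 1e-12)
    return math.log1p(mean_mu * mean_T / v0) / mean_T


def simple_concentration_model(params: AbundanceParams, dilution_rate: float,
                               t_grid, dt: float = 0.05) -> ConcentrationTrace:
    """Deterministic concentration-space model: the same delayed cascade with
    a linear ``-dilution_rate * x`` term on every species instead of explicit
    division events.  A fast alternative to the individual-based forward
    model; with ``dilution_rate = 0`` it coincides with a division-free
    single-cell simulation at unit volume."""
    if dilution_rate < 0:
        raise ValueError("dilution_rate must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    mesh, out, _ = _integrate_cascade(
        params, float(t_grid.max()), dt, np.empty(0), np.empty(0),
        dilution=float(dilution_rate))
    conc = _sample_mesh(mesh, out["Pm"], t_grid)[:, 0]
    return ConcentrationTrace(times=t_grid, conc=conc)


# ---------------------------------------------------------------------------
# Histone-pulse reporter model and cell-cycle trace alignment


@dataclass(frozen=True)
class HistonePulseSpec:
    """Pulsatile histone synthesis over a normalised cell cycle.

    Production runs at ``pulse_height`` (au/min) between ``pulse_start`` and
    ``pulse_end`` (fractions of cycle time; the defaults put the pulse from
    budding, at the 30:50 segment split, to 60% of the budded phase —
    histone synthesis stops well before anaphase, so the fluorescence
    plateau at the end of the displayed cycle window is reproduced).
    ``retained_fraction`` of the tagged pool stays with the mother lineage
    at each division.  ``budding_frac`` marks the budding landmark for
    alignment (defaults to ``pulse_start``).
    """

    pulse_start: float = 0.375
    pulse_end: float = 0.75
    pulse_height: float = 1.0
    retained_fraction: float = 0.7
    budding_frac: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pulse_start < self.pulse_end <= 1.0):
            raise ValueError("need 0 <= pulse_start < pulse_end <= 1")
        if self.pulse_height < 0:
            raise ValueError("pulse_height must be >= 0")
        if not (0.0 < self.retained_fraction <= 1.0):
            raise ValueError("retained_fraction must be in (0, 1]")

    @property
    def budding(self) -> float:
        return self.pulse_start if self.budding_frac is None else self.budding_frac


@dataclass
class HistoneProfile:
    """Cycle-periodic total fluorescence on the common 70-point grid."""

    phase: np.ndarray
    fluorescence: np.ndarray
    production: np.ndarray
    n_cycles_used: int
    converged: bool
    budding_frac: float
    budding_index: int = 29


def _alignment_times(k0: float, b: float, k1: float) -> np.ndarray:
    """Physical times of the common 70-point normalised-cycle grid: 30
    interpolation points from karyokinesis to budding, 50 from budding to the
    next karyokinesis, last 10 dropped."""
    seg1 = np.linspace(k0, b, 30)
    seg2 = np.linspace(b, k1, 51)[1:]
    return np.concatenate([seg1, seg2])[:70]


def _pulse_matrices(spec: HistonePulseSpec, fp: AbundanceParams):
    """Augmented constant-coefficient systems (production on / off)."""
    two = fp.kind == "two_step"
    n = 4 if two else 3          # (1, Pd1[, Pd2], Pm)
    A_on = np.zeros((n, n))
    if two:
        k1, k2 = fp.k_m1, fp.k_m2
        A_on[1, 0] = spec.pulse_height
        A_on[1, 1] = -k1
        A_on[2, 1], A_on[2, 2] = k1, -k2
        A_on[3, 2] = k2
    else:
        km = fp.k_m
        A_on[1, 0] = spec.pulse_height
        A_on[1, 1] = -km
        A_on[2, 1] = km
    A_off = A_on.copy()
    A_off[1, 0] = 0.0
    return A_on, A_off


def histone_pulse_model(spec: HistonePulseSpec, fp_params: AbundanceParams,
                        n_cycles: int = 200, T_cycle: float = 100.0,
                        rtol: float = 1e-6) -> HistoneProfile:
    """Cycle-periodic total fluorescence of a pulse-produced, maturing
    histone-FP fusion.

    Production directly feeds the dark precursor (no mRNA stage or delays:
    the pulse is an effective synthesis rate); maturation follows the one- or
    two-step cascade of ``fp_params``; at each cycle boundary the whole
    tagged pool is multiplied by ``retained_fraction``.  Cycles are iterated
    until the boundary state is periodic to relative tolerance ``rtol``.
    Segment propagation uses exact matrix exponentials.
    """
    A_on, A_off = _pulse_matrices(spec, fp_params)
    ts, te = spec.pulse_start * T_cycle, spec.pulse_end * T_cycle
    segs = [(0.0, ts, A_off), (ts, te, A_on), (te, T_cycle, A_off)]
    props = [expm(A * (b - a)) for a, b, A in segs if b > a]
    seg_bounds = [(a, b, A) for a, b, A in segs if b > a]

    n = A_on.shape[0]
    z = np.zeros(n)
    z[0] = 1.0
    converged = False
    used = n_cycles
    for cyc in range(1, n_cycles + 1):
        z_prev = z.copy()
        for P in props:
            z = P @ z
        z[1:] *= spec.retained_fraction
        z[0] = 1.0
        scale = max(np.abs(z[1:]).max(), 1e-300)
        if np.abs(z[1:] - z_prev[1:]).max() <= rtol * scale:
            converged = True
            used = cyc
            break
    if not converged:
        resid = np.abs(z[1:] - z_prev[1:]).max() / scale
        warnings.warn(
            f"histone pulse model not cycle-periodic after {n_cycles} "
            f"cycles (relative residual {resid:.2e})", RuntimeWarning)

    b = spec.budding
    times = _alignment_times(0.0, b * T_cycle, T_cycle)
    fluo = np.empty(times.size)
    prod = np.empty(times.size)
    for i, t in enumerate(times):
        zi = z.copy()
        for a, bnd, A in seg_bounds:
            if t <= a:
                break
            dt_seg = min(t, bnd) - a
            zi = expm(A * dt_seg) @ zi
        fluo[i] = zi[-1]
        prod[i] = spec.pulse_height if ts <= t < te else 0.0
    return HistoneProfile(
        phase=np.linspace(0.0, 1.0, 70), fluorescence=fluo, production=prod,
        n_cycles_used=used, converged=converged, budding_frac=b,
    )


@dataclass(frozen=True)
class CycleTrace:
    """One cell cycle's fluorescence samples with event annotations: the
    trace runs from karyokinesis (``time[0]``) to the next karyokinesis
    (``time[-1]``) with budding at ``budding_time``."""

    time: np.ndarray
    value: np.ndarray
    budding_time: float
    cell_id: str = ""


@dataclass
class AlignedProfiles:
    """Per-cycle traces aligned to the common 70-point normalised grid."""

    phase: np.ndarray
    mean: np.ndarray
    profiles: np.ndarray
    budding_index: int = 29


def align_cell_cycle_traces(traces) -> AlignedProfiles:
    """Interpolate and align per-cycle traces on a common normalised grid.

    The karyokinesis-to-budding segment is linearly interpolated to 30
    points and the budding-to-karyokinesis segment to 50; the last 10 points
    are dropped (the nucleus is partially in the unsegmented daughter there),
    giving 70 points on a [0, 1] normalised cycle axis.
    """
    traces = list(traces)
    if not traces:
        raise AnnotationError("no traces to align")
    rows = []
    for i, tr in enumerate(traces):
        label = tr.cell_id or f"trace {i}"
        t = np.asarray(tr.time, dtype=float)
        v = np.asarray(tr.value, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise AnnotationError(f"{label}: times must be increasing")
        k0, k1, b = t[0], t[-1], float(tr.budding_time)
        if not (k0 < b < k1):
            raise AnnotationError(
                f"{label}: budding time {b} must lie strictly between "
                f"karyokinesis events {k0} and {k1}"
            )
        rows.append(np.interp(_alignment_times(k0, b, k1), t, v))
    profiles = np.vstack(rows)
    return AlignedProfiles(
        phase=np.linspace(0.0, 1.0, 70),
        mean=profiles.mean(axis=0),
        profiles=profiles,
    )
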