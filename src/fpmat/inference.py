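"""Grid-based maximum likelihood and profile-likelihood analysis.

The observation model is the population-averaged mature-FP concentration
plus additive Gaussian noise with a fixed standard deviation
``sigma = 0.02 * max(y)``, so maximising the likelihood is minimising

    chi2(theta) = sum_n (y(t_n) - yhat(t_n, theta))^2 / sigma^2 .

Because the transcription rate ``k_r`` and translation rate ``k_p`` are not
separately identifiable from fluorescence in arbitrary units, ``k_r`` is tied
to ``k_p`` during estimation and the free parameter vector is
``theta = [k_dr, k_p, k_m]`` (one-step) or ``[k_dr, k_p, k_m1]`` with
``k_m2 = k_m1`` (two-step, the tied-rate convention).  ``chi2`` is evaluated
on a dense log-spaced grid — no local optimiser is required for so few
parameters, and the same dense evaluations serve directly for profile
likelihoods: ``chi2_PL(theta_i)`` is the grid minimum over the remaining
parameters, and the 95% confidence interval is the sub-level set at
``chi2(theta*) + 3.841`` (the chi-square(1) quantile).

The forward model is exactly linear in the product ``k_r * k_p`` (division
resets are linear operations), so the grid is simulated once per
``(k_dr, k_m)`` pair at unit amplitude and rescaled by ``k_p^2`` — an exact
reformulation, not an approximation.  A single fixed seed drives the forward
volume trajectories for every theta (common random numbers), which makes the
grid objective deterministic and smooth in theta.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .kinetics import (
    AbundanceParams,
    forward_volumes,
    maturation_half_time,
    population_average,
    population_mean_vectorized,
    simple_concentration_model,
    dilution_rate_from_distribution,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ProfileResult",
    "ModelSelection",
    "DegenerateCIError",
    "objective_chi2",
    "fit_ml",
    "profile_likelihood",
    "compare_models_aic",
    "ci_for_half_time",
]

LN2 = math.log(2.0)

KM_UPPER = 0.1386          # rate for a 5-min maturation half-time
KDR_LOWER = 0.0462         # mRNA half-life 15 min
KDR_UPPER = 0.1386         # mRNA half-life 5 min


class DegenerateCIError(RuntimeError):
    """The profile sub-level set is empty (it must contain theta*)."""


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    The maturation-rate search space is bounded above at 0.1386 /min (a
    5-min half-time) with no physical lower bound; a finite lower grid edge
    (default a 300-min half-time) is required for the grid, and profiles
    still below threshold there are reported as one-sided.  ``k_dr`` is
    restricted to mRNA half-lives between 5 and 15 min.  ``k_p`` only sets
    the amplitude, so it gets a wide log-spaced range.
    """

    km_bounds: tuple[float, float] = (LN2 / 300.0, KM_UPPER)
    kdr_bounds: tuple[float, float] = (KDR_LOWER, KDR_UPPER)
    kp_bounds: tuple[float, float] = (1e-3, 10.0)
    n_grid: int = 60           # grid points per dimension
    n_cells: int = 500         # cells in the forward population average
    sigma_frac: float = 0.02   # sigma = sigma_frac * max(y)
    alpha: float = 0.05
    seed: int = 0              # forward-simulation seed (common random numbers)
    dt: float = 0.5            # forward integration step (min)
    tau1: float = 2.0
    tau2: float = 4.0
    forward: str = "population"   # or "simple" (deterministic dilution model)
    dilution_rate: float | None = None   # simple model; default from volume fit
    refine: bool = False
    refine_iters: int = 2
    refine_points: int = 7

    def __post_init__(self) -> None:
        for name in ("km_bounds", "kdr_bounds", "kp_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lower < upper")
        if self.n_grid < 2:
            raise ValueError("need at least 2 grid points per dimension")
        if self.forward not in ("population", "simple"):
            raise ValueError("forward must be 'population' or 'simple'")

    def grids(self) -> dict[str, np.ndarray]:
        """Log-spaced parameter grids."""
        return {
            "k_dr": np.geomspace(*self.kdr_bounds, self.n_grid),
            "k_p": np.geomspace(*self.kp_bounds, self.n_grid),
            "k_m": np.geomspace(*self.km_bounds, self.n_grid),
        }

    @classmethod
    def reduced(cls, **kw) -> "FitConfig":
        """Desk-scale settings: 100 forward cells, 20 grid points per
        dimension, with local grid refinement switched on."""
        kw.setdefault("n_grid", 20)
        kw.setdefault("n_cells", 100)
        kw.setdefault("refine", True)
        return cls(**kw)

    def with_(self, **kw) -> "FitConfig":
        return replace(self, **kw)


@dataclass
class FitResult:
    """Maximum-likelihood estimate on the dense grid.

    ``theta`` maps parameter names to estimates (``k_r`` is tied to ``k_p``
    and ``k_m2`` to ``k_m1`` and therefore not listed).  ``chi2_grid`` is
    the dense chi-square surface over the (k_dr, k_m) grid with the
    amplitude parameter ``k_p`` minimised out exactly at every node (the
    model is linear in ``k_r * k_p = k_p^2``, so the optimal amplitude has a
    closed form); it is kept for profile-likelihood evaluation.
    ``unit_traces`` are the unit-amplitude forward traces underlying the
    surface, shape (n_t, n_kdr, n_km).
    """

    kind: str
    theta: dict[str, float]
    chi2: float
    aic: float
    n_free: int
    n_obs: int
    sigma: float
    grids: dict[str, np.ndarray] = field(repr=False)
    chi2_grid: np.ndarray = field(repr=False)
    unit_traces: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    config: FitConfig = field(repr=False, default=None)
    data_id: str = ""
    refined: bool = False

    @property
    def maturation_rate(self) -> float:
        return self.theta["k_m"]

    @property
    def half_time(self) -> float:
        """ML maturation half-time (min): ln2/k_m for one-step, the
        simulated equivalent half-time for (tied) two-step."""
        k = self.maturation_rate
        if self.kind == "one_step":
            return LN2 / k
        return maturation_half_time("two_step", (k, k))

    def params(self) -> AbundanceParams:
        """The ML estimate as an :class:`AbundanceParams` (k_r = k_p)."""
        base = dict(k_r=self.theta["k_p"], k_p=self.theta["k_p"],
                    k_dr=self.theta["k_dr"], tau1=self.config.tau1,
                    tau2=self.config.tau2)
        if self.kind == "one_step":
            return AbundanceParams(kind="one_step", k_m=self.theta["k_m"],
                                   **base)
        return AbundanceParams(kind="two_step", k_m1=self.theta["k_m"],
                               k_m2=self.theta["k_m"], **base)


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter over its grid.

    ``ci_lower``/``ci_upper`` bound the (1-alpha) confidence set
    (threshold-crossing positions, log-interpolated between grid nodes);
    ``lower_unbounded``/``upper_unbounded`` flag profiles that stay below
    threshold out to the grid edge (practical non-identifiability on that
    side — for k_m the "no lower bound" case).
    """

    param_name: str
    grid: np.ndarray
    chi2_pl: np.ndarray
    chi2_star: float
    threshold: float
    mle: float
    ci_lower: float
    ci_upper: float
    lower_unbounded: bool = False
    upper_unbounded: bool = False

    @property
    def ci(self) -> tuple[float, float]:
        lo = -math.inf if self.lower_unbounded else self.ci_lower
        hi = math.inf if self.upper_unbounded else self.ci_upper
        return (lo, hi)


@dataclass
class ModelSelection:
    """AIC comparison of the one- and two-step fits on the same data."""

    selected_kind: str
    delta_aic: float
    aic_one: float
    aic_two: float


def _data_id(data) -> str:
    y = np.asarray(data.mean_trace, dtype=float)
    return hashlib.sha256(y.tobytes()).hexdigest()[:16]


def _sigma(data, cfg: FitConfig) -> float:
    y = np.asarray(data.mean_trace, dtype=float)
    s = cfg.sigma_frac * float(np.max(np.abs(y)))
    if s <= 0:
        raise ValueError("sigma is zero: the data contain no signal")
    return s


def _check_data(data, cfg: FitConfig):
    t = np.asarray(data.t_grid, dtype=float)
    y = np.asarray(data.mean_trace, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t_grid and mean_trace must be matching 1-D arrays")
    return t, y


def _template(kind: str, cfg: FitConfig) -> AbundanceParams:
    if kind == "one_step":
        return AbundanceParams(kind="one_step", k_r=1.0, k_dr=0.1, k_p=1.0,
                               k_m=0.1, tau1=cfg.tau1, tau2=cfg.tau2)
    return AbundanceParams(kind="two_step", k_r=1.0, k_dr=0.1, k_p=1.0,
                           k_m1=0.1, k_m2=0.1, tau1=cfg.tau1, tau2=cfg.tau2)


def objective_chi2(theta, data, cfg: FitConfig, kind: str = "one_step") -> float:
    """chi2 objective at one parameter vector ``theta = (k_dr, k_p, k_m)``
    with ``k_r = k_p`` (and ``k_m2 = k_m1`` for the two-step model)."""
    t_grid, y = _check_data(data, cfg)
    k_dr, k_p, k_m = (float(v) for v in theta)
    if kind == "one_step":
        params = AbundanceParams(kind="one_step", k_r=k_p, k_dr=k_dr,
                                 k_p=k_p, k_m=k_m,
                                 tau1=cfg.tau1, tau2=cfg.tau2)
    elif kind == "two_step":
        params = AbundanceParams(kind="two_step", k_r=k_p, k_dr=k_dr,
                                 k_p=k_p, k_m1=k_m, k_m2=k_m,
                                 tau1=cfg.tau1, tau2=cfg.tau2)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    try:
        if cfg.forward == "population":
            yhat = population_average(params, data.cell_cycle, cfg.n_cells,
                                      t_grid, rng_seed=cfg.seed,
                                      dt=cfg.dt).conc
        else:
            lam = (cfg.dilution_rate if cfg.dilution_rate is not None
                   else dilution_rate_from_distribution(data.cell_cycle))
            yhat = simple_concentration_model(params, lam, t_grid,
                                              dt=cfg.dt).conc
    except Exception as exc:
        raise RuntimeError(
            f"forward simulation failed at theta={theta!r}: {exc}"
        ) from exc
    sigma = _sigma(data, cfg)
    return float(np.sum((y - yhat) ** 2) / sigma**2)


def _unit_traces(kind: str, kdr: np.ndarray, km: np.ndarray, data,
                 cfg: FitConfig, t_grid: np.ndarray) -> np.ndarray:
    """Unit-amplitude (k_r = k_p = 1) forward traces for every (k_dr, k_m)
    pair; shape (n_t, n_kdr, n_km)."""
    KDR, KM = np.meshgrid(kdr, km, indexing="ij")
    ro = {"k_r": 1.0, "k_p": 1.0, "k_dr": KDR.ravel()}
    if kind == "one_step":
        ro["k_m"] = KM.ravel()
    else:
        ro["k_m1"] = KM.ravel()
        ro["k_m2"] = KM.ravel()
    template = _template(kind, cfg)
    if cfg.forward == "population":
        vols = forward_volumes(data.cell_cycle, cfg.n_cells, cfg.seed,
                               float(t_grid.max()))
        u = population_mean_vectorized(template, vols, t_grid, cfg.dt, ro)
    else:
        lam = (cfg.dilution_rate if cfg.dilution_rate is not None
               else dilution_rate_from_distribution(data.cell_cycle))
        from .kinetics import _integrate_cascade, _sample_mesh
        mesh, out, _ = _integrate_cascade(
            template, float(t_grid.max()), cfg.dt, np.empty(0), np.empty(0),
            dilution=lam, rates_override=ro, extra_times=t_grid)
        u = _sample_mesh(mesh, out["Pm"], t_grid)
    return u.reshape(t_grid.size, kdr.size, km.size)


def _moments(u: np.ndarray, y: np.ndarray):
    A = float(np.sum(y**2))
    B = np.einsum("n,nik->ik", y, u)
    C = np.einsum("nik,nik->ik", u, u)
    return A, B, C


def _chi2_concentrated(u: np.ndarray, y: np.ndarray, sigma: float,
                       kp_bounds: tuple[float, float]):
    """chi2 over the (k_dr, k_m) grid with the amplitude minimised exactly.

    ``yhat = k_p^2 * u`` (model linear in k_r*k_p, k_r tied to k_p), so
    ``min_a sum (y - a u)^2`` is attained at ``a* = <y,u>/<u,u>`` clamped to
    the allowed amplitude range.  Returns (chi2 surface, optimal k_p grid).
    """
    A, B, C = _moments(u, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(C > 0, B / np.maximum(C, 1e-300), 0.0)
    a = np.clip(a, kp_bounds[0] ** 2, kp_bounds[1] ** 2)
    chi2 = (A - 2.0 * a * B + a**2 * C) / sigma**2
    return chi2, np.sqrt(a)


def _chi2_cube(u: np.ndarray, kp: np.ndarray, y: np.ndarray,
               sigma: float) -> np.ndarray:
    """Full chi2 over the (k_dr, k_p, k_m) grid (used for k_p profiles)."""
    amp = kp**2
    A, B, C = _moments(u, y)
    cube = (A - 2.0 * amp[None, :, None] * B[:, None, :]
            + amp[None, :, None] ** 2 * C[:, None, :])
    return cube / sigma**2


def _argmin_tie_small_km(surface: np.ndarray) -> tuple[int, int]:
    """(k_dr, k_m) grid arg-min; ties broken toward the smallest k_m, then
    the smallest k_dr."""
    mn = surface.min()
    cand = np.argwhere(surface == mn)
    order = np.lexsort((cand[:, 0], cand[:, 1]))
    i, k = cand[order[0]]
    return int(i), int(k)


def _zoom_bounds(grid: np.ndarray, idx: int,
                 hard: tuple[float, float]) -> tuple[float, float]:
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, grid.size - 1)]
    return max(lo, hard[0]), min(hi, hard[1])


def fit_ml(data, cfg: FitConfig, kind: str = "one_step") -> FitResult:
    """Arg-min of the chi2 objective over the dense log-spaced (k_dr, k_m)
    grid with the amplitude k_p minimised exactly at every node, optionally
    followed by iterative local grid refinement around the best node (still
    purely grid-based and derivative-free)."""
    t_grid, y = _check_data(data, cfg)
    sigma = _sigma(data, cfg)
    grids = cfg.grids()
    u = _unit_traces(kind, grids["k_dr"], grids["k_m"], data, cfg, t_grid)
    surface, kp_opt = _chi2_concentrated(u, y, sigma, cfg.kp_bounds)
    if not np.all(np.isfinite(surface)):
        raise RuntimeError("chi2 evaluation failed across the grid")
    i, k = _argmin_tie_small_km(surface)
    theta = {"k_dr": grids["k_dr"][i], "k_p": kp_opt[i, k],
             "k_m": grids["k_m"][k]}
    chi2_star = float(surface[i, k])

    refined = False
    if cfg.refine:
        g = {"k_dr": grids["k_dr"], "k_m": grids["k_m"]}
        idx = {"k_dr": i, "k_m": k}
        hard = {"k_dr": cfg.kdr_bounds, "k_m": cfg.km_bounds}
        for _ in range(cfg.refine_iters):
            g = {n: np.geomspace(*_zoom_bounds(g[n], idx[n], hard[n]),
                                 cfg.refine_points)
                 for n in g}
            uz = _unit_traces(kind, g["k_dr"], g["k_m"], data, cfg, t_grid)
            sz, kpz = _chi2_concentrated(uz, y, sigma, cfg.kp_bounds)
            ii, kk = _argmin_tie_small_km(sz)
            idx = {"k_dr": ii, "k_m": kk}
            if sz[ii, kk] < chi2_star:
                chi2_star = float(sz[ii, kk])
                theta = {"k_dr": g["k_dr"][ii], "k_p": kpz[ii, kk],
                         "k_m": g["k_m"][kk]}
                refined = True

    n_free = 3
    return FitResult(
        kind=kind,
        theta={n: float(v) for n, v in theta.items()},
        chi2=chi2_star,
        aic=chi2_star + 2.0 * n_free,
        n_free=n_free,
        n_obs=y.size,
        sigma=sigma,
        grids=grids,
        chi2_grid=surface,
        unit_traces=u,
        y=y,
        config=cfg,
        data_id=_data_id(data),
        refined=refined,
    )


def _crossing(x0, x1, c0, c1, thr) -> float:
    """Log-interpolated position where the profile crosses the threshold."""
    if c1 == c0:
        return x1
    w = (thr - c0) / (c1 - c0)
    return float(np.exp(np.log(x0) + w * (np.log(x1) - np.log(x0))))


def profile_likelihood(data, cfg: FitConfig, kind: str, param_name: str,
                       fit: FitResult | None = None) -> ProfileResult:
    """Profile chi2 of one parameter, reusing the dense grid evaluations.

    For each grid value of the profiled parameter the chi2 is minimised over
    the remaining two parameters; the (1-alpha) CI is the sub-level set at
    ``chi2_star + Delta`` with ``Delta`` the chi-square(1) quantile (3.841
    at alpha = 0.05).
    """
    if fit is None:
        fit = fit_ml(data, cfg, kind)
    if param_name == "k_dr":
        chi2_pl = fit.chi2_grid.min(axis=1)
    elif param_name == "k_m":
        chi2_pl = fit.chi2_grid.min(axis=0)
    elif param_name == "k_p":
        # amplitude profile from the full 3-D cube over its own grid
        cube = _chi2_cube(fit.unit_traces, fit.grids["k_p"], fit.y, fit.sigma)
        chi2_pl = cube.min(axis=(0, 2))
    else:
        raise ValueError(f"unknown parameter {param_name!r}")
    grid = fit.grids[param_name]
    delta = float(chi2_dist.ppf(1.0 - cfg.alpha, df=1))
    threshold = fit.chi2 + delta
    below = chi2_pl <= threshold
    if not below.any():
        raise DegenerateCIError(
            "empty profile sub-level set: the confidence region must "
            "contain the ML estimate"
        )
    idx = np.flatnonzero(below)
    lo_i, hi_i = idx[0], idx[-1]
    lower_unbounded = lo_i == 0
    upper_unbounded = hi_i == grid.size - 1
    ci_lower = (grid[0] if lower_unbounded else
                _crossing(grid[lo_i - 1], grid[lo_i],
                          chi2_pl[lo_i - 1], chi2_pl[lo_i], threshold))
    ci_upper = (grid[-1] if upper_unbounded else
                _crossing(grid[hi_i], grid[hi_i + 1],
                          chi2_pl[hi_i], chi2_pl[hi_i + 1], threshold))
    mle = fit.theta[param_name]
    return ProfileResult(
        param_name=param_name, grid=grid, chi2_pl=chi2_pl,
        chi2_star=fit.chi2, threshold=threshold, mle=mle,
        ci_lower=float(min(ci_lower, mle)),
        ci_upper=float(max(ci_upper, mle)),
        lower_unbounded=bool(lower_unbounded),
        upper_unbounded=bool(upper_unbounded),
    )


def compare_models_aic(fit_one: FitResult, fit_two: FitResult) -> ModelSelection:
    """Select between the one- and two-step fits by AIC = chi2 + 2k (sigma is
    fixed by rule, so the Gaussian constant terms cancel)."""
    kinds = {fit_one.kind, fit_two.kind}
    if kinds != {"one_step", "two_step"}:
        raise ValueError("need one fit of each model kind")
    if fit_one.kind != "one_step":
        fit_one, fit_two = fit_two, fit_one
    if fit_one.n_obs != fit_two.n_obs or fit_one.data_id != fit_two.data_id:
        raise ValueError("fits were obtained on different data")
    selected = "one_step" if fit_one.aic <= fit_two.aic else "two_step"
    return ModelSelection(
        selected_kind=selected,
        delta_aic=float(abs(fit_one.aic - fit_two.aic)),
        aic_one=fit_one.aic,
        aic_two=fit_two.aic,
    )


def ci_for_half_time(profile: ProfileResult, kind: str) -> tuple[float, float]:
    """Map a maturation-rate CI to a half-time CI (order-reversing): ln2/k
    for one-step, the simulated equivalent half-time for tied two-step.
    A rate interval unbounded below gives a half-open half-time interval."""
    if profile.param_name != "k_m":
        raise ValueError("profile must be over the maturation rate k_m")

    def to_t50(k: float) -> float:
        if kind == "one_step":
            return LN2 / k
        return maturation_half_time("two_step", (k, k))

    t50_low = to_t50(profile.ci_upper)
    t50_high = math.inf if profile.lower_unbounded else to_t50(profile.ci_lower)
    return (float(t50_low), float(t50_high))
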