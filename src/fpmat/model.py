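"""Model/Results interface for FP maturation estimation.

``MaturationModel`` wraps a fluorescence dataset (observed or synthetic)
together with the fitted cell-cycle distribution and estimation settings;
``fit()`` returns a ``MaturationResults`` carrying the ML estimates, the
profile-likelihood confidence interval of the maturation rate, diagnostics
and a ``summary()`` table in the style of a maturation half-time report
(FP, t50, 95% CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, kinetics, volume
from .inference import FitConfig, FitResult, ProfileResult
from .synth import FluorescenceDataset
from .volume import CellCycleDistribution

__all__ = ["MaturationModel", "MaturationResults"]


class MaturationModel:
    """Delayed gene-expression model of FP maturation, bound to data.

    Parameters
    ----------
    data :
        Anything with ``t_grid`` (min), ``mean_trace`` (population-averaged
        FP concentration, arbitrary units) and ``cell_cycle`` (a
        :class:`~fpmat.volume.CellCycleDistribution` driving the forward
        volume model) — typically a
        :class:`~fpmat.synth.FluorescenceDataset`.
    kind :
        ``"one_step"`` or ``"two_step"`` maturation (two-step rates tied).
    config :
        :class:`~fpmat.inference.FitConfig`; defaults to the full-fidelity
        settings (500 forward cells, 60 grid points per dimension).
    """

    def __init__(self, data, kind: str = "one_step",
                 config: FitConfig | None = None, name: str = "FP"):
        if kind not in ("one_step", "two_step"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.data = data
        self.kind = kind
        self.config = config or FitConfig()
        self.name = name

    @classmethod
    def from_tables(cls, tracks, annotations, kind: str = "one_step",
                    config: FitConfig | None = None,
                    name: str = "FP") -> "MaturationModel":
        """Build the model from a cell-track table and cycle annotations.

        The population mean fluorescence is computed across cells at each
        time point, the cycle-parameter distribution is fitted from the
        annotations, and initial volumes are read from the t = 0 rows.
        """
        if not isinstance(tracks, pd.DataFrame):
            tracks = volume.read_tracks(tracks)
        dist = volume.fit_from_tables(tracks, annotations)
        mean = (tracks.groupby("time_min")["fluorescence_au"]
                .mean().sort_index())
        data = FluorescenceDataset(
            t_grid=mean.index.to_numpy(dtype=float),
            cell_traces=None,
            mean_trace=mean.to_numpy(dtype=float),
            sigma=float("nan"),
            cell_cycle=dist,
        )
        return cls(data, kind=kind, config=config, name=name)

    def fit(self, profile: bool = True) -> "MaturationResults":
        """Grid-based ML fit; with ``profile=True`` (default) also computes
        the profile likelihood and 95% CI of the maturation rate."""
        fit = inference.fit_ml(self.data, self.config, self.kind)
        prof = None
        if profile:
            prof = inference.profile_likelihood(
                self.data, self.config, self.kind, "k_m", fit=fit)
        return MaturationResults(model=self, fit=fit, km_profile=prof)

    def simulate(self, params=None, n_cells: int | None = None,
                 seed: int | None = None):
        """Forward-simulate the population-averaged concentration at given
        (or fitted-template) parameters; mirrors the fitting forward model."""
        if params is None:
            raise ValueError("pass AbundanceParams (e.g. results.params())")
        cfg = self.config
        return kinetics.population_average(
            params, self.data.cell_cycle,
            n_cells if n_cells is not None else cfg.n_cells,
            np.asarray(self.data.t_grid, dtype=float),
            rng_seed=cfg.seed if seed is None else seed, dt=cfg.dt)


@dataclass
class MaturationResults:
    """Estimates, uncertainties and diagnostics from a maturation fit."""

    model: MaturationModel
    fit: FitResult
    km_profile: ProfileResult | None = None
    _fitted: np.ndarray | None = field(default=None, repr=False)

    # -- estimates ---------------------------------------------------------
    @property
    def theta(self) -> dict:
        return self.fit.theta

    @property
    def chi2(self) -> float:
        return self.fit.chi2

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def half_time(self) -> float:
        return self.fit.half_time

    @property
    def half_time_ci(self) -> tuple[float, float]:
        """95% CI for the maturation half-time (min); upper bound is
        infinite when the rate profile never crosses the threshold on its
        lower side (practical non-identifiability)."""
        if self.km_profile is None:
            raise ValueError("fit was run without profiling k_m")
        return inference.ci_for_half_time(self.km_profile, self.fit.kind)

    def params(self) -> kinetics.AbundanceParams:
        return self.fit.params()

    def fitted_values(self) -> np.ndarray:
        """Forward-simulated population mean at the ML estimate."""
        if self._fitted is None:
            self._fitted = self.model.simulate(self.params()).conc
        return self._fitted

    def resid(self) -> np.ndarray:
        return (np.asarray(self.model.data.mean_trace, dtype=float)
                - self.fitted_values())

    def compare(self, other: "MaturationResults") -> inference.ModelSelection:
        """AIC comparison against a fit of the other maturation kind."""
        return inference.compare_models_aic(self.fit, other.fit)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = []
        kind_label = ("one-step" if self.fit.kind == "one_step"
                      else "two-step (tied rates)")
        lines.append("Maturation model fit")
        lines.append("=" * 54)
        lines.append(f"model kind:       {kind_label}")
        lines.append(f"observations:     {self.fit.n_obs}")
        lines.append(f"sigma (2% rule):  {self.fit.sigma:.4g}")
        lines.append(f"chi2 at optimum:  {self.fit.chi2:.2f}")
        lines.append(f"AIC:              {self.fit.aic:.2f}")
        lines.append("-" * 54)
        lines.append("parameter estimates (1/min):")
        for nm, v in self.fit.theta.items():
            lines.append(f"  {nm:<6} {v:.4g}")
        if self.fit.kind == "two_step":
            lines.append(f"  (k_m2 tied to k_m1; per-step half-time "
                         f"{math.log(2) / self.fit.theta['k_m']:.3g} min)")
        lines.append("-" * 54)
        w = max(12, len(self.model.name) + 2)
        lines.append(f"{'FP':<{w}}{'t50 (min)':<12}95% C.I.")
        t50 = self.half_time
        if self.km_profile is not None:
            lo, hi = self.half_time_ci
            hi_s = "inf" if math.isinf(hi) else f"{hi:.1f}"
            ci = f"[{lo:.1f}, {hi_s}]"
        else:
            ci = "n/a"
        lines.append(f"{self.model.name:<{w}}{t50:<12.1f}{ci}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fit (and profile, if present)."""
        out = {
            "name": self.model.name,
            "kind": self.fit.kind,
            "theta": self.fit.theta,
            "chi2": self.fit.chi2,
            "aic": self.fit.aic,
            "n_obs": self.fit.n_obs,
            "sigma": self.fit.sigma,
            "half_time_min": self.half_time,
            "refined": self.fit.refined,
            "grids": {k: v.tolist() for k, v in self.fit.grids.items()},
        }
        if self.km_profile is not None:
            lo, hi = self.half_time_ci
            out["half_time_ci_min"] = [lo, None if math.isinf(hi) else hi]
            out["km_profile"] = {
                "grid": self.km_profile.grid.tolist(),
                "chi2_pl": self.km_profile.chi2_pl.tolist(),
                "threshold": self.km_profile.threshold,
                "ci": [self.km_profile.ci_lower, self.km_profile.ci_upper],
                "lower_unbounded": self.km_profile.lower_unbounded,
                "upper_unbounded": self.km_profile.upper_unbounded,
            }
        return out

    # -- plotting ----------------------------------------------------------
    def plot_fit(self, ax=None):
        """Data vs fitted population mean."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = np.asarray(self.model.data.t_grid, dtype=float)
        ax.plot(t, self.model.data.mean_trace, "o", ms=3, label="data")
        ax.plot(t, self.fitted_values(), "-", label="model")
        ax.set_xlabel("time post-induction (min)")
        ax.set_ylabel("FP concentration (au)")
        ax.legend()
        return ax

    def plot_profile(self, ax=None):
        """Profile chi2 of the maturation rate with the CI threshold."""
        import matplotlib.pyplot as plt
        if self.km_profile is None:
            raise ValueError("fit was run without profiling k_m")
        if ax is None:
            _, ax = plt.subplots()
        p = self.km_profile
        ax.semilogx(p.grid, p.chi2_pl, "-o", ms=3)
        ax.axhline(p.threshold, ls="--", color="k",
                   label=r"$\chi^2(\theta^*) + \Delta_{1;0.95}$")
        ax.axvline(p.mle, ls=":", color="C1", label="ML estimate")
        ax.set_xlabel("maturation rate $k_m$ (1/min)")
        ax.set_ylabel(r"profile $\chi^2$")
        ax.legend()
        return ax
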