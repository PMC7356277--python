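"""Canopy dynamics and radiation interception.

Canopy cover as a function of thermal time ``t`` follows the determinate
beta growth function up to its peak,

    cc(t) = cc_max * (1 + (te - t)/(te - tm)) * (t/te)^(te/(te - tm)),  t <= te

where ``tm`` is the thermal time of maximum growth rate and ``te`` the
thermal time at peak cover ``cc_max``.  The beta form itself never declines,
so post-peak senescence is represented by a fitted linear segment
``cc_max + decline_slope * (t - te)`` clipped to [0, 1].  Canopy cover is
equated with ``f``, the fraction of incident PAR intercepted; summing
``f * PAR_inc`` daily gives the intercepted radiation and the interception
efficiency epsilon_i = 100 * PARint / PARinc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .weather import DEFAULT_T_BASE, cumulative_par, thermal_time

__all__ = [
    "BetaParams",
    "beta_cover",
    "interception_fraction",
    "RadiationSummary",
    "par_intercepted_and_epsilon_i",
    "BetaCanopyModel",
    "BetaCanopyResults",
]


@dataclass(frozen=True)
class BetaParams:
    """Parameters of the canopy cover curve (thermal-time scale, degC d)."""

    cc_max: float
    tm: float
    te: float
    decline_slope: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cc_max <= 1.0:
            raise ValueError(f"cc_max {self.cc_max} outside (0, 1]")
        if not 0.0 < self.tm < self.te:
            raise ValueError(f"need 0 < tm < te, got tm={self.tm}, te={self.te}")
        if self.decline_slope > 0:
            raise ValueError("decline_slope must be <= 0")


def beta_cover(t, params: BetaParams):
    """Canopy cover at thermal time ``t`` (scalar or array), in [0, 1]."""
    t = np.asarray(t, dtype=float)
    cc_max, tm, te, slope = (
        params.cc_max,
        params.tm,
        params.te,
        params.decline_slope,
    )
    expo = te / (te - tm)
    rising = np.zeros_like(t)
    pre = (t > 0) & (t <= te)
    tp = t[pre]
    rising[pre] = cc_max * (1.0 + (te - tp) / (te - tm)) * (tp / te) ** expo
    out = np.where(t <= te, rising, cc_max + slope * (t - te))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def interception_fraction(params: BetaParams, t):
    """Fraction of incident PAR intercepted at thermal time ``t`` (= cover)."""
    return beta_cover(t, params)


@dataclass(frozen=True)
class RadiationSummary:
    """Season totals of incident/intercepted PAR and epsilon_i (percent)."""

    par_inc_cum: float
    par_int_cum: float
    epsilon_i: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.par_int_cum <= self.par_inc_cum + 1e-9:
            raise ValueError("PARint must lie in [0, PARinc]")
        if not 0.0 <= self.epsilon_i <= 100.0 + 1e-9:
            raise ValueError("epsilon_i must lie in [0, 100]")


def par_intercepted_and_epsilon_i(
    weather: pd.DataFrame,
    params: BetaParams,
    harvest_dap: int,
    t_base: float = DEFAULT_T_BASE,
) -> RadiationSummary:
    """Integrate daily interception from dap 1 to harvest.

    PARint = sum over days of f(t) * PAR_inc; epsilon_i = 100 * PARint/PARinc.
    """
    par_inc = cumulative_par(weather, 1, harvest_dap)
    tt = thermal_time(weather, t_base=t_base)[:harvest_dap]
    f = beta_cover(tt, params)
    par_day = weather["par_inc"].to_numpy()[:harvest_dap]
    par_int = float(np.sum(f * par_day))
    eps_i = 100.0 * par_int / par_inc if par_inc > 0 else 0.0
    return RadiationSummary(par_inc, par_int, eps_i)


@dataclass
class BetaCanopyResults:
    """Fitted canopy dynamics with residual diagnostics."""

    params: BetaParams
    n_rising: int
    n_decline: int
    rss: float
    residuals: np.ndarray
    converged: bool
    model: "BetaCanopyModel" = field(repr=False)

    def predict(self, t):
        return beta_cover(t, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Beta canopy dynamics fit",
            "-" * 40,
            f"cc_max          {p.cc_max:10.4f}",
            f"tm (degC d)     {p.tm:10.1f}",
            f"te (degC d)     {p.te:10.1f}",
            f"decline_slope   {p.decline_slope:10.6f} cover per degC d",
            f"rising points   {self.n_rising:10d}",
            f"decline points  {self.n_decline:10d}",
            f"residual SS     {self.rss:10.3e}",
            f"converged       {str(self.converged):>10s}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tt, cc = self.model.tt, self.model.cc
        grid = np.linspace(0, tt.max() * 1.05, 300)
        ax.plot(tt, cc, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="fitted")
        ax.set_xlabel("thermal time (degC d)")
        ax.set_ylabel("canopy cover")
        ax.legend()
        return ax


class BetaCanopyModel:
    """Least-squares fit of the beta cover curve to per-flight canopy points.

    Parameters
    ----------
    tt : array
        Thermal time of each flight (degC d).
    cc : array
        Observed canopy cover fraction at each flight.
    """

    N_STARTS = 3

    def __init__(self, tt, cc):
        tt = np.asarray(tt, dtype=float)
        cc = np.asarray(cc, dtype=float)
        if tt.shape != cc.shape or tt.ndim != 1:
            raise ValueError("tt and cc must be 1-D arrays of equal length")
        if len(tt) < 5:
            raise ValueError("need at least 5 canopy points to fit")
        order = np.argsort(tt)
        self.tt, self.cc = tt[order], cc[order]

    @classmethod
    def from_points(cls, points, weather: pd.DataFrame, t_base: float = DEFAULT_T_BASE):
        """Build from CanopyPoint records using the trial's weather series."""
        tt_all = thermal_time(weather, t_base=t_base)
        daps = np.array([p.dap for p in points], dtype=int)
        if daps.max() > len(weather):
            raise ValueError("canopy point dap beyond weather series")
        tt = tt_all[daps - 1]
        cc = np.array([p.cc for p in points], dtype=float)
        return cls(tt, cc)

    def fit(self, seed: int = 0, xtol: float = 1e-14) -> BetaCanopyResults:
        """Joint bounded least squares of (cc_max, tm, te, decline_slope).

        All flights enter one residual vector through the piecewise curve
        (beta rise below te, linear senescence above), so the peak position
        is constrained from both sides and a noise-shifted empirical
        maximum cannot strand the fit.  Multi-start with a seeded generator.
        """
        tt, cc = self.tt, self.cc
        ipk = int(np.argmax(cc))
        te0 = float(np.clip(tt[ipk], 1.0, None))
        cc0 = float(np.clip(cc[ipk], 0.05, 1.0))
        t_max = float(tt.max())

        lo = np.array([0.01, 1.0, 2.0, -0.05])
        hi = np.array([1.0, 0.999 * t_max, 1.2 * t_max, 0.0])

        def resid(theta):
            cc_max, tm, te, slope = np.clip(theta, lo, hi)
            if tm >= te:
                return np.full_like(cc, 1e3)
            p = BetaParams(cc_max, tm, te, slope)
            return beta_cover(tt, p) - cc

        rng = np.random.default_rng(seed)
        starts = [(cc0, 0.5 * te0, te0, -1e-4)]
        for _ in range(self.N_STARTS - 1):
            starts.append(
                (
                    float(np.clip(cc0 * rng.uniform(0.8, 1.2), 0.05, 1.0)),
                    te0 * rng.uniform(0.3, 0.7),
                    float(np.clip(te0 * rng.uniform(0.8, 1.4), None, 1.2 * t_max)),
                    -(10.0 ** rng.uniform(-5, -3)),
                )
            )
        best = None
        for x0 in starts:
            sol = least_squares(
                resid,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                xtol=xtol,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        cc_max, tm, te, slope = np.clip(best.x, lo, hi)
        params = BetaParams(float(cc_max), float(tm), float(te), float(min(slope, 0.0)))
        res = beta_cover(tt, params) - cc
        return BetaCanopyResults(
            params=params,
            n_rising=int(np.sum(tt <= te)),
            n_decline=int(np.sum(tt > te)),
            rss=float(np.sum(res**2)),
            residuals=res,
            converged=bool(best.success),
            model=self,
        )
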