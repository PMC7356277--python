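"""Radiation-driven tuber growth and calibration.

Daily biomass accumulation is linear in intercepted radiation: with
radiation use efficiency RUE (g MJ^-1) and interception fraction f(t),

    dTB = RUE * f(t) * PAR_inc(t)          [g m^-2 d^-1]

Tuber mass is a time-varying fraction of total biomass following a Gompertz
partition curve on the thermal-time scale,

    p(tt) = a_max * exp(-exp(-b * (tt - tu)))

whose inflection abscissa ``tu`` (thermal time of maximum partition rate) is
the tuberization-precocity statistic: lower tu = earlier tuberization.
The harvest index at harvest equals p(tt_harvest), so a_max <= 1 guarantees
tuber mass never exceeds total biomass.  Calibration fits (RUE, a_max, b,
tu) to observed dry tuber mass by minimizing the mean relative error
|sim - obs| / obs, the criterion used to accept a calibrated accession.
Internal state is per m^2; per-plant masses use the plant area (default
0.78 m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .interception import BetaParams, beta_cover
from .weather import DEFAULT_T_BASE, thermal_time

__all__ = [
    "GompertzParams",
    "gompertz_partition",
    "GrowthResult",
    "simulate_growth",
    "extract_tu",
    "TuberGrowthModel",
    "TuberGrowthResults",
    "DEFAULT_PLANT_AREA",
]

#: Average ground area occupied by a single plant in the reference trial, m^2.
DEFAULT_PLANT_AREA = 0.78

#: Calibration bounds: (rue g/MJ, a_max, b per degC d, tu degC d).
DEFAULT_BOUNDS = {
    "rue": (0.2, 6.0),
    "a_max": (0.3, 1.0),
    "b": (0.002, 0.05),
    "tu": (150.0, 1500.0),
}


@dataclass(frozen=True)
class GompertzParams:
    """Tuber partition curve: asymptote a_max, rate b, inflection tu."""

    a_max: float
    b: float
    tu: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a_max <= 1.0:
            raise ValueError(f"a_max {self.a_max} outside (0, 1]")
        if self.b <= 0:
            raise ValueError("rate b must be > 0")
        if self.tu <= 0:
            raise ValueError("tu must be > 0")


def gompertz_partition(tt, params: GompertzParams):
    """Partition fraction at thermal time ``tt``; equals a_max/e at tt = tu."""
    tt = np.asarray(tt, dtype=float)
    out = params.a_max * np.exp(-np.exp(-params.b * (tt - params.tu)))
    return float(out) if out.ndim == 0 else out


def _as_f_curve(f_curve):
    if isinstance(f_curve, BetaParams):
        params = f_curve
        return lambda tt: beta_cover(tt, params)
    if callable(f_curve):
        return f_curve
    raise TypeError("f_curve must be BetaParams or a callable of thermal time")


def _intercepted_series(weather: pd.DataFrame, f_curve, t_base: float):
    """Per-day (tt, cumulative f*PAR) up to the end of the weather series."""
    tt = thermal_time(weather, t_base=t_base)
    f = np.clip(_as_f_curve(f_curve)(tt), 0.0, 1.0)
    fpar_cum = np.cumsum(f * weather["par_inc"].to_numpy())
    return tt, fpar_cum


@dataclass(frozen=True)
class GrowthResult:
    """Simulated state at harvest: totals per plant plus the daily trajectory."""

    tb: float
    ty_sim: float
    hi: float
    trajectory: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ty_sim > self.tb + 1e-9:
            raise ValueError("tuber mass exceeds total biomass")


def simulate_growth(
    weather: pd.DataFrame,
    f_curve,
    rue: float,
    gompertz: GompertzParams,
    harvest_dap: int,
    plant_area: float = DEFAULT_PLANT_AREA,
    t_base: float = DEFAULT_T_BASE,
) -> GrowthResult:
    """Forward-simulate biomass and tuber mass to harvest (g per plant)."""
    if rue <= 0:
        raise ValueError("rue must be > 0")
    if plant_area <= 0:
        raise ValueError("plant_area must be > 0")
    if harvest_dap > len(weather) or harvest_dap < 1:
        raise ValueError(
            f"harvest dap {harvest_dap} beyond weather series (1..{len(weather)})"
        )
    tt, fpar_cum = _intercepted_series(weather, f_curve, t_base)
    tb_m2 = rue * fpar_cum
    tuber_m2 = tb_m2 * gompertz_partition(tt, gompertz)
    traj = pd.DataFrame(
        {
            "dap": weather["dap"].to_numpy()[:harvest_dap],
            "tt": tt[:harvest_dap],
            "tb": tb_m2[:harvest_dap] * plant_area,
            "tuber": tuber_m2[:harvest_dap] * plant_area,
        }
    )
    tb = float(traj["tb"].iloc[-1])
    ty = float(traj["tuber"].iloc[-1])
    hi = ty / tb if tb > 0 else 0.0
    return GrowthResult(tb=tb, ty_sim=ty, hi=hi, trajectory=traj)


def extract_tu(
    params: GompertzParams,
    weather: pd.DataFrame | None = None,
    t_base: float = DEFAULT_T_BASE,
):
    """Return tu (degC d) and, given weather, its dap equivalent.

    The dap is the first day whose cumulative thermal time reaches tu; if tu
    lies beyond the simulated span the dap is None and ``beyond_span`` True.
    """
    if weather is None:
        return params.tu
    tt = thermal_time(weather, t_base=t_base)
    idx = int(np.searchsorted(tt, params.tu))
    beyond = idx >= len(tt)
    dap = None if beyond else int(weather["dap"].iloc[idx])
    return params.tu, dap, beyond


@dataclass
class TuberGrowthResults:
    """Calibrated growth model for one accession."""

    rue_: float
    gompertz_: GompertzParams
    mean_relative_error_: float
    converged: bool
    n_starts: int
    model: "TuberGrowthModel" = field(repr=False)

    @property
    def mean_relative_error_pct(self) -> float:
        return 100.0 * self.mean_relative_error_

    @property
    def tu_(self) -> float:
        return self.gompertz_.tu

    def predict(self, daps) -> np.ndarray:
        """Simulated dry tuber mass (g per plant) at the given daps."""
        return self.model._tuber_at(
            np.asarray(daps, dtype=int), self.rue_, self.gompertz_
        )

    def growth(self, harvest_dap: int | None = None) -> GrowthResult:
        m = self.model
        dap = harvest_dap if harvest_dap is not None else int(m.obs_daps.max())
        return simulate_growth(
            m.weather, m.f_curve, self.rue_, self.gompertz_, dap,
            plant_area=m.plant_area, t_base=m.t_base,
        )

    def summary(self) -> str:
        g = self.gompertz_
        lines = [
            "Tuber growth calibration",
            "-" * 40,
            f"RUE (g MJ^-1)        {self.rue_:10.3f}",
            f"a_max                {g.a_max:10.3f}",
            f"b (per degC d)       {g.b:10.4f}",
            f"tu (degC d)          {g.tu:10.1f}",
            f"mean relative error  {self.mean_relative_error_pct:9.2f} %",
            f"observations         {len(self.model.obs_daps):10d}",
            f"converged            {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


class TuberGrowthModel:
    """Calibrate (RUE, Gompertz) against observed dry tuber mass.

    Parameters
    ----------
    weather : DataFrame
        Daily weather (dap, par_inc, tmin, tmax) covering all observations.
    f_curve : BetaParams or callable
        Interception fraction as a function of thermal time.
    observations : DataFrame
        Columns ``dap`` and ``ty_obs`` (dry tuber mass, g per plant, > 0);
        optionally ``tb_obs`` (total dry biomass at the destructive final
        harvest, g per plant).  A total-biomass observation anchors RUE in
        closed form through RUE = TB/PARint; without it RUE and the
        partition asymptote are identified only through their product.
    """

    def __init__(
        self,
        weather: pd.DataFrame,
        f_curve,
        observations: pd.DataFrame,
        plant_area: float = DEFAULT_PLANT_AREA,
        t_base: float = DEFAULT_T_BASE,
    ):
        if len(observations) < 1:
            raise ValueError("need at least one observation")
        obs = observations.sort_values("dap")
        self.obs_daps = obs["dap"].to_numpy(dtype=int)
        self.obs_ty = obs["ty_obs"].to_numpy(dtype=float)
        if np.all(self.obs_ty <= 0):
            raise ValueError("all observations are non-positive")
        if self.obs_daps.max() > len(weather):
            raise ValueError("observation dap beyond weather series")
        self.tb_daps = np.array([], dtype=int)
        self.tb_obs = np.array([], dtype=float)
        if "tb_obs" in obs.columns:
            has_tb = obs["tb_obs"].notna() & (obs["tb_obs"] > 0)
            self.tb_daps = obs.loc[has_tb, "dap"].to_numpy(dtype=int)
            self.tb_obs = obs.loc[has_tb, "tb_obs"].to_numpy(dtype=float)
        self.weather = weather
        self.f_curve = f_curve
        self.plant_area = plant_area
        self.t_base = t_base
        self._tt, self._fpar_cum = _intercepted_series(weather, f_curve, t_base)

    def _tuber_at(self, daps: np.ndarray, rue: float, gomp: GompertzParams) -> np.ndarray:
        idx = daps - 1
        tb_m2 = rue * self._fpar_cum[idx]
        return tb_m2 * gompertz_partition(self._tt[idx], gomp) * self.plant_area

    def _mre(self, rue: float, gomp: GompertzParams) -> float:
        sim = self._tuber_at(self.obs_daps, rue, gomp)
        keep = self.obs_ty > 0
        return float(np.mean(np.abs(sim[keep] - self.obs_ty[keep]) / self.obs_ty[keep]))

    def fit(
        self,
        bounds: dict | None = None,
        fix_gompertz: GompertzParams | None = None,
        n_starts: int = 5,
        seed: int = 0,
    ) -> TuberGrowthResults:
        """Multi-start calibration minimizing the mean relative error.

        All observations (tuber series plus any total-biomass record) enter
        the objective as relative errors.  Each seeded start is pre-solved
        with smooth bounded least squares on the signed relative residuals,
        then refined with bounded Nelder-Mead on the mean-relative-error
        criterion itself.  With ``fix_gompertz`` only RUE is free.
        """
        bnds = dict(DEFAULT_BOUNDS)
        if bounds:
            bnds.update(bounds)
        rng = np.random.default_rng(seed)

        if fix_gompertz is not None:
            names = ["rue"]

            def unpack(x):
                return x[0], fix_gompertz
        else:
            names = ["rue", "a_max", "b", "tu"]

            def unpack(x):
                return x[0], GompertzParams(*x[1:])

        lo = np.array([bnds[n][0] for n in names])
        hi = np.array([bnds[n][1] for n in names])

        def rel_residuals(x):
            rue, gomp = unpack(np.clip(x, lo, hi))
            sim_ty = self._tuber_at(self.obs_daps, rue, gomp)
            res = (sim_ty - self.obs_ty) / self.obs_ty
            if len(self.tb_obs):
                sim_tb = rue * self._fpar_cum[self.tb_daps - 1] * self.plant_area
                res = np.concatenate([res, (sim_tb - self.tb_obs) / self.tb_obs])
            return res

        def objective(x):
            return float(np.mean(np.abs(rel_residuals(x))))

        starts = [0.5 * (lo + hi)]
        if len(self.tb_obs) and fix_gompertz is None:
            # anchor RUE at the closed-form TB/PARint estimate
            rue0 = float(
                np.clip(
                    np.mean(self.tb_obs / (self._fpar_cum[self.tb_daps - 1] * self.plant_area)),
                    *bnds["rue"],
                )
            )
            starts.append(np.array([rue0, 0.75, 0.012, 450.0]))
        while len(starts) < n_starts:
            starts.append(lo + rng.random(len(names)) * (hi - lo))
        best = None
        for x0 in starts:
            pre = least_squares(
                rel_residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            sol = minimize(
                objective,
                pre.x,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
            )
            if best is None or sol.fun < best.fun:
                best = sol
        rue, gomp = unpack(np.clip(best.x, lo, hi))
        sim_ty = self._tuber_at(self.obs_daps, rue, gomp)
        ty_mre = float(np.mean(np.abs(sim_ty - self.obs_ty) / self.obs_ty))
        return TuberGrowthResults(
            rue_=float(rue),
            gompertz_=gomp,
            mean_relative_error_=ty_mre,
            converged=bool(best.success),
            n_starts=n_starts,
            model=self,
        )
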