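"""Synthetic augmented field trials with known ground truth.

Generates everything the analysis pipeline consumes — daily weather around
monthly climate normals, an augmented block design (unreplicated test
accessions plus checks replicated in every block), per-accession true model
parameters, per-flight canopy reflectance (a two-endmember vegetation/soil
mixture weighted by the true cover curve, as plot means and optional toy
rasters), and noisy harvest observations produced by the forward growth
model.  Because every observable is simulated from known parameters, the
full pipeline can be checked by parameter recovery.

Default trial conditions mirror the reference Lima 2017 winter experiment:
planting 5 July, 20 test accessions + 4 checks in 4 blocks of 5+4 plots,
13 weekly flights, harvests at 121 or 141 days after planting, 0.78 m^2 per
plant, and true parameters drawn uniformly inside the observed ranges
(RUE 1.0-3.6 g MJ^-1, tu 356-556 degC d, harvest index 0.6-0.9, NDVI
senescence slope -0.006 to -0.002 per day).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import DEFAULT_PLANT_AREA, GompertzParams, simulate_growth
from .imaging import compute_ndvi
from .interception import BetaParams, beta_cover
from .weather import (
    DEFAULT_PLANTING_DATE,
    DEFAULT_T_BASE,
    LIMA_2017_PROFILE,
    WeatherProfile,
    generate_weather,
    thermal_time,
)

__all__ = [
    "Endmembers",
    "ParameterRanges",
    "AccessionTruth",
    "TrialDesign",
    "TrialConfig",
    "SyntheticTrial",
    "generate_design",
    "generate_truth",
    "generate_canopy_observations",
    "generate_harvest",
    "generate_trial",
    "DEFAULT_FLIGHT_DAPS",
]

#: 13 weekly flights covering canopy expansion through senescence.
DEFAULT_FLIGHT_DAPS = tuple(range(28, 119, 7))

_SPECIES_POOL = (
    ("S. tuberosum subsp. andigenum", 4),
    ("S. tuberosum subsp. tuberosum", 4),
    ("S. stenotomum subsp. stenotomum", 2),
    ("S. phureja", 2),
    ("S. chaucha", 3),
    ("S. juzepczukii", 3),
    ("S. curtilobum", 5),
)


@dataclass(frozen=True)
class Endmembers:
    """Pure vegetation and soil reflectance spectra (green, red, nir)."""

    veg: tuple[float, float, float] = (0.10, 0.08, 0.50)
    soil: tuple[float, float, float] = (0.18, 0.20, 0.25)

    @property
    def ndvi_contrast(self) -> float:
        v = compute_ndvi(self.veg[2], self.veg[1])
        s = compute_ndvi(self.soil[2], self.soil[1])
        return v - s


DEFAULT_ENDMEMBERS = Endmembers()


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform draw ranges for per-accession true parameters.

    Anchored to the spread observed across the reference landrace panel;
    canopy-timing ranges put peak cover near 60-85 days after planting under
    the default Lima winter weather.
    """

    rue: tuple[float, float] = (1.0, 3.6)          # g MJ^-1
    tu: tuple[float, float] = (356.3, 556.3)       # degC d
    hi: tuple[float, float] = (0.6, 0.9)           # asymptotic partition
    b: tuple[float, float] = (0.008, 0.02)         # per degC d
    cc_max: tuple[float, float] = (0.55, 0.95)
    te: tuple[float, float] = (850.0, 1250.0)      # degC d at peak cover
    tm_frac: tuple[float, float] = (0.40, 0.60)    # tm as fraction of te
    ndvi_slp: tuple[float, float] = (-0.006, -0.002)  # NDVI per day
    a_mean: tuple[float, float] = (17.0, 26.6)     # umol CO2 m^-2 s^-1
    delta_leaf: tuple[float, float] = (21.0, 23.0)  # permil
    #: Gaussian-copula correlation between senescence delay (NDVIslp) and
    #: RUE: accessions that stay green longer also convert radiation better,
    #: the trait structure seen in the reference panel.
    rue_ndvi_slp_corr: float = 0.7

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "rue_ndvi_slp_corr":
                if not -1.0 <= self.rue_ndvi_slp_corr <= 1.0:
                    raise ValueError("rue_ndvi_slp_corr outside [-1, 1]")
                continue
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"range {name} has low > high")


@dataclass(frozen=True)
class AccessionTruth:
    """True generating parameters of one accession."""

    accession_id: str
    beta: BetaParams
    gompertz: GompertzParams
    rue_true: float
    a_mean: float
    delta_leaf: float
    ndvi_slp_true: float

    def __post_init__(self) -> None:
        if self.rue_true <= 0:
            raise ValueError("rue_true must be > 0")


@dataclass(frozen=True)
class TrialDesign:
    """Augmented-design layout: one row per plot."""

    entries: pd.DataFrame
    plant_area: float = DEFAULT_PLANT_AREA
    n_blocks: int = 4

    def __post_init__(self) -> None:
        e = self.entries
        checks = e[e["is_check"]]
        news = e[~e["is_check"]]
        blocks = sorted(e["block"].unique())
        for chk in checks["accession"].unique():
            blks = sorted(checks.loc[checks["accession"] == chk, "block"])
            if blks != blocks:
                raise ValueError(f"check {chk} must appear exactly once per block")
        counts = news["accession"].value_counts()
        if (counts != 1).any():
            raise ValueError("each test accession must appear in exactly one block")
        sizes = e.groupby("block").size().unique()
        if len(sizes) != 1:
            raise ValueError("block sizes must be equal")

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.entries["accession"]))


def generate_design(
    n_new: int = 20,
    n_checks: int = 4,
    n_blocks: int = 4,
    new_per_block: int = 5,
    seed: int = 0,
    harvest_daps: tuple[int, ...] = (121, 141),
    plant_area: float = DEFAULT_PLANT_AREA,
) -> TrialDesign:
    """Randomized augmented block design, deterministic under ``seed``."""
    if n_new != n_blocks * new_per_block:
        raise ValueError(
            f"n_new={n_new} must equal n_blocks*new_per_block={n_blocks * new_per_block}"
        )
    rng = np.random.default_rng(seed)
    new_ids = [f"ACC{i + 1:03d}" for i in range(n_new)]
    check_ids = [f"CHK{i + 1}" for i in range(n_checks)]
    perm = rng.permutation(n_new)
    harvest = {}
    species = {}
    for acc in new_ids + check_ids:
        harvest[acc] = int(rng.choice(harvest_daps))
        sp, pl = _SPECIES_POOL[rng.integers(len(_SPECIES_POOL))]
        species[acc] = ("improved variety", 4) if acc.startswith("CHK") else (sp, pl)
    rows = []
    for j in range(n_blocks):
        block_new = [new_ids[perm[j * new_per_block + i]] for i in range(new_per_block)]
        for acc in block_new + check_ids:
            sp, pl = species[acc]
            rows.append(
                {
                    "plot_id": f"{acc}_b{j + 1}",
                    "accession": acc,
                    "species": sp,
                    "ploidy": pl,
                    "is_check": acc.startswith("CHK"),
                    "block": j + 1,
                    "harvest_dap": harvest[acc],
                }
            )
    return TrialDesign(pd.DataFrame(rows), plant_area=plant_area, n_blocks=n_blocks)


def _mean_degree_days(weather: pd.DataFrame, t_base: float) -> float:
    tt = thermal_time(weather, t_base=t_base)
    return float(tt[-1] / len(tt))


def _std_normal_cdf(z: float) -> float:
    from scipy.special import ndtr

    return float(ndtr(z))


def generate_truth(
    design: TrialDesign,
    ranges: ParameterRanges = ParameterRanges(),
    seed: int = 0,
    weather: pd.DataFrame | None = None,
    endmembers: Endmembers = DEFAULT_ENDMEMBERS,
    t_base: float = DEFAULT_T_BASE,
) -> dict[str, AccessionTruth]:
    """Draw true parameters per accession, uniform inside the ranges.

    The canopy decline slope is derived from the drawn NDVI senescence
    slope: cover loss per degC d = NDVIslp / (degree-days per day x NDVI
    contrast between the vegetation and soil endmembers), so the synthetic
    NDVI series declines at approximately the drawn per-day rate.
    """
    ranges.validate()
    accessions = design.accessions
    if not accessions:
        raise ValueError("design has no accessions")
    dd_per_day = 15.4 if weather is None else _mean_degree_days(weather, t_base)
    contrast = endmembers.ndvi_contrast
    rng = np.random.default_rng(seed)

    def u(rg):
        lo, hi = rg
        return float(lo + (hi - lo) * rng.random())

    def u_from_normal(rg, z):
        lo, hi = rg
        return float(lo + (hi - lo) * _std_normal_cdf(z))

    rho = ranges.rue_ndvi_slp_corr
    out: dict[str, AccessionTruth] = {}
    for acc in accessions:
        te = u(ranges.te)
        tm = te * u(ranges.tm_frac)
        # Gaussian copula linking senescence delay and RUE
        z1, z2 = rng.normal(size=2)
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
        ndvi_slp = u_from_normal(ranges.ndvi_slp, z1)
        rue_true = u_from_normal(ranges.rue, z2)
        decline = ndvi_slp / (dd_per_day * contrast)
        beta = BetaParams(cc_max=u(ranges.cc_max), tm=tm, te=te, decline_slope=decline)
        gomp = GompertzParams(a_max=u(ranges.hi), b=u(ranges.b), tu=u(ranges.tu))
        out[acc] = AccessionTruth(
            accession_id=acc,
            beta=beta,
            gompertz=gomp,
            rue_true=rue_true,
            a_mean=u(ranges.a_mean),
            delta_leaf=u(ranges.delta_leaf),
            ndvi_slp_true=ndvi_slp,
        )
    return out


@dataclass(frozen=True)
class CanopyObservations:
    """Per-flight plot reflectance with the generating cover for reference."""

    table: pd.DataFrame  # dap, green, red, nir, cc_true
    rasters: dict[int, np.ndarray] | None = None


def generate_canopy_observations(
    truth: AccessionTruth,
    weather: pd.DataFrame,
    flight_daps=DEFAULT_FLIGHT_DAPS,
    noise_sd: float = 0.01,
    seed: int = 0,
    raster_shape: tuple[int, int] | None = None,
    endmembers: Endmembers = DEFAULT_ENDMEMBERS,
    t_base: float = DEFAULT_T_BASE,
) -> CanopyObservations:
    """Mix endmember spectra by the true cover at each flight, plus noise.

    Plot-mean reflectance is the exact linear mixture with truncated
    Gaussian noise.  With ``raster_shape`` a toy raster per flight is also
    produced in which round(cc * n_pixels) randomly placed pixels carry the
    vegetation spectrum and the rest soil, so SAVI segmentation recovers
    cover to within one pixel quantum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    flight_daps = np.asarray(list(flight_daps), dtype=int)
    if flight_daps.max() > len(weather) or flight_daps.min() < 1:
        raise ValueError("flight dap beyond weather series")
    rng = np.random.default_rng(seed)
    tt = thermal_time(weather, t_base=t_base)[flight_daps - 1]
    cc = beta_cover(tt, truth.beta)
    veg = np.asarray(endmembers.veg)
    soil = np.asarray(endmembers.soil)
    means = cc[:, None] * veg[None, :] + (1.0 - cc[:, None]) * soil[None, :]
    noisy = np.clip(means + rng.normal(0.0, noise_sd or 0.0, means.shape)
                    if noise_sd > 0 else means, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "dap": flight_daps,
            "green": noisy[:, 0],
            "red": noisy[:, 1],
            "nir": noisy[:, 2],
            "cc_true": cc,
        }
    )
    rasters = None
    if raster_shape is not None:
        h, w = raster_shape
        npix = h * w
        rasters = {}
        for k, dap in enumerate(flight_daps):
            n_veg = int(round(cc[k] * npix))
            flat = np.tile(soil, (npix, 1))
            pos = rng.permutation(npix)[:n_veg]
            flat[pos] = veg
            if noise_sd > 0:
                flat = flat + rng.normal(0.0, noise_sd, flat.shape)
            rasters[int(dap)] = np.clip(flat.reshape(h, w, 3), 0.0, 1.0)
    return CanopyObservations(table=table, rasters=rasters)


def generate_harvest(
    truth: AccessionTruth,
    weather: pd.DataFrame,
    harvest_dap: int,
    noise_cv: float = 0.10,
    seed: int = 0,
    obs_daps=None,
    plant_area: float = DEFAULT_PLANT_AREA,
    t_base: float = DEFAULT_T_BASE,
) -> pd.DataFrame:
    """Observed dry tuber mass (g per plant) with multiplicative noise.

    ``obs_daps`` defaults to four points: three mid-season fresh-mass-derived
    estimates placed early enough to bracket the tuber-partitioning
    inflection (which falls near dap 25-40 under the default weather) plus
    the final dry harvest.  The final
    destructive harvest also records total dry biomass (``tb_obs``,
    tubers + haulm), which anchors RUE during calibration.  The noise
    factor is 1 + cv*z truncated below at 0.05 so observations stay
    strictly positive.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if harvest_dap > len(weather):
        raise ValueError("harvest dap beyond weather series")
    if obs_daps is None:
        obs_daps = [25, 45, 70, harvest_dap]
    obs_daps = [int(d) for d in obs_daps]
    rng = np.random.default_rng(seed)
    sim = simulate_growth(
        weather, truth.beta, truth.rue_true, truth.gompertz, harvest_dap,
        plant_area=plant_area, t_base=t_base,
    )
    traj = sim.trajectory.set_index("dap")
    rows = []
    for dap in obs_daps:
        true_ty = float(traj.loc[dap, "tuber"])
        factor = max(1.0 + noise_cv * rng.normal(), 0.05) if noise_cv > 0 else 1.0
        rec = {"dap": dap, "ty_obs": true_ty * factor, "ty_true": true_ty,
               "tb_obs": np.nan}
        if dap == harvest_dap:
            tb_factor = max(1.0 + noise_cv * rng.normal(), 0.05) if noise_cv > 0 else 1.0
            rec["tb_obs"] = float(traj.loc[dap, "tb"]) * tb_factor
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialConfig:
    """Knobs of the synthetic trial; defaults are the reference conditions."""

    n_new: int = 20
    n_checks: int = 4
    n_blocks: int = 4
    new_per_block: int = 5
    n_days: int = 141
    planting_date: _dt.date = DEFAULT_PLANTING_DATE
    profile: WeatherProfile = field(default_factory=lambda: LIMA_2017_PROFILE)
    flight_daps: tuple[int, ...] = DEFAULT_FLIGHT_DAPS
    harvest_daps: tuple[int, ...] = (121, 141)
    weather_dispersion: float = 1.0
    noise_sd: float = 0.01
    noise_cv: float = 0.10
    a_noise_sd: float = 1.5
    delta_noise_sd: float = 0.3
    plant_area: float = DEFAULT_PLANT_AREA
    t_base: float = DEFAULT_T_BASE
    raster_shape: tuple[int, int] | None = None
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    endmembers: Endmembers = field(default_factory=lambda: DEFAULT_ENDMEMBERS)
    seed: int = 0

    def noiseless(self) -> "TrialConfig":
        """Copy with every noise source switched off (for recovery checks)."""
        return replace(
            self, weather_dispersion=0.0, noise_sd=0.0, noise_cv=0.0,
            a_noise_sd=0.0, delta_noise_sd=0.0,
        )


@dataclass(frozen=True)
class SyntheticTrial:
    """Complete generated trial bundle."""

    config: TrialConfig
    weather: pd.DataFrame
    design: TrialDesign
    truths: dict[str, AccessionTruth]
    canopy: dict[str, CanopyObservations]   # keyed by plot_id
    harvest: dict[str, pd.DataFrame]        # keyed by plot_id
    physiology: pd.DataFrame                # plot-level A and delta_leaf


def generate_trial(config: TrialConfig = TrialConfig()) -> SyntheticTrial:
    """Generate a full synthetic trial; byte-identical under the same seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4)
    weather = generate_weather(
        config.profile, config.planting_date, config.n_days,
        seed=int(seeds[0]), dispersion=config.weather_dispersion,
    )
    design = generate_design(
        config.n_new, config.n_checks, config.n_blocks, config.new_per_block,
        seed=int(seeds[1]), harvest_daps=config.harvest_daps,
        plant_area=config.plant_area,
    )
    truths = generate_truth(
        design, config.ranges, seed=int(seeds[2]), weather=weather,
        endmembers=config.endmembers, t_base=config.t_base,
    )
    plot_rng = np.random.default_rng(seeds[3])
    canopy: dict[str, CanopyObservations] = {}
    harvest: dict[str, pd.DataFrame] = {}
    phys_rows = []
    for row in design.entries.itertuples():
        truth = truths[row.accession]
        s_canopy, s_harvest, s_phys = plot_rng.integers(2**31, size=3)
        canopy[row.plot_id] = generate_canopy_observations(
            truth, weather, config.flight_daps, noise_sd=config.noise_sd,
            seed=int(s_canopy), raster_shape=config.raster_shape,
            endmembers=config.endmembers, t_base=config.t_base,
        )
        harvest[row.plot_id] = generate_harvest(
            truth, weather, row.harvest_dap, noise_cv=config.noise_cv,
            seed=int(s_harvest), plant_area=config.plant_area,
            t_base=config.t_base,
        )
        prng = np.random.default_rng(int(s_phys))
        phys_rows.append(
            {
                "plot_id": row.plot_id,
                "accession": row.accession,
                "block": row.block,
                "is_check": row.is_check,
                "a_obs": truth.a_mean + config.a_noise_sd * prng.normal(),
                "delta_leaf_obs": truth.delta_leaf + config.delta_noise_sd * prng.normal(),
            }
        )
    return SyntheticTrial(
        config=config,
        weather=weather,
        design=design,
        truths=truths,
        canopy=canopy,
        harvest=harvest,
        physiology=pd.DataFrame(phys_rows),
    )
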