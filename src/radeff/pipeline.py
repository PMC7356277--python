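"""End-to-end orchestration: reflectance + weather + harvest -> trait stats.

Stages, per plot: (1) canopy points from reflectance (mixture inversion on
plot means, or SAVI segmentation when rasters are present); (2) NDVI
senescence slope; (3) beta canopy fit on the thermal-time scale; (4)
cumulative incident/intercepted PAR and epsilon_i; (5) growth-model
calibration against tuber-mass observations giving RUE, tu, total biomass
and harvest index; (6) the efficiency set.  Then across plots: augmented
design ANOVA with adjusted means per trait, Pearson correlations, PCA,
Ward clustering on retained component scores, and regression of tuber
yield on the principal components.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efficiency import DEFAULT_CONSTANTS, EfficiencyConstants, efficiency_set
from .fieldstats import (
    AugmentedDesignModel,
    PCAResult,
    ndvi_senescence_slope,
    pca,
    pearson_matrix,
    regress_on_pcs,
    ward_cluster,
)
from .growth import DEFAULT_PLANT_AREA, TuberGrowthModel, extract_tu
from .imaging import (
    DEFAULT_SAVI_L,
    DEFAULT_SAVI_THRESHOLD,
    compute_ndvi,
    cover_from_mixture,
    plot_mean_index,
    segment_canopy_cover,
)
from .interception import BetaCanopyModel, par_intercepted_and_epsilon_i
from .synthetic import DEFAULT_ENDMEMBERS, Endmembers, SyntheticTrial
from .weather import DEFAULT_T_BASE, thermal_time

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResults", "analyze_trial", "run_pipeline"]

#: Traits entering the multivariate stage (the 7 ordination traits + yield).
PCA_TRAITS = ["epsilon_i", "epsilon_c", "epsilon_p", "a", "delta_leaf", "ndvi_slp", "tu"]
ALL_TRAITS = ["ty"] + PCA_TRAITS


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; seeds cover every stochastic stage."""

    savi_threshold: float | str = DEFAULT_SAVI_THRESHOLD
    savi_L: float = DEFAULT_SAVI_L
    t_base: float = DEFAULT_T_BASE
    plant_area: float = DEFAULT_PLANT_AREA
    constants: EfficiencyConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    endmembers: Endmembers = field(default_factory=lambda: DEFAULT_ENDMEMBERS)
    calibration_starts: int = 5
    n_pcs: int = 3
    n_clusters: int = 3
    seed: int = 0


@dataclass
class PipelineResults:
    """Everything the pipeline computes, plus a reproducibility manifest."""

    plot_table: pd.DataFrame
    trait_table: pd.DataFrame          # adjusted means per accession
    anova: dict[str, pd.DataFrame]
    tukey: dict[str, pd.Series]
    correlation: pd.DataFrame
    pca: PCAResult
    clusters: pd.Series
    merge_heights: np.ndarray
    pc_regression: object
    manifest: dict

    def summary(self) -> str:
        reg = self.pc_regression
        coefs = "  ".join(
            f"{n}={v:.1f}" for n, v in reg.params.items()
        )
        lines = [
            "Radiation-efficiency trial analysis",
            "=" * 60,
            f"plots analysed      {len(self.plot_table)}",
            f"accessions          {len(self.trait_table)}",
            "",
            "Adjusted trait means (first rows):",
            self.trait_table.head().to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            f"PCA cumulative variance (first {self.manifest['n_pcs']} PCs): "
            + ", ".join(
                f"{v:.1f}%" for v in self.pca.cumulative_variance[: self.manifest["n_pcs"]]
            ),
            f"Ward clusters (k={self.manifest['n_clusters']}): "
            + ", ".join(
                f"G{g}: n={int(n)}" for g, n in self.clusters.value_counts().sort_index().items()
            ),
            f"TY ~ PCs regression: {coefs}",
            f"  R^2 = {reg.rsquared:.3f}, F = {reg.fvalue:.1f}, p = {reg.f_pvalue:.2g}",
        ]
        return "\n".join(lines)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.plot_table.to_csv(outdir / "plot_traits.csv", index=False)
        self.trait_table.to_csv(outdir / "adjusted_traits.csv")
        self.correlation.to_csv(outdir / "pearson_correlation.csv")
        self.pca.loadings.to_csv(outdir / "pca_loadings.csv")
        pd.DataFrame(
            {
                "eigenvalue": self.pca.eigenvalues,
                "cumulative_variance_pct": self.pca.cumulative_variance,
            }
        ).to_csv(outdir / "pca_eigenvalues.csv", index=False)
        self.pca.scores.to_csv(outdir / "pca_scores.csv")
        self.clusters.to_csv(outdir / "clusters.csv")
        for trait, table in self.anova.items():
            table.to_csv(outdir / f"anova_{trait}.csv")
        reg = self.pc_regression
        regression = {
            "coefficients": {k: float(v) for k, v in reg.params.items()},
            "r_squared": float(reg.rsquared),
            "f_value": float(reg.fvalue),
            "f_pvalue": float(reg.f_pvalue),
        }
        (outdir / "pc_regression.json").write_text(json.dumps(regression, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def extract_canopy_points(obs, config: PipelineConfig) -> pd.DataFrame:
    """Per-flight (dap, cc, ndvi) for one plot.

    Rasters (when present) are segmented on SAVI; plot-mean reflectance
    rows are inverted through the two-endmember mixture on the NIR band.
    NDVI is the plot mean either way.
    """
    table = obs.table
    if obs.rasters:
        rows = []
        for dap in table["dap"]:
            raster = obs.rasters[int(dap)]
            cc = segment_canopy_cover(raster, config.savi_threshold, L=config.savi_L)
            rows.append((int(dap), cc, plot_mean_index(raster)))
        return pd.DataFrame(rows, columns=["dap", "cc", "ndvi"])
    veg_nir = config.endmembers.veg[2]
    soil_nir = config.endmembers.soil[2]
    cc = cover_from_mixture(table["nir"].to_numpy(), veg_nir, soil_nir)
    ndvi = compute_ndvi(table["nir"].to_numpy(), table["red"].to_numpy())
    return pd.DataFrame({"dap": table["dap"].to_numpy(), "cc": cc, "ndvi": ndvi})


def analyze_plot(
    plot, weather: pd.DataFrame, obs, harvest: pd.DataFrame, config: PipelineConfig,
    seed: int,
) -> dict:
    """Run stages 1-6 for one plot; returns the per-plot trait record."""
    points = extract_canopy_points(obs, config)
    tt_all = thermal_time(weather, t_base=config.t_base)
    tt = tt_all[points["dap"].to_numpy() - 1]
    beta_res = BetaCanopyModel(tt, points["cc"].to_numpy()).fit(seed=seed)
    radiation = par_intercepted_and_epsilon_i(
        weather, beta_res.params, plot.harvest_dap, t_base=config.t_base
    )
    obs_cols = ["dap", "ty_obs"] + (["tb_obs"] if "tb_obs" in harvest else [])
    growth_model = TuberGrowthModel(
        weather,
        beta_res.params,
        harvest[obs_cols],
        plant_area=config.plant_area,
        t_base=config.t_base,
    )
    fit = growth_model.fit(n_starts=config.calibration_starts, seed=seed)
    growth = fit.growth(plot.harvest_dap)
    eff = efficiency_set(
        plot.accession, radiation, growth, config.plant_area, config.constants
    )
    slope = ndvi_senescence_slope(points["dap"], points["ndvi"])
    tu, tu_dap, beyond = extract_tu(fit.gompertz_, weather, t_base=config.t_base)
    return {
        "plot_id": plot.plot_id,
        "accession": plot.accession,
        "block": plot.block,
        "is_check": plot.is_check,
        "harvest_dap": plot.harvest_dap,
        "ty": float(harvest.loc[harvest["dap"].idxmax(), "ty_obs"]),
        "epsilon_i": eff.epsilon_i,
        "epsilon_c": eff.epsilon_c,
        "epsilon_p": eff.epsilon_p,
        "rue": fit.rue_,
        "par_int": radiation.par_int_cum,
        "par_inc": radiation.par_inc_cum,
        "tb": growth.tb,
        "ty_sim": growth.ty_sim,
        "hi": growth.hi,
        "ndvi_slp": slope,
        "tu": tu,
        "tu_dap": tu_dap if not beyond else np.nan,
        "a": None,
        "delta_leaf": None,
        "calibration_mre": fit.mean_relative_error_,
        "cc_max": beta_res.params.cc_max,
        "beta_tm": beta_res.params.tm,
        "beta_te": beta_res.params.te,
        "decline_slope": beta_res.params.decline_slope,
    }


def analyze_trial(trial, config: PipelineConfig = PipelineConfig()) -> PipelineResults:
    """Run the full analysis on a trial bundle (synthetic or loaded)."""
    t0 = time.time()
    weather = trial.weather
    design = trial.design
    seed_rng = np.random.default_rng(config.seed)
    phys = trial.physiology.set_index("plot_id")
    records = []
    for plot in design.entries.itertuples():
        seed = int(seed_rng.integers(2**31))
        try:
            rec = analyze_plot(
                plot, weather, trial.canopy[plot.plot_id],
                trial.harvest[plot.plot_id], config, seed,
            )
        except Exception as exc:
            raise RuntimeError(
                f"plot analysis failed for accession {plot.accession} "
                f"(plot {plot.plot_id}): {exc}"
            ) from exc
        if plot.plot_id in phys.index:
            rec["a"] = float(phys.loc[plot.plot_id, "a_obs"])
            rec["delta_leaf"] = float(phys.loc[plot.plot_id, "delta_leaf_obs"])
        records.append(rec)
        logger.info("plot %s done", plot.plot_id)
    plot_table = pd.DataFrame(records)

    anova, tukey = {}, {}
    adjusted = {}
    for trait in ALL_TRAITS:
        if plot_table[trait].isna().all():
            continue
        res = AugmentedDesignModel(plot_table, trait).fit()
        anova[trait] = res.anova
        tukey[trait] = res.tukey_groups
        adjusted[trait] = res.adjusted_means
    trait_table = pd.DataFrame(adjusted)
    trait_table.index.name = "accession"

    correlation = pearson_matrix(trait_table, list(trait_table.columns))
    pca_res = pca(trait_table, [t for t in PCA_TRAITS if t in trait_table])
    retained = pca_res.scores.iloc[:, : config.n_pcs]
    clusters, heights = ward_cluster(retained, config.n_clusters)
    ty_rows = trait_table.loc[retained.index, "ty"]
    regression = regress_on_pcs(ty_rows, retained)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "t_base": config.t_base,
        "plant_area": config.plant_area,
        "savi_threshold": config.savi_threshold,
        "savi_L": config.savi_L,
        "calibration_starts": config.calibration_starts,
        "n_pcs": config.n_pcs,
        "n_clusters": config.n_clusters,
        "n_plots": len(plot_table),
        "runtime_s": round(time.time() - t0, 2),
    }
    return PipelineResults(
        plot_table=plot_table,
        trait_table=trait_table,
        anova=anova,
        tukey=tukey,
        correlation=correlation,
        pca=pca_res,
        clusters=clusters,
        merge_heights=heights,
        pc_regression=regression,
        manifest=manifest,
    )


def run_pipeline(
    trial: SyntheticTrial | None = None,
    indir=None,
    outdir=None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResults:
    """Analyze a generated or on-disk trial, optionally writing all outputs."""
    if trial is None:
        if indir is None:
            raise ValueError("provide a trial bundle or an input directory")
        from .io import read_trial

        trial = read_trial(indir)
    results = analyze_trial(trial, config)
    if outdir is not None:
        results.write(outdir)
    return results
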