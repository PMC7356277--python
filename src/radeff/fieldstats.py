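"""Trait statistics for the augmented field trial.

Covers the multivariate characterization stage: the NDVI senescence-decline
slope, analysis of variance for the augmented block design (unreplicated
test entries plus checks replicated in every block, with Federer-style
adjusted means), Pearson correlations, correlation-matrix PCA, Ward
hierarchical clustering on retained component scores, and multiple
regression of tuber yield on principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = [
    "ndvi_senescence_slope",
    "AugmentedDesignModel",
    "AugmentedDesignResults",
    "pearson_matrix",
    "pca",
    "PCAResult",
    "ward_cluster",
    "regress_on_pcs",
]


def ndvi_senescence_slope(daps, ndvi) -> float:
    """OLS slope of NDVI vs dap from the flight of maximum NDVI onward.

    Higher (less negative) slope = longer senescence delay.  Requires at
    least 3 flights at or after the maximum.
    """
    daps = np.asarray(daps, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    if daps.shape != ndvi.shape or daps.ndim != 1:
        raise ValueError("daps and ndvi must be 1-D arrays of equal length")
    order = np.argsort(daps)
    daps, ndvi = daps[order], ndvi[order]
    start = int(np.argmax(ndvi))
    x, y = daps[start:], ndvi[start:]
    if len(x) < 3:
        raise ValueError(
            f"need >= 3 flights at or after the NDVI maximum, have {len(x)}"
        )
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Augmented block design (DAU) analysis
# ---------------------------------------------------------------------------


@dataclass
class AugmentedDesignResults:
    """ANOVA table, adjusted means and Tukey letter groups."""

    anova: pd.DataFrame
    adjusted_means: pd.Series
    block_effects: pd.Series
    error_ms: float
    error_df: int
    tukey_groups: pd.Series
    trait: str

    def summary(self) -> str:
        lines = [
            f"Augmented block design analysis: {self.trait}",
            "-" * 60,
            self.anova.to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            f"error MS {self.error_ms:.4g} on {self.error_df} df",
            "",
            "Adjusted means (Tukey letters):",
        ]
        for acc, mean in self.adjusted_means.sort_values(ascending=False).items():
            lines.append(f"  {acc:<16s} {mean:10.3f}  {self.tukey_groups[acc]}")
        return "\n".join(lines)


class AugmentedDesignModel:
    """Federer augmented-RCBD analysis of one trait.

    Parameters
    ----------
    data : DataFrame
        One row per plot with columns ``accession``, ``block``, ``is_check``
        and the trait column.
    trait : str
        Name of the response column.

    Block effects are estimated from the replicated checks; the adjusted
    value of an unreplicated test entry in block j is its raw value minus
    (mean of checks in block j - grand mean of checks).  The treatment sum
    of squares is partitioned into checks, augmented (test) entries, and the
    checks-vs-augmented contrast, all tested against the checks-in-blocks
    residual mean square.
    """

    def __init__(self, data: pd.DataFrame, trait: str):
        required = {"accession", "block", "is_check", trait}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns: {sorted(missing)}")
        self.data = data.copy()
        self.trait = trait
        checks = self.data[self.data["is_check"]]
        blocks = sorted(self.data["block"].unique())
        tab = checks.pivot_table(
            index="accession", columns="block", values=trait, aggfunc="count"
        ).reindex(columns=blocks)
        if tab.isna().any().any() or (tab != 1).any().any():
            raise ValueError("every check must appear exactly once in every block")
        if checks[trait].isna().any():
            raise ValueError("check trait values must be complete")
        self.blocks = blocks
        self.check_ids = sorted(checks["accession"].unique())
        if len(self.check_ids) < 2 or len(blocks) < 2:
            raise ValueError("need >= 2 checks and >= 2 blocks for error estimation")

    def fit(self, alpha: float = 0.05) -> AugmentedDesignResults:
        d, trait = self.data, self.trait
        checks = d[d["is_check"]]
        news = d[~d["is_check"]]
        b, c = len(self.blocks), len(self.check_ids)

        grand_check = checks[trait].mean()
        block_check_mean = checks.groupby("block")[trait].mean()
        block_eff = block_check_mean - grand_check

        # two-way residual of checks in blocks -> error mean square
        check_mean = checks.groupby("accession")[trait].mean()
        resid = (
            checks[trait].to_numpy()
            - check_mean.loc[checks["accession"]].to_numpy()
            - block_check_mean.loc[checks["block"]].to_numpy()
            + grand_check
        )
        ss_error = float(np.sum(resid**2))
        df_error = (b - 1) * (c - 1)
        if df_error == 0:
            raise ValueError("zero error degrees of freedom")
        ms_error = ss_error / df_error

        # adjusted values: checks keep their replicate mean, test entries are
        # corrected by the block effect of their block
        adj_new = news[trait].to_numpy() - block_eff.loc[news["block"]].to_numpy()
        adjusted = pd.concat(
            [check_mean, pd.Series(adj_new, index=news["accession"].to_numpy())]
        )
        adjusted.name = f"{trait}_adjusted"
        adjusted.index.name = "accession"

        n_new = len(news)
        ss_check = b * float(np.sum((check_mean - grand_check) ** 2))
        df_check = c - 1
        mean_adj_new = float(np.mean(adj_new))
        ss_new = float(np.sum((adj_new - mean_adj_new) ** 2))
        df_new = n_new - 1
        n_check_obs = b * c
        ss_cvn = (
            n_check_obs * n_new / (n_check_obs + n_new)
            * (grand_check - mean_adj_new) ** 2
        )
        ss_block = c * float(np.sum((block_check_mean - grand_check) ** 2))

        rows = []
        for name, ss, df in [
            ("block (checks)", ss_block, b - 1),
            ("check", ss_check, df_check),
            ("augmented", ss_new, df_new),
            ("check vs augmented", ss_cvn, 1),
            ("error (checks)", ss_error, df_error),
        ]:
            ms = ss / df if df > 0 else np.nan
            if name == "error (checks)":
                f_val, p_val = np.nan, np.nan
            elif ms_error == 0:  # degenerate: checks fit the additive model exactly
                f_val = np.inf if ms > 0 else np.nan
                p_val = 0.0 if ms > 0 else np.nan
            else:
                f_val = ms / ms_error
                p_val = float(sps.f.sf(f_val, df, df_error))
            rows.append((name, df, ss, ms, f_val, p_val))
        anova = pd.DataFrame(
            rows, columns=["source", "df", "SS", "MS", "F", "p"]
        ).set_index("source")

        groups = self._tukey_letters(adjusted, ms_error, df_error, b, c, alpha)
        return AugmentedDesignResults(
            anova=anova,
            adjusted_means=adjusted,
            block_effects=block_eff,
            error_ms=ms_error,
            error_df=df_error,
            tukey_groups=groups,
            trait=trait,
        )

    def _pair_variance(self, a: str, b_: str, ms: float, b: int, c: int) -> float:
        """Federer variance of the difference of two adjusted means."""
        d = self.data
        a_chk, b_chk = a in self.check_ids, b_ in self.check_ids
        if a_chk and b_chk:
            return 2 * ms / b
        if a_chk != b_chk:
            return ms * (1 + 1 / b + 1 / c + 1 / (b * c))
        blk = d.set_index("accession")["block"]
        same_block = blk[a] == blk[b_]
        return 2 * ms if same_block else 2 * ms * (1 + 1 / c)

    def _tukey_letters(
        self,
        means: pd.Series,
        ms: float,
        df: int,
        b: int,
        c: int,
        alpha: float,
    ) -> pd.Series:
        k = len(means)
        q = float(sps.studentized_range.ppf(1 - alpha, k, df))
        order = means.sort_values(ascending=False)
        ids = list(order.index)

        def differ(x, y):
            sed = np.sqrt(self._pair_variance(x, y, ms, b, c) / 2)
            return abs(means[x] - means[y]) > q * sed

        # sweep: grow maximal runs of mutually non-different means
        groups: list[list[str]] = []
        for i in range(k):
            run = [ids[i]]
            for j in range(i + 1, k):
                if differ(ids[i], ids[j]):
                    break
                run.append(ids[j])
            if not groups or not set(run) <= set(groups[-1]):
                groups.append(run)
        letters = {acc: "" for acc in ids}
        for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
            for acc in grp:
                letters[acc] += letter
        return pd.Series(letters, name="group").reindex(means.index)


# ---------------------------------------------------------------------------
# Correlation, ordination, clustering, PC regression
# ---------------------------------------------------------------------------


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix; zero-variance columns give NaN."""
    cols = columns or list(table.columns)
    sub = table[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    zero_var = [c for c in cols if np.isclose(sub[c].var(ddof=1), 0.0)]
    if zero_var:
        logger.warning("zero-variance columns in correlation: %s", zero_var)
    return sub.corr(method="pearson")


@dataclass
class PCAResult:
    """Correlation-matrix PCA: loadings, eigenvalues, scores."""

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    cumulative_variance: np.ndarray  # percent
    scores: pd.DataFrame
    excluded: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Principal component analysis (correlation matrix)", "-" * 60]
        head = "trait".ljust(12) + "".join(
            f"{c:>10s}" for c in self.loadings.columns
        )
        lines.append(head)
        for t, row in self.loadings.iterrows():
            lines.append(t.ljust(12) + "".join(f"{v:10.3f}" for v in row))
        lines.append(
            "eigenvalue".ljust(12)
            + "".join(f"{v:10.3f}" for v in self.eigenvalues[: self.loadings.shape[1]])
        )
        lines.append(
            "cum var %".ljust(12)
            + "".join(
                f"{v:10.1f}"
                for v in self.cumulative_variance[: self.loadings.shape[1]]
            )
        )
        return "\n".join(lines)


def pca(table: pd.DataFrame, traits: list[str], n_components: int | None = None) -> PCAResult:
    """PCA of z-standardized traits via the correlation-matrix eigenproblem.

    Rows with missing values in the selected traits are excluded with a
    warning (unreplicated accessions lacking physiological measurements).
    The sign of each component is fixed so its largest-|loading| trait loads
    positively.
    """
    sub = table[traits]
    excluded = list(sub.index[sub.isna().any(axis=1)])
    if excluded:
        logger.warning("excluding rows with missing traits from PCA: %s", excluded)
    sub = sub.dropna()
    p = len(traits)
    if len(sub) < p + 1:
        raise ValueError(f"need at least {p + 1} complete rows for {p} traits")
    z = (sub - sub.mean()) / sub.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: dominant trait of each component loads positive
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    m = n_components or p
    names = [f"PC{k + 1}" for k in range(m)]
    loadings = pd.DataFrame(eigvec[:, :m], index=traits, columns=names)
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec[:, :m], index=sub.index, columns=names
    )
    cumvar = 100.0 * np.cumsum(eigval) / p
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigval,
        cumulative_variance=cumvar,
        scores=scores,
        excluded=excluded,
    )


def ward_cluster(scores: pd.DataFrame, k: int):
    """Ward hierarchical clustering of PC scores cut at k groups.

    Returns (labels Series, merge heights array).
    """
    x = np.asarray(scores, dtype=float)
    if k > len(x):
        raise ValueError(f"k={k} exceeds number of rows {len(x)}")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    index = scores.index if isinstance(scores, pd.DataFrame) else None
    return pd.Series(labels, index=index, name="cluster"), z[:, 2]


def regress_on_pcs(ty, scores: pd.DataFrame):
    """OLS of tuber yield on retained principal-component scores.

    With centered orthogonal regressors the intercept is mean(ty) and each
    slope is cov(ty, PCk)/var(PCk).  Returns the fitted statsmodels results.
    """
    y = np.asarray(ty, dtype=float)
    x = sm.add_constant(np.asarray(scores, dtype=float))
    if x.shape[1] > len(y):
        raise ValueError("more regressors than observations")
    names = ["const"] + (
        list(scores.columns)
        if isinstance(scores, pd.DataFrame)
        else [f"PC{i+1}" for i in range(x.shape[1] - 1)]
    )
    res = sm.OLS(y, pd.DataFrame(x, columns=names)).fit()
    return res
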