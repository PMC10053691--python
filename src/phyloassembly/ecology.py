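"""Downstream ecology of clades under homogeneous selection (HoS).

Per-sample contributions of HoS taxa to richness and relative
abundance, group comparisons (glacier-fed vs tributary streams), linear
models of those contributions against sediment chlorophyll a,
genus-level Spearman correlations with chlorophyll a, and the
upstream/downstream chronosequence environmental comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hos_contribution(rel: pd.DataFrame, hos_asvs: set) -> pd.DataFrame:
    """Per-sample fraction of observed taxa, and of relative abundance,
    belonging to any HoS clade.  Empty samples get missing values."""
    pres = rel > 0
    hos_cols = [c for c in rel.columns if c in hos_asvs]
    richness = pres.sum(axis=1)
    hos_richness = pres[hos_cols].sum(axis=1)
    totals = rel.sum(axis=1)
    hos_abund = rel[hos_cols].sum(axis=1)
    out = pd.DataFrame(
        {
            "richness_fraction": hos_richness / richness.replace(0, np.nan),
            "abundance_fraction": hos_abund / totals.replace(0, np.nan),
        }
    )
    out.index.name = "sample_id"
    return out


def group_comparison(
    values: pd.Series, groups: pd.Series, test: str = "welch"
) -> dict:
    """Two-group comparison (Welch t by default, Wilcoxon rank-sum as
    option or fallback under degenerate variance)."""
    groups = groups.reindex(values.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    x = values[groups == levels[0]].dropna().to_numpy()
    y = values[groups == levels[1]].dropna().to_numpy()
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if test not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    used = test
    if test == "welch" and np.var(x) == 0 and np.var(y) == 0:
        logger.warning("degenerate variance; falling back to Wilcoxon")
        used = "wilcoxon"
    if used == "welch":
        stat, p = stats.ttest_ind(x, y, equal_var=False)
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "group_a": levels[0],
        "group_b": levels[1],
        "mean_a": float(np.mean(x)),
        "sd_a": float(np.std(x, ddof=1)),
        "mean_b": float(np.mean(y)),
        "sd_b": float(np.std(y, ddof=1)),
        "n_a": int(x.size),
        "n_b": int(y.size),
        "statistic": float(stat),
        "p_value": float(p),
        "test": used,
        "direction": levels[0] if np.mean(x) > np.mean(y) else levels[1],
    }


def chla_model(y: pd.Series, chla: pd.Series) -> dict:
    """OLS of a HoS contribution on chlorophyll a for one floodplain."""
    df = pd.DataFrame({"y": y, "x": chla.reindex(y.index)}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete (chla, y) observations")
    if df["x"].nunique() == 1:
        raise ValueError("chlorophyll a is constant; slope undefined")
    if df["y"].nunique() == 1:
        raise ValueError("response is constant; model degenerate")
    X = sm.add_constant(df["x"].to_numpy())
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p_value": float(fit.pvalues[1]),
        "r2_adj": float(fit.rsquared_adj),
        "n": int(len(df)),
    }


def chla_models(
    contributions: pd.DataFrame,
    chla: pd.Series,
    floodplain: pd.Series,
) -> pd.DataFrame:
    """Per-floodplain OLS of richness and abundance fractions on
    chlorophyll a."""
    rows = []
    for fp, idx in contributions.groupby(floodplain.reindex(contributions.index)).groups.items():
        for response in ("richness_fraction", "abundance_fraction"):
            try:
                res = chla_model(contributions.loc[idx, response], chla)
            except ValueError as exc:
                logger.warning("chla model skipped for %s/%s: %s", fp, response, exc)
                continue
            rows.append({"floodplain": fp, "response": response, **res})
    return pd.DataFrame(
        rows,
        columns=[
            "floodplain", "response", "slope", "intercept",
            "p_value", "r2_adj", "n",
        ],
    )


def genus_heatmap_stats(
    rel: pd.DataFrame,
    taxonomy: pd.DataFrame,
    hos_asvs: set,
    chla: pd.Series,
    top_n: int = 30,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genus-level abundances of HoS taxa versus chlorophyll a.

    HoS ASVs are aggregated at the genus rank (taxa without a genus are
    dropped and counted), samples are ordered by ascending chlorophyll
    a, and the ``top_n`` genera by mean relative abundance are kept.
    Returns (per-genus Spearman correlations with BH-adjusted p-values,
    genus x ordered-sample abundance matrix).
    """
    hos_cols = [c for c in rel.columns if c in hos_asvs]
    genus = taxonomy["genus"].reindex(hos_cols)
    dropped = int(genus.isna().sum() + (genus == "").sum())
    if dropped:
        logger.info("genus aggregation dropped %d HoS ASVs without genus", dropped)
    genus = genus.dropna()
    genus = genus[genus != ""]
    if genus.empty:
        logger.warning("no genus-level taxonomy for any HoS ASV")
        return (
            pd.DataFrame(columns=["genus", "rho", "p_raw", "p_adjusted", "significant"]),
            pd.DataFrame(),
        )
    agg = rel[genus.index].T.groupby(genus).sum().T  # samples x genera
    chla = chla.reindex(agg.index)
    order = chla.dropna().sort_values().index
    agg = agg.loc[order]
    top = agg.mean(axis=0).sort_values(ascending=False).index[:top_n]
    agg = agg[top]
    rows = []
    for g in top:
        vals = agg[g]
        if vals.nunique() <= 1:
            rows.append({"genus": g, "rho": np.nan, "p_raw": np.nan})
            continue
        rho, p = stats.spearmanr(chla.loc[order], vals)
        rows.append({"genus": g, "rho": float(rho), "p_raw": float(p)})
    corr = pd.DataFrame(rows, columns=["genus", "rho", "p_raw"])
    ok = corr["p_raw"].notna()
    corr["p_adjusted"] = np.nan
    if ok.any():
        corr.loc[ok, "p_adjusted"] = multipletests(
            corr.loc[ok, "p_raw"], method="fdr_bh"
        )[1]
    corr["significant"] = corr["p_adjusted"] < fdr
    matrix = agg.T
    matrix.index.name = "genus"
    return corr, matrix


def compare_environment(
    metadata: pd.DataFrame,
    variables: list[str],
    group_col: str = "region",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Nonparametric (Mann-Whitney) per-variable comparison between two
    regions, BH-corrected across variables."""
    levels = sorted(metadata[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 levels of {group_col}, got {levels}")
    rows = []
    for var in variables:
        x = metadata.loc[metadata[group_col] == levels[0], var].dropna()
        y = metadata.loc[metadata[group_col] == levels[1], var].dropna()
        if len(x) < 2 or len(y) < 2:
            logger.warning("variable %s skipped (insufficient data)", var)
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "variable": var,
                "statistic": float(stat),
                "p_raw": float(p),
                "median_a": float(x.median()),
                "median_b": float(y.median()),
            }
        )
    df = pd.DataFrame(
        rows, columns=["variable", "statistic", "p_raw", "median_a", "median_b"]
    )
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < fdr
    return df
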