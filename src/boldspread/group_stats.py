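"""Aggregation and group-level statistics for peak and spread measures.

Covers four analyses that sit on top of the per-run measures:

* :func:`aggregate` — run -> condition -> ROI -> network averaging into tidy
  ROI-level and network-level measure tables;
* :func:`group_compare` — covariate-adjusted (ANCOVA-style) linear-model group
  comparison of any measure, with adjusted group means;
* :func:`age_regression` — multiple regression of the age criterion on
  standardized peak and spread entered simultaneously, to ask what each
  measure explains beyond the other;
* :func:`shared_variance` — the intra/inter-class independence analysis:
  average shared variance (Pearson r²) between spread measures in different
  regions of a network (SS), between peak measures in different regions (PP),
  between spread in one region and peak in different regions (SP-all), and
  between spread and peak from the same region (SP-same).  If peak and spread
  carry independent information, SS and PP stay high while SP-same falls to
  the SP-all baseline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate",
    "group_compare",
    "age_regression",
    "shared_variance",
    "shared_variance_matrices",
    "SharedVarianceSummary",
]


def aggregate(
    records: pd.DataFrame,
    covariate_cols: tuple[str, ...] = (),
) -> dict[str, pd.DataFrame]:
    """Average a long measure table up the run -> condition -> ROI -> network hierarchy.

    ``records`` needs columns ``subject_id, group, network, roi_label,
    measure, value`` and may carry ``run_id`` and ``condition`` plus covariate
    columns (constant within subject).  Non-finite values are excluded (and
    logged) before averaging.  Returns ``{"roi": ..., "network": ...}`` tidy
    tables with one row per subject x (roi|network) x measure.
    """
    required = {"subject_id", "group", "network", "roi_label", "measure", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    bad = ~np.isfinite(df["value"].to_numpy(dtype=float))
    if bad.any():
        logger.warning("aggregate: excluding %d non-finite measure value(s)", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no finite measure values to aggregate")

    id_cols = ["subject_id", "group", *covariate_cols]
    keys = [*id_cols, "network", "roi_label", "measure"]
    # run level -> condition level
    if "run_id" in df.columns:
        level = [*keys] + (["condition"] if "condition" in df.columns else [])
        df = df.groupby(level, as_index=False)["value"].mean()
    # condition level -> ROI level
    if "condition" in df.columns:
        df = df.groupby(keys, as_index=False)["value"].mean()
    roi_table = df[[*keys, "value"]].copy()
    network_table = roi_table.groupby(
        [*id_cols, "network", "measure"], as_index=False
    )["value"].mean()
    return {"roi": roi_table, "network": network_table}


def _numeric_covariates(df: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code non-numeric covariates so adjusted means are straightforward."""
    out = df.copy()
    names: list[str] = []
    for cov in covariates:
        if cov not in out.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        if pd.api.types.is_numeric_dtype(out[cov]):
            names.append(cov)
        else:
            dummies = pd.get_dummies(out[cov], prefix=cov, drop_first=True, dtype=float)
            out = pd.concat([out, dummies], axis=1)
            names.extend(dummies.columns)
    return out, names


def group_compare(
    table: pd.DataFrame,
    measure: str,
    covariates: tuple[str, ...] = (),
    group_col: str = "group",
) -> pd.DataFrame:
    """Covariate-adjusted group comparison of one measure, per network.

    Fits ``value ~ C(group) + covariates`` by OLS for each network and
    reports the group-effect F and p (type-II ANOVA) together with adjusted
    group means (covariates held at their sample means).  With no covariates
    this reproduces the one-way ANOVA F exactly.
    """
    df = table[table["measure"] == measure]
    if df.empty:
        raise ValueError(f"measure {measure!r} not present in table")
    rows = []
    for network, sub in df.groupby("network", sort=True):
        sub, cov_names = _numeric_covariates(sub, covariates)
        groups = sorted(sub[group_col].unique())
        if len(groups) < 2:
            raise ValueError(f"network {network!r}: need >= 2 groups")
        counts = sub[group_col].value_counts()
        if (counts < 3).any():
            raise ValueError(f"network {network!r}: every group needs n >= 3, got {dict(counts)}")
        formula = f"value ~ C({group_col})"
        for cov in cov_names:
            formula += f" + Q('{cov}')"
        fit = smf.ols(formula, data=sub).fit()
        table_anova = anova_lm(fit, typ=2)
        f_stat = float(table_anova.loc[f"C({group_col})", "F"])
        p_value = float(table_anova.loc[f"C({group_col})", "PR(>F)"])
        at_means = {cov: sub[cov].mean() for cov in cov_names}
        adjusted = {
            g: float(fit.predict(pd.DataFrame([{group_col: g, **at_means}])).iloc[0])
            for g in groups
        }
        rows.append(
            {
                "network": network,
                "measure": measure,
                "F": f_stat,
                "p": p_value,
                "df_num": float(table_anova.loc[f"C({group_col})", "df"]),
                "df_den": float(table_anova.loc["Residual", "df"]),
                **{f"adj_mean_{g}": v for g, v in adjusted.items()},
            }
        )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


def age_regression(
    table: pd.DataFrame,
    peak_measure: str = "peak_3mm",
    spread_measure: str = "spread_slope",
    criterion: str = "group",
) -> pd.DataFrame:
    """Regress the age criterion on standardized peak + spread simultaneously.

    ``table`` is a network-level measure table.  The criterion is either a
    numeric column (e.g. age in years) or a two-level group column, coded 0/1.
    Both predictors and the criterion are z-scored, so the reported betas are
    standardized coefficients; ``R`` is the multiple correlation.  A
    zero-variance predictor is dropped from the model and reported with
    beta 0 (flagged in the ``constant_predictors`` column).
    """
    wide = table.pivot_table(
        index=["subject_id", "group"]
        + ([criterion] if criterion in table.columns and criterion != "group" else []),
        columns="measure",
        values="value",
    ).reset_index()
    for m in (peak_measure, spread_measure):
        if m not in wide.columns:
            raise ValueError(f"measure {m!r} not present in table")

    rows = []
    networks = table["network"].unique()
    for network in sorted(networks):
        sub = table[table["network"] == network]
        w = sub.pivot_table(index=["subject_id", "group"], columns="measure", values="value")
        w = w.reset_index()
        if criterion == "group":
            levels = sorted(w["group"].unique())
            if len(levels) != 2:
                raise ValueError(f"criterion 'group' needs exactly 2 levels, got {levels}")
            y = (w["group"] == levels[1]).to_numpy(dtype=float)
        else:
            crit = table[["subject_id", criterion]].drop_duplicates("subject_id")
            y = w.merge(crit, on="subject_id")[criterion].to_numpy(dtype=float)
        if y.std(ddof=1) == 0:
            raise ValueError("criterion has zero variance")
        y = _zscore(y)

        predictors, constant = {}, []
        for name, m in (("peak", peak_measure), ("spread", spread_measure)):
            x = w[m].to_numpy(dtype=float)
            if x.std(ddof=1) == 0:
                constant.append(name)
            else:
                predictors[name] = _zscore(x)
        if not predictors:
            raise ValueError("both predictors are constant")
        X = sm.add_constant(pd.DataFrame(predictors))
        fit = sm.OLS(y, X).fit()
        row = {
            "network": network,
            "R": float(np.sqrt(max(fit.rsquared, 0.0))),
            "R2": float(fit.rsquared),
            "p_model": float(fit.f_pvalue),
            "n": int(len(y)),
            "constant_predictors": ",".join(constant),
        }
        for name in ("peak", "spread"):
            if name in predictors:
                row[f"beta_{name}"] = float(fit.params[name])
                row[f"p_{name}"] = float(fit.pvalues[name])
            else:
                row[f"beta_{name}"] = 0.0
                row[f"p_{name}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SharedVarianceSummary:
    """Per-network and overall SS / PP / SP-all / SP-same mean shared variances."""

    table: pd.DataFrame  # network, SS, PP, SP_all, SP_same, p_ss_vs_sp_same, p_pp_vs_sp_same


def shared_variance_matrices(
    spread: pd.DataFrame,
    peak: pd.DataFrame,
) -> dict[str, float]:
    """SS/PP/SP-all/SP-same from aligned subjects x regions matrices.

    ``spread`` and ``peak`` must share index (subjects) and columns (regions).
    SS and PP average r² over distinct region pairs of the same measure;
    SP_all averages r²(spread_i, peak_j) over all ordered pairs i != j;
    SP_same averages r²(spread_i, peak_i) over regions.  Raises on
    zero-variance regions or fewer than 4 subjects / 2 regions.
    """
    if list(spread.columns) != list(peak.columns):
        raise ValueError("spread and peak matrices must share region columns")
    if not spread.index.equals(peak.index):
        raise ValueError("spread and peak matrices must share subject index")
    n, m = spread.shape
    if n < 4:
        raise ValueError(f"need >= 4 subjects, got {n}")
    if m < 2:
        raise ValueError(f"need >= 2 regions per network, got {m}")
    S = spread.to_numpy(dtype=float)
    P = peak.to_numpy(dtype=float)
    for name, M in (("spread", S), ("peak", P)):
        sds = M.std(axis=0, ddof=1)
        if np.any(sds == 0):
            zero = [spread.columns[i] for i in np.where(sds == 0)[0]]
            raise ValueError(f"zero-variance {name} measure in region(s) {zero}")
    C = np.corrcoef(np.hstack([S, P]), rowvar=False)  # (2m, 2m)
    r2 = C**2
    pairs = list(itertools.combinations(range(m), 2))
    ss = float(np.mean([r2[i, j] for i, j in pairs]))
    pp = float(np.mean([r2[m + i, m + j] for i, j in pairs]))
    sp_all = float(np.mean([r2[i, m + j] for i in range(m) for j in range(m) if i != j]))
    sp_same = float(np.mean([r2[i, m + i] for i in range(m)]))
    return {"SS": ss, "PP": pp, "SP_all": sp_all, "SP_same": sp_same}


def _exchange_pvalues(
    S: np.ndarray, P: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Permutation p-values for SS > SP_same and PP > SP_same.

    Null: within each region, the 'spread'/'peak' measure-type labels are
    exchangeable (columns z-scored first, since correlations ignore scale).
    Each permutation flips the two labels independently per region and
    recomputes the mean within-measure shared variances from the precomputed
    combined correlation matrix.
    """
    n, m = S.shape
    Z = np.hstack([(S - S.mean(0)) / S.std(0, ddof=1), (P - P.mean(0)) / P.std(0, ddof=1)])
    C2 = np.corrcoef(Z, rowvar=False) ** 2
    pairs = np.array(list(itertools.combinations(range(m), 2)))
    sp_same = float(np.mean([C2[i, m + i] for i in range(m)]))
    ss_obs = float(np.mean(C2[pairs[:, 0], pairs[:, 1]]))
    pp_obs = float(np.mean(C2[m + pairs[:, 0], m + pairs[:, 1]]))

    ge_ss = ge_pp = 0
    for _ in range(n_permutations):
        flip = rng.integers(0, 2, size=m).astype(bool)
        s_idx = np.where(flip, np.arange(m) + m, np.arange(m))
        p_idx = np.where(flip, np.arange(m), np.arange(m) + m)
        ss_b = float(np.mean(C2[s_idx[pairs[:, 0]], s_idx[pairs[:, 1]]]))
        pp_b = float(np.mean(C2[p_idx[pairs[:, 0]], p_idx[pairs[:, 1]]]))
        # sp_same is invariant under within-region label flips
        ge_ss += (ss_b - sp_same) >= (ss_obs - sp_same)
        ge_pp += (pp_b - sp_same) >= (pp_obs - sp_same)
    p_ss = (1 + ge_ss) / (n_permutations + 1)
    p_pp = (1 + ge_pp) / (n_permutations + 1)
    return float(p_ss), float(p_pp)


def shared_variance(
    table: pd.DataFrame,
    spread_measure: str = "spread_slope",
    peak_measure: str = "peak_3mm",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> SharedVarianceSummary:
    """Independence analysis of peak and spread from an ROI-level measure table.

    For each network, builds subjects x regions matrices of the two measures
    and computes the four mean shared variances, plus permutation p-values
    (measure-type labels exchanged within region) for the planned contrasts
    SS vs SP-same and PP vs SP-same.  An ``all`` row averages the shared
    variances over networks with equal weight (its p-values are not defined
    and reported as NaN).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for network, sub in table.groupby("network", sort=True):
        spread_m = sub[sub["measure"] == spread_measure].pivot(
            index="subject_id", columns="roi_label", values="value"
        )
        peak_m = sub[sub["measure"] == peak_measure].pivot(
            index="subject_id", columns="roi_label", values="value"
        )
        spread_m = spread_m.dropna()
        peak_m = peak_m.loc[spread_m.index].dropna()
        spread_m = spread_m.loc[peak_m.index]
        values = shared_variance_matrices(spread_m, peak_m)
        p_ss, p_pp = _exchange_pvalues(
            spread_m.to_numpy(float), peak_m.to_numpy(float), n_permutations, rng
        )
        rows.append(
            {"network": network, **values, "p_ss_vs_sp_same": p_ss, "p_pp_vs_sp_same": p_pp}
        )
    out = pd.DataFrame(rows)
    overall = {
        "network": "all",
        **{k: float(out[k].mean()) for k in ("SS", "PP", "SP_all", "SP_same")},
        "p_ss_vs_sp_same": float("nan"),
        "p_pp_vs_sp_same": float("nan"),
    }
    out = pd.concat([out, pd.DataFrame([overall])], ignore_index=True)
    return SharedVarianceSummary(table=out)
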