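"""Statistical layer: group tests, BH correction, volcano and heatmap values.

Conventions, all config-switchable where noted:

* pairwise group comparisons use the equal-variance (Student) two-sample t;
  stimulation responses are tested with a one-sample t on the per-animal
  stimulated − unstimulated differences (equivalent to a paired t on the
  matched aliquots);
* multi-group comparisons use one-way ANOVA (for two groups, F = t²);
* Benjamini–Hochberg adjustment is applied within declared families — all
  populations × comparisons within a tissue for frequencies, the selected
  features within a (tissue, stimulation) for signaling ANOVAs, and
  features × one outcome within a tissue for outcome correlations;
* volcano classification uses the *uncorrected* t-test p-value with the
  thresholds p < 0.05 and |mean arcsinh change| > 0.1;
* feature selection takes the top fraction by combined rank (ascending
  p-value rank plus descending |change| rank) within each
  (tissue, stimulation);
* heatmap Z-scores are (group mean − grand mean of all animal values) in
  units of the population-convention SD of all animal values;
* undefined statistics (zero variance, missing values) are flagged and
  excluded from the BH family size m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    estimate: float
    statistic: float
    p_raw: float
    p_adj: float = math.nan
    family: str | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def two_group_ttest(x, y, paired: bool = False) -> StatResult:
    """Two-sided Student t-test; estimate is mean(x) − mean(y).

    Unpaired tests pool variance (equal-variance Student t); paired tests
    reduce to a one-sample t on the differences.  Zero within-group variance
    with zero mean difference yields t = 0, p = 1, flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("paired test needs >= 2 matched pairs")
        d = x - y
        est = float(d.mean())
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(est, 0.0):
                return StatResult(est, 0.0, 1.0, degenerate=True)
            return StatResult(est, math.inf, 0.0, degenerate=True)
        t, p = sps.ttest_1samp(d, 0.0)
        return StatResult(est, float(t), float(p))
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    est = float(x.mean() - y.mean())
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        if np.allclose(est, 0.0):
            return StatResult(est, 0.0, 1.0, degenerate=True)
        return StatResult(est, math.inf, 0.0, degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return StatResult(est, float(t), float(p))


def one_sample_ttest(x, popmean: float = 0.0) -> StatResult:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return StatResult(math.nan, math.nan, math.nan, degenerate=True)
    est = float(x.mean() - popmean)
    if np.allclose(x.std(ddof=1), 0.0):
        if np.allclose(est, 0.0):
            return StatResult(est, 0.0, 1.0, degenerate=True)
        return StatResult(est, math.inf, 0.0, degenerate=True)
    t, p = sps.ttest_1samp(x, popmean)
    return StatResult(est, float(t), float(p))


def anova_oneway(groups: list) -> StatResult:
    """One-way fixed-effects ANOVA; estimate is the F statistic."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrs)
    if np.allclose(pooled.std(ddof=0), 0.0):
        return StatResult(0.0, 0.0, 1.0, degenerate=True)
    f, p = sps.f_oneway(*arrs)
    return StatResult(float(f), float(f), float(p))


def pearson(x, y) -> StatResult:
    """Pearson correlation; degenerate (NaN) when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return StatResult(math.nan, math.nan, math.nan, degenerate=True)
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        return StatResult(math.nan, math.nan, math.nan, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return StatResult(float(r), float(r), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity enforcement.

    NaN entries are excluded from the family size m and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, math.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(q)
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# volcano and feature selection
# ---------------------------------------------------------------------------

def volcano_classify(mean_diff: float, p_raw: float,
                     p_cutoff: float = 0.05, diff_cutoff: float = 0.1) -> str:
    """'up' / 'down' / 'ns' using the uncorrected p-value."""
    if math.isnan(mean_diff) or math.isnan(p_raw):
        return "ns"
    if p_raw < p_cutoff and mean_diff > diff_cutoff:
        return "up"
    if p_raw < p_cutoff and mean_diff < -diff_cutoff:
        return "down"
    return "ns"


def rank_top_features(features: pd.DataFrame, fraction: float = 0.2,
                      p_col: str = "p_raw", change_col: str = "abs_change",
                      id_col: str = "feature_id") -> pd.DataFrame:
    """Select the top ``fraction`` of features by combined rank.

    Ranks ascend with p-value and descend with |change|; the combined rank
    is their sum and the ⌈fraction·N⌉ smallest are selected.  Ties break
    deterministically by larger |change|, then lexicographic feature id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = features.copy()
    n = len(df)
    if n == 0:
        df["combined_rank"] = []
        df["selected"] = []
        return df
    rank_p = df[p_col].rank(method="min", ascending=True)
    rank_m = df[change_col].rank(method="min", ascending=False)
    df["combined_rank"] = rank_p + rank_m
    k = math.ceil(fraction * n)
    order = df.sort_values(
        ["combined_rank", change_col, id_col],
        ascending=[True, False, True], kind="stable")
    selected_ids = set(order[id_col].iloc[:k])
    df["selected"] = df[id_col].isin(selected_ids)
    return df


# ---------------------------------------------------------------------------
# heatmap values
# ---------------------------------------------------------------------------

def group_zscores(values_by_group: dict, population_sd: bool = True) -> dict:
    """Per-group Z: (group mean − grand mean) / SD of all animal values.

    The grand mean and SD pool every animal-level value; SD uses the
    population convention (ddof=0) by default.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float)
                             for v in values_by_group.values()])
    pooled = pooled[~np.isnan(pooled)]
    sd = pooled.std(ddof=0 if population_sd else 1)
    if sd == 0 or np.isnan(sd):
        return {g: math.nan for g in values_by_group}
    grand = pooled.mean()
    out = {}
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        out[g] = float((v.mean() - grand) / sd) if v.size else math.nan
    return out


def log2_vs_mock(group_mean: float, mock_mean: float) -> float:
    """log2 of a vaccine group's mean relative to mock; NaN if undefined."""
    if not (group_mean > 0 and mock_mean > 0):
        return math.nan
    return float(np.log2(group_mean / mock_mean))


# ---------------------------------------------------------------------------
# table-level pipelines
# ---------------------------------------------------------------------------

def group_vs_mock_tests(freq_table: pd.DataFrame, mock: str = "mock",
                        value_col: str = "frequency") -> pd.DataFrame:
    """Each vaccine group vs mock, per (tissue, population); BH per tissue.

    Frequencies are taken from the unstimulated condition when a ``stim``
    column is present.
    """
    df = freq_table
    if "stim" in df.columns:
        df = df[df["stim"] == "UNSTIM"]
    groups = [g for g in df["group"].unique() if g != mock]
    rows = []
    for (tissue, pop), sub in df.groupby(["tissue", "population"]):
        mock_vals = sub.loc[sub["group"] == mock, value_col].to_numpy()
        for g in groups:
            vals = sub.loc[sub["group"] == g, value_col].to_numpy()
            if len(vals) < 2 or len(mock_vals) < 2:
                continue
            res = two_group_ttest(vals, mock_vals)
            rows.append({
                "tissue": tissue, "population": pop, "comparison": g,
                "estimate": res.estimate, "t": res.statistic,
                "p_raw": res.p_raw, "degenerate": res.degenerate,
                "family": f"freq:{tissue}",
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = math.nan
        for fam, idx in out.groupby("family").groups.items():
            out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p_raw"])
    return out


def stim_response_tests(responses: pd.DataFrame,
                        p_cutoff: float = 0.05, diff_cutoff: float = 0.1
                        ) -> pd.DataFrame:
    """Per-feature paired stimulation test pooled over groups, plus volcano.

    A feature is (tissue, stim, population, marker); the test is a
    one-sample t across animals on the per-animal responses (equivalent to
    pairing each animal's stimulated and unstimulated aliquots).
    """
    rows = []
    keys = ["tissue", "stim", "population", "marker"]
    for key, sub in responses.groupby(keys):
        vals = sub["response"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            continue
        res = one_sample_ttest(vals)
        rows.append({
            **dict(zip(keys, key)),
            "feature_id": "|".join(str(k) for k in key),
            "mean_change": res.estimate, "abs_change": abs(res.estimate),
            "t": res.statistic, "p_raw": res.p_raw,
            "n_animals": len(vals), "degenerate": res.degenerate,
            "direction": volcano_classify(res.estimate, res.p_raw,
                                          p_cutoff, diff_cutoff),
        })
    return pd.DataFrame(rows)


def select_top_features(volcano: pd.DataFrame, fraction: float = 0.2
                        ) -> pd.DataFrame:
    """Combined-rank top-fraction selection within each (tissue, stim)."""
    parts = []
    for _, sub in volcano.groupby(["tissue", "stim"]):
        parts.append(rank_top_features(sub, fraction))
    return pd.concat(parts, ignore_index=True) if parts else volcano.copy()


def anova_group_differences(responses: pd.DataFrame, selected: pd.DataFrame
                            ) -> pd.DataFrame:
    """ANOVA across vaccine groups for the selected features; BH per
    (tissue, stim)."""
    sel = selected[selected["selected"]] if "selected" in selected else selected
    rows = []
    keys = ["tissue", "stim", "population", "marker"]
    for _, feat in sel.iterrows():
        sub = responses
        for k in keys:
            sub = sub[sub[k] == feat[k]]
        by_group = [g["response"].dropna().to_numpy()
                    for _, g in sub.groupby("group")]
        by_group = [g for g in by_group if len(g) >= 2]
        if len(by_group) < 2:
            continue
        res = anova_oneway(by_group)
        rows.append({
            **{k: feat[k] for k in keys},
            "feature_id": feat["feature_id"],
            "F": res.statistic, "p_raw": res.p_raw,
            "degenerate": res.degenerate,
            "family": f"anova:{feat['tissue']}:{feat['stim']}",
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = math.nan
        for fam, idx in out.groupby("family").groups.items():
            out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p_raw"])
    return out


def zscore_table(responses: pd.DataFrame, selected: pd.DataFrame,
                 population_sd: bool = True) -> pd.DataFrame:
    """Per-(feature, group) Z-scores for the selected features."""
    sel = selected[selected["selected"]] if "selected" in selected else selected
    rows = []
    keys = ["tissue", "stim", "population", "marker"]
    for _, feat in sel.iterrows():
        sub = responses
        for k in keys:
            sub = sub[sub[k] == feat[k]]
        by_group = {g: grp["response"].dropna().to_numpy()
                    for g, grp in sub.groupby("group")}
        z = group_zscores(by_group, population_sd)
        for g, v in z.items():
            rows.append({**{k: feat[k] for k in keys},
                         "feature_id": feat["feature_id"],
                         "group": g, "zscore": v})
    return pd.DataFrame(rows)


def log2_ratio_table(freq_table: pd.DataFrame, mock: str = "mock"
                     ) -> pd.DataFrame:
    """log2(group mean frequency / mock mean) per (tissue, population, group).

    The mock column is identically zero by definition.
    """
    df = freq_table
    if "stim" in df.columns:
        df = df[df["stim"] == "UNSTIM"]
    rows = []
    for (tissue, pop), sub in df.groupby(["tissue", "population"]):
        means = sub.groupby("group")["frequency"].mean()
        if mock not in means.index:
            continue
        for g, m in means.items():
            val = 0.0 if g == mock else log2_vs_mock(m, means[mock])
            rows.append({"tissue": tissue, "population": pop, "group": g,
                         "log2_ratio": val,
                         "undefined": math.isnan(val)})
    return pd.DataFrame(rows)


def correlate_outcomes(features: pd.DataFrame, outcomes: pd.DataFrame,
                       outcome_cols: list[str] | None = None,
                       per_group: bool = False) -> pd.DataFrame:
    """Pearson correlations between features and clinical outcomes.

    ``features`` is long-format with columns (feature_id, tissue, family,
    animal_id, value).  Correlations pool animals across groups by default;
    ``per_group=True`` additionally emits within-group coefficients.  BH is
    applied within each (tissue, outcome, family) across features; the
    ``hatch`` flag marks adjusted p > 0.05.
    """
    outcome_cols = outcome_cols or [
        c for c in outcomes.columns if c != "animal_id"]
    oc = outcomes.set_index("animal_id")
    rows = []

    def corr_rows(sub: pd.DataFrame, label: str):
        merged = sub.set_index("animal_id").join(oc, how="inner")
        for out_col in outcome_cols:
            res = pearson(merged["value"], merged[out_col])
            rows.append({
                "feature_id": sub["feature_id"].iloc[0],
                "tissue": sub["tissue"].iloc[0],
                "family": sub["family"].iloc[0],
                "outcome": out_col, "scope": label,
                "r": res.estimate, "p_raw": res.p_raw,
                "n": int((~(merged["value"].isna()
                            | merged[out_col].isna())).sum()),
                "degenerate": res.degenerate,
            })

    for _, sub in features.groupby("feature_id"):
        corr_rows(sub, "pooled")
        if per_group and "group" in sub.columns:
            for g, gsub in sub.groupby("group"):
                corr_rows(gsub, g)

    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = math.nan
        pooled = out["scope"] == "pooled"
        for (_, _, _), idx in out[pooled].groupby(
                ["tissue", "outcome", "family"]).groups.items():
            out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p_raw"])
        out["hatch"] = ~(out["p_adj"] <= 0.05)
    return out
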