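"""Precision of relative-abundance estimation for two dominant taxa.

The two fish genera dominating the study system (Salmo from the rearing
facility effluent, Coregonus likewise) give a repeated quantitative target:
the per-sample fraction S / (S + C) of Salmo reads among Salmo + Coregonus
reads, computed separately per barcode locus.  Comparing the spread of this
fraction between sampling methods measures how precisely each method estimates
relative abundance.  Estimates built on fewer than 20 reads are flagged and
omitted from inference (proportions from few observations carry high standard
error); the 12S and COI loci contribute independent estimates per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .filtering import CountMatrix
from .metrics import pool_grab_replicates

__all__ = [
    "RatioEstimate",
    "compute_fractions",
    "center_by_site",
    "variance_f_test",
    "two_way_anova",
    "time_correlations",
]


@dataclass(frozen=True)
class RatioEstimate:
    sample_id: str
    locus: str
    site: str
    method: str
    initiation_time_min: float
    s_count: int
    c_count: int
    fraction: float  # NaN when s + c == 0
    retained: bool


def compute_fractions(
    matrix: CountMatrix,
    taxon_s: str = "Salmo",
    taxon_c: str = "Coregonus",
    loci: tuple[str, ...] = ("12S", "COI"),
    min_total: int = 20,
    pool_grabs: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-locus fractions s/(s+c) with the low-count retention flag.

    Grab replicates are pooled into events first (so each estimate reflects one
    sampling occasion).  A sample with s + c = 0 yields fraction NaN and
    retained False; totals below ``min_total`` are retained=False.
    """
    if pool_grabs:
        matrix = pool_grab_replicates(matrix)
    meta = matrix.meta_for()
    tm = matrix.taxon_meta
    rows: list[RatioEstimate] = []
    for locus in loci:
        if tm is not None and "locus" in tm.columns:
            cols = tm.index[tm["locus"] == locus]
            sub = matrix.counts[[c for c in cols if c in matrix.counts.columns]]
            def _find(target: str):
                for c in sub.columns:
                    if c == target or c.startswith(target + "-") or c.split(" ")[0] == target:
                        return c
                return None

            s_col, c_col = _find(taxon_s), _find(taxon_c)
        else:
            s_col = f"{taxon_s}-{locus}" if f"{taxon_s}-{locus}" in matrix.counts.columns else None
            c_col = f"{taxon_c}-{locus}" if f"{taxon_c}-{locus}" in matrix.counts.columns else None
        if s_col is None or c_col is None:
            raise KeyError(f"taxa {taxon_s!r}/{taxon_c!r} not found at locus {locus}")
        for sample in matrix.samples:
            s = int(matrix.counts.at[sample, s_col])
            c = int(matrix.counts.at[sample, c_col])
            total = s + c
            frac = s / total if total > 0 else float("nan")
            rows.append(
                RatioEstimate(
                    sample_id=sample,
                    locus=locus,
                    site=str(meta.at[sample, "site"]),
                    method=str(meta.at[sample, "method"]),
                    initiation_time_min=float(meta.at[sample, "initiation_time_min"]),
                    s_count=s,
                    c_count=c,
                    fraction=frac,
                    retained=total >= min_total,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def center_by_site(estimates: pd.DataFrame, value_col: str = "fraction") -> pd.DataFrame:
    """Subtract each site's mean fraction, pooling loci and methods within site.

    Centering lets the two sites be pooled for method comparisons under the
    assumption that only the spread, not the level, differs by site.
    """
    df = estimates[estimates["retained"]].copy()
    if df.empty:
        raise ValueError("no retained estimates to center")
    for site, sub in df.groupby("site"):
        if sub.empty:
            raise ValueError(f"site {site} has no retained estimates")
    df["centered"] = df[value_col] - df.groupby("site")[value_col].transform("mean")
    return df


def variance_f_test(group_a, group_b) -> dict:
    """Two-sided F test of variance heterogeneity between two groups.

    F = s_a^2 / s_b^2 (sample variances, n-1 denominator) on (n_a - 1, n_b - 1)
    degrees of freedom; the two-sided p doubles the smaller tail.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return {"F": float(f), "df_a": dfa, "df_b": dfb, "p": float(p),
            "var_a": float(va), "var_b": float(vb), "n_a": len(a), "n_b": len(b)}


def two_way_anova(
    values, factor_site, factor_method, ss_type: int = 2
) -> pd.DataFrame:
    """Two-way ANOVA of values on site, method and their interaction.

    Returns a table with sum_sq, df, mean_sq, F and p rows for site, method,
    interaction, within (residual) and total.  ``ss_type`` selects Type I or
    Type II sums of squares for unbalanced data (identical when balanced).
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "site": pd.Categorical(factor_site),
         "method": pd.Categorical(factor_method)}
    )
    for name in ("site", "method"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name} needs >= 2 levels")
    cell_sizes = df.groupby(["site", "method"], observed=True).size()
    full = pd.MultiIndex.from_product([df["site"].unique(), df["method"].unique()])
    if len(cell_sizes) < len(full) or (cell_sizes == 0).any():
        raise ValueError("every site x method cell needs at least one observation")
    model = smf.ols("value ~ C(site) * C(method)", data=df).fit()
    if ss_type not in (1, 2):
        raise ValueError("ss_type must be 1 or 2")
    tab = anova_lm(model, typ=ss_type)
    tab = tab.rename(
        index={"C(site)": "site", "C(method)": "method",
               "C(site):C(method)": "interaction", "Residual": "within"}
    )
    tab = tab[["sum_sq", "df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})
    total_ss = float(((df["value"] - df["value"].mean()) ** 2).sum())
    tab.loc["total"] = [total_ss, len(df) - 1, np.nan, np.nan]
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    return tab[["sum_sq", "df", "mean_sq", "F", "p"]]


def time_correlations(
    estimates: pd.DataFrame,
    value_col: str = "fraction",
    time_col: str = "initiation_time_min",
    log_values: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of the estimate against sample initiation time,
    per site.  Constant series yield an undefined flag (NaN r) rather than an
    error; ``log_values`` correlates natural-log values (for raw counts)."""
    rows = []
    df = estimates[estimates["retained"]] if "retained" in estimates else estimates
    for site, sub in df.groupby("site"):
        y = sub[value_col].to_numpy(dtype=float)
        t = sub[time_col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(t)
        y, t = y[ok], t[ok]
        if log_values:
            y = np.log(y)
        if len(y) < 3:
            raise ValueError(f"site {site}: need >= 3 points for a correlation")
        if np.ptp(y) == 0 or np.ptp(t) == 0:
            rows.append({"site": site, "r": np.nan, "p": np.nan, "n": len(y),
                         "undefined": True})
            continue
        r, p = stats.pearsonr(y, t)
        rows.append({"site": site, "r": float(r), "p": float(p), "n": len(y),
                     "undefined": False})
    return pd.DataFrame(rows)
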