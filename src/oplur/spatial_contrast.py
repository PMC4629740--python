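"""Spatial-contrast analysis of adjusted annual averages.

Covers the descriptive comparison of site types: per-type summary
statistics, overall spatial contrast (range as a percentage of the mean),
one-way ANOVA across site types, multiplicative site-type ratios from a
log-linear model, and squared-Pearson correlation matrices between
metrics.

Site-type ratios come from OLS of ln(concentration) on site-type
indicators with urban background (UB) as the reference level, so
exp(slope) is directly the S/UB or RB/UB geometric-mean ratio; the S/RB
ratio is obtained from a refit with RB as reference to get its own
standard error.  p-values are two-sided slope t-tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import SITE_TYPES

logger = logging.getLogger(__name__)


def range_percent(values) -> float:
    """Spatial contrast: 100 * (max - min) / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("range_percent needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"nonpositive mean {mean}: not a valid concentration set")
    return float(100.0 * (v.max() - v.min()) / mean)


def _log_linear_fit(values: np.ndarray, types: np.ndarray, reference: str):
    levels = [t for t in SITE_TYPES if t in set(types) and t != reference]
    X = pd.DataFrame(
        {lvl: (types == lvl).astype(float) for lvl in levels}
    )
    res = sm.OLS(np.log(values), sm.add_constant(X, has_constant="add")).fit()
    return res, levels


def site_type_ratios(values, site_types) -> dict[str, dict[str, float]]:
    """Geometric-mean ratios between site types with slope p-values.

    Returns ``{"S/UB": {"ratio": ..., "p": ...}, "RB/UB": ..., "S/RB": ...}``
    for the contrasts whose site types are present.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(site_types)
    if (v <= 0).any():
        bad = int((v <= 0).sum())
        raise ValueError(f"{bad} nonpositive concentrations: log-ratio undefined")
    present = [st for st in SITE_TYPES if (t == st).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need >= 2 site types with >= 2 sites each")

    out: dict[str, dict[str, float]] = {}
    if "UB" in present:
        res, levels = _log_linear_fit(v, t, reference="UB")
        for lvl in levels:
            out[f"{lvl}/UB"] = {
                "ratio": float(np.exp(res.params[lvl])),
                "p": float(res.pvalues[lvl]),
            }
    if "RB" in present and "S" in present:
        res, levels = _log_linear_fit(v, t, reference="RB")
        out["S/RB"] = {
            "ratio": float(np.exp(res.params["S"])),
            "p": float(res.pvalues["S"]),
        }
    return out


def anova_site_type(values, site_types) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of annual averages across site types."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(site_types)
    groups = [v[t == st] for st in SITE_TYPES if (t == st).any()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 site types")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every site type needs at least 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def squared_pearson_matrix(columns: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise squared Pearson correlations over sites.

    Missing values are handled pairwise-complete; a cell with fewer than
    ``min_pairs`` complete pairs raises.  Zero-variance columns raise.
    The diagonal is exactly 1.
    """
    df = columns.astype(float)
    for name in df.columns:
        col = df[name].dropna()
        if len(col) >= 2 and float(np.var(col)) == 0.0:
            raise ValueError(f"column {name!r} has zero variance")
    notna = df.notna().astype(int)
    pair_counts = notna.T @ notna
    if (pair_counts.to_numpy() < min_pairs).any():
        raise ValueError(f"some column pairs have fewer than {min_pairs} complete pairs")
    r2 = df.corr(method="pearson") ** 2
    np.fill_diagonal(r2.to_numpy(), 1.0)
    return r2


def descriptives_by_type(values, site_types) -> pd.DataFrame:
    """Mean/median/quartiles/min/max of annual averages per site type."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "site_type": site_types})
    agg = df.groupby("site_type")["value"].agg(
        n="count",
        mean="mean",
        median="median",
        p25=lambda s: s.quantile(0.25),
        p75=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    )
    return agg.reindex([t for t in SITE_TYPES if t in agg.index])


def contrast_report(annual: pd.DataFrame, sites: pd.DataFrame) -> dict:
    """Full per-metric contrast report.

    ``annual`` is the tidy (site_id, metric, value) table of adjusted
    annual averages; ``sites`` carries site_id and site_type.
    """
    type_of = sites.set_index("site_id")["site_type"]
    report: dict = {}
    for metric, grp in annual.groupby("metric"):
        vals = grp["value"].to_numpy(dtype=float)
        types = type_of.reindex(grp["site_id"]).to_numpy()
        if pd.isna(types).any():
            unknown = grp["site_id"][pd.isna(types)].tolist()
            raise ValueError(f"annual averages for sites not in roster: {unknown}")
        f, p = anova_site_type(vals, types)
        pos = vals > 0
        if not pos.all():
            logger.warning(
                "%s: %d nonpositive annual average(s) excluded from log-ratio "
                "analysis", metric, int((~pos).sum()),
            )
        report[metric] = {
            "descriptives": descriptives_by_type(vals, types),
            "range_percent": range_percent(vals),
            "anova_F": f,
            "anova_p": p,
            "ratios": site_type_ratios(vals[pos], types[pos]),
        }
    return report
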