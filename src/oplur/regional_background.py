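"""Regional background estimation by inverse-distance-squared interpolation.

The regional background concentration at a site is estimated from the
adjusted annual averages measured at the regional-background (RB) sites,
weighted by inverse squared planar distance.  When the target site is
itself a regional site, it is excluded from its own donor set (leave-self-
out), so the estimate is a genuine out-of-sample background level.  The
resulting per-site estimate enters the LUR candidate pool as an ordinary
predictor with a-priori direction "+".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lur_model import PredictorMeta, PredictorTable
from .metrics import check_metric


def regional_predictor_name(metric: str) -> str:
    return f"regional_estimate_{metric}"


def idw_estimate(
    target_xy: np.ndarray,
    donor_xy: np.ndarray,
    donor_values: np.ndarray,
    power: float = 2.0,
) -> float:
    """Inverse-distance-weighted estimate sum(w_i v_i)/sum(w_i), w_i = d_i^-power.

    A coincident donor (d == 0) returns that donor's value exactly (the mean
    of all coincident donors if several), matching the exact-interpolation
    limit of IDW.
    """
    if power < 0:
        raise ValueError("IDW power must be nonnegative")
    donor_xy = np.atleast_2d(np.asarray(donor_xy, dtype=float))
    donor_values = np.asarray(donor_values, dtype=float)
    if len(donor_xy) == 0:
        raise ValueError("empty donor set for IDW interpolation")
    if len(donor_xy) != len(donor_values):
        raise ValueError("donor coordinates and values differ in length")
    d = np.sqrt(((donor_xy - np.asarray(target_xy, dtype=float)) ** 2).sum(axis=1))
    coincident = d == 0
    if coincident.any():
        return float(donor_values[coincident].mean())
    w = d ** -power
    return float((w * donor_values).sum() / w.sum())


def regional_estimates(
    sites: pd.DataFrame,
    annual: pd.DataFrame,
    metric: str,
    power: float = 2.0,
) -> pd.DataFrame:
    """Regional background estimate for every roster site.

    Parameters
    ----------
    sites : DataFrame with columns site_id, site_type, x, y.
    annual : tidy DataFrame with columns site_id, metric, value (adjusted
        annual averages); only rows at RB sites for ``metric`` are used
        as donors.
    metric : which OP metric's background to interpolate.

    Returns a DataFrame indexed by site_id with columns ``estimate`` and
    ``n_donors``.
    """
    check_metric(metric)
    regional = sites[sites["site_type"] == "RB"]
    if regional.empty:
        raise ValueError("no regional background (RB) sites available as donors")
    vals = (
        annual[annual["metric"] == metric]
        .set_index("site_id")["value"]
        .reindex(regional["site_id"])
    )
    if vals.isna().any():
        missing = vals.index[vals.isna()].tolist()
        raise ValueError(f"regional sites without annual average for {metric}: {missing}")
    donor_xy_all = regional[["x", "y"]].to_numpy(dtype=float)
    donor_vals_all = vals.to_numpy(dtype=float)
    donor_ids = regional["site_id"].to_numpy()

    rows = []
    for _, site in sites.iterrows():
        keep = donor_ids != site["site_id"]
        if not keep.any():
            raise ValueError(
                f"no donors remain for regional site {site['site_id']!r}"
            )
        est = idw_estimate(
            np.array([site["x"], site["y"]], dtype=float),
            donor_xy_all[keep],
            donor_vals_all[keep],
            power=power,
        )
        rows.append((site["site_id"], est, int(keep.sum())))
    out = pd.DataFrame(rows, columns=["site_id", "estimate", "n_donors"])
    return out.set_index("site_id")


def interpolate_at(
    points: pd.DataFrame,
    sites: pd.DataFrame,
    annual: pd.DataFrame,
    metric: str,
    power: float = 2.0,
) -> pd.Series:
    """Regional background at arbitrary receptor locations (all RB donors).

    ``points`` must have columns x, y and be indexed by receptor id.
    """
    check_metric(metric)
    regional = sites[sites["site_type"] == "RB"]
    if regional.empty:
        raise ValueError("no regional background (RB) sites available as donors")
    vals = (
        annual[annual["metric"] == metric]
        .set_index("site_id")["value"]
        .reindex(regional["site_id"])
    )
    donor_xy = regional[["x", "y"]].to_numpy(dtype=float)
    donor_vals = vals.to_numpy(dtype=float)
    est = [
        idw_estimate(np.array([row["x"], row["y"]], dtype=float), donor_xy, donor_vals, power)
        for _, row in points.iterrows()
    ]
    return pd.Series(est, index=points.index, name=regional_predictor_name(metric))


def add_regional_predictor(
    table: PredictorTable,
    sites: pd.DataFrame,
    annual: pd.DataFrame,
    metric: str,
    power: float = 2.0,
) -> PredictorTable:
    """Append the regional background estimate to a predictor table as a
    candidate with a-priori direction '+'."""
    est = regional_estimates(sites, annual, metric, power=power)["estimate"]
    name = regional_predictor_name(metric)
    meta = PredictorMeta(name=name, direction="+", buffer=None, units="metric units")
    return table.with_column(name, est, meta)
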