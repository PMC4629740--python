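"""Blank correction, reference-site temporal adjustment, annual averaging.

Raw 2-week measurements are first corrected by subtracting the assay's
mean field-blank level.  Each period value is then adjusted for temporal
variability by subtracting the contemporaneous deviation of a continuously
monitored reference site from its own annual mean:

    adjusted = value - (reference_period - reference_annual_mean)

The correction is a signed additive shift (a literal magnitude would only
ever lower values and would not center at the annual mean).  The adjusted
annual average per site and metric is the arithmetic mean of the adjusted
period values; values below the limit of detection and negative
blank-corrected values are retained, flagged, never dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_MEASUREMENT_COLS = ("site_id", "period_id", "metric", "value")
REQUIRED_REFERENCE_COLS = ("period_id", "metric", "value")


def blank_correct(value, blank_mean: float):
    """Subtract the mean field-blank level; negative results are retained."""
    if blank_mean < 0:
        raise ValueError(f"blank_mean must be >= 0, got {blank_mean}")
    return value - blank_mean


def temporal_adjust(value, reference_value: float, reference_annual_mean: float):
    """Subtract the reference site's period deviation from its annual mean."""
    return value - (reference_value - reference_annual_mean)


def reference_annual_means(reference: pd.DataFrame) -> pd.Series:
    """Annual mean of the reference series per metric (mean over its periods)."""
    _check_columns(reference, REQUIRED_REFERENCE_COLS, "reference")
    return reference.groupby("metric")["value"].mean()


def adjusted_annual_averages(
    measurements: pd.DataFrame,
    reference: pd.DataFrame,
    blank_means: dict[str, float] | None = None,
    reference_annual_means: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Adjusted annual average per site and metric.

    Parameters
    ----------
    measurements : long-format records with columns site_id, period_id,
        metric, value (and optionally below_lod).
    reference : reference-site series with columns period_id, metric, value;
        must cover every (period, metric) present in the measurements.
    blank_means : per-metric field-blank level subtracted from measurements
        and reference alike (consistent blank correction commutes with the
        adjustment).  None means already blank-corrected input.
    reference_annual_means : per-metric annual mean of the reference site,
        e.g. from its full-year continuous series.  Defaults to the mean of
        the supplied reference periods; supplying it explicitly makes the
        adjustment exactly invariant to a constant shift applied to one
        period at all sites and the reference alike.

    Returns a tidy DataFrame with columns site_id, metric, value,
    n_periods_used.
    """
    _check_columns(measurements, REQUIRED_MEASUREMENT_COLS, "measurements")
    _check_columns(reference, REQUIRED_REFERENCE_COLS, "reference")
    if measurements.empty:
        raise ValueError("measurements table is empty")
    dup = measurements.duplicated(subset=["site_id", "period_id", "metric"])
    if dup.any():
        bad = measurements.loc[dup, ["site_id", "period_id", "metric"]].head()
        raise ValueError(f"duplicate (site, period, metric) records:\n{bad}")

    meas = measurements.copy()
    ref = reference.copy()
    if blank_means is not None:
        for metric, blank in blank_means.items():
            meas.loc[meas["metric"] == metric, "value"] = blank_correct(
                meas.loc[meas["metric"] == metric, "value"], blank
            )
            ref.loc[ref["metric"] == metric, "value"] = blank_correct(
                ref.loc[ref["metric"] == metric, "value"], blank
            )

    if reference_annual_means is None:
        ref_mean = ref.groupby("metric")["value"].mean()
    else:
        ref_mean = pd.Series(dict(reference_annual_means), dtype=float)
        if blank_means is not None:
            for metric, blank in blank_means.items():
                if metric in ref_mean.index:
                    ref_mean[metric] = blank_correct(ref_mean[metric], blank)
        missing_means = set(ref["metric"]) - set(ref_mean.index)
        if missing_means:
            raise ValueError(f"reference annual means missing metrics: {missing_means}")
    ref_lookup = ref.set_index(["metric", "period_id"])["value"]

    needed = meas[["metric", "period_id"]].drop_duplicates()
    missing = [
        (m, p)
        for m, p in needed.itertuples(index=False)
        if (m, p) not in ref_lookup.index
    ]
    if missing:
        raise ValueError(f"reference series missing (metric, period) pairs: {missing}")

    corr = meas.set_index(["metric", "period_id"]).index.map(
        lambda mp: ref_lookup[mp] - ref_mean[mp[0]]
    )
    meas["adjusted"] = meas["value"].to_numpy() - np.asarray(corr, dtype=float)

    out = (
        meas.groupby(["site_id", "metric"], sort=True)["adjusted"]
        .agg(value="mean", n_periods_used="count")
        .reset_index()
    )
    out["n_periods_used"] = out["n_periods_used"].astype(int)
    return out


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks required columns: {missing}")
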