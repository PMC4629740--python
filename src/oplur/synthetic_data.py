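"""Synthetic monitoring-campaign generator.

Emulates a one-year, 40-site PM2.5 oxidative-potential campaign over a
Netherlands/Belgium-scale study region: 10 regional background (RB),
12 urban background (UB) and 18 street (S) sites, each measured in three
2-week periods, plus a centrally located reference site measured in every
period.  Two assay metrics are generated (OP_DTT, OP_ESR), each with its
own units, blank level and generating model.

Generating model
----------------
Street and urban sites cluster around 5-7 synthetic city centers; regional
sites sit in small towns in rings around the cities.  GIS-style buffer predictors (road length,
traffic load, traffic intensity x inverse distance, population density,
seminatural area, industrial area) are drawn with site-type-dependent
log-normal / beta distributions and a smooth low-order polynomial spatial
trend, producing the skew and zero-inflation typical of buffer variables.

The noiseless annual truth at every site is an exact linear model in the
candidate predictors *as the analysis pipeline sees them*:

    y_i = a + b * g_i + sum_j beta_j x_ij

where g_i is the leave-self-out inverse-distance-squared interpolation of
the regional sites' truths.  Because g depends on the regional truths
themselves, the ten regional values solve the small linear fixed-point
system y_R = (I - b W)^-1 (a + X_R beta), with W the row-stochastic IDW
weight matrix among regional sites.  The interpolated field b*g then plays
the role of the large-scale regional trend; its spatial structure comes
from polynomial-trend gradients in the regional sites' land-use predictors.
This construction guarantees that, at zero noise, the direction-constrained
regression can recover the generating slopes exactly.

Each 2-week measurement is truth + per-period temporal offset + Gaussian
noise + assay field-blank level, so blank correction and reference-site
temporal adjustment are both exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lur_model import PredictorMeta, PredictorTable
from .metrics import METRICS, METRIC_UNITS

REFERENCE_SITE_ID = "REF"

#: Default a-priori directions for the generated predictor inventory.
PREDICTOR_DEFS = (
    PredictorMeta("road_length_500m", "+", 500.0, "m"),
    PredictorMeta("road_length_100m", "+", 100.0, "m"),
    PredictorMeta("ti_invdist_major_road", "+", None, "veh/day/m"),
    PredictorMeta("traffic_load_50m", "+", 50.0, "veh*m/day"),
    PredictorMeta("population_density_5000m", "+", 5000.0, "inhabitants"),
    PredictorMeta("seminatural_1000m", "-", 1000.0, "m2"),
    PredictorMeta("industry_100m", "+", 100.0, "m2"),
)


@dataclass
class TrueModel:
    """Generating model for one metric: intercept, regional-background
    weight (slope on the leave-self-out IDW field) and raw slopes on local
    predictors."""

    intercept: float
    background_slope: float
    slopes: dict[str, float]

    def direction_of(self, name: str) -> str:
        return "+" if self.slopes[name] > 0 else "-"


def _default_true_models() -> dict[str, TrueModel]:
    # Slopes scaled so each term's P10-P90 contribution is an appreciable
    # share of the between-site contrast, mirroring a model of the form
    # regional background + one local traffic variable + one urbanity
    # variable per metric.
    return {
        "OP_DTT": TrueModel(
            intercept=1.60,
            background_slope=0.84,
            slopes={
                "road_length_500m": 8.0e-5,
                "seminatural_1000m": -6.0e-7,
            },
        ),
        "OP_ESR": TrueModel(
            intercept=3700.0,
            background_slope=0.86,
            slopes={
                "traffic_load_50m": 4.6e-4,
                "seminatural_1000m": -1.3e-3,
            },
        ),
    }


@dataclass
class CampaignConfig:
    """Study-design parameters of a synthetic campaign.

    Defaults reproduce the emulated design: 10 RB + 12 UB + 18 S sites,
    three 2-week periods (120 records per metric), field-blank levels of
    0.12 nmol DTT/m3 (OP_DTT) and 850 A.U./m3 (OP_ESR), zero-mean seasonal
    offsets, and measurement noise calibrated so that the generating model
    explains roughly 70% of the annual between-site variance.
    """

    n_regional: int = 10
    n_urban: int = 12
    n_street: int = 18
    n_periods: int = 3
    region_extent: float = 200_000.0  # meters (square study area)
    true_models: dict[str, TrueModel] = field(default_factory=_default_true_models)
    temporal_effects: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "OP_DTT": (0.15, -0.09, -0.06),
            "OP_ESR": (300.0, -180.0, -120.0),
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"OP_DTT": 0.84, "OP_ESR": 1600.0}
    )
    blank_mean: dict[str, float] = field(
        default_factory=lambda: {"OP_DTT": 0.12, "OP_ESR": 850.0}
    )
    zero_fraction_scale: float = 1.0  # scales zero-inflation of small-buffer traffic vars
    seed: int = 0
    geometry_seed: int | None = None  # split off so noise seeds reuse one geometry

    def __post_init__(self) -> None:
        for nm in ("n_regional", "n_urban", "n_street", "n_periods"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1, got {getattr(self, nm)}")
        if self.region_extent <= 0:
            raise ValueError("region_extent must be positive")
        known = {m.name for m in PREDICTOR_DEFS}
        for metric, tm in self.true_models.items():
            for nm, slope in tm.slopes.items():
                if nm not in known:
                    raise ValueError(
                        f"true model for {metric} references unknown predictor {nm!r}"
                    )
                if slope == 0:
                    raise ValueError(f"true slope for {nm!r} must be nonzero")
            if not (0 <= tm.background_slope < 1):
                raise ValueError("background_slope must lie in [0, 1)")
        for metric, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError("noise_sd must be nonnegative")
        for metric, te in self.temporal_effects.items():
            if len(te) != self.n_periods:
                raise ValueError(
                    f"temporal_effects[{metric}] must have n_periods={self.n_periods} entries"
                )

    @property
    def n_sites(self) -> int:
        return self.n_regional + self.n_urban + self.n_street

    @property
    def period_ids(self) -> list[str]:
        return [f"P{k + 1}" for k in range(self.n_periods)]


def generate_predictor_metadata(config: CampaignConfig | None = None) -> list[PredictorMeta]:
    """Predictor inventory with a-priori directions of effect.

    Traffic, urbanity and regional-background variables carry '+';
    seminatural/forested area carries '-'.  The declared directions agree
    with the signs of the generating slopes by construction.
    """
    metas = list(PREDICTOR_DEFS)
    if config is not None:
        by_name = {m.name: m for m in metas}
        for metric, tm in config.true_models.items():
            for nm, slope in tm.slopes.items():
                declared = by_name[nm].sign
                if declared != (1 if slope > 0 else -1):
                    raise ValueError(
                        f"true slope sign of {nm!r} contradicts its a-priori direction"
                    )
    return metas


@dataclass
class SyntheticCampaign:
    """A complete generated campaign plus its generating truth."""

    config: CampaignConfig
    sites: pd.DataFrame          # site_id, site_type, x, y
    predictors: PredictorTable   # roster sites only
    reference: pd.DataFrame      # period_id, metric, value (raw, incl. blank)
    measurements: pd.DataFrame   # site_id, period_id, metric, value, below_lod
    truth: dict                  # per metric: slopes, intercept, annual means, field

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.csv", index=False)
        self.measurements.to_csv(outdir / "measurements.csv", index=False)
        self.reference.to_csv(outdir / "reference.csv", index=False)
        pred = self.predictors.values.reset_index().rename(columns={"index": "site_id"})
        pred.to_csv(outdir / "predictors.csv", index=False)
        meta = [dataclasses.asdict(m) for m in self.predictors.meta.values()]
        with open(outdir / "predictor_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _generate_geometry(config: CampaignConfig, rng: np.random.Generator):
    """Site coordinates: UB/S sites clustered in 3-6 city centers, RB sites
    outside the cities, reference site near the region center."""
    ext = config.region_extent
    n_cities = int(rng.integers(5, 8))
    centers: list[np.ndarray] = []
    while len(centers) < n_cities:  # well-separated city centers
        cand = rng.uniform(0.15 * ext, 0.85 * ext, size=2)
        if all(np.linalg.norm(cand - c) > 0.18 * ext for c in centers):
            centers.append(cand)
    centers = np.array(centers)

    def _clip(xy):
        return np.clip(xy, 0.0, ext)

    # regional sites sit in small towns in a ring around the cities, so each
    # city's interpolated background is dominated by its nearby donors
    records = []
    for i in range(config.n_regional):
        c = i % n_cities
        for _ in range(200):
            r = rng.uniform(0.04 * ext, 0.18 * ext)
            th = rng.uniform(0, 2 * np.pi)
            xy = _clip(centers[c] + r * np.array([np.cos(th), np.sin(th)]))
            if np.sqrt(((centers - xy) ** 2).sum(axis=1)).min() > 0.035 * ext:
                break
        records.append((f"RB{i + 1:02d}", "RB", xy[0], xy[1], c))
    for i in range(config.n_urban):
        c = i % n_cities
        xy = _clip(centers[c] + rng.normal(0.0, 2500.0, size=2))
        records.append((f"UB{i + 1:02d}", "UB", xy[0], xy[1], c))
    for i in range(config.n_street):
        c = i % n_cities
        xy = _clip(centers[c] + rng.normal(0.0, 3500.0, size=2))
        records.append((f"S{i + 1:02d}", "S", xy[0], xy[1], c))
    sites = pd.DataFrame(records, columns=["site_id", "site_type", "x", "y", "city"])
    ref_xy = _clip(np.array([0.5 * ext, 0.5 * ext]) + rng.normal(0.0, 0.02 * ext, size=2))
    return sites, centers, ref_xy, n_cities


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def _trend(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smooth low-order polynomial surface on unit coordinates; modulates
    population density to give urbanity a mild large-scale gradient."""
    return 0.7 + 0.4 * u + 0.25 * v - 0.2 * u * v


def _generate_predictors(
    config: CampaignConfig,
    sites: pd.DataFrame,
    n_cities: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sites)
    st = sites["site_type"].to_numpy()
    city = sites["city"].to_numpy()
    u = sites["x"].to_numpy() / config.region_extent
    v = sites["y"].to_numpy() / config.region_extent
    trend = _trend(u, v)
    zf = config.zero_fraction_scale

    def lognorm(mu_by_type: dict, sigma_by_type: dict) -> np.ndarray:
        mu = np.array([mu_by_type[t] for t in st])
        sg = np.array([sigma_by_type[t] for t in st])
        return np.exp(rng.normal(mu, sg))

    def zero_mask(frac_by_type: dict) -> np.ndarray:
        p = np.clip(np.array([frac_by_type[t] for t in st]) * zf, 0.0, 1.0)
        return rng.random(n) < p

    out = pd.DataFrame(index=sites["site_id"])
    ln = np.log
    out["road_length_500m"] = lognorm(
        {"RB": ln(1500.0), "UB": ln(6000.0), "S": ln(9000.0)},
        {"RB": 0.55, "UB": 0.50, "S": 0.50},
    )
    out["road_length_100m"] = (
        out["road_length_500m"].to_numpy() * 0.18 * np.exp(rng.normal(0.0, 0.50, n))
    )
    ti = lognorm(
        {"RB": ln(50.0), "UB": ln(300.0), "S": ln(2000.0)},
        {"RB": 0.7, "UB": 0.6, "S": 0.5},
    )
    ti[zero_mask({"RB": 0.45, "UB": 0.10, "S": 0.0})] = 0.0
    out["ti_invdist_major_road"] = ti
    tl = lognorm(
        {"RB": ln(3.0e4), "UB": ln(2.0e5), "S": ln(1.5e6)},
        {"RB": 0.8, "UB": 0.75, "S": 0.75},
    )
    tl[zero_mask({"RB": 0.60, "UB": 0.15, "S": 0.0})] = 0.0
    out["traffic_load_50m"] = tl

    city_pop = np.exp(rng.normal(np.log(2.5e5), 0.4, size=n_cities))
    pop = np.where(
        st != "RB",
        city_pop[np.maximum(city, 0)] * np.exp(rng.normal(0.0, 0.30, n)),
        np.exp(rng.normal(np.log(2.0e4), 0.5, n)),
    )
    out["population_density_5000m"] = pop * trend

    # seminatural/forested share: each province (city surroundings) has its
    # own rural land-use character, shared by the regional sites in its ring
    # -- this between-province heterogeneity is what gives the interpolated
    # regional background field its contrast.  Inside cities the share is
    # low and noisy.
    province_semi = rng.uniform(0.05, 0.95, size=n_cities)
    frac = np.where(
        st == "RB",
        np.clip(province_semi[np.maximum(city, 0)] + rng.normal(0.0, 0.06, n), 0.05, 0.95),
        np.where(st == "UB", rng.beta(3.5, 9.0, n), rng.beta(2.5, 12.0, n)),
    )
    buffer_area = np.pi * 1000.0 ** 2
    out["seminatural_1000m"] = np.clip(frac, 0.0, 0.95) * buffer_area

    ind = np.exp(rng.normal(np.log(800.0), 0.8, n))
    ind[zero_mask({"RB": 0.9, "UB": 0.82, "S": 0.82})] = 0.0
    out["industry_100m"] = ind
    return out


def _reference_predictors(config: CampaignConfig, rng: np.random.Generator, ref_xy) -> pd.Series:
    """Urban-background-like predictor values for the reference site."""
    u, v = ref_xy[0] / config.region_extent, ref_xy[1] / config.region_extent
    trend = _trend(np.array([u]), np.array([v]))[0]
    ln = np.log
    return pd.Series(
        {
            "road_length_500m": float(np.exp(rng.normal(ln(6000.0), 0.35))),
            "road_length_100m": float(np.exp(rng.normal(ln(1100.0), 0.35))),
            "ti_invdist_major_road": float(np.exp(rng.normal(ln(300.0), 0.6))),
            "traffic_load_50m": float(np.exp(rng.normal(ln(2.0e5), 0.5))),
            "population_density_5000m": float(np.exp(rng.normal(ln(2.5e5), 0.3)) * trend),
            "seminatural_1000m": float(
                np.clip(rng.beta(2.5, 6.0), 0, 0.95) * np.pi * 1000.0 ** 2
            ),
            "industry_100m": 0.0,
        },
        name=REFERENCE_SITE_ID,
    )


# ---------------------------------------------------------------------------
# truth: fixed-point regional field + linear model
# ---------------------------------------------------------------------------

def _idw_weight_matrix(xy: np.ndarray) -> np.ndarray:
    """Row-stochastic inverse-distance-squared weights among regional sites,
    zero diagonal (leave-self-out)."""
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    w = 1.0 / d ** 2
    return w / w.sum(axis=1, keepdims=True)


def _compute_truth(
    config: CampaignConfig,
    sites: pd.DataFrame,
    predictors: pd.DataFrame,
    ref_xy: np.ndarray,
    ref_predictors: pd.Series,
) -> dict:
    """Noiseless annual truth per site and metric.

    Regional truths solve y_R = (I - b W)^-1 (a + X_R beta); all other
    truths (and the reference site's) are a + b * IDW(y_R) + X beta.
    """
    is_rb = (sites["site_type"] == "RB").to_numpy()
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    xy_rb = xy[is_rb]
    w_rb = _idw_weight_matrix(xy_rb)

    truth: dict = {}
    for metric, tm in config.true_models.items():
        names = list(tm.slopes)
        beta = np.array([tm.slopes[nm] for nm in names])
        locals_all = predictors[names].to_numpy(dtype=float) @ beta
        b = tm.background_slope
        y_rb = np.linalg.solve(
            np.eye(is_rb.sum()) - b * w_rb, tm.intercept + locals_all[is_rb]
        )
        # leave-self-out field at regional sites; all-donor field elsewhere
        g = np.empty(len(sites))
        g[is_rb] = w_rb @ y_rb
        other_xy = xy[~is_rb]
        d = np.sqrt(((other_xy[:, None, :] - xy_rb[None, :, :]) ** 2).sum(-1))
        d[d == 0] = 1e-9
        w = 1.0 / d ** 2
        g[~is_rb] = (w * y_rb).sum(axis=1) / w.sum(axis=1)
        y = tm.intercept + b * g + locals_all
        y[is_rb] = y_rb

        d_ref = np.sqrt(((xy_rb - ref_xy) ** 2).sum(axis=1))
        d_ref[d_ref == 0] = 1e-9
        w_ref = 1.0 / d_ref ** 2
        g_ref = float((w_ref * y_rb).sum() / w_ref.sum())
        ref_locals = float(sum(tm.slopes[nm] * ref_predictors[nm] for nm in names))
        y_ref = tm.intercept + b * g_ref + ref_locals

        te_mean = float(np.mean(config.temporal_effects[metric]))
        truth[metric] = {
            "intercept": tm.intercept,
            "background_slope": b,
            "slopes": dict(tm.slopes),
            "units": METRIC_UNITS[metric],
            "annual_mean": {
                sid: float(val + te_mean) for sid, val in zip(sites["site_id"], y)
            },
            "regional_field": {
                sid: float(val) for sid, val in zip(sites["site_id"], g)
            },
            "reference_true": float(y_ref),
        }
    return truth


# ---------------------------------------------------------------------------
# campaign assembly
# ---------------------------------------------------------------------------

def generate_campaign(config: CampaignConfig | None = None) -> SyntheticCampaign:
    """Generate a full synthetic campaign from a configuration.

    Deterministic in ``config.seed``: the master seed is split into
    geometry, predictor and noise streams, so supplying an explicit
    ``geometry_seed`` reuses one site layout across noise realizations.
    """
    if config is None:
        config = CampaignConfig()
    metas = generate_predictor_metadata(config)

    master = np.random.SeedSequence(config.seed)
    geo_ss, pred_ss, noise_ss = master.spawn(3)
    if config.geometry_seed is not None:
        geo_ss = np.random.SeedSequence(config.geometry_seed)
    rng_geo = np.random.default_rng(geo_ss)
    rng_pred = np.random.default_rng(pred_ss)
    rng_noise = np.random.default_rng(noise_ss)

    sites_full, centers, ref_xy, n_cities = _generate_geometry(config, rng_geo)
    pred_df = _generate_predictors(config, sites_full, n_cities, rng_pred)
    ref_pred = _reference_predictors(config, rng_pred, ref_xy)
    truth = _compute_truth(config, sites_full, pred_df, ref_xy, ref_pred)

    sites = sites_full[["site_id", "site_type", "x", "y"]].copy()
    table = PredictorTable(pred_df, {m.name: m for m in metas})

    meas_rows = []
    ref_rows = []
    for metric in config.true_models:
        te = config.temporal_effects[metric]
        sd = config.noise_sd[metric]
        blank = config.blank_mean[metric]
        y_true = np.array(
            [truth[metric]["annual_mean"][sid] for sid in sites["site_id"]]
        ) - float(np.mean(te))
        for p_idx, pid in enumerate(config.period_ids):
            noise = rng_noise.normal(0.0, sd, size=len(sites)) if sd > 0 else 0.0
            vals = y_true + te[p_idx] + noise + blank
            for sid, val in zip(sites["site_id"], vals):
                meas_rows.append((sid, pid, metric, float(val), False))
            ref_noise = float(rng_noise.normal(0.0, sd)) if sd > 0 else 0.0
            ref_rows.append(
                (
                    pid,
                    metric,
                    float(truth[metric]["reference_true"] + te[p_idx] + ref_noise + blank),
                )
            )
    measurements = pd.DataFrame(
        meas_rows, columns=["site_id", "period_id", "metric", "value", "below_lod"]
    )
    reference = pd.DataFrame(ref_rows, columns=["period_id", "metric", "value"])

    return SyntheticCampaign(
        config=config,
        sites=sites,
        predictors=table,
        reference=reference,
        measurements=measurements,
        truth=truth,
    )


def generate_receptors(
    config: CampaignConfig,
    n_receptors: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an independent receptor set (sites + local predictor rows)
    for model comparison at locations not used in fitting.

    Receptors are a UB/S-style mix over a fresh geometry; ids are prefixed
    ``RC`` so they can never collide with a training roster.  Returns
    (receptor sites, predictor rows).
    """
    if n_receptors < 1:
        raise ValueError("n_receptors must be >= 1")
    sub = dataclasses.replace(
        config,
        n_regional=max(2, n_receptors // 5),
        n_urban=max(1, n_receptors // 2),
        n_street=max(1, n_receptors - n_receptors // 2),
        seed=seed,
        geometry_seed=None,
    )
    camp = generate_campaign(sub)
    roster = camp.sites[camp.sites["site_type"].isin(["UB", "S"])].head(n_receptors)
    if len(roster) < n_receptors:
        roster = camp.sites.head(n_receptors)
    ids = [f"RC{k + 1:03d}" for k in range(len(roster))]
    sites = roster.copy()
    sites["site_id"] = ids
    pred = camp.predictors.values.loc[roster["site_id"]].copy()
    pred.index = ids
    return sites.reset_index(drop=True), pred
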