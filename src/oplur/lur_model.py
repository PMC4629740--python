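"""Supervised forward-selection land-use regression (LUR) with sign constraints.

Implements the ESCAPE-style model development protocol for annual-average
exposure surfaces: candidate predictors carry an a-priori direction of
effect; predictors are added greedily by adjusted-R-squared gain subject to
every coefficient in the trial fit conforming to its declared direction;
the accepted model is then pruned on p-values and variance inflation
factors, and screened for influential observations (Cook's D) and spatial
autocorrelation of the residuals (Moran's I).

The fitted model is an ordinary least-squares linear model

    y_i = b0 + sum_j b_j x_ij + e_i

over monitoring sites i, where y is the temporally adjusted annual average
of the pollutant metric and x_j are GIS-style predictor variables
(buffer road length, traffic load, population density, seminatural area,
and an interpolated regional background estimate).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTIONS = ("+", "-")


@dataclass(frozen=True)
class PredictorMeta:
    """Metadata for one candidate predictor.

    Parameters
    ----------
    name : str
        Column name in the predictor table.
    direction : {"+", "-"}
        A-priori direction of effect; a fitted slope must carry this sign
        for the predictor to stay in a model.
    buffer : float or None
        Buffer radius in meters for buffer-type GIS variables, None for
        point/derived variables (e.g. the regional background estimate).
    units : str
        Units of the raw predictor values.
    """

    name: str
    direction: str
    buffer: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction of {self.name!r} must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )

    @property
    def sign(self) -> int:
        return 1 if self.direction == "+" else -1


@dataclass
class PredictorTable:
    """Site-by-predictor matrix plus per-predictor metadata.

    ``values`` is indexed by site id with one column per predictor;
    ``meta`` maps predictor name to its :class:`PredictorMeta`.
    """

    values: pd.DataFrame
    meta: dict[str, PredictorMeta]

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate predictor columns: {dupes}")
        missing = [c for c in self.values.columns if c not in self.meta]
        if missing:
            raise ValueError(f"predictors without metadata: {missing}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing cells in predictor columns: {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def zero_counts(self) -> pd.Series:
        return (self.values == 0).sum(axis=0)

    def percentile_span(self, name: str) -> float:
        """P90 - P10 of a predictor over the table's sites (linear interpolation)."""
        col = self.values[name].to_numpy(dtype=float)
        p10, p90 = np.percentile(col, [10.0, 90.0])
        return float(p90 - p10)

    def subset_sites(self, site_ids: Sequence) -> "PredictorTable":
        return PredictorTable(self.values.loc[list(site_ids)].copy(), dict(self.meta))

    def with_column(self, name: str, values: pd.Series, meta: PredictorMeta) -> "PredictorTable":
        df = self.values.copy()
        df[name] = values.reindex(df.index)
        new_meta = dict(self.meta)
        new_meta[name] = meta
        return PredictorTable(df, new_meta)

    def drop(self, names: Iterable[str]) -> "PredictorTable":
        names = list(names)
        df = self.values.drop(columns=names)
        new_meta = {k: v for k, v in self.meta.items() if k not in names}
        return PredictorTable(df, new_meta)


@dataclass
class LurTerm:
    """One selected predictor with its raw OLS slope and entry statistics."""

    name: str
    slope: float
    se: float
    pvalue: float
    cum_adj_r2: float  # adjusted R^2 of the model at the step this term entered


@dataclass
class LurModel:
    """A fitted direction-constrained LUR model.

    ``terms`` preserves selection order; slopes are raw (per predictor
    unit).  ``std_coefficients`` holds the reporting convention used for
    model tables: raw slope times the predictor's P90 - P10 difference
    over the training sites, with standard errors scaled identically and
    the intercept left unscaled.
    """

    metric: str
    intercept: float
    intercept_se: float
    intercept_p: float
    terms: list[LurTerm]
    model_r2: float
    adjusted_r2: float
    rmse: float
    n_sites: int
    training_site_ids: list
    diagnostics: dict = field(default_factory=dict)
    std_coefficients: list[dict] = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LurModel":
        d = dict(d)
        d["terms"] = [LurTerm(**t) for t in d["terms"]]
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "LurModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# screening and elementary statistics
# ---------------------------------------------------------------------------

def default_max_zero_sites(n_sites: int) -> int:
    """Zero-inflation screening threshold: retain unless more than
    ceil(0.75 * N) sites have exact zeros (30 at the 40-site design)."""
    return math.ceil(0.75 * n_sites)


def screen_predictors(table: PredictorTable, max_zero_sites: int | None = None) -> PredictorTable:
    """Drop predictors with exact zeros at strictly more than ``max_zero_sites`` sites."""
    if max_zero_sites is None:
        max_zero_sites = default_max_zero_sites(table.n_sites)
    zc = table.zero_counts()
    dropped = [name for name in table.names if zc[name] > max_zero_sites]
    if dropped:
        logger.info("screened out zero-inflated predictors: %s", dropped)
    kept = table.drop(dropped)
    if not kept.names:
        raise ValueError("all predictors removed by zero-inflation screening")
    return kept


def adjusted_r2(r2: float, n_sites: int, n_predictors: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    dof = n_sites - n_predictors - 1
    if dof <= 0:
        raise ValueError(
            f"degenerate degrees of freedom: n={n_sites}, p={n_predictors}"
        )
    return 1.0 - (1.0 - r2) * (n_sites - 1) / dof


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X.astype(float), has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def _signs_conform(res, names: Sequence[str], meta: Mapping[str, PredictorMeta]) -> bool:
    for name in names:
        if np.sign(res.params[name]) != meta[name].sign:
            return False
    return True


# ---------------------------------------------------------------------------
# supervised forward selection
# ---------------------------------------------------------------------------

def forward_select(
    y: pd.Series,
    table: PredictorTable,
    delta: float = 0.01,
    blacklist: Iterable[str] = (),
) -> LurModel:
    """Greedy supervised selection by adjusted-R^2 gain under sign constraints.

    At each step every remaining candidate is fitted alongside the current
    terms; a candidate is eligible only if its own slope and all previously
    entered slopes keep their a-priori directions in the trial fit.  The
    eligible candidate with the highest adjusted R^2 enters if the gain over
    the current model exceeds ``delta``.  Ties (to machine precision) go to
    the larger absolute t statistic of the entrant, then lexicographic name.
    """
    blacklist = set(blacklist)
    candidates = [c for c in table.names if c not in blacklist]
    if not candidates:
        raise ValueError("empty candidate set for forward selection")
    y = y.loc[table.values.index]
    yv = y.to_numpy(dtype=float)

    selected: list[str] = []
    cum_adj: list[float] = []
    current_adj = 0.0  # intercept-only model
    while True:
        best = None  # (adj_r2, abs_t, name, results)
        for cand in candidates:
            if cand in selected:
                continue
            cols = selected + [cand]
            res = _ols(yv, table.values[cols])
            if not np.isfinite(res.params).all():
                continue
            if not _signs_conform(res, cols, table.meta):
                logger.debug("candidate %s rejected: sign violation", cand)
                continue
            adj = res.rsquared_adj
            abs_t = abs(res.tvalues[cand])
            key = (adj, abs_t, _name_rank(cand))
            if best is None or key > best[0]:
                best = (key, cand, res, adj)
        if best is None:
            logger.info("forward selection stops: no eligible candidate")
            break
        _, cand, res, adj = best
        if adj - current_adj <= delta:
            logger.info(
                "forward selection stops: best gain %.4f (candidate %s) <= %.3f",
                adj - current_adj, cand, delta,
            )
            break
        logger.info(
            "forward selection: %s enters, adjusted R^2 %.4f -> %.4f",
            cand, current_adj, adj,
        )
        selected.append(cand)
        cum_adj.append(adj)
        current_adj = adj
        if current_adj >= 1.0 - 1e-12:
            break

    return _build_model(y, table, selected, cum_adj)


def _name_rank(name: str) -> tuple:
    # lexicographically SMALLER name wins a tie; invert for max() comparison
    return tuple(-ord(ch) for ch in name)


def _build_model(
    y: pd.Series,
    table: PredictorTable,
    selected: Sequence[str],
    cum_adj: Sequence[float] | None = None,
    metric: str = "",
) -> LurModel:
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if selected:
        res = _ols(yv, table.values[list(selected)])
        terms = []
        for k, name in enumerate(selected):
            terms.append(
                LurTerm(
                    name=name,
                    slope=float(res.params[name]),
                    se=float(res.bse[name]),
                    pvalue=float(res.pvalues[name]),
                    cum_adj_r2=float(cum_adj[k]) if cum_adj is not None else float("nan"),
                )
            )
        r2 = float(res.rsquared)
        adj = float(res.rsquared_adj)
        rmse = float(np.sqrt(np.mean(res.resid ** 2)))
        icpt, icpt_se, icpt_p = (
            float(res.params["const"]),
            float(res.bse["const"]),
            float(res.pvalues["const"]),
        )
    else:
        mu = float(np.mean(yv))
        sd = float(np.std(yv))
        icpt, icpt_se, icpt_p = mu, float(sd / np.sqrt(n)) if n else float("nan"), float("nan")
        terms, r2, adj, rmse = [], 0.0, 0.0, sd
    return LurModel(
        metric=metric,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_p=icpt_p,
        terms=terms,
        model_r2=r2,
        adjusted_r2=adj,
        rmse=rmse,
        n_sites=n,
        training_site_ids=list(y.index),
    )


def refit(y: pd.Series, table: PredictorTable, term_names: Sequence[str],
          metric: str = "") -> LurModel:
    """Re-estimate coefficients for a fixed predictor set (the LOOCV refit)."""
    y = y.loc[table.values.index]
    return _build_model(y, table, list(term_names), metric=metric)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_pvalues(
    model: LurModel,
    y: pd.Series,
    table: PredictorTable,
    alpha: float = 0.10,
) -> LurModel:
    """Iteratively drop terms with p > alpha (worst first), refitting after
    each removal; a term whose refitted slope flips against its a-priori
    direction is removed the same way."""
    selected = model.term_names
    y = y.loc[table.values.index]
    while selected:
        res = _ols(y.to_numpy(dtype=float), table.values[selected])
        violations = [
            nm for nm in selected
            if np.sign(res.params[nm]) != table.meta[nm].sign
        ]
        if violations:
            worst = max(violations, key=lambda nm: res.pvalues[nm])
            logger.info("pruning %s: direction violation after refit", worst)
            selected = [s for s in selected if s != worst]
            continue
        over = {nm: res.pvalues[nm] for nm in selected if res.pvalues[nm] > alpha}
        if not over:
            break
        worst = max(over, key=over.get)
        logger.info("pruning %s: p = %.3f > %.2f", worst, over[worst], alpha)
        selected = [s for s in selected if s != worst]
    cum = [t.cum_adj_r2 for t in model.terms if t.name in selected]
    out = _build_model(y, table, selected, cum, metric=model.metric)
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j), from regressing
    predictor j on the remaining model predictors with intercept.

    Single-column designs have VIF identically 1; perfect collinearity is
    reported as +inf.
    """
    cols = list(design.columns)
    out = {}
    for j, name in enumerate(cols):
        others = [c for c in cols if c != name]
        if not others:
            out[name] = 1.0
            continue
        res = _ols(design[name].to_numpy(dtype=float), design[others])
        r2 = res.rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, dtype=float)


def prune_vif(
    model: LurModel,
    y: pd.Series,
    table: PredictorTable,
    threshold: float = 3.0,
    delta: float = 0.01,
    alpha: float = 0.10,
    blacklist: Iterable[str] = (),
) -> LurModel:
    """Remove collinear terms: while any VIF exceeds ``threshold``, blacklist
    the worst offender and redevelop the model (forward selection plus
    p-value pruning) on the remaining candidate pool."""
    blacklist = set(blacklist)
    current = model
    while len(current.terms) >= 2:
        v = vif(table.values[current.term_names])
        if v.max() <= threshold:
            break
        offender = v.idxmax()
        logger.info("VIF pruning: %s removed (VIF %.2f), rerunning selection",
                    offender, v.max())
        blacklist.add(offender)
        current, blacklist = _select_prune_fixed_point(
            y, table, delta=delta, alpha=alpha, blacklist=blacklist
        )
        current.metric = model.metric
    return current


def _select_prune_fixed_point(
    y: pd.Series,
    table: PredictorTable,
    delta: float,
    alpha: float,
    blacklist: set[str],
):
    """Forward selection and p-value pruning iterated to a fixed point; a
    pruned term is blacklisted and selection rerun, since its removal can
    unblock a candidate that previously failed the direction check."""
    blacklist = set(blacklist)
    while True:
        model = forward_select(y, table, delta=delta, blacklist=blacklist)
        pruned = prune_pvalues(model, y, table, alpha=alpha)
        dropped = set(model.term_names) - set(pruned.term_names)
        if not dropped:
            return pruned, blacklist
        blacklist |= dropped
        logger.info("redeveloping after pruning %s", sorted(dropped))


# ---------------------------------------------------------------------------
# influence and spatial autocorrelation diagnostics
# ---------------------------------------------------------------------------

def cooks_d(y: pd.Series, table: PredictorTable, term_names: Sequence[str]) -> pd.Series:
    """Per-site Cook's distance of the fitted model (intercept-only if the
    model is empty).  Leverage-one observations yield +inf."""
    y = y.loc[table.values.index]
    yv = y.to_numpy(dtype=float)
    if term_names:
        X = sm.add_constant(table.values[list(term_names)].astype(float), has_constant="add")
    else:
        X = pd.DataFrame({"const": np.ones(len(yv))}, index=table.values.index)
    res = sm.OLS(yv, X).fit()
    infl = res.get_influence()
    h = infl.hat_matrix_diag
    p = X.shape[1]
    mse = res.mse_resid
    sst = float(((yv - yv.mean()) ** 2).sum())
    if res.ssr <= 1e-12 * max(sst, 1e-300):
        # numerically perfect fit: influence on coefficients is nil and the
        # ratio of round-off residuals to round-off MSE is meaningless
        d = np.zeros(len(yv))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (res.resid ** 2 / (p * mse)) * (h / (1.0 - h) ** 2)
        d = np.where(h >= 1.0 - 1e-12, np.inf, d)
    return pd.Series(d, index=table.values.index, name="cooks_d")


def spatial_weights(
    coords: np.ndarray,
    scheme: str = "idw",
    k: int = 5,
) -> np.ndarray:
    """Row-standardized spatial weight matrix with zero diagonal.

    ``idw`` uses inverse squared distance; ``knn`` uses binary k-nearest
    neighbours.  Coincident points receive the maximum finite weight in
    the row to keep the matrix finite.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 locations for spatial weights")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if scheme == "idw":
        with np.errstate(divide="ignore"):
            w = 1.0 / d ** 2
        if np.isinf(w).any():
            finite_max = w[np.isfinite(w)].max(initial=1.0)
            w[np.isinf(w)] = finite_max
    elif scheme == "knn":
        w = np.zeros_like(d)
        k = min(k, n - 1)
        nearest = np.argsort(d, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        w[rows, nearest.ravel()] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs


def morans_i(residuals: np.ndarray, weights: np.ndarray) -> dict:
    """Moran's I of a residual vector under a spatial weight matrix.

    I = (n / S0) * sum_ij w_ij e_i e_j / sum_i e_i^2 with mean-centered
    residuals e.  Expectation, variance, z and two-sided p follow the
    normal approximation under the randomization assumption.
    """
    e = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(e)
    if n < 5:
        raise ValueError("Moran's I needs at least 5 observations")
    if w.shape != (n, n):
        raise ValueError("weight matrix shape does not match residuals")
    if (w < 0).any() or np.diag(w).any():
        raise ValueError("weights must be nonnegative with zero diagonal")
    e = e - e.mean()
    ss = float(e @ e)
    if ss == 0:
        raise ValueError("residuals have zero variance; Moran's I undefined")
    s0 = w.sum()
    i_stat = (n / s0) * float(e @ w @ e) / ss

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * float((e ** 4).sum()) / ss ** 2
    num = (
        n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
        - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2)
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    var = num / den - e_i ** 2
    z = (i_stat - e_i) / np.sqrt(var) if var > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return {
        "I": float(i_stat),
        "expected": float(e_i),
        "variance": float(var),
        "z": float(z),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# reporting and prediction
# ---------------------------------------------------------------------------

def standardize_coefficients(model: LurModel, table: PredictorTable) -> list[dict]:
    """Reporting convention for model tables: raw slope multiplied by the
    predictor's P90 - P10 difference over the training sites; standard
    errors scaled identically; the intercept is reported unscaled."""
    out = []
    for term in model.terms:
        span = table.percentile_span(term.name)
        if span == 0:
            raise ValueError(f"degenerate predictor {term.name!r}: P90 == P10")
        out.append(
            {
                "name": term.name,
                "raw_slope": term.slope,
                "p10_p90_span": span,
                "std_coefficient": term.slope * span,
                "std_se": term.se * span,
                "pvalue": term.pvalue,
                "cum_adj_r2": term.cum_adj_r2,
            }
        )
    return out


def predict(model: LurModel, predictors: pd.DataFrame) -> pd.Series:
    """Apply a fitted model to predictor rows: intercept + sum slope * value.

    Negative predictions are retained (they flag sites outside the model's
    calibration range rather than being truncated).
    """
    missing = [t.name for t in model.terms if t.name not in predictors.columns]
    if missing:
        raise KeyError(f"receptor table lacks model predictors: {missing}")
    pred = np.full(len(predictors), model.intercept, dtype=float)
    for term in model.terms:
        pred += term.slope * predictors[term.name].to_numpy(dtype=float)
    return pd.Series(pred, index=predictors.index, name=f"pred_{model.metric}")


# ---------------------------------------------------------------------------
# full development pipeline
# ---------------------------------------------------------------------------

def develop_model(
    y: pd.Series,
    table: PredictorTable,
    metric: str = "",
    delta: float = 0.01,
    alpha: float = 0.10,
    vif_threshold: float = 3.0,
    max_zero_sites: int | None = None,
    coords: np.ndarray | None = None,
    moran_scheme: str = "idw",
) -> LurModel:
    """Run the full protocol: zero-inflation screening, supervised forward
    selection, p-value pruning, VIF pruning with redevelopment, Cook's D
    flagging, and Moran's I residual diagnostics.

    ``coords`` (n x 2 planar meters, aligned with ``y``) enables the
    Moran's I diagnostic; without it the diagnostic is skipped.
    """
    table = table.subset_sites(y.index)
    screened = screen_predictors(table, max_zero_sites=max_zero_sites)
    model, blacklist = _select_prune_fixed_point(
        y, screened, delta=delta, alpha=alpha, blacklist=set()
    )
    model = prune_vif(model, y, screened, threshold=vif_threshold,
                      delta=delta, alpha=alpha, blacklist=blacklist)
    model.metric = metric

    diagnostics: dict = {}
    if model.terms:
        diagnostics["max_vif"] = float(vif(screened.values[model.term_names]).max())
    else:
        diagnostics["max_vif"] = 1.0
    d = cooks_d(y, screened, model.term_names)
    diagnostics["max_cooks_d"] = float(d.max())
    diagnostics["cooks_flag"] = bool(d.max() > 1.0)
    if diagnostics["cooks_flag"]:
        logger.warning("max Cook's D %.2f > 1: influential site %s should be examined",
                       d.max(), d.idxmax())
    if coords is not None:
        resid = y.loc[screened.values.index].to_numpy(dtype=float) - predict(
            model, screened.values
        ).to_numpy()
        if np.allclose(resid, resid[0]):
            diagnostics["morans_i"] = None
        else:
            w = spatial_weights(coords, scheme=moran_scheme)
            diagnostics["morans_i"] = morans_i(resid, w)
    model.diagnostics = diagnostics
    model.std_coefficients = standardize_coefficients(model, screened)
    return model
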