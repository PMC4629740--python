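"""Model validation: leave-one-out cross-validation and stratified holdout.

LOOCV keeps the final model *structure* fixed and re-estimates only the
coefficients on the remaining N-1 sites before predicting the held-out
site.  Holdout validation (HV) is the stricter protocol: repeated
stratified 50/50 train/test splits by site type, with the *entire*
development pipeline (screening, supervised forward selection, pruning)
rerun on each training half, and the refit model scored on the test half.

Validation R^2 is reported two ways: the squared Pearson correlation
between observed and predicted (primary, the convention in the LUR
literature) and the variance-explained form 1 - SSE/SST (secondary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import lur_model
from .lur_model import LurModel, PredictorTable

logger = logging.getLogger(__name__)


def _pearson_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    r, _ = stats.pearsonr(obs, pred)
    return float(r ** 2)


def _mse_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


@dataclass
class LoocvResult:
    predictions: dict                # site_id -> out-of-sample prediction
    r2: float                        # squared Pearson correlation
    r2_mse: float                    # 1 - SSE/SST variant
    rmse: float
    skipped_sites: list = field(default_factory=list)


@dataclass
class HoldoutResult:
    splits: list                     # per split: train/test ids, model summary, test_r2
    hv_mean: float
    hv_se: float
    hv_mean_mse: float
    seed: int


@dataclass
class ValidationReport:
    metric: str
    loocv: LoocvResult
    holdout: HoldoutResult

    def to_dict(self) -> dict:
        return asdict(self)


def loocv(y: pd.Series, model: LurModel, table: PredictorTable) -> LoocvResult:
    """Leave-one-out CV with fixed model structure.

    For each site, the coefficients of the final predictor set are refit on
    the other N-1 sites and the held-out site is predicted.
    """
    names = model.term_names
    if len(y) < len(names) + 3:
        raise ValueError("too few sites for LOOCV with this model size")
    tab = table.subset_sites(y.index)
    preds: dict = {}
    skipped: list = []
    for sid in y.index:
        rest = y.index[y.index != sid]
        try:
            refit = lur_model.refit(y.loc[rest], tab.subset_sites(rest), names)
        except Exception as exc:  # singular refit
            logger.warning("LOOCV refit failed for site %s: %s", sid, exc)
            skipped.append(sid)
            continue
        preds[sid] = float(
            lur_model.predict(refit, tab.values.loc[[sid]]).iloc[0]
        )
    used = [s for s in y.index if s in preds]
    obs = y.loc[used].to_numpy(dtype=float)
    pr = np.array([preds[s] for s in used])
    return LoocvResult(
        predictions=preds,
        r2=_pearson_r2(obs, pr),
        r2_mse=_mse_r2(obs, pr),
        rmse=float(np.sqrt(np.mean((obs - pr) ** 2))),
        skipped_sites=skipped,
    )


def stratified_split(
    sites: pd.DataFrame,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Random split with ``train_fraction`` of each site type in training.

    Odd type counts give training floor(n * fraction) sites, with the
    fractional remainder allocated to training at random.
    """
    train: list = []
    test: list = []
    for st, grp in sites.groupby("site_type", sort=True):
        ids = grp["site_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"site type {st!r} has fewer than 2 sites")
        perm = rng.permutation(len(ids))
        n_exact = len(ids) * train_fraction
        n_train = int(np.floor(n_exact))
        if n_exact - n_train > 0 and rng.random() < (n_exact - n_train):
            n_train += 1
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return sorted(train), sorted(test)


def holdout_validation(
    y: pd.Series,
    table: PredictorTable,
    sites: pd.DataFrame,
    n_splits: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
    metric: str = "",
    **develop_kwargs,
) -> HoldoutResult:
    """Stratified holdout validation with full model redevelopment per split.

    Split k uses the RNG seeded by ``SeedSequence([seed, k])``, so adding
    splits never changes earlier ones.  An empty refit model predicts the
    training mean everywhere; its test R^2 is recorded as 0 (no prediction
    variance).
    """
    sites = sites[sites["site_id"].isin(y.index)]
    rows = []
    r2s = []
    r2s_mse = []
    for k in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        train_ids, test_ids = stratified_split(sites, train_fraction, rng)
        model = lur_model.develop_model(
            y.loc[train_ids], table.subset_sites(train_ids), metric=metric,
            **develop_kwargs,
        )
        pred = lur_model.predict(model, table.values.loc[test_ids])
        obs = y.loc[test_ids].to_numpy(dtype=float)
        r2 = _pearson_r2(obs, pred.to_numpy())
        r2s.append(r2)
        r2s_mse.append(_mse_r2(obs, pred.to_numpy()))
        rows.append(
            {
                "split": k,
                "train_ids": train_ids,
                "test_ids": test_ids,
                "n_terms": len(model.terms),
                "terms": model.term_names,
                "train_r2": model.model_r2,
                "test_r2": r2,
            }
        )
        logger.info("holdout split %d: %d terms, train R^2 %.2f, test R^2 %.2f",
                    k, len(model.terms), model.model_r2, r2)
    r2_arr = np.array(r2s)
    hv_se = float(r2_arr.std(ddof=1) / np.sqrt(len(r2_arr))) if len(r2_arr) > 1 else 0.0
    return HoldoutResult(
        splits=rows,
        hv_mean=float(r2_arr.mean()),
        hv_se=hv_se,
        hv_mean_mse=float(np.mean(r2s_mse)),
        seed=seed,
    )


def validate_model(
    y: pd.Series,
    model: LurModel,
    table: PredictorTable,
    sites: pd.DataFrame,
    n_splits: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
    **develop_kwargs,
) -> ValidationReport:
    """LOOCV of the fitted model plus stratified holdout validation."""
    return ValidationReport(
        metric=model.metric,
        loocv=loocv(y, model, table),
        holdout=holdout_validation(
            y, table, sites, n_splits=n_splits, train_fraction=train_fraction,
            seed=seed, metric=model.metric, **develop_kwargs,
        ),
    )
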