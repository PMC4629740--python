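"""Comparison of LUR model predictions at held-out receptor locations.

Two or more fitted models are applied to a common receptor set whose
sites were used in none of the models' training rosters, and the pairwise
squared Pearson correlations of the prediction vectors are reported.
High between-model R^2 means the exposure surfaces are hard to
disentangle in an epidemiological analysis; moderate R^2 leaves room to
test which metric predicts health effects better.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .lur_model import LurModel, predict
from .spatial_contrast import squared_pearson_matrix


def compare_predictions(
    models: Sequence[LurModel],
    receptors: pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Squared-Pearson matrix of model predictions at common receptors.

    ``receptors`` is a predictor DataFrame indexed by receptor id covering
    the union of all models' predictors.  A receptor appearing in any
    model's training roster violates the held-out contract and raises.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if len(receptors) < 3:
        raise ValueError("need at least 3 receptors")
    if labels is None:
        labels = [m.metric or f"model_{k}" for k, m in enumerate(models)]
    if len(labels) != len(models):
        raise ValueError("labels and models differ in length")
    for model, label in zip(models, labels):
        overlap = set(receptors.index) & set(model.training_site_ids)
        if overlap:
            raise ValueError(
                f"receptors {sorted(overlap)} were used to train model {label!r}"
            )
    preds = pd.DataFrame(
        {label: predict(m, receptors) for m, label in zip(models, labels)}
    )
    degenerate = [c for c in preds.columns if float(np.var(preds[c])) == 0.0]
    if degenerate:
        raise ValueError(
            f"models {degenerate} predict a constant at the receptors; "
            "correlation undefined"
        )
    return squared_pearson_matrix(preds)
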