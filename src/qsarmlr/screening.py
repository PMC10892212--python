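"""End-to-end candidate screening: predict, check the domain, rank.

Applies a fitted MLR model to query descriptor vectors, attaches
leverage-based applicability-domain flags, and compares each prediction
against the most active training compound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .applicability import leverages, warning_leverage, williams_classification
from .datasets import DescriptorDataset
from .mlr import ModelFit, predict_mlr


@dataclass
class ScreenReport:
    """One screened candidate set against one model."""

    compound_ids: list[str]
    predicted: np.ndarray
    leverage: np.ndarray
    in_domain: np.ndarray
    exceeds_best_training: np.ndarray
    h_star: float
    best_training_pic50: float
    best_training_compound: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "predicted_pIC50": self.predicted,
                "leverage": self.leverage,
                "h_star": self.h_star,
                "in_domain": self.in_domain,
                "exceeds_best_training": self.exceeds_best_training,
                "best_training_pIC50": self.best_training_pic50,
            }
        )


def screen_candidates(
    model: ModelFit,
    train: DescriptorDataset,
    queries: DescriptorDataset,
    include_intercept_leverage: bool = True,
) -> ScreenReport:
    """Score query compounds with a model fitted on ``train``.

    ``train`` and ``queries`` must be restricted to the model's descriptors
    (same order).  The activity reference is the maximum observed pIC50
    among the training compounds (test compounds excluded).  Query
    compounds have no observed activity, so domain classification rests on
    leverage alone.
    """
    for ds, what in ((train, "training"), (queries, "query")):
        if list(ds.descriptor_names) != list(model.descriptor_names):
            raise ValueError(
                f"{what} descriptors {ds.descriptor_names} do not match the "
                f"model's {model.descriptor_names}"
            )
    if train.y is None:
        raise ValueError("training set has no activities")
    best_i = int(np.argmax(train.y))
    best_y = float(train.y[best_i])

    if queries.n_compounds == 0:
        empty = np.empty(0)
        return ScreenReport(
            compound_ids=[],
            predicted=empty,
            leverage=empty,
            in_domain=empty.astype(bool),
            exceeds_best_training=empty.astype(bool),
            h_star=warning_leverage(model.k, train.n_compounds),
            best_training_pic50=best_y,
            best_training_compound=train.compound_ids[best_i],
        )

    pred = predict_mlr(model, queries)
    lev = leverages(train.X, queries.X, include_intercept=include_intercept_leverage)
    h_star = warning_leverage(model.k, train.n_compounds)
    ad = williams_classification(queries.compound_ids, lev, h_star)
    report = ScreenReport(
        compound_ids=list(queries.compound_ids),
        predicted=pred,
        leverage=lev,
        in_domain=ad.in_domain,
        exceeds_best_training=pred > best_y,
        h_star=h_star,
        best_training_pic50=best_y,
        best_training_compound=train.compound_ids[best_i],
    )
    assert len(report.compound_ids) == queries.n_compounds
    return report
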