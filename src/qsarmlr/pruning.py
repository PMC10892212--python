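"""Objective feature selection: near-constant and collinearity filters.

Descriptors whose modal value occupies more than 95% of compounds carry
essentially no information; of any pair with Pearson |r| > 0.90 only one
member is kept, to keep multi-collinear and spurious variables out of the
subset search.  Both thresholds are the conventional objective-selection
defaults and are adjustable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .datasets import DescriptorDataset

CONSTANT_FRACTION_DEFAULT = 0.95
R_THRESHOLD_DEFAULT = 0.90


@dataclass
class PruningReport:
    """Which descriptors survived the objective filters, and why not."""

    kept: list[str]
    dropped_constant: list[str]
    dropped_collinear: list[tuple[str, str, float]]  # (dropped, partner, |r|)
    thresholds: dict = field(default_factory=dict)


def _modal_fraction(col: np.ndarray) -> float:
    # round to 12 significant digits so float noise cannot hide a constant
    counts = Counter(float(f"{v:.12g}") for v in col)
    return max(counts.values()) / col.size


def drop_near_constant(
    ds: DescriptorDataset, fraction: float = CONSTANT_FRACTION_DEFAULT
) -> PruningReport:
    """Flag descriptors whose modal value occupies > ``fraction`` of rows."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if ds.n_compounds < 1:
        raise ValueError("empty dataset")
    dropped = [
        name
        for j, name in enumerate(ds.descriptor_names)
        if _modal_fraction(ds.X[:, j]) > fraction
    ]
    kept = [n for n in ds.descriptor_names if n not in set(dropped)]
    return PruningReport(
        kept=kept,
        dropped_constant=dropped,
        dropped_collinear=[],
        thresholds={"constant_fraction": fraction},
    )


def drop_collinear(
    ds: DescriptorDataset,
    y: np.ndarray | None = None,
    r_threshold: float = R_THRESHOLD_DEFAULT,
) -> PruningReport:
    """Greedy removal of one member of every descriptor pair with |r| > threshold.

    Pairs are swept in order of descending |r| (ties: earlier column pair
    first); within a pair the member less correlated with the activity is
    dropped, the later column on an exact tie.  Survivors are guaranteed
    pairwise |r| <= threshold.
    """
    if ds.n_compounds < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    if y is None:
        y = ds.y
    X = ds.X
    sd = X.std(axis=0)
    if np.any(sd == 0):
        zero = [n for n, s in zip(ds.descriptor_names, sd) if s == 0]
        raise ValueError(
            f"zero-variance descriptors {zero}; run the near-constant filter first"
        )
    R = np.corrcoef(X, rowvar=False)
    if ds.n_descriptors == 1:
        R = np.atleast_2d(R)
    if y is not None:
        yc = np.asarray(y, dtype=float)
        ry = np.abs(
            np.array(
                [np.corrcoef(X[:, j], yc)[0, 1] if yc.std() > 0 else 0.0
                 for j in range(X.shape[1])]
            )
        )
    else:
        ry = np.zeros(X.shape[1])

    p = ds.n_descriptors
    pairs = [
        (abs(R[i, j]), i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(R[i, j]) > r_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    removed: dict[int, tuple[int, float]] = {}  # dropped idx -> (partner, |r|)
    for r, i, j in pairs:
        if i in removed or j in removed:
            continue
        if ry[i] > ry[j]:
            drop, keep = j, i
        elif ry[i] < ry[j]:
            drop, keep = i, j
        else:
            drop, keep = max(i, j), min(i, j)
        removed[drop] = (keep, r)

    names = ds.descriptor_names
    return PruningReport(
        kept=[n for idx, n in enumerate(names) if idx not in removed],
        dropped_constant=[],
        dropped_collinear=[
            (names[d], names[partner], float(r))
            for d, (partner, r) in sorted(removed.items())
        ],
        thresholds={"r_threshold": r_threshold},
    )


def prune(
    ds: DescriptorDataset,
    y: np.ndarray | None = None,
    constant_fraction: float = CONSTANT_FRACTION_DEFAULT,
    r_threshold: float = R_THRESHOLD_DEFAULT,
) -> tuple[DescriptorDataset, PruningReport]:
    """Apply the near-constant filter, then the collinearity filter.

    Returns the reduced dataset (input column order preserved) and a full
    report.  Raises if every descriptor would be dropped.
    """
    const = drop_near_constant(ds, constant_fraction)
    reduced = ds.select_descriptors(const.kept)
    if reduced.n_descriptors == 0:
        raise ValueError("all descriptors removed by the near-constant filter")
    coll = drop_collinear(reduced, y, r_threshold)
    final = reduced.select_descriptors(coll.kept)
    if final.n_descriptors == 0:
        raise ValueError("all descriptors removed by the collinearity filter")
    report = PruningReport(
        kept=coll.kept,
        dropped_constant=const.dropped_constant,
        dropped_collinear=coll.dropped_collinear,
        thresholds={
            "constant_fraction": constant_fraction,
            "r_threshold": r_threshold,
        },
    )
    return final, report
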