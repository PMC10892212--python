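"""Descriptor-table containers, delimited-text I/O and the built-in triazole dataset.

A :class:`DescriptorDataset` is the universe every pipeline stage consumes:
a compounds x descriptors matrix with optional activity (pIC50) and an
optional train/test/query split label per compound.

The package ships the descriptor matrix of 33 synthesized 1,2,4-triazole
alpha-glucosidase inhibitors (five curated descriptors: AATSC8s, VE3_Dzs,
nHsOH, CIC1, RotBFrac, plus experimental pIC50 and a fixed 27/6 train/test
partition) together with seven designed candidate compounds and the
published predictions and leverages for them, so the whole modelling chain
can be reproduced from in-package data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_SPLITS = ("train", "test", "query")

#: Published summary statistics of the reference 5-descriptor model, shipped
#: for side-by-side comparison in reports (never used in any computation).
#: ``q2_loo`` and ``r2_ext`` are printed inconsistently at the source
#: (0.633/0.649 swapped between two places); both printed values are kept.
PUBLISHED_MODEL = {
    "intercept": 6.403,
    "coefficients": {
        "AATSC8s": 0.759,
        "VE3_Dzs": 0.022,
        "nHsOH": -0.112,
        "CIC1": -0.338,
        "RotBFrac": -1.804,
    },
    "r2": 0.767,
    "r2_adj": 0.712,
    "rmse": 0.082,
    "q2_loo_printed": (0.649, 0.633),
    "r2_ext_printed": (0.633, 0.649),
    "yrand_mean_r": 0.428,
    "yrand_mean_r2": 0.196,
    "yrand_mean_q2": -0.342,
    "crp2": 0.669,
    "h_star": 0.667,
}


class DatasetError(ValueError):
    """Raised for malformed descriptor tables or inconsistent datasets."""


@dataclass
class DescriptorDataset:
    """Compounds x descriptors matrix with optional activity and split labels.

    Parameters
    ----------
    compound_ids
        Unique text labels, one per row of ``X``.
    descriptor_names
        Unique, ordered descriptor (column) labels.
    X
        Real-valued matrix, shape ``(n_compounds, n_descriptors)``; all
        entries must be finite.
    y
        Optional activity vector (pIC50, dimensionless). NaN entries are
        allowed only on rows whose split is ``query``.
    split
        Optional per-compound label in ``{"train", "test", "query"}``.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    y: np.ndarray | None = None
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D matrix")
        n, p = self.X.shape
        if len(self.compound_ids) != n:
            raise DatasetError(
                f"{len(self.compound_ids)} compound ids for {n} rows of X"
            )
        if len(self.descriptor_names) != p:
            raise DatasetError(
                f"{len(self.descriptor_names)} descriptor names for {p} columns of X"
            )
        dup = _first_duplicate(self.compound_ids)
        if dup is not None:
            raise DatasetError(f"duplicate compound id: {dup!r}")
        dup = _first_duplicate(self.descriptor_names)
        if dup is not None:
            raise DatasetError(f"duplicate descriptor name: {dup!r}")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"non-finite descriptor value at compound {self.compound_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape != (n,):
                raise DatasetError("split length does not match number of compounds")
            bad = set(self.split) - set(VALID_SPLITS)
            if bad:
                raise DatasetError(f"invalid split labels: {sorted(bad)}")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (n,):
                raise DatasetError("y length does not match number of compounds")
            missing = ~np.isfinite(self.y)
            if missing.any():
                labels = (
                    self.split[missing]
                    if self.split is not None
                    else np.array(["train"] * int(missing.sum()))
                )
                if any(lab != "query" for lab in labels):
                    i = int(np.flatnonzero(missing)[0])
                    raise DatasetError(
                        f"missing activity for non-query compound "
                        f"{self.compound_ids[i]!r}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    # -- selection ------------------------------------------------------
    def select_descriptors(self, names: Sequence[str]) -> "DescriptorDataset":
        """Restrict to the given descriptors (order as given)."""
        idx = []
        for name in names:
            try:
                idx.append(self.descriptor_names.index(name))
            except ValueError:
                raise DatasetError(f"unknown descriptor: {name!r}") from None
        return DescriptorDataset(
            compound_ids=list(self.compound_ids),
            descriptor_names=[self.descriptor_names[i] for i in idx],
            X=self.X[:, idx].copy(),
            y=None if self.y is None else self.y.copy(),
            split=None if self.split is None else self.split.copy(),
        )

    def subset_rows(self, mask: np.ndarray) -> "DescriptorDataset":
        mask = np.asarray(mask, dtype=bool)
        return DescriptorDataset(
            compound_ids=[c for c, m in zip(self.compound_ids, mask) if m],
            descriptor_names=list(self.descriptor_names),
            X=self.X[mask].copy(),
            y=None if self.y is None else self.y[mask].copy(),
            split=None if self.split is None else self.split[mask].copy(),
        )

    def split_mask(self, label: str) -> np.ndarray:
        if self.split is None:
            raise DatasetError("dataset has no split labels")
        return np.asarray([s == label for s in self.split])

    def training_set(self) -> "DescriptorDataset":
        return self.subset_rows(self.split_mask("train"))

    def test_set(self) -> "DescriptorDataset":
        return self.subset_rows(self.split_mask("test"))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id, split (if any), descriptors, pIC50 (if any)."""
        data: dict[str, object] = {"compound_id": self.compound_ids}
        if self.split is not None:
            data["split"] = list(self.split)
        for j, name in enumerate(self.descriptor_names):
            data[name] = self.X[:, j]
        if self.y is not None:
            data["pIC50"] = self.y
        return pd.DataFrame(data)


@dataclass
class ReferenceData:
    """The built-in triazole study data.

    Attributes
    ----------
    synthesized
        33 synthesized compounds with experimental pIC50 and the fixed
        27-train / 6-test partition (test compounds: 1, 2, 7, 8, 12, 18).
    designed
        7 designed candidate compounds (P3, P4, P6, P7, P10, P14, P19),
        split ``query``, no experimental activity.
    reference_predictions
        Published predicted pIC50 per designed compound.
    reference_leverages
        Published leverage per designed compound.
    """

    synthesized: DescriptorDataset
    designed: DescriptorDataset
    reference_predictions: dict[str, float]
    reference_leverages: dict[str, float]


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def pic50_from_ic50(ic50) -> float | np.ndarray:
    """Convert a molar IC50 into pIC50 = -log10(IC50).

    >>> pic50_from_ic50(1e-6)
    6.0
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be a positive, finite molar concentration")
    out = -np.log10(arr)
    return float(out) if out.ndim == 0 else out


def load_descriptor_table(
    path: str | Path,
    id_column: str = "compound_id",
    activity_column: str | None = None,
    split_column: str | None = None,
    activity_is_ic50: bool = False,
) -> DescriptorDataset:
    """Read a delimited descriptor table (CSV, UTF-8, header row).

    Every column other than the id / activity / split columns is taken as a
    descriptor, in file order.  Unicode minus signs are normalised to ASCII
    on ingest.  A missing activity value is tolerated only on rows labelled
    ``query``.

    Parameters
    ----------
    activity_is_ic50
        If true, the activity column holds molar IC50 values and is
        transformed to pIC50; by default it is taken to be pIC50 already.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"−": "-", "–": "-"}, regex=True)
    if id_column not in df.columns:
        raise DatasetError(f"id column {id_column!r} not found in {path.name}")
    ids = [s.strip() for s in df[id_column]]
    dup = _first_duplicate(ids)
    if dup is not None:
        raise DatasetError(f"duplicate compound id: {dup!r} in {path.name}")

    split = None
    if split_column is not None:
        if split_column not in df.columns:
            raise DatasetError(f"split column {split_column!r} not found")
        split = np.asarray([s.strip() for s in df[split_column]], dtype=object)

    y = None
    if activity_column is not None:
        if activity_column not in df.columns:
            raise DatasetError(f"activity column {activity_column!r} not found")
        raw = [s.strip() for s in df[activity_column]]
        vals = []
        for i, s in enumerate(raw):
            if s == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(float(s))
            except ValueError:
                raise DatasetError(
                    f"non-numeric activity {s!r} for compound {ids[i]!r}"
                ) from None
        y = np.asarray(vals)
        if activity_is_ic50:
            finite = np.isfinite(y)
            y = np.where(finite, pic50_from_ic50(np.where(finite, y, 1.0)), y)

    drop = {id_column} | {c for c in (activity_column, split_column) if c}
    desc_cols = [c for c in df.columns if c not in drop]
    X = np.empty((len(df), len(desc_cols)))
    for j, col in enumerate(desc_cols):
        for i, s in enumerate(df[col]):
            s = s.strip()
            try:
                X[i, j] = float(s)
            except ValueError:
                raise DatasetError(
                    f"non-numeric descriptor value {s!r} at compound {ids[i]!r}, "
                    f"column {col!r}"
                ) from None

    return DescriptorDataset(
        compound_ids=ids, descriptor_names=desc_cols, X=X, y=y, split=split
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("qsarmlr.data") / name)


def load_reference_data() -> ReferenceData:
    """Load the packaged triazole dataset (33 synthesized + 7 designed).

    Values are carried exactly as published (three printed decimals); the
    designed compounds additionally carry the published predicted pIC50 and
    leverage so reproductions can be compared against them.
    """
    synthesized = load_descriptor_table(
        _data_path("triazole_synthesized.csv"),
        activity_column="pIC50",
        split_column="split",
    )
    ddf = pd.read_csv(_data_path("triazole_designed.csv"))
    ref_pred = dict(zip(ddf["compound_id"], ddf["published_pIC50"].astype(float)))
    ref_lev = dict(zip(ddf["compound_id"], ddf["published_leverage"].astype(float)))
    desc = [c for c in ddf.columns if c not in ("compound_id", "published_pIC50", "published_leverage")]
    designed = DescriptorDataset(
        compound_ids=list(ddf["compound_id"].astype(str)),
        descriptor_names=desc,
        X=ddf[desc].to_numpy(dtype=float),
        y=np.full(len(ddf), np.nan),
        split=np.asarray(["query"] * len(ddf), dtype=object),
    )
    data = ReferenceData(
        synthesized=synthesized,
        designed=designed,
        reference_predictions=ref_pred,
        reference_leverages=ref_lev,
    )
    assert int(synthesized.split_mask("train").sum()) == 27
    assert int(synthesized.split_mask("test").sum()) == 6
    assert designed.n_compounds == 7
    return data


def random_split(
    ds: DescriptorDataset, test_fraction: float = 0.2, seed: int = 0
) -> DescriptorDataset:
    """Assign a seeded plain-random train/test partition (no stratification).

    ``round(n * test_fraction)`` compounds become the test set; existing
    split labels are replaced.  Query rows (no activity) keep their label.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = ds.n_compounds
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("test_fraction leaves an empty train or test set")
    labels = np.asarray(["train"] * n, dtype=object)
    labels[rng.choice(n, size=n_test, replace=False)] = "test"
    if ds.split is not None:
        labels[np.asarray([s == "query" for s in ds.split])] = "query"
    return DescriptorDataset(
        compound_ids=list(ds.compound_ids),
        descriptor_names=list(ds.descriptor_names),
        X=ds.X.copy(),
        y=None if ds.y is None else ds.y.copy(),
        split=labels,
    )


# -- report serialisation ----------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"__type__": type(obj).__name__}
        d.update({k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()})
        return d
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else repr(obj)
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialise a result object to structured text.

    ``.json`` paths get a JSON document (floats at full precision, so the
    round trip is numerically exact); ``.csv`` paths require the object to
    expose ``to_frame()`` and get a tabular CSV.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() == ".csv":
        if not hasattr(report, "to_frame"):
            raise TypeError(f"{type(report).__name__} has no tabular form")
        report.to_frame().to_csv(path, index=False)
        return
    path.write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
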