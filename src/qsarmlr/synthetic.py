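"""Synthetic descriptor datasets with known ground truth.

Emulates the structure of a curated QSAR table — a few hundred candidate
descriptors, a linear activity signal carried by a small planted subset,
Gaussian noise, plus the pathologies the objective filters must catch:
engineered near-collinear pairs and near-constant columns.  Descriptor
marginals are standard normal; no attempt is made to mimic real descriptor
blocks' correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DescriptorDataset


@dataclass
class SyntheticSpec:
    """Generative ground truth for one synthetic dataset.

    Collinear pairs overwrite decoy columns: each pair's partner is the
    primary column plus Gaussian jitter scaled so the population correlation
    equals ``collinear_r``.  Near-constant columns hold a single value on a
    ``near_constant_fraction`` share of compounds and standard-normal noise
    elsewhere.  Special columns never overlap the informative subset.
    """

    n_compounds: int
    n_descriptors: int
    informative_subset: tuple[int, ...]
    true_intercept: float
    true_coefficients: tuple[float, ...]
    noise_sd: float
    n_collinear_pairs: int = 0
    collinear_r: float = 0.97
    n_near_constant: int = 0
    near_constant_fraction: float = 0.97
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_subset = tuple(self.informative_subset)
        self.true_coefficients = tuple(self.true_coefficients)
        if len(set(self.informative_subset)) != len(self.informative_subset):
            raise ValueError("informative_subset indices must be distinct")
        if any(not 0 <= i < self.n_descriptors for i in self.informative_subset):
            raise ValueError("informative_subset indices out of range")
        if len(self.true_coefficients) != len(self.informative_subset):
            raise ValueError("one coefficient per informative descriptor required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_compounds <= len(self.informative_subset) + 1:
            raise ValueError("need n_compounds > |informative_subset| + 1")
        n_special = 2 * self.n_collinear_pairs + self.n_near_constant
        if n_special > self.n_descriptors - len(self.informative_subset):
            raise ValueError(
                "more engineered special columns than free (non-informative) "
                "descriptors"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted (for recovery tests)."""

    spec: SyntheticSpec
    informative_names: list[str]
    collinear_pairs: list[tuple[str, str]]
    near_constant_names: list[str]
    split: np.ndarray = field(repr=False)
    y_clean: np.ndarray = field(repr=False)


def generate_dataset(spec: SyntheticSpec) -> tuple[DescriptorDataset, GroundTruth]:
    """Draw one dataset from ``spec``; the same seed gives identical output.

    Descriptors are named ``d000, d001, ...``; compounds ``C0001, ...``.
    The activity is ``true_intercept + X[:, informative] @ true_coefficients
    + N(0, noise_sd)`` and the split is a seeded plain-random partition with
    ``round(n * test_fraction)`` test compounds.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    X = rng.standard_normal((n, p))

    free = [j for j in range(p) if j not in set(spec.informative_subset)]
    coll_pairs: list[tuple[int, int]] = []
    pos = 0
    for _ in range(spec.n_collinear_pairs):
        a, b = free[pos], free[pos + 1]
        pos += 2
        # corr(Z, Z + eps*W) = 1/sqrt(1+eps^2)  for independent unit normals
        eps = np.sqrt(1.0 / spec.collinear_r**2 - 1.0)
        X[:, b] = X[:, a] + eps * rng.standard_normal(n)
        coll_pairs.append((a, b))
    const_cols = []
    for _ in range(spec.n_near_constant):
        c = free[pos]
        pos += 1
        n_same = int(np.ceil(spec.near_constant_fraction * n))
        col = rng.standard_normal(n)
        idx = rng.choice(n, size=n_same, replace=False)
        col[idx] = rng.standard_normal()
        X[:, c] = col
        const_cols.append(c)

    info = list(spec.informative_subset)
    y_clean = spec.true_intercept + X[:, info] @ np.asarray(spec.true_coefficients)
    y = y_clean + spec.noise_sd * rng.standard_normal(n)

    n_test = int(round(n * spec.test_fraction))
    split = np.asarray(["train"] * n, dtype=object)
    split[rng.choice(n, size=n_test, replace=False)] = "test"

    width = max(3, len(str(p - 1)))
    names = [f"d{j:0{width}d}" for j in range(p)]
    ds = DescriptorDataset(
        compound_ids=[f"C{i + 1:04d}" for i in range(n)],
        descriptor_names=names,
        X=X,
        y=y,
        split=split,
    )
    truth = GroundTruth(
        spec=spec,
        informative_names=[names[j] for j in info],
        collinear_pairs=[(names[a], names[b]) for a, b in coll_pairs],
        near_constant_names=[names[c] for c in const_cols],
        split=split.copy(),
        y_clean=y_clean,
    )
    return ds, truth
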