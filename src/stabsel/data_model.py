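"""Domain types and I/O for mating-trial pair tables.

The unit of analysis is a mating pair: one male and one female, each
described by a vector of morphological traits (centroid size plus
relative-warp shape scores), and a binary outcome recording whether the
trial produced offspring (absolute fitness 1) or not (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "PairDataset",
    "StandardizedTraits",
    "RelativeFitness",
    "load_pair_table",
    "write_pair_table",
    "standardize",
    "relative_fitness",
]


class ConfigurationError(ValueError):
    """Raised when a column-role mapping or run configuration is invalid."""


class DataError(ValueError):
    """Raised when input data violate the pair-table contract."""


_TRUE_TOKENS = {"1", "1.0", "true", "TRUE", "True"}
_FALSE_TOKENS = {"0", "0.0", "false", "FALSE", "False"}


@dataclass
class PairDataset:
    """Per-pair trait values and binary mating success.

    Attributes
    ----------
    male_traits, female_traits : (n, p) float arrays
        Trait values; columns follow ``male_trait_names`` /
        ``female_trait_names``.
    success : (n,) int array of {0, 1}
        Absolute fitness: 1 if the pair transferred a spermatophore
        (produced offspring), 0 otherwise.
    pair_id : (n,) array of labels
    n_dropped : int
        Pairs excluded at load time because a trait value was missing
        or damaged (listwise deletion across both sexes).
    """

    male_traits: np.ndarray
    female_traits: np.ndarray
    success: np.ndarray
    male_trait_names: list[str]
    female_trait_names: list[str]
    pair_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.male_traits = np.asarray(self.male_traits, dtype=float)
        self.female_traits = np.asarray(self.female_traits, dtype=float)
        self.success = np.asarray(self.success)
        if self.male_traits.shape[0] != self.female_traits.shape[0]:
            raise DataError("male and female trait tables have different lengths")
        if self.success.shape[0] != self.male_traits.shape[0]:
            raise DataError("success vector length does not match trait tables")
        if not np.isin(self.success, (0, 1)).all():
            raise DataError("success must be binary {0, 1}")
        self.success = self.success.astype(int)
        if self.male_traits.shape[1] != len(self.male_trait_names):
            raise DataError("male trait name list does not match column count")
        if self.female_traits.shape[1] != len(self.female_trait_names):
            raise DataError("female trait name list does not match column count")
        if np.isnan(self.male_traits).any() or np.isnan(self.female_traits).any():
            raise DataError("trait matrices contain missing values after loading")
        if self.pair_id is None:
            self.pair_id = np.arange(len(self.success))

    @property
    def n_pairs(self) -> int:
        return int(self.success.shape[0])

    @property
    def n_success(self) -> int:
        return int(self.success.sum())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single table with ``male_``/``female_`` prefixes."""
        data: dict[str, np.ndarray] = {"pair_id": self.pair_id}
        for j, name in enumerate(self.male_trait_names):
            data[f"male_{name}"] = self.male_traits[:, j]
        for j, name in enumerate(self.female_trait_names):
            data[f"female_{name}"] = self.female_traits[:, j]
        data["success"] = self.success
        return pd.DataFrame(data)


@dataclass
class StandardizedTraits:
    """Column z-scores with the means and SDs needed to invert them.

    Each column of ``z`` has mean 0 and sample standard deviation 1
    (n-1 denominator), the Lande-Arnold convention that makes selection
    gradients comparable across traits and studies.
    """

    z: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    trait_names: list[str]

    def inverse(self) -> np.ndarray:
        """Map the z-scores back to the original trait scale."""
        return self.z * self.sds + self.means


@dataclass
class RelativeFitness:
    """Relative fitness w = absolute fitness / mean absolute fitness."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < 0).any():
            raise DataError("relative fitness must be nonnegative")
        if abs(self.w.mean() - 1.0) > 1e-12:
            raise DataError("relative fitness must have mean 1")


def _coerce_success(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        token = str(v).strip()
        if token in _TRUE_TOKENS:
            out[i] = 1
        elif token in _FALSE_TOKENS:
            out[i] = 0
        else:
            raise DataError(
                f"non-binary success value {v!r} in row {values.index[i]}"
            )
    return out


def load_pair_table(
    path: str | Path,
    male_columns: Sequence[str],
    female_columns: Sequence[str],
    success_column: str = "success",
    pair_id_column: str | None = None,
    delimiter: str = ",",
) -> PairDataset:
    """Read a delimited pair table, dropping pairs with missing traits.

    Exclusion is listwise across both sexes: a missing or unparseable
    value in any trait column removes the whole pair (both partners).
    The number of dropped pairs is recorded on the returned dataset.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)

    wanted = list(male_columns) + list(female_columns) + [success_column]
    if pair_id_column is not None:
        wanted.append(pair_id_column)
    missing_cols = [c for c in wanted if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"columns not found in {path.name}: {missing_cols}"
        )

    trait_cols = list(male_columns) + list(female_columns)
    traits = df[trait_cols].apply(pd.to_numeric, errors="coerce")
    keep = ~traits.isna().any(axis=1)
    n_dropped = int((~keep).sum())

    kept = df.loc[keep]
    success = _coerce_success(kept[success_column])
    pair_id = (
        kept[pair_id_column].to_numpy()
        if pair_id_column is not None
        else kept.index.to_numpy()
    )
    return PairDataset(
        male_traits=traits.loc[keep, list(male_columns)].to_numpy(),
        female_traits=traits.loc[keep, list(female_columns)].to_numpy(),
        success=success,
        male_trait_names=list(male_columns),
        female_trait_names=list(female_columns),
        pair_id=pair_id,
        n_dropped=n_dropped,
    )


def write_pair_table(dataset: PairDataset, path: str | Path) -> None:
    """Write a pair dataset as CSV with ``male_``/``female_`` prefixed columns."""
    dataset.to_frame().to_csv(path, index=False)


def load_written_pair_table(path: str | Path) -> PairDataset:
    """Load a table produced by :func:`write_pair_table` (prefix convention)."""
    header = pd.read_csv(path, nrows=0).columns
    male = [c[len("male_"):] for c in header if c.startswith("male_")]
    female = [c[len("female_"):] for c in header if c.startswith("female_")]
    return load_pair_table(
        path,
        male_columns=[f"male_{c}" for c in male],
        female_columns=[f"female_{c}" for c in female],
        success_column="success",
        pair_id_column="pair_id",
    )


def standardize(
    traits: np.ndarray, trait_names: Sequence[str] | None = None
) -> StandardizedTraits:
    """Z-score each trait column (sample SD, n-1 denominator)."""
    X = np.asarray(traits, dtype=float)
    if X.ndim != 2:
        raise DataError("trait matrix must be 2-D")
    n, p = X.shape
    if n < 3:
        raise DataError("need at least 3 pairs to standardize")
    names = list(trait_names) if trait_names is not None else [
        f"trait_{j}" for j in range(p)
    ]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        raise DataError(
            "zero-variance trait column(s): " + ", ".join(names[j] for j in bad)
        )
    return StandardizedTraits(z=(X - means) / sds, means=means, sds=sds,
                              trait_names=names)


def relative_fitness(success: np.ndarray) -> RelativeFitness:
    """Divide absolute fitness by its population mean.

    For binary mating success with k successes out of n pairs this gives
    successful pairs w = n/k and failed pairs w = 0, so mean(w) = 1.
    """
    s = np.asarray(success, dtype=float)
    if not np.isin(s, (0.0, 1.0)).all():
        raise DataError("success must be binary {0, 1}")
    mean = s.mean()
    if mean == 0:
        raise DataError("relative fitness undefined: no successful pairs")
    return RelativeFitness(w=s / mean)
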