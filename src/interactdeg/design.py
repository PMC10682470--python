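"""Treatment-coded design matrices for one- and two-factor count models.

The three designs used throughout the package are ``~ diet``,
``~ diet + weeks`` and ``~ diet + weeks + diet:weeks``.  Factors are
dummy (treatment) coded against a reference level, so with references
``SD`` and week 3 the intercept is the log2 expression at (SD, week 3),
the ``diet[WD]`` column carries the diet main effect at the reference
week, ``weeks[w]`` the week-w effect under SD, and ``diet[WD]:weeks[w]``
the interaction: the amount by which the diet effect at week w differs
from the diet effect at the reference week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise invalid designs."""


def _sorted_levels(values) -> tuple:
    uniq = pd.unique(pd.Series(values))

    def key(v):
        try:
            return (0, float(v), "")
        except (TypeError, ValueError):
            return (1, 0.0, str(v))

    return tuple(sorted(uniq.tolist(), key=key))


@dataclass(frozen=True)
class Factor:
    """A categorical design factor.

    ``levels`` and ``reference`` may be left ``None`` and are then resolved
    from the metadata (levels sorted, numerically where possible; reference =
    first level, i.e. SD and the smallest week for the standard factors).
    """

    name: str
    levels: tuple | None = None
    reference: object | None = None

    def resolve(self, metadata: pd.DataFrame) -> "Factor":
        if self.name not in metadata.columns:
            raise DesignError(f"factor {self.name!r} not in metadata columns")
        levels = self.levels if self.levels is not None else _sorted_levels(metadata[self.name])
        reference = self.reference if self.reference is not None else levels[0]
        if reference not in levels:
            raise DesignError(f"reference {reference!r} not a level of {self.name!r}")
        observed = set(metadata[self.name])
        unknown = observed - set(levels)
        if unknown:
            raise DesignError(f"unknown level(s) {sorted(map(str, unknown))} for {self.name!r}")
        # reference first, remaining levels in declared order
        ordered = (reference,) + tuple(l for l in levels if l != reference)
        return Factor(self.name, ordered, reference)


@dataclass(frozen=True)
class DesignSpec:
    """Specification of the model design: factors plus optional interaction."""

    factors: tuple[Factor, ...]
    interaction: bool = False

    def __post_init__(self):
        if self.interaction and len(self.factors) != 2:
            raise DesignError("interaction designs require exactly two factors")

    # -- convenience constructors for the three standard designs -------------
    @classmethod
    def one_factor(cls, name: str = "diet", reference=None) -> "DesignSpec":
        return cls((Factor(name, reference=reference),), interaction=False)

    @classmethod
    def additive(cls, first: str = "diet", second: str = "weeks") -> "DesignSpec":
        return cls((Factor(first), Factor(second)), interaction=False)

    @classmethod
    def with_interaction(cls, first: str = "diet", second: str = "weeks") -> "DesignSpec":
        return cls((Factor(first), Factor(second)), interaction=True)

    def resolve(self, metadata: pd.DataFrame) -> "DesignSpec":
        return DesignSpec(tuple(f.resolve(metadata) for f in self.factors), self.interaction)

    def matrix(self, metadata: pd.DataFrame) -> pd.DataFrame:
        """Build the dummy-coded design matrix for the given samples."""
        resolved = self.resolve(metadata)
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
        dummies: dict[str, dict[object, np.ndarray]] = {}
        for factor in resolved.factors:
            dummies[factor.name] = {}
            for level in factor.levels[1:]:
                col = (metadata[factor.name] == level).to_numpy(float)
                cols[f"{factor.name}[{level}]"] = col
                dummies[factor.name][level] = col
        if resolved.interaction:
            f1, f2 = resolved.factors
            for l1, l2 in product(f1.levels[1:], f2.levels[1:]):
                cols[f"{f1.name}[{l1}]:{f2.name}[{l2}]"] = (
                    dummies[f1.name][l1] * dummies[f2.name][l2]
                )
        X = pd.DataFrame(cols, index=metadata.index)
        _check_full_rank(X, metadata, resolved)
        return X

    def interaction_columns(self, metadata: pd.DataFrame) -> list[str]:
        return [c for c in self.matrix(metadata).columns if ":" in c]


def _check_full_rank(X: pd.DataFrame, metadata: pd.DataFrame, spec: DesignSpec) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # diagnose: report empty factor-level combinations
    names = [f.name for f in spec.factors]
    empty: list[str] = []
    if len(names) == 2:
        observed = set(map(tuple, metadata[names].itertuples(index=False)))
        for combo in product(*(f.levels for f in spec.factors)):
            if combo not in observed:
                empty.append(str(dict(zip(names, combo))))
    detail = f"; empty design cell(s): {empty}" if empty else ""
    raise DesignError(
        f"design matrix is rank deficient (rank {rank} < {arr.shape[1]} columns){detail}"
    )


def design_cells(X: pd.DataFrame) -> list[np.ndarray]:
    """Group samples by identical design rows; returns index arrays per cell."""
    arr = X.to_numpy()
    _, inverse = np.unique(arr, axis=0, return_inverse=True)
    return [np.where(inverse == k)[0] for k in range(inverse.max() + 1)]
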