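"""Agreement weight matrices over the observed-category subset.

Weighted agreement coefficients penalize a disagreement between categories
k and l by 1 - w[k][l].  Four standard weighting schemes are provided; all
yield a symmetric matrix with unit diagonal and entries in [0, 1]:

identity
    w = 1 iff k == l (nominal data; AC2 reduces to AC1).
linear
    w = 1 - |k-l| / (Q-1).
quadratic
    w = 1 - (k-l)^2 / (Q-1)^2.
ordinal
    w = 1 - C(|k-l|+1, 2) / C(Q, 2), the pairs-combination weighting
    recommended for ordinal staging data.

Conservative category exclusion: stages never used by any observer in the
analyzed table are dropped from the alphabet before the weights are built
(:func:`observed_categories`), which shrinks Q and hence amplifies the
relative penalty for the discrepancies that did occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .exceptions import DegenerateAlphabetError, InsufficientDataError, ValidationError
from .study import RatingMatrix

KINDS = ("identity", "linear", "quadratic", "ordinal")


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric agreement weights over an ordered category list."""

    categories: tuple[str, ...]
    w: np.ndarray
    kind: str

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        q = len(self.categories)
        if self.w.shape != (q, q):
            raise ValueError("weight matrix shape does not match categories")

    @property
    def q(self) -> int:
        return len(self.categories)

    @property
    def total(self) -> float:
        """T_w, the sum of all weights."""
        return float(self.w.sum())

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.w, np.eye(self.q)))


def observed_categories(matrix: RatingMatrix) -> tuple[str, ...]:
    """Scheme categories restricted to those used in >= 1 non-NA cell.

    Order follows the scheme alphabet.  All-NA matrices have no observed
    categories and raise.
    """
    if matrix.scheme.is_continuous:
        raise ValidationError("observed_categories requires an ordinal matrix")
    seen = {v for row in matrix.cells for v in row if v is not None}
    if not seen:
        raise InsufficientDataError("matrix contains no non-NA cells")
    return tuple(c for c in matrix.scheme.categories if c in seen)


def _offdiag_weight(kind: str, d: int, q: int) -> float:
    if kind == "identity":
        return 0.0 if d else 1.0
    if kind == "linear":
        return 1.0 - d / (q - 1)
    if kind == "quadratic":
        return 1.0 - d * d / (q - 1) ** 2
    if kind == "ordinal":
        return 1.0 - comb(d + 1, 2) / comb(q, 2)
    raise ValueError(f"unknown weight kind {kind!r}; choose from {KINDS}")


def build_weights(categories, kind: str = "ordinal") -> WeightMatrix:
    """Build a Q x Q weight matrix of the given kind over ``categories``."""
    cats = tuple(categories)
    if kind not in KINDS:
        raise ValueError(f"unknown weight kind {kind!r}; choose from {KINDS}")
    q = len(cats)
    if q == 0:
        raise DegenerateAlphabetError("cannot build weights over an empty alphabet")
    if q == 1:
        if kind != "identity":
            raise DegenerateAlphabetError(
                "a single-category alphabet admits only identity weights"
            )
        return WeightMatrix(cats, np.ones((1, 1)), kind)
    idx = np.arange(q)
    d = np.abs(idx[:, None] - idx[None, :])
    w = np.vectorize(lambda dd: _offdiag_weight(kind, int(dd), q))(d).astype(float)
    return WeightMatrix(cats, w, kind)


def weights_for_matrix(
    matrix: RatingMatrix, kind: str = "ordinal", exclude_unobserved: bool = True
) -> WeightMatrix:
    """Weights for an analysis matrix, applying the category-exclusion rule."""
    cats = observed_categories(matrix) if exclude_unobserved else matrix.scheme.categories
    if len(cats) == 1 and kind != "identity":
        # a constant matrix: degenerate alphabet, identity is the only option
        return build_weights(cats, "identity")
    return build_weights(cats, kind)
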