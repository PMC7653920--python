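"""Quadratic least-squares adjustment between two scRNA-seq platforms.

When the same nominal cell type is profiled on two platforms (e.g. a 10x
3'-UMI run versus a plate-based protocol), their pseudo-bulk log-expression
scales differ systematically. The adjustment fits

    y = a*x^2 + b*x + c

by ordinary least squares over per-feature pseudo-bulk means of the shared
cell type (inner join on feature id), then maps the second platform's values
onto the first platform's scale. The fit is done on log-scale expression
(log2 of scaled counts plus one); no weighting, robust loss or clamping is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InputError


@dataclass
class PolyFit:
    """Coefficients of y = a*x^2 + b*x + c plus fit bookkeeping."""

    a: float
    b: float
    c: float
    n_points: int
    rss: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise InputError("non-finite coefficients")

    @property
    def coeffs(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def fit_quadratic(x, y) -> PolyFit:
    """Ordinary least squares on the monomial basis {x^2, x, 1}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise DegenerateDesignError("need >= 3 distinct x values for a quadratic")
    design = np.vstack([x ** 2, x, np.ones_like(x)]).T
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise DegenerateDesignError("rank-deficient design matrix")
    resid = y - design @ coef
    return PolyFit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                   n_points=len(x), rss=float(resid @ resid))


def apply_adjustment(fit: PolyFit, values) -> np.ndarray:
    """Element-wise y = a*x^2 + b*x + c; preserves the input's shape."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise InputError("non-finite input values")
    return fit.a * values ** 2 + fit.b * values + fit.c


def fit_platform_adjustment(reference: pd.Series, other: pd.Series) -> PolyFit:
    """Fit the adjustment from per-feature pseudo-bulk means of the same cell
    type on two platforms: ``other`` (x) is mapped onto the scale of
    ``reference`` (y). Features are paired by inner join on the index."""
    shared = reference.index.intersection(other.index)
    if len(shared) < 3:
        raise InputError("fewer than 3 shared features between platforms")
    return fit_quadratic(other.loc[shared].to_numpy(),
                         reference.loc[shared].to_numpy())


def adjust_profile(fit: PolyFit, profile: pd.Series) -> pd.Series:
    """Apply the fitted curve to a whole pseudo-bulk profile."""
    return pd.Series(apply_adjustment(fit, profile.to_numpy()),
                     index=profile.index)
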