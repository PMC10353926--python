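"""Natural cubic splines, the exposure-lag cross-basis, and related design matrices.

The exposure-response function along the temperature axis is a natural cubic
spline: cubic between knots, C2-continuous, and constrained to be linear
beyond the boundary knots.  The lag structure is an unconstrained set of
integer weekly lags (an indicator lag basis), so the cross-basis is one
exposure-spline block per lag and the overall cumulative exposure-response
curve is the plain sum of the lag-specific curves.

The basis here uses the classic truncated-power representation of natural
splines; it is not numerically identical to any particular statistical
package, but spans the same function space (verified in the test suite
against a generic constrained piecewise-cubic fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "CrossBasis",
    "natural_cubic_basis",
    "build_cross_basis",
    "reduction_transform",
    "time_spline",
    "spec_from_percentiles",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline on the temperature axis (degC).

    ``n_basis`` equals ``len(internal_knots) + 1`` (no intercept column):
    three internal knots therefore give the 4-dimensional basis used for the
    exposure-response function.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        bk = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if len(ik) < 1:
            raise ValueError("at least one internal knot is required")
        allk = (bk[0],) + ik + (bk[1],)
        if not all(a < b for a, b in zip(allk, allk[1:])):
            raise ValueError(
                f"knots must be strictly increasing with internal knots strictly "
                f"inside the boundary: {allk}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray(
            (self.boundary_knots[0],) + self.internal_knots + (self.boundary_knots[1],)
        )

    @property
    def n_basis(self) -> int:
        return len(self.internal_knots) + 1

    def to_dict(self) -> dict:
        return {
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "n_basis": self.n_basis,
        }


def spec_from_percentiles(
    temps: np.ndarray,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
) -> SplineSpec:
    """Knots at given percentiles of a temperature series, boundaries at min/max."""
    x = np.asarray(temps, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty temperature series")
    internal = tuple(np.percentile(x, percentiles))
    return SplineSpec(internal_knots=internal, boundary_knots=(x.min(), x.max()))


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(n, n_basis)`` matrix.  Outside the boundary knots every
    basis function continues linearly (zero second derivative), so
    evaluation is defined on the whole real line.  NaN in ``x`` propagates
    to NaN rows.

    Uses the truncated-power natural-spline basis: with knots
    ``k_1 < ... < k_K`` (boundaries included), the functions are ``x`` and
    ``d_j(x) - d_{K-1}(x)`` for ``j = 1..K-2`` where
    ``d_j(x) = [(x-k_j)_+^3 - (x-k_K)_+^3] / (k_K - k_j)``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = spec.all_knots
    K = knots.size

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [x]
    dlast = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dlast)
    return np.column_stack(cols)


@dataclass
class CrossBasis:
    """Lagged non-linear exposure design matrix.

    ``matrix`` is ``n_weeks x (n_basis * n_lags)`` in basis-major column
    order: all lags of basis function 1, then all lags of basis function 2,
    and so on.  Rows whose lagged exposures reach before the start of the
    series are NaN and flagged in ``valid``.
    """

    matrix: np.ndarray
    spec: SplineSpec
    lags: tuple[int, ...]
    column_order: str = "basis-major"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_basis(self) -> int:
        return self.spec.n_basis

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def n_columns(self) -> int:
        return self.n_basis * self.n_lags

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "lags": list(self.lags),
            "column_order": self.column_order,
            "n_rows": int(self.matrix.shape[0]),
        }


def build_cross_basis(
    temp: np.ndarray,
    spec: SplineSpec,
    lags: tuple[int, ...] = (0, 1, 2, 3),
) -> CrossBasis:
    """Cross-basis of a weekly temperature series with integer lags.

    Column ``b * n_lags + l`` holds basis function ``b`` evaluated at the
    series shifted back by ``lags[l]`` weeks.
    """
    temp = np.asarray(temp, dtype=float)
    lags = tuple(int(l) for l in lags)
    if any(l < 0 for l in lags):
        raise ValueError("lags must be non-negative")
    maxlag = max(lags)
    n = temp.size
    if n < maxlag + 1:
        raise ValueError(f"series of {n} weeks shorter than max lag {maxlag}")

    nb = spec.n_basis
    nl = len(lags)
    mat = np.full((n, nb * nl), np.nan)
    for li, lag in enumerate(lags):
        shifted = np.full(n, np.nan)
        if lag == 0:
            shifted[:] = temp
        else:
            shifted[lag:] = temp[:-lag]
        block = natural_cubic_basis(shifted, spec)  # NaN rows propagate
        for b in range(nb):
            mat[:, b * nl + li] = block[:, b]
    valid = ~np.isnan(mat).any(axis=1)
    return CrossBasis(matrix=mat, spec=spec, lags=lags, valid=valid)


def reduction_transform(cb: CrossBasis) -> np.ndarray:
    """Matrix summing cross-basis coefficients over lags.

    With basis-major column ordering the reduced (overall cumulative)
    coefficients are ``eta = M theta`` and covariance ``M V M^T`` with
    ``M = I_{n_basis} (kron) 1_{n_lags}^T``.
    """
    return np.kron(np.eye(cb.n_basis), np.ones((1, cb.n_lags)))


def time_spline(n_weeks: int, df_per_year: float = 8.0) -> np.ndarray:
    """Natural cubic spline of the week index for seasonal and long-term trends.

    Total degrees of freedom are ``round(df_per_year * n_weeks / 52.18)``
    (52.18 = mean number of ISO weeks per year); knots are equally spaced on
    the index.  Returns an ``(n_weeks, df)`` matrix without intercept.
    """
    if n_weeks < 52:
        raise ValueError("need at least one year of weeks")
    df = int(round(df_per_year * n_weeks / 52.18))
    if df < 3:
        raise ValueError(f"total df {df} < 3; increase df_per_year or series length")
    idx = np.arange(n_weeks, dtype=float)
    # df columns require df-1 internal knots between the boundary knots
    knots = np.linspace(0.0, n_weeks - 1.0, df + 1)
    spec = SplineSpec(internal_knots=tuple(knots[1:-1]), boundary_knots=(knots[0], knots[-1]))
    return natural_cubic_basis(idx, spec)
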