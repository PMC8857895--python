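"""Restricted cubic spline (natural spline) basis in Harrell's parameterisation.

With knots t_1 < ... < t_k the basis has k-1 columns: the identity (linear)
term plus k-2 nonlinear terms, each a combination of truncated cubes chosen
so that the fitted function is exactly linear beyond the boundary knots and
has continuous value, first and second derivative everywhere.  The nonlinear
terms are scaled by (t_k - t_1)^2 so their numeric range is comparable to the
linear term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "rcs_basis", "quantile_knots"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations (days on the changepoint-centred axis) for an RCS basis."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 3:
            raise ValueError(f"restricted cubic spline needs >=3 knots, got {len(knots)}")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    def column_names(self, prefix: str = "time") -> list[str]:
        return [f"{prefix}_{j + 1}" for j in range(self.n_basis)]


def rcs_basis(t, spec: SplineSpec | tuple) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at times ``t``.

    Returns an array of shape (len(t), k-1): column 0 is ``t`` itself and the
    remaining k-2 columns are the restricted nonlinear terms.  Every nonlinear
    column is identically zero for t at or below the first knot, and linear
    (second derivative zero) beyond the last knot.
    """
    if not isinstance(spec, SplineSpec):
        spec = SplineSpec(tuple(spec))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    kn = np.asarray(spec.knots)
    k = kn.size
    out = np.empty((t.size, k - 1))
    out[:, 0] = t
    scale = (kn[-1] - kn[0]) ** 2

    def tc3(knot: float) -> np.ndarray:
        return np.maximum(t - knot, 0.0) ** 3

    last_gap = kn[-1] - kn[-2]
    for j in range(k - 2):
        term = (
            tc3(kn[j])
            - tc3(kn[-2]) * (kn[-1] - kn[j]) / last_gap
            + tc3(kn[-1]) * (kn[-2] - kn[j]) / last_gap
        )
        out[:, j + 1] = term / scale
    return out


def quantile_knots(t, n_knots: int = 4) -> SplineSpec:
    """Knots at Harrell's recommended quantiles of the observed times."""
    t = np.asarray(t, dtype=float)
    placement = {
        3: (0.10, 0.50, 0.90),
        4: (0.05, 0.35, 0.65, 0.95),
        5: (0.05, 0.275, 0.50, 0.725, 0.95),
        6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
        7: (0.025, 0.1833, 0.3417, 0.5, 0.6583, 0.8167, 0.975),
    }
    if n_knots not in placement:
        raise ValueError(f"no quantile recommendation for {n_knots} knots")
    qs = np.quantile(t, placement[n_knots])
    return SplineSpec(tuple(qs))
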