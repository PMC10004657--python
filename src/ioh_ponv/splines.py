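"""Natural cubic spline basis with 3 degrees of freedom.

Truncated-power construction of the natural (restricted) cubic spline:
with knots xi_1 < ... < xi_K the basis columns are

    N_1(x) = x,    N_{j+1}(x) = d_j(x) - d_{K-1}(x),  j = 1..K-2,
    d_j(x) = [ (x - xi_j)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_j),

which is cubic between knots and exactly linear beyond the boundary
knots. With K = 4 knots (boundary at observed min/max, interior at the
33.3rd/66.7th percentiles) this yields the 3-df basis used for the
exposure, age, and surgery-duration terms. The span equals R's
``splines::ns`` basis for the same knots (up to an invertible linear
map), so fitted values and contrasts are identical.

When the data cannot support four distinct knots the basis degrades to
a single linear column and records that fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SplineBasis:
    """Frozen knot set; transforms values to basis coordinates.

    Refitting on held-out data must reuse the training knots, so the
    basis is a value object that serializes with the fit artifact.
    """

    knots: np.ndarray
    linear_fallback: bool = False
    df: int = field(init=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.linear_fallback:
            self.df = 1
        else:
            if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
                raise ValueError("need >= 3 strictly increasing knots")
            self.df = len(self.knots) - 1

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Map values to an (n, df) coordinate matrix."""
        x = np.asarray(x, dtype=float)
        if self.linear_fallback:
            return x[:, None].copy()
        k = self.knots
        K = len(k)

        def d(j: int) -> np.ndarray:
            return (np.clip(x - k[j], 0, None) ** 3
                    - np.clip(x - k[K - 1], 0, None) ** 3) / (k[K - 1] - k[j])

        cols = [x] + [d(j) - d(K - 2) for j in range(K - 2)]
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "linear_fallback": self.linear_fallback}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(knots=np.array(d["knots"], dtype=float),
                   linear_fallback=bool(d["linear_fallback"]))


def natural_spline_basis(
    x: np.ndarray,
    df: int = 3,
    knots: np.ndarray | None = None,
    interior_from: np.ndarray | None = None,
) -> tuple[SplineBasis, np.ndarray]:
    """Build a natural cubic basis from data and return its coordinates.

    Boundary knots sit at the observed min/max of ``x``; the df-1
    interior knots at equally spaced percentiles (33.3/66.7 for df=3) of
    ``interior_from`` when given (used for zero-inflated exposures,
    where interior knots come from the nonzero values) else of ``x``.
    Degrades to a single linear column when fewer than df+1 distinct
    knots are available.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("spline input contains non-finite values")
    if knots is not None:
        basis = SplineBasis(knots=np.asarray(knots, dtype=float))
        return basis, basis.transform(x)
    ref = x if interior_from is None else np.asarray(interior_from, dtype=float)
    if len(ref) == 0:
        ref = x
    probs = np.linspace(0, 100, df + 1)[1:-1]
    interior = np.percentile(ref, probs)
    cand = np.concatenate([[x.min()], interior, [x.max()]])
    if len(np.unique(cand)) < df + 1 or np.any(np.diff(cand) <= 0):
        logger.warning("degenerate knot set %s: falling back to a linear term", cand)
        basis = SplineBasis(knots=cand, linear_fallback=True)
    else:
        basis = SplineBasis(knots=cand)
    return basis, basis.transform(x)
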