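"""Local polynomial regression (loess) with tricube neighbourhood weights.

This is the smoother used to turn an observer's calibration trials into a
bias curve: at each query point a low-degree polynomial is fitted by
weighted least squares to the ``span`` fraction of nearest training points,
with tricube distance weights and a Gaussian (unweighted-residual) error
family.  The conventions follow R's ``stats::loess`` with
``surface = "direct"``: the neighbourhood radius at a query point is the
distance to the ``floor(span * n)``-th nearest training point, and points
at exactly that radius get zero weight only when the radius itself is zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LoessFit"]


class LoessFit:
    """Univariate loess fit ``y ~ x``.

    Parameters
    ----------
    x, y : array-like, shape (n,)
        Training abscissae and responses. ``x`` need not be sorted;
        duplicate abscissae are allowed.
    span : float
        Fraction of points entering each local fit (0 < span <= 1).
    degree : int
        Degree of the local polynomial (1 or 2).
    """

    def __init__(self, x, y, span: float = 0.75, degree: int = 2):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not 0.0 < span <= 1.0:
            raise ValueError(f"span must be in (0, 1], got {span}")
        if degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {degree}")
        n = x.size
        if n < degree + 2:
            raise ValueError(f"need at least {degree + 2} points, got {n}")
        if np.ptp(x) == 0.0:
            raise ValueError("x values are all identical; cannot fit")
        self.x = x
        self.y = y
        self.span = float(span)
        self.degree = int(degree)
        # number of points in each local neighbourhood, as in R loess
        self._k = int(np.clip(np.floor(span * n + 1e-9), degree + 1, n))

    # -- internals ---------------------------------------------------------

    def _local_coefs(self, x0: np.ndarray) -> np.ndarray:
        """Batched WLS coefficients of the local polynomial at each query.

        Returns an array of shape (nq, degree + 1); column 0 is the fitted
        value at the query point, column 1 the local slope (the basis is
        centred at the query point).
        """
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        nq = x0.size
        d = np.abs(self.x[None, :] - x0[:, None])          # (nq, n)
        # neighbourhood radius: k-th smallest distance per query
        h = np.partition(d, self._k - 1, axis=1)[:, self._k - 1]
        h = np.maximum(h, 1e-12 * max(1.0, float(np.ptp(self.x))))
        u = np.clip(d / h[:, None], 0.0, 1.0)
        w = (1.0 - u**3) ** 3                               # tricube

        # basis centred at the query and scaled by the neighbourhood radius:
        # keeps the normal equations well conditioned; beta_0 is the fitted
        # value and beta_1 / h the local slope.
        z = (self.x[None, :] - x0[:, None]) / h[:, None]
        p = self.degree + 1
        basis = np.stack([z**j for j in range(p)], axis=2)  # (nq, n, p)
        wb = w[:, :, None] * basis
        ata = np.einsum("qnp,qnr->qpr", wb, basis)          # (nq, p, p)
        atb = np.einsum("qnp,qn->qp", wb, np.broadcast_to(self.y, (nq, self.x.size)))
        # tiny relative ridge keeps degenerate neighbourhoods (heavy ties) solvable
        scale = np.einsum("qpp->q", ata) / p
        ata += (1e-12 * scale)[:, None, None] * np.eye(p)
        coefs = np.linalg.solve(ata, atb[:, :, None])[:, :, 0]
        coefs[:, 1:] /= h[:, None] ** np.arange(1, p)[None, :]
        return coefs

    # -- public API --------------------------------------------------------

    def predict(self, x0):
        """Loess prediction at ``x0`` (scalar or array)."""
        scalar = np.isscalar(x0) or np.ndim(x0) == 0
        out = self._local_coefs(x0)[:, 0]
        return float(out[0]) if scalar else out

    def predict_with_slope(self, x0):
        """Fitted value and local first derivative at ``x0``."""
        coefs = self._local_coefs(x0)
        scalar = np.isscalar(x0) or np.ndim(x0) == 0
        if scalar:
            return float(coefs[0, 0]), float(coefs[0, 1])
        return coefs[:, 0], coefs[:, 1]

    def residuals(self) -> np.ndarray:
        """Training residuals ``y - fitted`` at the training abscissae."""
        return self.y - self.predict(self.x)
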