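"""Low-rank thin-plate regression spline basis (1-D).

Construction: radial basis eta(r) = r^3 on the observed covariate values
(knots), null space {1, x}.  The smoothing penalty c'Ec is reduced to the
constraint space (T'c = 0), eigendecomposed, and the k-2 smoothest penalized
directions are kept; coefficients in the returned basis carry an iid N(0,
tau^2) smoothing prior because the penalty is absorbed into the basis scale.

The covariate is z-scored internally and penalized columns are normalized to
unit sample SD, so fits are invariant to affine rescaling of the covariate
axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ThinPlateBasis"]


class ThinPlateBasis:
    """Design-matrix builder for a penalized thin-plate-style smooth.

    Parameters
    ----------
    x : array
        Observed covariate values; unique values become knots.
    k : int
        Total basis dimension including the {1, x} null space; the study
        convention restricts smooths to 3 or 5 basis functions to avoid
        overfitting short annual series.
    """

    def __init__(self, x: np.ndarray, k: int):
        x = np.asarray(x, dtype=float)
        if k < 3:
            raise ValueError("k must be >= 3 (2 null-space + >=1 penalized)")
        if k > x.size - 2:
            raise ValueError(f"k={k} too large for n={x.size} observations")
        knots = np.unique(x)
        if knots.size < k:
            raise ValueError(
                f"k={k} exceeds the number of distinct covariate values "
                f"({knots.size})"
            )
        self.k = int(k)
        self.x_center = float(x.mean())
        self.x_scale = float(x.std(ddof=1)) or 1.0
        z_knots = (knots - self.x_center) / self.x_scale
        self.z_knots = z_knots

        n = z_knots.size
        E = np.abs(z_knots[:, None] - z_knots[None, :]) ** 3
        T = np.column_stack([np.ones(n), z_knots])
        # rank-k spectral truncation of the radial basis (dominant components)
        d, U = np.linalg.eigh(E)
        order = np.argsort(np.abs(d))[::-1][:k]
        Uk, Dk = U[:, order], d[order]
        # absorb the identifiability constraint T' c = 0 (c = Uk delta)
        A = T.T @ Uk  # 2 x k
        q, _ = np.linalg.qr(A.T, mode="complete")
        W = q[:, 2:]  # k x (k-2), basis of null(A)
        S = W.T @ (Dk[:, None] * W)
        S = 0.5 * (S + S.T)
        lam, P = np.linalg.eigh(S)
        lam = np.clip(np.abs(lam), 1e-10, None)
        # reparameterize so the penalty is the identity: coefficients carry
        # an iid N(0, tau^2) smoothing prior
        self._coef_map = Uk @ W @ (P / np.sqrt(lam)[None, :])
        # normalize penalized columns to unit SD on the training covariate
        pen = self._radial((x - self.x_center) / self.x_scale) @ self._coef_map
        scale = pen.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        self._coef_map = self._coef_map / scale[None, :]
        self._pen_center = (pen / scale[None, :]).mean(axis=0)

    def _radial(self, z: np.ndarray) -> np.ndarray:
        return np.abs(z[:, None] - self.z_knots[None, :]) ** 3

    def _radial_grad(self, z: np.ndarray) -> np.ndarray:
        d = z[:, None] - self.z_knots[None, :]
        return 3.0 * d * np.abs(d)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix [1, z, penalized columns] at covariate values x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x - self.x_center) / self.x_scale
        pen = self._radial(z) @ self._coef_map - self._pen_center[None, :]
        return np.column_stack([np.ones(z.size), z, pen])

    def design_grad(self, x: np.ndarray) -> np.ndarray:
        """d(design)/dx, row-wise, on the natural covariate scale."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x - self.x_center) / self.x_scale
        dpen = self._radial_grad(z) @ self._coef_map
        out = np.column_stack([np.zeros(z.size), np.ones(z.size), dpen])
        return out / self.x_scale
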