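"""Kernel functions and Gaussian convolution identities.

Everything downstream (bandwidth selection, bootstrap MISE, density
functionals) is expressed through closed-form Gaussian identities.  The only
kernel shipped is the standard normal one: kernel choice is of secondary
importance for the efficiency of the estimators, while the bandwidth matters
greatly, so the extra machinery of exchangeable kernels would buy nothing
here.  The :class:`Kernel` interface nevertheless keeps the door open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["Kernel", "GaussianKernel", "gaussian_kernel", "gaussian_selfconv_derivative"]

# Hermite-polynomial coefficients (probabilists', with the (-1)^r sign folded
# in) such that  d^r/dx^r phi(x) = poly_r(x) * phi(x)  for the standard
# normal density phi.
_HERMITE = {
    0: [1.0],
    1: [-1.0, 0.0],
    2: [1.0, 0.0, -1.0],
    3: [-1.0, 0.0, 3.0, 0.0],
    4: [1.0, 0.0, -6.0, 0.0, 3.0],
    5: [-1.0, 0.0, 10.0, 0.0, -15.0, 0.0],
    6: [1.0, 0.0, -15.0, 0.0, 45.0, 0.0, -15.0],
    7: [-1.0, 0.0, 21.0, 0.0, -105.0, 0.0, 105.0, 0.0],
    8: [1.0, 0.0, -28.0, 0.0, 210.0, 0.0, -420.0, 0.0, 105.0],
}


def normal_pdf_derivative(x, scale: float, order: int):
    """``order``-th derivative of the normal density with sd ``scale`` at x."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if order not in _HERMITE:
        raise ValueError(f"derivative order {order} not supported (0..8)")
    x = np.asarray(x, dtype=float)
    z = x / scale
    return np.polyval(_HERMITE[order], z) * norm.pdf(z) / scale ** (order + 1)


def gaussian_selfconv_derivative(x, scale: float, order: int):
    """Derivatives of the self-convolution of two scale-``scale`` Gaussians.

    ``(K_s * K_s)^{(order)}(x)`` equals the ``order``-th derivative of the
    normal density with standard deviation ``scale * sqrt(2)``.  This is the
    closed-form engine behind the exact bootstrap MISE and the integrated
    squared density derivatives: for a grouped sample with midpoints ``t`` and
    weights ``w``,

        int (fhat_h^{(r)})^2 = (-1)^r sum_ij w_i w_j (K_h*K_h)^{(2r)}(t_i-t_j).

    Parameters
    ----------
    x : array_like
        Evaluation points.
    scale : float
        Standard deviation of each convolved Gaussian; must be positive.
    order : int
        Even derivative order in {0, 2, 4, 6, 8}.
    """
    if order % 2:
        raise ValueError("order must be even")
    if order not in (0, 2, 4, 6, 8):
        raise ValueError("order must be one of 0, 2, 4, 6, 8")
    return normal_pdf_derivative(x, scale * math.sqrt(2.0), order)


@dataclass(frozen=True)
class Kernel:
    """A symmetric probability kernel with its antiderivative and constants.

    Attributes
    ----------
    name : str
    roughness : float
        ``R(K) = int K(u)^2 du``.
    second_moment : float
        ``mu_2(K) = int u^2 K(u) du``.
    cdf_roughness : float
        ``rho(K) = 2 int u K(u) KK(u) du`` with ``KK`` the antiderivative;
        this is the constant entering the smoothed-CDF bandwidth formula.
    """

    name: str
    roughness: float
    second_moment: float
    cdf_roughness: float

    def evaluate(self, u, derivative_order: int = 0):
        """Evaluate ``K`` or one of its derivatives.

        ``derivative_order = -1`` returns the antiderivative
        ``KK(u) = int_{-inf}^{u} K``; nonnegative orders return ``K^{(r)}``.
        """
        raise NotImplementedError

    def deriv_at_zero(self, order: int) -> float:
        return float(self.evaluate(0.0, order))


@dataclass(frozen=True)
class GaussianKernel(Kernel):
    name: str = "gaussian"
    roughness: float = field(default=1.0 / (2.0 * math.sqrt(math.pi)))
    second_moment: float = 1.0
    cdf_roughness: float = field(default=1.0 / math.sqrt(math.pi))

    def evaluate(self, u, derivative_order: int = 0):
        if derivative_order == -1:
            return norm.cdf(np.asarray(u, dtype=float))
        return normal_pdf_derivative(u, 1.0, derivative_order)


#: module-level singleton; the package's estimators all take this by default
gaussian_kernel = GaussianKernel()
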