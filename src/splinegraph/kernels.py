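"""Reproducing kernels for the cubic-spline RKHS on [0, 1] and discrete factors.

The continuous model space for each variable is the Sobolev space
``W2^2[0,1]`` decomposed as ``{1} ⊕ H0 ⊕ H1`` where ``H0 = span{k1}`` is the
unpenalized linear contrast and ``H1`` carries the smooth (penalized) part.
The kernels are built from scaled Bernoulli polynomials::

    k1(x) = x - 1/2
    k2(x) = (k1(x)^2 - 1/12) / 2
    k4(x) = (k1(x)^4 - k1(x)^2/2 + 7/240) / 24

    R0(x, z) = k1(x) k1(z)                      (linear contrast space)
    R1(x, z) = k2(x) k2(z) - k4(|x - z|)        (smooth space)

Binary (and generally L-level categorical) variables use the discrete RKHS
with the constant-orthogonal contrast kernel ``δ(x, z) - 1/L``.

Interaction spaces are tensor products: the kernel of ``H(α) ⊗ H(k)`` is the
product of the full constant-orthogonal kernels ``R̄ = R0 + R1`` (continuous)
or ``δ - 1/L`` (discrete) of the two coordinates.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "k1",
    "k2",
    "k4",
    "cubic_R0",
    "cubic_R1",
    "cubic_kernel",
    "binary_kernel",
    "interaction_kernel",
    "gram",
]


def _check_unit(x, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError(f"{name} must lie in [0, 1]; got values outside range")
    return np.clip(x, 0.0, 1.0)


def k1(x):
    """First scaled Bernoulli polynomial, ``x - 1/2``."""
    return _check_unit(x) - 0.5


def k2(x):
    """Second scaled Bernoulli polynomial, ``(k1^2 - 1/12) / 2``."""
    t = k1(x)
    return (t * t - 1.0 / 12.0) / 2.0


def k4(x):
    """Fourth scaled Bernoulli polynomial, ``(k1^4 - k1^2/2 + 7/240) / 24``."""
    t = k1(x)
    t2 = t * t
    return (t2 * t2 - t2 / 2.0 + 7.0 / 240.0) / 24.0


def cubic_R0(x, z):
    """Kernel of the linear-contrast space H0: ``k1(x) k1(z)``."""
    return k1(x) * k1(z)


def cubic_R1(x, z):
    """Kernel of the smooth space H1: ``k2(x) k2(z) - k4(|x - z|)``."""
    x = _check_unit(x)
    z = _check_unit(z, "z")
    return k2(x) * k2(z) - k4(np.abs(x - z))


def cubic_kernel(x, z):
    """Full constant-orthogonal kernel ``R̄ = R0 + R1`` of ``W2^2 ⊖ {1}``."""
    return cubic_R0(x, z) + cubic_R1(x, z)


def binary_kernel(x, z, levels: int = 2):
    """Constant-orthogonal contrast kernel ``δ(x, z) - 1/levels`` on a finite set.

    Row sums of the Gram matrix over all levels vanish, making the contrast
    space orthogonal to constants under the counting measure.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    return (x == z).astype(float) - 1.0 / levels


def marginal_kernel(x, z, kind: str):
    """Full constant-orthogonal kernel for one coordinate.

    ``kind`` is ``"continuous"`` (cubic spline on [0,1]) or ``"binary"``.
    """
    if kind == "continuous":
        return cubic_kernel(x, z)
    if kind == "binary":
        return binary_kernel(x, z)
    raise ValueError(f"unknown variable kind: {kind!r}")


def interaction_kernel(s, t, s2, t2, kind_a: str = "continuous",
                       kind_b: str = "continuous"):
    """Tensor-product kernel of the two-way interaction space.

    ``R((s, t), (s2, t2)) = R̄_a(s, s2) · R̄_b(t, t2)`` with ``R̄`` the full
    constant-orthogonal kernel of each coordinate.
    """
    return marginal_kernel(s, s2, kind_a) * marginal_kernel(t, t2, kind_b)


def gram(points, kernel) -> np.ndarray:
    """Symmetric Gram matrix of ``kernel`` over a 1-D point set."""
    pts = np.asarray(points, dtype=float)
    return kernel(pts[:, None], pts[None, :])
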