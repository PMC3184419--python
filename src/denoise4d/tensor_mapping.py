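"""Mapping the structure tensor to the control tensor.

The magnitude of the tensor is estimated without eigendecomposition by
repeated matrix squaring, T_mag = ||T^8||_F^(1/8) (close to the largest
eigenvalue), normalized over the dataset and passed through the M-function
(a soft noise threshold with optional overshoot).  The tensor shape is then
remapped by a matrix polynomial whose scalar transfer pushes small
eigenvalues towards 0 and large ones towards 1, so that highpass
information is restored only along well-defined structure.  A 2D
eigendecomposition-based mapping (M-function on the magnitude, mu-function
on the isotropy lambda2/lambda1) is provided as the classic reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_estimation import TensorField4D

__all__ = [
    "MappingParams",
    "MagnitudeField",
    "ControlTensorField",
    "m_function",
    "mu_function",
    "tensor_magnitude",
    "smoothstep_shape",
    "map_shape_matrices",
    "control_tensor",
    "eigen_transfer",
    "control_tensor_2d",
]


@dataclass(frozen=True)
class MappingParams:
    """Parameters of the magnitude and shape mapping.

    alpha : overshoot / transition parameter (>= 0); default 0.55
    beta : slope / softness parameter (> 0); default 1.5
    sigma : soft noise threshold, proportional to the data SNR (>= 0);
        default 0.1
    mag_exponent : even power used in the eigenvalue-free magnitude
        estimate (default 8; higher is closer to the largest eigenvalue)
    """

    alpha: float = 0.55
    beta: float = 1.5
    sigma: float = 0.1
    mag_exponent: int = 8

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        e = self.mag_exponent
        if e < 1 or (e & (e - 1)) != 0:
            raise ValueError("mag_exponent must be a power of 2")


@dataclass
class MagnitudeField:
    """Tensor magnitude, its dataset-normalized form, and the mapped gamma."""

    t_mag: np.ndarray
    gamma0: np.ndarray
    gamma: np.ndarray | None = None
    mag_max: float = 0.0


def m_function(gamma0, p: MappingParams):
    """Magnitude transfer gamma = g0^beta / (g0^(alpha+beta) + sigma^beta).

    Monotone near 0 with a soft threshold at sigma; for suitable alpha the
    curve overshoots 1 at intermediate magnitudes, amplifying structures
    slightly above the noise floor.
    """
    g0 = np.asarray(gamma0, dtype=float)
    if np.any(g0 < 0) or np.any(g0 > 1):
        raise ValueError("gamma0 must lie in [0, 1]")
    num = g0**p.beta
    den = g0 ** (p.alpha + p.beta) + p.sigma**p.beta
    out = np.zeros_like(g0)
    np.divide(num, den, out=out, where=den > 0)
    if out.ndim == 0:
        return float(out)
    return out


def mu_function(phi0, alpha: float, beta: float):
    """Isotropy transfer, monotone on [0, 1] with mu(alpha) = 1/2.

    phi = (phi0*(1-alpha))^beta / ((phi0*(1-alpha))^beta + (alpha*(1-phi0))^beta).
    alpha controls where the transition sits and beta its softness.
    """
    p0 = np.asarray(phi0, dtype=float)
    if np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("phi0 must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    a = (p0 * (1.0 - alpha)) ** beta
    b = (alpha * (1.0 - p0)) ** beta
    out = np.zeros_like(p0)
    np.divide(a, a + b, out=out, where=(a + b) > 0)
    if out.ndim == 0:
        return float(out)
    return out


def _matrix_power_pow2(mats: np.ndarray, exponent: int) -> np.ndarray:
    out = mats
    e = exponent
    while e > 1:
        out = out @ out
        e //= 2
    return out


def tensor_magnitude(tf: TensorField4D, exponent: int = 8,
                     mag_max: float | None = None) -> MagnitudeField:
    """Eigenvalue-free magnitude T_mag = ||T^exponent||_F^(1/exponent).

    The matrix power is built by repeated squaring (T2 = T*T, T4 = T2*T2,
    T8 = T4*T4 for the default exponent).  gamma0 = T_mag / max(T_mag),
    where the max is over the dataset unless a precomputed global maximum is
    supplied (slab-wise two-pass processing).  For a PSD tensor the result
    lies between lambda_1 and d^(1/(2*exponent)) * lambda_1.
    """
    if exponent < 1 or (exponent & (exponent - 1)) != 0:
        raise ValueError("exponent must be a power of 2")
    mats = tf.to_matrices()
    tp = _matrix_power_pow2(mats, exponent)
    t_mag = np.linalg.norm(tp, axis=(-2, -1)) ** (1.0 / exponent)
    mx = float(np.max(t_mag)) if mag_max is None else float(mag_max)
    gamma0 = np.zeros_like(t_mag) if mx <= 0 else np.clip(t_mag / mx, 0.0, 1.0)
    return MagnitudeField(t_mag=t_mag, gamma0=gamma0, mag_max=mx)


def smoothstep_shape(lam):
    """g(lambda) = lambda^2 * (3 - 2*lambda), the scalar form of the shape
    helper T_f = T^2 * (I + 2*(I - T))."""
    lam = np.asarray(lam, dtype=float)
    return lam**2 * (3.0 - 2.0 * lam)


def eigen_transfer(lam):
    """Scalar eigenvalue transfer of the full shape mapping.

    f(lambda) = 1 - (1 - g)^8 * (1 + 8*g) with g = lambda^2*(3 - 2*lambda).
    Fixed points at 0 and 1; monotone and S-shaped on [0, 1], so small
    eigenvalues shrink and large ones grow.  Serves as the
    eigendecomposition oracle for the matrix-polynomial path.
    """
    g = smoothstep_shape(lam)
    return 1.0 - (1.0 - g) ** 8 * (1.0 + 8.0 * g)


def map_shape_matrices(that: np.ndarray) -> np.ndarray:
    """Matrix-polynomial shape mapping of normalized tensors (*grid, d, d).

    T_f = T^2 * (I + 2*(I - T)); result = I - (I - T_f)^8 * (I + 8*T_f),
    with the 8th power formed by three squarings.  Shares the eigensystem of
    the input, applying ``eigen_transfer`` to each eigenvalue.
    """
    d = that.shape[-1]
    eye = np.eye(d)
    tf_ = (that @ that) @ (3.0 * eye - 2.0 * that)
    r = eye - tf_
    r8 = _matrix_power_pow2(r, 8)
    return eye - r8 @ (eye + 8.0 * tf_)


def control_tensor(tf: TensorField4D, mag: MagnitudeField,
                   p: MappingParams) -> "ControlTensorField":
    """Map the structure tensor field to the control tensor field.

    The tensor is normalized by its magnitude (shape only), passed through
    the matrix-polynomial shape mapping, and scaled by gamma from the
    M-function.  Voxels whose magnitude is at the noise floor (T_mag <=
    1e-12 * global max) get C = 0, which yields pure lowpass output there.
    """
    mats = tf.to_matrices()
    t_mag = mag.t_mag
    eps = 1e-12 * mag.mag_max
    live = t_mag > eps
    safe = np.where(live, t_mag, 1.0)
    that = mats / safe[..., None, None]
    mapped = map_shape_matrices(that)
    gamma = m_function(mag.gamma0, p)
    scale = np.where(live, gamma, 0.0)
    cmats = mapped * scale[..., None, None]
    ctf = TensorField4D.from_matrices(cmats, valid=tf.valid)
    return ControlTensorField(comps=ctf.comps, gamma=np.asarray(gamma),
                              dim=tf.dim, valid=tf.valid)


@dataclass
class ControlTensorField:
    """Mapped control tensor components plus the scalar magnitude map."""

    comps: np.ndarray
    gamma: np.ndarray
    dim: int = 4
    valid: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = tuple((0, n) for n in self.comps.shape[:-1])

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.comps.shape[:-1]

    def to_matrices(self) -> np.ndarray:
        return TensorField4D(self.comps, dim=self.dim,
                             valid=self.valid).to_matrices()


def control_tensor_2d(T: np.ndarray, p: MappingParams,
                      mag_max: float | None = None) -> np.ndarray:
    """Classic 2D eigen-based mapping C = gamma*e1*e1' + gamma*phi*e2*e2'.

    gamma0 = sqrt(lambda1^2 + lambda2^2) (normalized by ``mag_max`` when
    given), mapped by the M-function; phi0 = lambda2/lambda1 mapped by the
    mu-function.  A zero tensor maps to zero.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("expected a 2x2 symmetric tensor")
    lam, vec = np.linalg.eigh(T)
    l1, l2 = float(lam[1]), float(lam[0])  # eigh sorts ascending
    if l1 <= 0:
        return np.zeros((2, 2))
    e1, e2 = vec[:, 1], vec[:, 0]
    g0 = np.hypot(l1, l2)
    if mag_max is not None and mag_max > 0:
        g0 = g0 / mag_max
    g0 = min(g0, 1.0)
    gamma = m_function(g0, p)
    phi = mu_function(np.clip(l2 / l1, 0.0, 1.0), p.alpha, p.beta)
    return gamma * np.outer(e1, e1) + gamma * phi * np.outer(e2, e2)
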