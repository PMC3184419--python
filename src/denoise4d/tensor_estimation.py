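"""Local structure tensor estimation from monomial filter responses.

The monomial bank is applied to the volume (spatial or FFT backend), and the
unique components of the symmetric structure tensor are assembled from
pointwise products of the responses: the order-1 (odd) responses contribute
Q1*Q1' and the order-2 (even) responses Q2*Q2', whose sum is phase
invariant for simple signals.  The tensor field is then smoothed with a
small separable lowpass under certainty weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .conv_engine import (CertaintyMask, Volume4D, default_modes,
                          nonseparable_conv, normalized_conv, separable_conv)
from .filter_bank import (AXIS_NAMES, FilterBank, FrequencyGrid,
                          monomial_frequency_response, monomial_pairs,
                          tensor_component_count)

__all__ = [
    "MonomialResponses",
    "TensorField4D",
    "TENSOR_SMOOTH_KERNELS",
    "apply_monomial_bank",
    "assemble_tensor",
    "smooth_tensor",
]

# separable binomial smoothing weights: 5 taps on x, y, z and 3 on t
TENSOR_SMOOTH_KERNELS = (
    np.array([1, 4, 6, 4, 1]) / 16.0,
    np.array([1, 4, 6, 4, 1]) / 16.0,
    np.array([1, 4, 6, 4, 1]) / 16.0,
    np.array([1, 2, 1]) / 4.0,
)


@dataclass
class MonomialResponses:
    """Stacked real monomial responses, ordered (x, y, z, t, xx, xy, ..., tt).

    ``data`` has shape (n_filters, *grid); for dimensionality d the first d
    entries are the order-1 responses and the remaining d*(d+1)/2 the
    order-2 responses in m <= n pair order.
    """

    data: np.ndarray
    dim: int
    valid: tuple[tuple[int, int], ...]

    @property
    def names(self) -> list[str]:
        first = [AXIS_NAMES[i] for i in range(self.dim)]
        second = [AXIS_NAMES[m] + AXIS_NAMES[n] for m, n in monomial_pairs(self.dim)]
        return first + second

    def order1(self) -> np.ndarray:
        return self.data[: self.dim]

    def order2(self) -> np.ndarray:
        return self.data[self.dim:]


@dataclass
class TensorField4D:
    """Unique components of the symmetric structure tensor per voxel.

    ``comps`` has shape (*grid, n_comp) with n_comp = d*(d+1)/2, laid out in
    m <= n pair order; for d = 4 this is (xx, xy, xz, xt, yy, yz, yt, zz,
    zt, tt), i.e. components t1..t10 of the 4x4 tensor.
    """

    comps: np.ndarray
    dim: int = 4
    valid: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        nc = tensor_component_count(self.dim)
        if self.comps.shape[-1] != nc:
            raise ValueError(
                f"expected {nc} components for dim {self.dim}, "
                f"got {self.comps.shape[-1]}")
        if self.valid is None:
            self.valid = tuple((0, n) for n in self.comps.shape[:-1])

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.comps.shape[:-1]

    def to_matrices(self) -> np.ndarray:
        """Expand to full symmetric matrices of shape (*grid, d, d)."""
        d = self.dim
        out = np.empty(self.grid_shape + (d, d), dtype=self.comps.dtype)
        for k, (m, n) in enumerate(monomial_pairs(d)):
            out[..., m, n] = self.comps[..., k]
            out[..., n, m] = self.comps[..., k]
        return out

    @classmethod
    def from_matrices(cls, mats: np.ndarray, valid=None) -> "TensorField4D":
        d = mats.shape[-1]
        pairs = monomial_pairs(d)
        comps = np.stack([mats[..., m, n] for m, n in pairs], axis=-1)
        return cls(comps=comps, dim=d, valid=valid)


def apply_monomial_bank(vol: Volume4D, bank: FilterBank,
                        backend: str = "spatial") -> MonomialResponses:
    """Filter a volume with every kernel of the monomial bank.

    The spatial backend convolves the windowed kernels with the pipeline
    boundary modes (x, y, t circular, z valid); the FFT backend multiplies
    with the exact ideal responses on the volume's own grid, so every axis
    is circular and the whole extent stays valid.
    """
    if bank.kind != "monomial":
        raise ValueError("bank is not a monomial bank")
    if backend == "spatial":
        modes = default_modes(vol.periodic_t)
        support = bank.kernels[0].support
        for s, n, m in zip(support, vol.shape, modes):
            if m != "circular" and s > n:
                raise ValueError(
                    f"volume extent {vol.shape} smaller than kernel support {support}")
        fields = []
        valid = None
        for k in bank:
            r = nonseparable_conv(vol, k, modes)
            fields.append(r.values)
            valid = r.valid
        return MonomialResponses(np.stack(fields), dim=bank.dim, valid=valid)
    if backend == "fft":
        grid = FrequencyGrid(vol.shape)
        spec = scipy.fft.fftn(np.asarray(vol.values, dtype=float))
        fields = []
        for k in bank:
            resp = monomial_frequency_response(k.order, k.indices, grid,
                                               bank.radial)
            fields.append(scipy.fft.ifftn(spec * resp).real)
        return MonomialResponses(np.stack(fields), dim=bank.dim,
                                 valid=tuple((0, n) for n in vol.shape))
    raise ValueError(f"unknown backend {backend!r}")


def assemble_tensor(resp: MonomialResponses) -> TensorField4D:
    """Pointwise tensor assembly T = Q1*Q1' + Q2*Q2'.

    Component (m, n) is fr1[m]*fr1[n] plus the dot product of rows m and n
    of the symmetric order-2 response matrix; for d = 4 this expands to the
    ten explicit component formulas (t1 = fr1^2 + fr5^2 + fr6^2 + fr7^2 +
    fr8^2, and so on).
    """
    d = resp.dim
    pairs = monomial_pairs(d)
    pair_index = {p: i for i, p in enumerate(pairs)}
    o1 = resp.order1()
    o2 = resp.order2()

    def row(m: int, k: int) -> np.ndarray:
        # entry (m, k) of the symmetric order-2 response matrix
        return o2[pair_index[(m, k) if m <= k else (k, m)]]

    comps = []
    for m, n in pairs:
        t = o1[m] * o1[n]
        for k in range(d):
            t = t + row(m, k) * row(n, k)
        comps.append(t)
    return TensorField4D(np.stack(comps, axis=-1), dim=d, valid=resp.valid)


def smooth_tensor(tf: TensorField4D, cert: CertaintyMask | None = None,
                  kernels=TENSOR_SMOOTH_KERNELS, modes=None,
                  use_normalized_conv: bool = True) -> TensorField4D:
    """Smooth each tensor component with the separable binomial lowpass.

    With certainty weighting (normalized convolution) the borders along the
    valid z-range keep their extent; without it the valid interval shrinks
    by the kernel half-widths.  Componentwise smoothing trivially preserves
    tensor symmetry.
    """
    if tf.dim != 4:
        raise ValueError("smooth_tensor operates on 4D tensor fields")
    grid = tf.grid_shape
    if modes is None:
        modes = default_modes(True)
    if cert is None:
        cert = CertaintyMask(np.ones(grid))
    out = np.empty_like(tf.comps, dtype=float)
    for k in range(tf.comps.shape[-1]):
        volk = Volume4D(tf.comps[..., k], valid=tf.valid)
        if use_normalized_conv:
            sm, _ = normalized_conv(volk, cert, [np.asarray(kk) for kk in kernels],
                                    modes)
        else:
            sm = separable_conv(volk, kernels, modes)
        out[..., k] = sm.values
        new_valid = sm.valid
    return TensorField4D(out, dim=4, valid=new_valid)
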