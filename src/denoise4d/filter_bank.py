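"""Monomial and reconstruction filter banks with lognormal radial profiles.

The tensor-estimation bank consists of polynomial ("monomial") filters whose
directional frequency response is a product of unit-frequency components:
order-1 filters respond as -i*R(rho)*u_m (odd, edge-like structure) and
order-2 filters as R(rho)*u_m*u_n (even, line-like structure).  In 4D this
gives 4 + 10 = 14 filters; the reconstruction bank is one isotropic lowpass
plus the 10 second-order highpass filters (11 total).

Ideal responses are defined on a full frequency grid (used directly by the
FFT filtering backend); small spatial kernels for the spatial backend are
realized by windowed frequency sampling of the ideal response.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import scipy.fft

AXIS_NAMES = "xyzt"

__all__ = [
    "AXIS_NAMES",
    "RadialSpec",
    "FrequencyGrid",
    "FilterKernel",
    "FilterBank",
    "lognormal_radial",
    "monomial_frequency_response",
    "quadrature_frequency_response",
    "reconstruction_lowpass_response",
    "reconstruction_highpass_response",
    "design_spatial_kernel",
    "build_monomial_bank",
    "build_reconstruction_bank",
    "monomial_pairs",
    "tensor_component_count",
    "save_bank",
    "load_bank",
]


def tensor_component_count(dim: int) -> int:
    """Number of unique components of a symmetric dim x dim tensor.

    This is also the minimum number of filters needed to estimate the local
    structure tensor (10 in 4D).
    """
    return dim * (dim + 1) // 2


def monomial_pairs(dim: int) -> list[tuple[int, int]]:
    """Ordered (m, n) index pairs, m <= n, for the second-order filters."""
    return [(m, n) for m in range(dim) for n in range(m, dim)]


@dataclass(frozen=True)
class RadialSpec:
    """Lognormal radial profile R(rho) = exp(C * ln^2(rho / u0)).

    Parameters
    ----------
    u0 : float
        Centre frequency in radians per sample, 0 < u0 <= pi.
        Default 3*pi/5.
    bandwidth : float
        Relative bandwidth in octaves (> 0).  Default 2.5.

    The exponent constant C = -4 / (bandwidth^2 * ln 2) makes the profile
    reach amplitude 1/2 exactly half a bandwidth (in octaves) away from u0.
    """

    u0: float = 3.0 * math.pi / 5.0
    bandwidth: float = 2.5

    def __post_init__(self) -> None:
        if not (0.0 < self.u0 <= math.pi):
            raise ValueError(f"u0 must be in (0, pi], got {self.u0}")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")

    @property
    def C_exp(self) -> float:
        return -4.0 / (self.bandwidth**2 * math.log(2.0))


def lognormal_radial(rho, spec: RadialSpec):
    """Evaluate the lognormal radial profile; 0 at rho = 0 by continuity."""
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho must be finite")
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    out = np.zeros_like(rho)
    pos = rho > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(spec.C_exp * np.log(rho[pos] / spec.u0) ** 2)
    if out.ndim == 0:
        return float(out)
    return out


class FrequencyGrid:
    """Angular frequency coordinates of an FFT grid (DC at index 0).

    Per-axis coordinates lie in (-pi, pi] (the Nyquist bin of an even-length
    axis is assigned +pi).  ``rho`` is the radial magnitude and ``unit(n)``
    the n-th unit-direction component, defined as 0 at the DC bin.
    """

    def __init__(self, shape: Sequence[int]):
        self.shape = tuple(int(n) for n in shape)
        if any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        self.ndim = len(self.shape)
        coords = []
        for ax, n in enumerate(self.shape):
            u = 2.0 * math.pi * scipy.fft.fftfreq(n)
            u[u == -math.pi] = math.pi
            sh = [1] * self.ndim
            sh[ax] = n
            coords.append(u.reshape(sh))
        self.coords = coords
        self._rho: np.ndarray | None = None

    @property
    def rho(self) -> np.ndarray:
        if self._rho is None:
            sq = np.zeros(self.shape)
            for c in self.coords:
                sq = sq + c**2
            self._rho = np.sqrt(sq)
        return self._rho

    def unit(self, axis: int) -> np.ndarray:
        rho = self.rho
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.broadcast_to(self.coords[axis], self.shape) / rho
        u = np.where(rho > 0, u, 0.0)
        return u


def monomial_frequency_response(order: int, indices, grid: FrequencyGrid,
                                spec: RadialSpec) -> np.ndarray:
    """Ideal monomial response on the grid.

    Order 1 returns the purely imaginary field -i*R(rho)*u_m (odd; its
    spatial kernel is real and odd); order 2 returns the real even field
    R(rho)*u_m*u_n.  The DC bin is exactly zero.
    """
    indices = tuple(int(i) for i in np.atleast_1d(indices))
    if any(i < 0 or i >= grid.ndim for i in indices):
        raise ValueError(f"indices {indices} invalid for a {grid.ndim}D grid")
    R = lognormal_radial(grid.rho, spec)
    if order == 1:
        (m,) = indices
        return -1j * R * grid.unit(m)
    if order == 2:
        m, n = indices
        return R * grid.unit(m) * grid.unit(n)
    raise ValueError(f"order must be 1 or 2, got {order}")


def quadrature_frequency_response(direction, grid: FrequencyGrid,
                                  spec: RadialSpec) -> np.ndarray:
    """Reference quadrature response R(rho)*(u.n)^2 on the half-space u.n > 0.

    The filter is zero in the opposite half of the frequency domain, which is
    what makes the magnitude of its (complex) spatial response phase
    invariant.  Provided as a reference constructor only; the production
    tensor path uses the monomial bank.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("direction vector must be nonzero")
    d = d / nrm
    R = lognormal_radial(grid.rho, spec)
    proj = np.zeros(grid.shape)
    for ax in range(grid.ndim):
        proj = proj + grid.unit(ax) * d[ax]
    return np.where(proj > 0, R * proj**2, 0.0)


def reconstruction_lowpass_response(grid: FrequencyGrid) -> np.ndarray:
    """Isotropic lowpass L(rho) = cos^2(rho/2), clipped to 0 beyond rho = pi."""
    rho = grid.rho
    return np.where(rho <= math.pi, np.cos(rho / 2.0) ** 2, 0.0)


def reconstruction_highpass_response(m: int, n: int,
                                     grid: FrequencyGrid) -> np.ndarray:
    """Directional highpass (1 - L(rho)) * u_m * u_n.

    Together with the lowpass these satisfy L + (1-L) * sum_m u_m^2 = 1 at
    every bin, so reconstruction with an identity control tensor is allpass.
    """
    L = reconstruction_lowpass_response(grid)
    return (1.0 - L) * grid.unit(m) * grid.unit(n)


@dataclass
class FilterKernel:
    """A small real spatial kernel with its bank metadata."""

    order: int
    indices: tuple[int, ...]
    values: np.ndarray
    parity: str  # "even" | "odd"
    band: str    # "bandpass" | "lowpass" | "highpass"

    @property
    def support(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def name(self) -> str:
        if self.order == 0:
            return "lp"
        return "".join(AXIS_NAMES[i] for i in self.indices)


@dataclass
class FilterBank:
    """A set of FilterKernel plus the shared radial spec and dimensionality."""

    kernels: list[FilterKernel]
    radial: RadialSpec
    dim: int
    kind: str  # "monomial" | "reconstruction"

    @property
    def n_filters(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)


def _raised_cosine_window(support: Sequence[int]) -> np.ndarray:
    """Separable raised-cosine taper over an odd cubic support."""
    axes = []
    for s in support:
        m = (s - 1) // 2
        d = np.arange(-m, m + 1)
        axes.append(0.5 * (1.0 + np.cos(math.pi * d / (m + 1))))
    w = axes[0]
    for a in axes[1:]:
        w = np.multiply.outer(w, a)
    return w


def _dtft_at(kernel: np.ndarray, freq) -> complex:
    """DTFT of a centred kernel at one frequency vector (radians/sample)."""
    val = kernel.astype(complex)
    for ax, (n, u) in enumerate(zip(kernel.shape, freq)):
        m = (n - 1) // 2
        sh = [1] * kernel.ndim
        sh[ax] = n
        val = val * np.exp(-1j * u * np.arange(-m, m + 1)).reshape(sh)
    return complex(val.sum())


def design_spatial_kernel(freq_response: np.ndarray, support, *,
                          order: int, indices=(), band: str = "bandpass",
                          window: str = "raised_cosine",
                          calibrate=None) -> FilterKernel:
    """Realize an ideal frequency response as a small windowed spatial kernel.

    The ideal response (FFT layout, DC at index 0) is inverse transformed,
    centred, tapered with a separable raised-cosine window over the requested
    odd support, and cropped.  The parity of the ideal response is enforced
    exactly by symmetrization; bandpass/highpass kernels are driven to zero
    coefficient sum (odd kernels sum to zero by symmetry already; for even
    kernels the mean is subtracted) and the lowpass kernel is normalized to
    unit sum.

    ``calibrate``, when given as (frequency vector, ideal complex response),
    rescales the windowed kernel so its realized response matches the ideal
    at that point.  The bank builders calibrate every bandpass kernel at its
    principal direction on the filter's centre frequency, which equalizes
    the passband gains of the odd and even filters — the property the tensor
    assembly relies on for phase invariance.
    """
    if window != "raised_cosine":
        raise ValueError(f"unknown window {window!r}")
    freq_response = np.asarray(freq_response)
    support = tuple(int(s) for s in np.broadcast_to(support, (freq_response.ndim,)))
    for s, n in zip(support, freq_response.shape):
        if s % 2 == 0:
            raise ValueError(f"support must be odd, got {support}")
        if s > n:
            raise ValueError(f"support {support} exceeds design grid {freq_response.shape}")

    spatial = scipy.fft.ifftn(freq_response)
    spatial = scipy.fft.fftshift(spatial).real
    centre = tuple(n // 2 for n in freq_response.shape)
    sl = tuple(slice(c - (s - 1) // 2, c + (s - 1) // 2 + 1)
               for c, s in zip(centre, support))
    k = spatial[sl] * _raised_cosine_window(support)

    parity = "odd" if order == 1 else "even"
    flipped = k[tuple(slice(None, None, -1) for _ in support)]
    k = 0.5 * (k - flipped) if parity == "odd" else 0.5 * (k + flipped)

    if band == "lowpass":
        k = k / k.sum()
    elif parity == "even":  # bandpass / highpass: enforce zero DC response
        k = k - k.sum() / k.size

    if calibrate is not None:
        freq, ideal = calibrate
        actual = _dtft_at(k, freq)
        if abs(actual) > 0:
            scale = (complex(ideal) * actual.conjugate()).real / abs(actual) ** 2
            k = k * scale
    return FilterKernel(order=order, indices=tuple(indices), values=k,
                        parity=parity, band=band)


def _design_grid_size(support: int) -> int:
    # comfortably larger than the support so circular aliasing of the ideal
    # impulse response is negligible before windowing
    return max(4 * support - 4, 24)


@lru_cache(maxsize=8)
def _build_monomial_bank_cached(dim: int, u0: float, bandwidth: float,
                                support: int) -> FilterBank:
    spec = RadialSpec(u0=u0, bandwidth=bandwidth)
    n = _design_grid_size(support)
    grid = FrequencyGrid((n,) * dim)
    kernels = []
    for m in range(dim):
        resp = monomial_frequency_response(1, (m,), grid, spec)
        freq = np.zeros(dim)
        freq[m] = spec.u0
        kernels.append(design_spatial_kernel(resp, support, order=1,
                                             indices=(m,), band="bandpass",
                                             calibrate=(freq, -1j)))
    for m, nn in monomial_pairs(dim):
        resp = monomial_frequency_response(2, (m, nn), grid, spec)
        freq = np.zeros(dim)
        if m == nn:
            freq[m] = spec.u0
            cal = (freq, 1.0)
        else:
            freq[m] = freq[nn] = spec.u0 / math.sqrt(2)
            cal = (freq, 0.5)
        kernels.append(design_spatial_kernel(resp, support, order=2,
                                             indices=(m, nn), band="bandpass",
                                             calibrate=cal))
    return FilterBank(kernels=kernels, radial=spec, dim=dim, kind="monomial")


def build_monomial_bank(dim: int, spec: RadialSpec | None = None,
                        support: int = 7) -> FilterBank:
    """All order-1 and order-2 monomial kernels: dim + dim*(dim+1)/2 filters.

    Filter order matches the tensor assembly convention: the dim order-1
    filters (x, y, z, t) followed by the order-2 filters (xx, xy, ..., tt).
    Default support is 7 per axis.
    """
    if dim not in (2, 3, 4):
        raise ValueError(f"dim must be 2, 3 or 4, got {dim}")
    spec = spec or RadialSpec()
    return _build_monomial_bank_cached(dim, spec.u0, spec.bandwidth, int(support))


@lru_cache(maxsize=8)
def _build_reconstruction_bank_cached(dim: int, support: int) -> FilterBank:
    n = _design_grid_size(support)
    grid = FrequencyGrid((n,) * dim)
    spec = RadialSpec()  # metadata only; reconstruction uses the cos^2 split
    kernels = [design_spatial_kernel(
        reconstruction_lowpass_response(grid).astype(complex), support,
        order=0, indices=(), band="lowpass")]
    for m, nn in monomial_pairs(dim):
        resp = reconstruction_highpass_response(m, nn, grid)
        kernels.append(design_spatial_kernel(resp.astype(complex), support,
                                             order=2, indices=(m, nn),
                                             band="highpass"))
    return FilterBank(kernels=kernels, radial=spec, dim=dim,
                      kind="reconstruction")


def build_reconstruction_bank(dim: int, support: int = 11) -> FilterBank:
    """One zeroth-order lowpass plus dim*(dim+1)/2 directional highpass kernels.

    The radial split is L(rho) = cos^2(rho/2) for the lowpass and 1 - L(rho)
    for the highpass filters, so that weighting the highpass responses with an
    identity control tensor restores an exact allpass.  Default support is 11
    per axis.
    """
    if dim not in (2, 3, 4):
        raise ValueError(f"dim must be 2, 3 or 4, got {dim}")
    return _build_reconstruction_bank_cached(dim, int(support))


def save_bank(bank: FilterBank, path) -> None:
    """Write a bank to an HDF5 container (bit-exact round trip)."""
    import h5py

    meta = {"dim": bank.dim, "kind": bank.kind,
            "u0": bank.radial.u0, "bandwidth": bank.radial.bandwidth}
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps(meta)
        for i, k in enumerate(bank.kernels):
            ds = f.create_dataset(f"kernel_{i:02d}", data=k.values)
            ds.attrs["order"] = k.order
            ds.attrs["indices"] = list(k.indices)
            ds.attrs["parity"] = k.parity
            ds.attrs["band"] = k.band


def load_bank(path) -> FilterBank:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        kernels = []
        for name in sorted(k for k in f.keys() if k.startswith("kernel_")):
            ds = f[name]
            kernels.append(FilterKernel(
                order=int(ds.attrs["order"]),
                indices=tuple(int(i) for i in ds.attrs["indices"]),
                values=ds[()],
                parity=str(ds.attrs["parity"]),
                band=str(ds.attrs["band"])))
    return FilterBank(kernels=kernels,
                      radial=RadialSpec(u0=meta["u0"], bandwidth=meta["bandwidth"]),
                      dim=int(meta["dim"]), kind=meta["kind"])
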