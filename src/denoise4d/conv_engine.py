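"""Filtering primitives and valid-region accounting.

Separable and nonseparable nD convolution with per-axis boundary modes
("circular" or "valid"), FFT-based circular filtering, certainty-weighted
normalized convolution, and the slice-bookkeeping planner that tracks how
many z-slices survive the full filtering chain.

Outputs keep the full grid extent; the per-axis ``valid`` intervals of the
returned Volume4D record where the result depends only on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.ndimage
import scipy.signal

from .filter_bank import FilterKernel

__all__ = [
    "Volume4D",
    "CertaintyMask",
    "default_modes",
    "separable_conv",
    "nonseparable_conv",
    "fft_filter",
    "fft_filter_pair",
    "normalized_conv",
    "ValidSlicePlan",
    "plan_valid_slices",
    "z_validity_intervals",
]

DEFAULT_SPACING = (0.75, 0.75, 0.75, 1.0)


@dataclass
class Volume4D:
    """A 4D scalar field (x, y, z, t) with spacing and validity metadata.

    ``valid`` holds one half-open index interval per axis; ``periodic_t``
    marks the time axis as circular (natural for cardiac-gated data, where
    the cycle is periodic).
    """

    values: np.ndarray
    spacing: tuple[float, ...] = DEFAULT_SPACING
    valid: tuple[tuple[int, int], ...] | None = None
    periodic_t: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected a 4D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.valid is None:
            self.valid = tuple((0, n) for n in self.values.shape)
        self.valid = tuple((int(a), int(b)) for a, b in self.valid)
        for (a, b), n in zip(self.valid, self.values.shape):
            if not (0 <= a <= b <= n):
                raise ValueError(f"valid interval ({a},{b}) outside [0,{n})")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def valid_slices(self) -> tuple[slice, ...]:
        return tuple(slice(a, b) for a, b in self.valid)


@dataclass
class CertaintyMask:
    """Per-voxel certainty in [0, 1] on the same grid as a Volume4D."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("certainty values must lie in [0, 1]")


def default_modes(periodic_t: bool = True, circular_xy: bool = True):
    """Pipeline boundary modes: x, y circular, z valid, t per the flag."""
    return ("circular" if circular_xy else "valid",
            "circular" if circular_xy else "valid",
            "valid",
            "circular" if periodic_t else "valid")


def _check_modes(modes, ndim: int):
    modes = tuple(modes)
    if len(modes) != ndim:
        raise ValueError(f"need {ndim} axis modes, got {len(modes)}")
    for m in modes:
        if m not in ("circular", "valid"):
            raise ValueError(f"unknown axis mode {m!r}")
    return modes


def _shrink_valid(valid, halfwidths, modes):
    out = []
    for (a, b), h, m in zip(valid, halfwidths, modes):
        if m == "circular" or h == 0:
            out.append((a, b))
        else:
            a2, b2 = a + h, b - h
            if a2 >= b2:
                a2 = b2 = min(b, max(a, a2))
            out.append((a2, b2))
    return tuple(out)


def separable_conv(vol: Volume4D, kernels: Sequence, modes) -> Volume4D:
    """Sequential per-axis 1D convolution.

    ``kernels`` holds one odd-length 1D coefficient list per axis (use [1]
    for axes that should pass through).  Valid intervals shrink by the kernel
    half-width on each non-circular axis.
    """
    modes = _check_modes(modes, vol.values.ndim)
    out = np.asarray(vol.values, dtype=float)
    halfwidths = []
    for ax, (k, m) in enumerate(zip(kernels, modes)):
        k = np.asarray(k, dtype=float)
        if k.ndim != 1 or k.size % 2 == 0:
            raise ValueError(f"axis {ax}: kernel must be 1D with odd length")
        h = (k.size - 1) // 2
        if m != "circular" and k.size > out.shape[ax]:
            raise ValueError(f"axis {ax}: kernel longer than axis extent")
        halfwidths.append(h)
        if k.size > 1:
            nd_mode = "wrap" if m == "circular" else "constant"
            out = scipy.ndimage.convolve1d(out, k, axis=ax, mode=nd_mode, cval=0.0)
    return Volume4D(out, spacing=vol.spacing,
                    valid=_shrink_valid(vol.valid, halfwidths, modes),
                    periodic_t=vol.periodic_t)


def _kernel_array(kernel) -> np.ndarray:
    if isinstance(kernel, FilterKernel):
        return kernel.values
    return np.asarray(kernel, dtype=float)


def nonseparable_conv(vol: Volume4D, kernel, modes) -> Volume4D:
    """Direct nD convolution with per-axis boundary modes.

    Circular axes are wrap-padded by the kernel reach before the convolution
    and cropped afterwards; valid axes zero-pad and the valid interval
    shrinks by the kernel half-width.
    """
    k = _kernel_array(kernel)
    if k.ndim != vol.values.ndim:
        raise ValueError("kernel dimensionality does not match volume")
    if any(s % 2 == 0 for s in k.shape):
        raise ValueError(f"kernel support must be odd per axis, got {k.shape}")
    modes = _check_modes(modes, vol.values.ndim)
    halfwidths = [(s - 1) // 2 for s in k.shape]
    for ax, (h, m) in enumerate(zip(halfwidths, modes)):
        if m != "circular" and k.shape[ax] > vol.values.shape[ax]:
            raise ValueError(f"axis {ax}: kernel longer than axis extent")

    pad = [(h, h) if m == "circular" else (0, 0)
           for h, m in zip(halfwidths, modes)]
    padded = np.pad(np.asarray(vol.values, dtype=float), pad, mode="wrap")
    res = scipy.signal.fftconvolve(padded, k, mode="same")
    crop = tuple(slice(p[0], p[0] + n) for p, n in zip(pad, vol.values.shape))
    return Volume4D(res[crop], spacing=vol.spacing,
                    valid=_shrink_valid(vol.valid, halfwidths, modes),
                    periodic_t=vol.periodic_t)


def _kernel_to_response(kernel: np.ndarray, shape) -> np.ndarray:
    """Zero-pad a centred spatial kernel to the grid and move its centre to
    index 0 (the FFT shift that circular filtering requires)."""
    k = np.asarray(kernel)
    if any(ks > n for ks, n in zip(k.shape, shape)):
        raise ValueError(f"kernel {k.shape} larger than grid {shape}")
    padded = np.zeros(shape, dtype=complex if np.iscomplexobj(k) else float)
    padded[tuple(slice(0, s) for s in k.shape)] = k
    centre = [(s - 1) // 2 for s in k.shape]
    padded = np.roll(padded, [-c for c in centre], axis=range(len(shape)))
    return scipy.fft.fftn(padded)


def fft_filter(vol: Volume4D, response: np.ndarray | None = None,
               kernel=None) -> Volume4D:
    """Circular filtering on all axes via the FFT.

    Supply either a full-grid frequency ``response`` (FFT layout, DC at
    index 0) or a small spatial ``kernel`` which is zero-padded and
    centre-shifted first.  Returns the real part; the whole extent is valid.
    """
    if (response is None) == (kernel is None):
        raise ValueError("supply exactly one of response or kernel")
    if kernel is not None:
        response = _kernel_to_response(_kernel_array_complex(kernel), vol.shape)
    response = np.asarray(response)
    if response.shape != vol.shape:
        raise ValueError(f"response shape {response.shape} != volume {vol.shape}")
    spec = scipy.fft.fftn(np.asarray(vol.values, dtype=float))
    out = scipy.fft.ifftn(spec * response).real
    return Volume4D(out, spacing=vol.spacing, valid=None,
                    periodic_t=vol.periodic_t)


def _kernel_array_complex(kernel) -> np.ndarray:
    if isinstance(kernel, FilterKernel):
        return kernel.values
    return np.asarray(kernel)


def fft_filter_pair(vol: Volume4D, kernel_a, kernel_b) -> tuple[Volume4D, Volume4D]:
    """Apply two real kernels with a single complex FFT filtering pass.

    The kernels are packed as the real and imaginary parts of one complex
    kernel; for a real input the two responses separate as the real and
    imaginary parts of the filtered result.
    """
    ka = _kernel_array(kernel_a)
    kb = _kernel_array(kernel_b)
    if ka.shape != kb.shape:
        raise ValueError("paired kernels must share a support")
    response = _kernel_to_response(ka + 1j * kb, vol.shape)
    spec = scipy.fft.fftn(np.asarray(vol.values, dtype=float))
    out = scipy.fft.ifftn(spec * response)
    mk = lambda v: Volume4D(v.copy(), spacing=vol.spacing, valid=None,
                            periodic_t=vol.periodic_t)
    return mk(out.real), mk(out.imag)


def _conv_any(values: np.ndarray, kernel, modes) -> np.ndarray:
    """Convolve with either a per-axis separable kernel list or an nD array.

    Valid-mode axes shorter than the kernel are zero-padded (certainty
    weighting gives such borders a meaning that plain convolution lacks).
    """
    separable = isinstance(kernel, (list, tuple)) and not np.isscalar(kernel[0])
    if separable:
        sizes = [np.asarray(k).size for k in kernel]
    else:
        sizes = list(np.asarray(kernel).shape)
    pad = [(0, max(0, s - n)) if m != "circular" else (0, 0)
           for s, n, m in zip(sizes, values.shape, modes)]
    padded = np.pad(values, pad) if any(p != (0, 0) for p in pad) else values
    vol = Volume4D(padded, periodic_t=True)
    if separable:
        out = separable_conv(vol, kernel, modes).values
    else:
        out = nonseparable_conv(vol, np.asarray(kernel, dtype=float), modes).values
    if padded is not values:
        out = out[tuple(slice(0, n) for n in values.shape)]
    return out


def normalized_conv(signal: Volume4D, cert: CertaintyMask, kernel,
                    modes) -> tuple[Volume4D, np.ndarray]:
    """Certainty-weighted filtering ((c*s) conv f) / (c conv f).

    ``kernel`` must be nonnegative with positive sum; it may be a per-axis
    list of 1D kernels (separable) or an nD array.  Returns the filtered
    volume and a boolean map of where the output is defined (denominator
    above eps = 1e-12 * kernel sum); undefined voxels are set to 0.
    """
    if isinstance(kernel, (list, tuple)) and not np.isscalar(kernel[0]):
        ksum = float(np.prod([np.sum(k) for k in kernel]))
        neg = any(np.any(np.asarray(k) < 0) for k in kernel)
    else:
        karr = np.asarray(kernel, dtype=float)
        ksum = float(karr.sum())
        neg = bool(np.any(karr < 0))
    if neg or ksum <= 0:
        raise ValueError("normalized convolution requires a nonnegative "
                         "kernel with positive sum")
    c = np.asarray(cert.values, dtype=float)
    if c.shape != signal.shape:
        raise ValueError("certainty grid does not match signal grid")
    num = _conv_any(c * np.asarray(signal.values, dtype=float), kernel, modes)
    den = _conv_any(c, kernel, modes)
    eps = 1e-12 * ksum
    defined = den > eps
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=defined)
    # validity: with certainty handling the borders, circular semantics apply
    # to the shape; callers track which voxels are defined via the mask
    return (Volume4D(out, spacing=signal.spacing, valid=signal.valid,
                     periodic_t=signal.periodic_t),
            defined)


# ---------------------------------------------------------------------------
# valid-slice accounting for the fixed pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidSlicePlan:
    """Z-axis slice counts surviving each stage of the denoising chain."""

    n_slices: int
    use_normalized_conv: bool
    after_lowpass: int
    after_downsample: int
    after_monomial: int
    after_tensor_lowpass: int
    after_control_lowpass: int
    coverage_full_res: int
    output_slices: int
    # absolute index intervals (half-open), used by the slab executor
    half_valid: tuple[int, int] = field(default=(0, 0))
    output_range: tuple[int, int] = field(default=(0, 0))


def z_validity_intervals(n_slices: int, use_normalized_conv: bool):
    """Propagate absolute z-index validity intervals through the chain.

    Returns (stage intervals dict) with half-open intervals.  Downsampling
    keeps even indices, so a valid full-resolution interval [a, b) maps to
    half-resolution [ceil(a/2), (b-1)//2 + 1).
    """
    n = int(n_slices)
    if n < 1:
        raise ValueError("n_slices must be >= 1")
    nc = bool(use_normalized_conv)

    def clamp(lo, hi):
        return (lo, hi) if lo < hi else (min(lo, hi), min(lo, hi))

    lp = (0, n) if nc else clamp(1, n - 1)
    half = clamp(math.ceil(lp[0] / 2), (lp[1] - 1) // 2 + 1 if lp[1] > lp[0] else math.ceil(lp[0] / 2))
    mono = clamp(half[0] + 3, half[1] - 3)
    tlp = mono if nc else clamp(mono[0] + 2, mono[1] - 2)
    clp = tlp if nc else clamp(tlp[0] + 2, tlp[1] - 2)
    if clp[0] < clp[1]:
        coverage = (2 * clp[0], 2 * (clp[1] - 1) + 1)
    else:
        coverage = (0, 0)
    recon = clamp(5, n - 5)
    out = clamp(max(coverage[0], recon[0]), min(coverage[1], recon[1]))
    return {"lowpass": lp, "half": half, "monomial": mono,
            "tensor_lowpass": tlp, "control_lowpass": clp,
            "coverage": coverage, "output": out}


def plan_valid_slices(n_slices: int, use_normalized_conv: bool) -> ValidSlicePlan:
    """Count valid z-slices after each stage of the fixed denoising chain.

    With standard convolution each non-circular filtering stage consumes its
    half-width on both ends; with normalized convolution the lowpass stages
    keep the full extent and only the monomial filtering (which cannot use
    plain certainty weighting, as its coefficients change sign) and the
    reconstruction margin consume slices.
    """
    iv = z_validity_intervals(n_slices, use_normalized_conv)
    ln = lambda ab: max(0, ab[1] - ab[0])
    return ValidSlicePlan(
        n_slices=int(n_slices),
        use_normalized_conv=bool(use_normalized_conv),
        after_lowpass=ln(iv["lowpass"]),
        after_downsample=ln(iv["half"]),
        after_monomial=ln(iv["monomial"]),
        after_tensor_lowpass=ln(iv["tensor_lowpass"]),
        after_control_lowpass=ln(iv["control_lowpass"]),
        coverage_full_res=ln(iv["coverage"]),
        output_slices=ln(iv["output"]),
        half_valid=iv["control_lowpass"],
        output_range=iv["output"],
    )
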