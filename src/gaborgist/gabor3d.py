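"""3D spatiotemporal Gabor filter bank.

A 3D Gabor filter is a Gaussian envelope multiplied by cosine carriers,

    G(x, y, t) = exp(-(X^2/(2 sx) + Y^2/(2 sy) + T^2/(2 st)))
                 * cos(2 pi X / lambda_x) * cos(2 pi Y / lambda_y),

where (X, Y, T) are the input coordinates rotated by the spatial orientation
theta (a rotation in the y-t plane) and the temporal orientation omega (a
rotation in the x-t plane).  By default the envelope denominators are read as
variances, ``sx = sigma_x**2`` etc. (the standard Gaussian form); the flag
``sigma_as_variance=True`` instead treats the sigma parameters literally as
the denominators ``sx = sigma_x`` — both conventions are supported because
either reading of the envelope appears in the literature.

The default bank has one scale and four orientations — four kernels total.
Sampled kernels are mean-subtracted and L2-normalized, which makes every
filter exactly zero-DC: the response to any constant volume vanishes, the
testable form of robustness to illumination changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.fft

from .video_io import VideoVolume

__all__ = [
    "GaborParams",
    "GaborKernel",
    "FilterBank",
    "DEFAULT_ORIENTATIONS",
    "rotate_coords",
    "gabor_value",
    "build_kernel",
    "build_default_bank",
    "bank_from_config",
    "dump_kernel",
    "filter_volume",
    "filter_volume_bank",
]

#: Default (theta, omega) orientation pairs, radians: pure-spatial
#: horizontal/vertical and their temporally tilted variants.
DEFAULT_ORIENTATIONS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (np.pi / 2, 0.0),
    (0.0, np.pi / 2),
    (np.pi / 2, np.pi / 2),
)


@dataclass(frozen=True)
class GaborParams:
    """Parameter set of one 3D Gabor kernel.

    sigma_x, sigma_y are in pixels, sigma_t in frames; lambda_x, lambda_y are
    carrier wavelengths in pixels; theta and omega are the spatial and
    temporal orientations in radians; support = (hx, hy, ht) are integer tap
    half-extents, so the sampled kernel has shape (2*hy+1, 2*hx+1, 2*ht+1)
    laid out as (row, column, frame).
    """

    sigma_x: float = 8.0
    sigma_y: float = 8.0
    sigma_t: float = 3.0
    lambda_x: float = 32.0
    lambda_y: float = 32.0
    theta: float = 0.0
    omega: float = 0.0
    support: tuple[int, int, int] = (16, 16, 6)
    sigma_as_variance: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_y", "sigma_t", "lambda_x", "lambda_y"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        hx, hy, ht = self.support
        if min(hx, hy, ht) < 1:
            raise ValueError(f"support half-extents must be >= 1, got {self.support}")


@dataclass(frozen=True)
class GaborKernel:
    """Sampled kernel taps plus the parameters that produced them."""

    taps: np.ndarray
    params: GaborParams
    normalized: bool = True

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        if taps.ndim != 3 or any(s % 2 == 0 for s in taps.shape):
            raise ValueError(f"kernel taps must be 3-D with odd extents, got {taps.shape}")
        object.__setattr__(self, "taps", taps)
        if self.normalized:
            tol = 1e-10 * taps.size
            if abs(taps.sum()) > tol:
                raise ValueError(f"normalized kernel must be zero-mean, sum={taps.sum():.3e}")
            if abs(np.linalg.norm(taps) - 1.0) > 1e-10:
                raise ValueError("normalized kernel must have unit L2 norm")


@dataclass(frozen=True)
class FilterBank:
    """Ordered list of kernels; feature layout downstream depends on the order."""

    kernels: tuple[GaborKernel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernels", tuple(self.kernels))
        if len(self.kernels) == 0:
            raise ValueError("filter bank must contain at least one kernel")

    def __len__(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)


def rotate_coords(x, y, t, theta: float, omega: float):
    """Rotate (x, y, t) by the spatial (theta) then temporal (omega) rotation.

    Returns (X, Y, T) = R_theta @ R_omega @ (x, y, t) with

        R_theta = [[1, 0, 0], [0, cos, -sin], [0, sin, cos]]   (y-t plane)
        R_omega = [[cos, 0, sin], [0, 1, 0], [-sin, 0, cos]]   (x-t plane)

    Both matrices are orthonormal, so the Euclidean norm is preserved.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    cw, sw = np.cos(omega), np.sin(omega)
    # R_omega
    x1 = cw * x + sw * t
    y1 = y
    t1 = -sw * x + cw * t
    ct, st = np.cos(theta), np.sin(theta)
    # R_theta
    X = x1
    Y = ct * y1 - st * t1
    T = st * y1 + ct * t1
    return X, Y, T


def gabor_value(params: GaborParams, x, y, t):
    """Evaluate the (unnormalized) 3D Gabor function at (x, y, t)."""
    X, Y, T = rotate_coords(x, y, t, params.theta, params.omega)
    if params.sigma_as_variance:
        dx, dy, dt = params.sigma_x, params.sigma_y, params.sigma_t
    else:
        dx, dy, dt = params.sigma_x ** 2, params.sigma_y ** 2, params.sigma_t ** 2
    envelope = np.exp(-(X * X / (2 * dx) + Y * Y / (2 * dy) + T * T / (2 * dt)))
    carrier = np.cos(2 * np.pi * X / params.lambda_x) * np.cos(2 * np.pi * Y / params.lambda_y)
    return envelope * carrier


def build_kernel(params: GaborParams, normalize: bool = True) -> GaborKernel:
    """Sample the Gabor function on its integer support grid.

    Taps are laid out as (row=y, column=x, frame=t).  When ``normalize`` the
    taps are mean-subtracted then L2-normalized, making the kernel zero-DC.
    """
    hx, hy, ht = params.support
    ys = np.arange(-hy, hy + 1, dtype=np.float64)
    xs = np.arange(-hx, hx + 1, dtype=np.float64)
    ts = np.arange(-ht, ht + 1, dtype=np.float64)
    Y, X, T = np.meshgrid(ys, xs, ts, indexing="ij")
    taps = gabor_value(params, X, Y, T)
    if normalize:
        taps = taps - taps.mean()
        norm = np.linalg.norm(taps)
        if norm < 1e-300:
            raise ValueError(
                "degenerate kernel: taps are constant on the requested support"
            )
        taps = taps / norm
    return GaborKernel(taps=taps, params=params, normalized=normalize)


def build_default_bank(
    sigma: tuple[float, float, float] = (8.0, 8.0, 3.0),
    lambdas: tuple[float, float] = (32.0, 32.0),
    support: tuple[int, int, int] = (16, 16, 6),
    orientations: Sequence[tuple[float, float]] = DEFAULT_ORIENTATIONS,
    sigma_as_variance: bool = False,
) -> FilterBank:
    """Build the default one-scale bank: four (theta, omega) orientations.

    All kernels share the same sigma/lambda scale; only the orientation pair
    differs.  The orientation order is fixed and defines the feature layout.
    """
    orientations = tuple(orientations)
    if len(orientations) == 0:
        raise ValueError("bank must have at least one orientation")
    sx, sy, st = sigma
    lx, ly = lambdas
    kernels = [
        build_kernel(
            GaborParams(
                sigma_x=sx, sigma_y=sy, sigma_t=st,
                lambda_x=lx, lambda_y=ly,
                theta=th, omega=om,
                support=tuple(support),
                sigma_as_variance=sigma_as_variance,
            )
        )
        for th, om in orientations
    ]
    return FilterBank(kernels=tuple(kernels))


def bank_from_config(path) -> FilterBank:
    """Build a bank from a key-value (YAML/JSON) configuration file.

    Recognized keys (all optional, defaults as in :func:`build_default_bank`):
    ``sigma: [sx, sy, st]``, ``lambdas: [lx, ly]``,
    ``support: [hx, hy, ht]``, ``orientations:`` list of ``[theta, omega]``
    pairs, ``angles_in: degrees|radians`` (default radians), and
    ``sigma_as_variance: true|false``.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    if "sigma" in cfg:
        kwargs["sigma"] = tuple(float(v) for v in cfg["sigma"])
    if "lambdas" in cfg:
        kwargs["lambdas"] = tuple(float(v) for v in cfg["lambdas"])
    if "support" in cfg:
        kwargs["support"] = tuple(int(v) for v in cfg["support"])
    if "orientations" in cfg:
        pairs = [tuple(float(v) for v in pair) for pair in cfg["orientations"]]
        if str(cfg.get("angles_in", "radians")).lower().startswith("deg"):
            pairs = [(np.deg2rad(t), np.deg2rad(o)) for t, o in pairs]
        kwargs["orientations"] = pairs
    if "sigma_as_variance" in cfg:
        kwargs["sigma_as_variance"] = bool(cfg["sigma_as_variance"])
    return build_default_bank(**kwargs)


def dump_kernel(kernel: GaborKernel, path) -> None:
    """Write kernel taps for inspection: ``.npy`` binary or plain text.

    The text form stores the shape on a header line followed by the taps
    flattened in C order, one value per line.
    """
    path = str(path)
    if path.endswith(".npy"):
        np.save(path, kernel.taps)
        return
    with open(path, "w") as fh:
        fh.write("# shape: {} {} {}\n".format(*kernel.taps.shape))
        np.savetxt(fh, kernel.taps.reshape(-1, 1))


def _as_data(volume) -> np.ndarray:
    return volume.data if isinstance(volume, VideoVolume) else np.asarray(volume, float)


def _check_support(data: np.ndarray, taps: np.ndarray) -> None:
    if any(k > d for k, d in zip(taps.shape, data.shape)):
        raise ValueError(
            f"kernel support {taps.shape} exceeds volume shape {data.shape}"
        )


def _fft_shape(data_shape, tap_shape):
    return tuple(
        scipy.fft.next_fast_len(d + k - 1) for d, k in zip(data_shape, tap_shape)
    )


def _pad_boundary(data: np.ndarray, tap_shape, boundary: str) -> np.ndarray:
    """Extend the volume by half the kernel support on every side."""
    pads = tuple((k // 2, k // 2) for k in tap_shape)
    if boundary == "symmetric":
        return np.pad(data, pads, mode="symmetric")
    if boundary == "zero":
        return np.pad(data, pads, mode="constant")
    raise ValueError(f"unknown boundary mode {boundary!r}")


def _correlate_valid(padded: np.ndarray, taps: np.ndarray, out_shape) -> np.ndarray:
    """Valid-region cross-correlation of a pre-padded volume, via FFT."""
    fshape = _fft_shape(padded.shape, taps.shape)
    fd = scipy.fft.rfftn(padded, fshape)
    # correlation = convolution with the axis-reversed kernel
    fk = scipy.fft.rfftn(taps[::-1, ::-1, ::-1], fshape)
    full = scipy.fft.irfftn(fd * fk, fshape)
    starts = [k - 1 for k in taps.shape]
    return full[tuple(slice(s, s + d) for s, d in zip(starts, out_shape))].copy()


def filter_volume(
    volume,
    kernel: GaborKernel,
    chunk_frames: int | None = None,
    boundary: str = "symmetric",
) -> np.ndarray:
    """Cross-correlate a volume with one kernel; output has the input's shape.

    Borders are extended symmetrically by default (``boundary="zero"``
    zero-pads instead).  Symmetric extension keeps the zero-DC property exact
    up to the volume edge: a constant volume maps to an identically-zero
    response, so the output is invariant under constant intensity offsets
    everywhere, not just in the interior.

    ``chunk_frames`` optionally processes the temporal axis in chunks of that
    many frames with a ``2*ht``-frame overlap; the stitched result equals the
    unchunked one exactly (the overlap covers the kernel's temporal reach),
    bounding peak memory on long clips.
    """
    data = _as_data(volume)
    taps = kernel.taps
    _check_support(data, taps)
    if chunk_frames is None or data.shape[2] <= chunk_frames:
        return _correlate_valid(_pad_boundary(data, taps.shape, boundary), taps, data.shape)

    ht = taps.shape[2] // 2
    n = data.shape[2]
    out = np.empty_like(data)
    for start in range(0, n, chunk_frames):
        stop = min(start + chunk_frames, n)
        lo = max(start - ht, 0)
        hi = min(stop + ht, n)
        piece = filter_volume(data[:, :, lo:hi], kernel, boundary=boundary)
        out[:, :, start:stop] = piece[:, :, start - lo : start - lo + (stop - start)]
    return out


def filter_volume_bank(volume, bank: FilterBank, boundary: str = "symmetric") -> list[np.ndarray]:
    """Filter a volume with every kernel of a bank, sharing the volume FFT.

    Equivalent to ``[filter_volume(volume, k) for k in bank]`` but computes
    the forward FFT of the (padded) volume once, which dominates the cost for
    clip-sized volumes.  All kernels must share one support shape (the
    default bank does); mixed supports fall back to per-kernel filtering.
    """
    data = _as_data(volume)
    shapes = {k.taps.shape for k in bank}
    if len(shapes) != 1:
        return [filter_volume(data, k, boundary=boundary) for k in bank]
    tap_shape = next(iter(shapes))
    _check_support(data, np.empty(tap_shape))
    padded = _pad_boundary(data, tap_shape, boundary)
    fshape = _fft_shape(padded.shape, tap_shape)
    fd = scipy.fft.rfftn(padded, fshape)
    starts = [k - 1 for k in tap_shape]
    window = tuple(slice(s, s + d) for s, d in zip(starts, data.shape))
    out = []
    for kernel in bank:
        fk = scipy.fft.rfftn(kernel.taps[::-1, ::-1, ::-1], fshape)
        out.append(scipy.fft.irfftn(fd * fk, fshape)[window].copy())
    return out
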