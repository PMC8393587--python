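"""Discrete narrow-band operators.

The narrow band of a segmentation boundary is built in two steps: an edge
extractor ``chi`` (a fixed smoothed central-difference gradient-magnitude
stencil) marks the one-pixel neighbourhood of every label transition, and a
band dilator ``zeta`` (a B×B moving-window maximum, B×B×B in 3D) grows that
edge map into a strip of half-width ``B // 2``.  Applied to a ground-truth
mask ``y`` the composition ``zeta(chi(y))`` is the ground-truth narrow band;
applied to a network feature map it is the transitional gate that turns region
features into contour (``F_LC``) and band (``F_LN``) attention maps.

Every operator accepts either a plain numpy array or an autodiff
:class:`~nbac.autodiff.Tensor`; the Tensor path is differentiable and shares
the exact arithmetic of the numpy path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, maximum

__all__ = [
    "BandSpec",
    "GroundTruthBand",
    "InvalidParameterError",
    "DegenerateMaskError",
    "DegenerateBandWarning",
    "heaviside_smooth",
    "signed_distance",
    "edge_extract",
    "dilate_band",
    "ground_truth_band",
    "transitional_gate",
]


class InvalidParameterError(ValueError):
    """An operator parameter violates its contract (e.g. even band width)."""


class DegenerateMaskError(ValueError):
    """A mask has no boundary (all foreground or all background)."""


class DegenerateBandWarning(UserWarning):
    """A constant mask produced an empty narrow band."""


@dataclass(frozen=True)
class BandSpec:
    """Band width and operator choices for the transitional gate.

    ``B`` is the full width of the dilation window in pixels and must be odd
    so the window is centred; ``B=1`` makes the dilation the identity.
    """

    B: int = 5
    edge_mode: str = "finite_difference"
    dilation_shape: str = "square"
    boundary_padding: str = "replicate"

    def __post_init__(self):
        if self.B < 1 or self.B % 2 == 0:
            raise InvalidParameterError(f"band width B must be odd and >= 1, got {self.B}")
        if self.edge_mode != "finite_difference":
            raise InvalidParameterError(f"unknown edge_mode {self.edge_mode!r}")
        if self.dilation_shape != "square":
            raise InvalidParameterError(f"unknown dilation_shape {self.dilation_shape!r}")
        if self.boundary_padding != "replicate":
            raise InvalidParameterError(f"unknown boundary_padding {self.boundary_padding!r}")


# ---------------------------------------------------------------------------
# smooth Heaviside
# ---------------------------------------------------------------------------


def heaviside_smooth(x, epsilon: float):
    """Arctangent step ``H_eps(x) = 1/2 (1 + (2/pi) arctan(x/eps))``.

    Strictly increasing, maps R into (0, 1) and satisfies
    ``H(x) + H(-x) = 1``.  Works on numpy arrays, scalars and Tensors.
    """
    if epsilon <= 0:
        raise InvalidParameterError(f"epsilon must be > 0, got {epsilon}")
    if isinstance(x, Tensor):
        return 0.5 * (1.0 + (2.0 / np.pi) * (x / epsilon).arctan())
    x = np.asarray(x, dtype=np.float64)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(x / epsilon))


# ---------------------------------------------------------------------------
# signed distance
# ---------------------------------------------------------------------------


def signed_distance(mask) -> np.ndarray:
    """Signed Euclidean distance field of a binary mask.

    Positive strictly inside (mask == 1), negative strictly outside, with
    magnitude the pixel-centre-to-pixel-centre distance to the nearest
    opposite-valued pixel.  Raises :class:`DegenerateMaskError` when the mask
    is constant, since no boundary exists.
    """
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise InvalidParameterError("signed_distance expects a strictly binary mask")
    inside = m.astype(bool)
    if inside.all() or not inside.any():
        raise DegenerateMaskError("mask has a single value; no boundary exists")
    # distance of each 1-pixel to the nearest 0-pixel, and vice versa
    d_in = ndimage.distance_transform_edt(inside)
    d_out = ndimage.distance_transform_edt(~inside)
    return d_in - d_out


# ---------------------------------------------------------------------------
# shifts (replicate padding) shared by chi and zeta
# ---------------------------------------------------------------------------


def _shift(F, axis: int, offset: int):
    """Shift along ``axis`` by ``offset`` pixels with replicate padding.

    ``offset=+1`` brings in each pixel's successor (F[..., i+1, ...]).
    """
    n = F.shape[axis]
    idx = np.clip(np.arange(n) + offset, 0, n - 1)
    if isinstance(F, Tensor):
        return F.take(idx, axis=axis)
    return np.take(F, idx, axis=axis)


def _spatial_axes(F, spatial_ndim: int | None) -> tuple[int, ...]:
    nd = F.ndim
    if spatial_ndim is None:
        if nd not in (2, 3):
            raise InvalidParameterError(
                "spatial_ndim must be given explicitly for rank-"
                f"{nd} inputs (leading axes are treated as batch/channel)"
            )
        spatial_ndim = nd
    if spatial_ndim not in (2, 3) or spatial_ndim > nd:
        raise InvalidParameterError(f"unsupported spatial_ndim {spatial_ndim}")
    return tuple(range(nd - spatial_ndim, nd))


# ---------------------------------------------------------------------------
# chi: edge extraction
# ---------------------------------------------------------------------------


def edge_extract(F, spec: BandSpec | None = None, spatial_ndim: int | None = None):
    """Gradient-magnitude edge map ``chi(F)``.

    Fixed smoothed central-difference stencil inside a 3×3 (3×3×3) window:
    the derivative along each spatial axis is the central difference
    ``(F[i+1] - F[i-1]) / 2`` smoothed with ``[1/4, 1/2, 1/4]`` along the
    remaining spatial axes (a Sobel kernel normalized so a unit-slope ramp
    responds with exactly 1), with replicate padding.  The output is
    ``sqrt(sum_a d_a^2)``: non-negative, exactly zero on locally constant
    regions, and differentiable on the Tensor path.
    """
    axes = _spatial_axes(F, spatial_ndim)
    comps = []
    for a in axes:
        d = (_shift(F, a, +1) - _shift(F, a, -1)) * 0.5
        for b in axes:
            if b == a:
                continue
            d = _shift(d, b, +1) * 0.25 + d * 0.5 + _shift(d, b, -1) * 0.25
        comps.append(d * d)
    total = comps[0]
    for c in comps[1:]:
        total = total + c
    if isinstance(total, Tensor):
        return total.sqrt()
    return np.sqrt(total)


# ---------------------------------------------------------------------------
# zeta: band dilation
# ---------------------------------------------------------------------------


def dilate_band(F, spec: BandSpec, spatial_ndim: int | None = None):
    """Grayscale dilation ``zeta(F)``: moving-window maximum over a B-wide
    square (cube) window with replicate padding.

    The square window is separable, so the maximum is taken axis by axis.
    ``B=1`` is the identity.
    """
    if not isinstance(spec, BandSpec):
        spec = BandSpec(B=int(spec))
    axes = _spatial_axes(F, spatial_ndim)
    r = spec.B // 2
    if r == 0:
        return F if isinstance(F, Tensor) else np.asarray(F, dtype=np.float64)
    if isinstance(F, Tensor):
        out = F
        for a in axes:
            acc = out
            for off in range(-r, r + 1):
                if off == 0:
                    continue
                acc = maximum(acc, _shift(out, a, off))
            out = acc
        return out
    out = np.asarray(F, dtype=np.float64)
    for a in axes:
        out = ndimage.maximum_filter1d(out, size=spec.B, axis=a, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# ground-truth narrow band
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthBand:
    """The narrow band ``zeta(chi(y))`` of a ground-truth mask and its parts.

    ``band`` is the raw grayscale field; ``indicator`` binarizes it
    (``band > 0``); ``inner``/``outer`` split the indicator by the mask value
    (inside vs outside the ground-truth region).  ``degenerate`` flags a
    constant mask whose band is empty.
    """

    band: np.ndarray
    indicator: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    degenerate: bool = field(default=False)


def ground_truth_band(y, spec: BandSpec, spatial_ndim: int | None = None) -> GroundTruthBand:
    """Build the ground-truth narrow band of a binary mask ``y``."""
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
        raise InvalidParameterError("ground_truth_band expects a binary mask")
    band = dilate_band(edge_extract(y, spec, spatial_ndim), spec, spatial_ndim)
    indicator = band > 0
    degenerate = not indicator.any()
    if degenerate:
        warnings.warn(
            "constant mask: narrow band is empty", DegenerateBandWarning, stacklevel=2
        )
    inner = indicator & (y == 1)
    outer = indicator & (y == 0)
    return GroundTruthBand(band, indicator, inner, outer, degenerate)


# ---------------------------------------------------------------------------
# transitional gate
# ---------------------------------------------------------------------------


def transitional_gate(F_H, spec: BandSpec, spatial_ndim: int | None = None):
    """Map a feature field to its contour and narrow-band maps.

    ``F_LC = chi(F_H)`` and ``F_LN = zeta(F_LC)``; ``F_LN >= F_LC``
    elementwise by the dilation property.  Differentiable on Tensor input.
    """
    F_LC = edge_extract(F_H, spec, spatial_ndim)
    F_LN = dilate_band(F_LC, spec, spatial_ndim)
    return F_LC, F_LN
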