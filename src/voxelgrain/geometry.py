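"""Log-polar stimulus geometry and retinotopic ROI layout.

Conventions used throughout the package
---------------------------------------
* Visual-field **polar angle** is measured in degrees clockwise from the
  upper vertical meridian, so 45 deg is the upper-right diagonal, 135 deg
  the lower-right, 225 deg the lower-left and 315 deg the upper-left.
* **Orientations** live in [0, 180) degrees with 0 = vertical, increasing
  clockwise.  Under this convention a "plus45" grating (tilted 45 deg
  clockwise from vertical, i.e. right-tilted) has orientation 45 and a
  "minus45" (left-tilted) grating has orientation 135.
* The **radial** orientation at a visual-field location equals its polar
  angle modulo 180; the **tangential** orientation is orthogonal to it.

The stimuli are an annulus of oriented square-wave gratings (two exemplars
tilted +/-45 deg from vertical) and logarithmic spirals whose edges keep a
constant +/-45 deg angle to the radius, so the two exemplars of either kind
are orthogonal everywhere.  Spirals are radially balanced (both deviate
45 deg from radial everywhere) and gratings are vertically balanced, which
is what makes the two stimulus families complementary probes of coarse
radial and vertical response biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, OutOfDomainError, UnsupportedGeometryError

GRATING_VARIANTS = ("plus45", "minus45")
SPIRAL_VARIANTS = ("clockwise", "anticlockwise")

#: Canonical patch-relative preference labels, per stimulus kind, in
#: (reference, anti-reference) order.  "Reference" is the label whose
#: coarse bias the corresponding stimulus family can probe.
LABEL_PAIRS = {"grating": ("radial", "tangential"), "spiral": ("vertical", "horizontal")}


@dataclass(frozen=True)
class AnnulusSpec:
    """Log-polar stimulus annulus: radii in degrees visual angle."""

    r_inner: float = 1.5
    r_outer: float = 7.04
    n_rings: int = 3
    n_wedges: int = 12

    def __post_init__(self):
        if not (self.r_outer > self.r_inner > 0):
            raise InvalidParameterError(
                f"need r_outer > r_inner > 0, got ({self.r_inner}, {self.r_outer})"
            )
        if self.n_rings < 1 or self.n_wedges < 1:
            raise InvalidParameterError("n_rings and n_wedges must be >= 1")

    def contains(self, eccentricity) -> np.ndarray:
        ecc = np.asarray(eccentricity, dtype=float)
        return (ecc >= self.r_inner) & (ecc <= self.r_outer)


DEFAULT_ANNULUS = AnnulusSpec()


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus exemplar: oriented grating or logarithmic spiral.

    ``spatial_frequency`` (cycles/deg) applies to gratings;
    ``cycles_per_perimeter`` to spirals.  ``phase`` only affects rendering,
    never the analytic orientation field.
    """

    kind: str
    variant: str
    spatial_frequency: float = 1.25
    cycles_per_perimeter: float = 22.0
    phase: float = 0.0

    def __post_init__(self):
        allowed = {"grating": GRATING_VARIANTS, "spiral": SPIRAL_VARIANTS}
        if self.kind not in allowed:
            raise InvalidParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.variant not in allowed[self.kind]:
            raise InvalidParameterError(
                f"variant {self.variant!r} inconsistent with kind {self.kind!r}"
            )
        if self.spatial_frequency <= 0 or self.cycles_per_perimeter <= 0:
            raise InvalidParameterError("spatial frequencies must be positive")


def stimulus_pair(kind: str) -> tuple[StimulusSpec, StimulusSpec]:
    """The two orthogonal exemplars of one stimulus kind, in canonical order."""
    if kind == "grating":
        return StimulusSpec("grating", "plus45"), StimulusSpec("grating", "minus45")
    if kind == "spiral":
        return StimulusSpec("spiral", "clockwise"), StimulusSpec("spiral", "anticlockwise")
    raise InvalidParameterError(f"unknown stimulus kind {kind!r}")


@dataclass(frozen=True)
class PatchSpec:
    """A quarterfield ROI patch: central third of a quadrant's polar range.

    ``ecc_band`` is 0..2 for one of the three eccentricity sub-ROIs or
    ``"all"`` for the full-eccentricity patch.
    """

    patch_id: int
    polar_center: float
    ecc_range: tuple[float, float]
    polar_width: float = 30.0
    ecc_band: int | str = "all"

    def __post_init__(self):
        lo, hi = self.ecc_range
        if not (hi > lo > 0):
            raise InvalidParameterError(f"bad ecc_range {self.ecc_range}")

    @property
    def polar_range(self) -> tuple[float, float]:
        return (self.polar_center - self.polar_width / 2, self.polar_center + self.polar_width / 2)


def logpolar_radii(r_inner: float, r_outer: float, n_rings: int) -> np.ndarray:
    """Ring-boundary radii of the log-polar tiling, geometrically spaced.

    Returns ``n_rings + 1`` strictly increasing radii with exact endpoints:
    ``radius[k] = r_inner * (r_outer / r_inner) ** (k / n_rings)``.
    """
    if not (r_outer > r_inner > 0):
        raise InvalidParameterError(f"need r_outer > r_inner > 0, got ({r_inner}, {r_outer})")
    if n_rings < 1:
        raise InvalidParameterError("n_rings must be >= 1")
    radii = np.geomspace(r_inner, r_outer, n_rings + 1)
    # geomspace guarantees exact endpoints
    return radii


def local_stimulus_orientation(
    stim: StimulusSpec,
    polar_angle,
    eccentricity,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
):
    """Local orientation of a stimulus at a visual-field position, in [0, 180).

    Gratings are uniform fields (45 for plus45, 135 for minus45).  Spiral
    edges keep a constant 45 deg angle to the radius, so their local
    orientation follows the polar angle: ``(polar + 45) mod 180`` for the
    clockwise variant and ``(polar - 45) mod 180`` for the anticlockwise
    one.  The two variants of either kind are orthogonal everywhere.

    Raises :class:`OutOfDomainError` for locations outside the annulus.
    """
    polar = np.asarray(polar_angle, dtype=float)
    ecc = np.asarray(eccentricity, dtype=float)
    if not np.all(annulus.contains(ecc)):
        raise OutOfDomainError("eccentricity outside the stimulus annulus")
    if stim.kind == "grating":
        value = 45.0 if stim.variant == "plus45" else 135.0
        out = np.broadcast_to(np.float64(value), np.broadcast_shapes(polar.shape, ecc.shape)).copy()
    else:
        offset = 45.0 if stim.variant == "clockwise" else -45.0
        out = np.mod(polar + offset, 180.0)
        out = np.broadcast_to(out, np.broadcast_shapes(polar.shape, ecc.shape)).copy()
    if out.ndim == 0:
        return float(out)
    return out


def patch_reference_orientations(polar_center: float) -> tuple[float, float]:
    """(radial, tangential) reference orientations of a patch center."""
    radial = float(np.mod(polar_center, 180.0))
    tangential = float(np.mod(polar_center + 90.0, 180.0))
    return radial, tangential


def condition_label_map(
    stim_pair: tuple[StimulusSpec, StimulusSpec],
    patch: PatchSpec,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
) -> dict[str, str]:
    """Map each condition (variant name) to its patch-relative label.

    For gratings the condition whose orientation equals the patch's radial
    reference is "radial" and the other "tangential".  For spirals the
    condition whose local orientation at the patch center is vertical (0)
    is "vertical" and the orthogonal one "horizontal".  Only the diagonal
    patches (polar centers at odd multiples of 45 deg) admit these
    labelings; anything else raises :class:`UnsupportedGeometryError`.
    """
    a, b = stim_pair
    if a.kind != b.kind or a.variant == b.variant:
        raise InvalidParameterError("stim_pair must be the orthogonal pair of one kind")
    ecc_mid = float(np.sqrt(patch.ecc_range[0] * patch.ecc_range[1]))
    ori = {
        s.variant: float(
            np.round(local_stimulus_orientation(s, patch.polar_center, ecc_mid, annulus), 9)
        )
        % 180.0
        for s in (a, b)
    }
    if a.kind == "grating":
        radial, _ = patch_reference_orientations(patch.polar_center)
        matches = {v: o for v, o in ori.items() if np.isclose(o, radial)}
        if len(matches) != 1:
            raise UnsupportedGeometryError(
                f"patch at {patch.polar_center} deg: neither grating is radial"
            )
        (radial_variant,) = matches
        other = b.variant if radial_variant == a.variant else a.variant
        return {radial_variant: "radial", other: "tangential"}
    # spirals: vertical / horizontal at the patch center
    vertical = {v for v, o in ori.items() if np.isclose(o % 180.0, 0.0)}
    horizontal = {v for v, o in ori.items() if np.isclose(o, 90.0)}
    if len(vertical) != 1 or len(horizontal) != 1:
        raise UnsupportedGeometryError(
            f"patch at {patch.polar_center} deg: spirals are neither vertical nor horizontal"
        )
    return {vertical.pop(): "vertical", horizontal.pop(): "horizontal"}


QUARTERFIELD_CENTERS = (45.0, 135.0, 225.0, 315.0)


def build_rois(annulus: AnnulusSpec = DEFAULT_ANNULUS) -> list[PatchSpec]:
    """Quarterfield ROI patches: 4 all-eccentricity + 4 x 3 eccentricity bands.

    Each patch covers the central third (30 deg) of one quadrant's polar
    range.  Eccentricity bands divide [r_inner, r_outer] at geometrically
    equal (log-equal) radii — the flat-map stand-in for bands of
    approximately equal cortical surface area under log cortical
    magnification.
    """
    bounds = logpolar_radii(annulus.r_inner, annulus.r_outer, 3)
    rois: list[PatchSpec] = []
    for pid, center in enumerate(QUARTERFIELD_CENTERS, start=1):
        rois.append(
            PatchSpec(pid, center, (annulus.r_inner, annulus.r_outer), ecc_band="all")
        )
    for pid, center in enumerate(QUARTERFIELD_CENTERS, start=1):
        for band in range(3):
            rois.append(
                PatchSpec(pid, center, (float(bounds[band]), float(bounds[band + 1])), ecc_band=band)
            )
    return rois


def quarterfield_patches(annulus: AnnulusSpec = DEFAULT_ANNULUS) -> list[PatchSpec]:
    """Just the 4 all-eccentricity quarterfield patches."""
    return [p for p in build_rois(annulus) if p.ecc_band == "all"]


def rois_to_table(rois: list[PatchSpec]) -> pd.DataFrame:
    """Tabular serialization of an ROI layout (one row per patch)."""
    rows = []
    for p in rois:
        lo, hi = p.polar_range
        rows.append(
            dict(
                patch_id=p.patch_id,
                polar_lo=lo,
                polar_hi=hi,
                ecc_lo=p.ecc_range[0],
                ecc_hi=p.ecc_range[1],
                ecc_band=p.ecc_band,
            )
        )
    return pd.DataFrame(rows)


def render_stimulus(
    stim: StimulusSpec,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
    size: int = 512,
) -> np.ndarray:
    """Rasterize a stimulus for visual inspection (documentation aid only).

    Returns a (size, size) array in [-1, 1]; mid-gray (0) outside the
    annulus and along the log-polar grout lines.  The analysis path never
    consumes pixel images — it uses the analytic orientation field.
    """
    half = annulus.r_outer * 1.05
    ax = np.linspace(-half, half, size)
    xx, yy = np.meshgrid(ax, -ax)  # row 0 = top of the visual field
    r = np.hypot(xx, yy)
    theta = np.mod(np.degrees(np.arctan2(xx, yy)), 360.0)  # clockwise from vertical
    with np.errstate(divide="ignore"):
        logr = np.log(np.where(r > 0, r, 1.0))
    if stim.kind == "grating":
        ori = np.radians(45.0 if stim.variant == "plus45" else 135.0)
        # stripes perpendicular to the orientation axis
        coord = xx * np.cos(ori) - yy * np.sin(ori)
        img = np.sign(np.sin(2 * np.pi * stim.spatial_frequency * coord + stim.phase))
    else:
        sgn = 1.0 if stim.variant == "clockwise" else -1.0
        img = np.sign(
            np.sin(stim.cycles_per_perimeter * (np.radians(theta) + sgn * logr) + stim.phase)
        )
    inside = (r >= annulus.r_inner) & (r <= annulus.r_outer)
    img = np.where(inside, img, 0.0)
    # grout lines of the log-polar tiling
    ring_r = logpolar_radii(annulus.r_inner, annulus.r_outer, annulus.n_rings)
    for rr in ring_r:
        img[np.abs(r - rr) < half / size * 2] = 0.0
    wedge_step = 360.0 / annulus.n_wedges
    near_wedge = np.min(np.abs(((theta[..., None] - np.arange(annulus.n_wedges) * wedge_step) + 180) % 360 - 180), axis=-1)
    img[(near_wedge < 0.75) & inside] = 0.0
    return img
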