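"""Chord profiles and non-dimensional radii of wing-area moments.

The central quantity is the radius of the second moment of wing area,

    r2(S) = ( integral_0^1  c_hat(r_hat) r_hat^2 d r_hat )^(1/2),

where ``r_hat = r / R`` is span position normalized by wing length R
(measured from the wing base along the base->apex axis) and
``c_hat = c / (S / R)`` is the local chord normalized by the mean chord.
The RSM is proportional to the mean lift force of a flapping wing: low
values mean area concentrated toward the wing base and cheaper flight,
high values a tip-heavy wing. The first three moment radii r1 <= r2 <= r3
are computed by the same machinery.

Profiles are measured by partitioning the wing into strips perpendicular
to the base->apex axis; the chord of a strip is its area divided by its
width. Strip areas are exact: the cumulative area left of each strip
boundary is evaluated analytically from the polygon's edges (Green's
theorem with per-edge clipping), so the only discretization error is the
piecewise-constant chord representation itself, which vanishes as
O(1/n_strips^2) on smooth outlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .exceptions import GeometryError, ValidationError

__all__ = [
    "WingOutline",
    "ChordProfile",
    "MomentRadii",
    "chord_profile",
    "moment_radius",
    "moment_radii",
    "rsm_from_outline",
    "mask_to_outline",
]


@dataclass
class WingOutline:
    """An ordered planar polygon with designated base and apex points.

    ``vertices`` is an (m, 2) array in physical units (mm assumed in the
    docs; any consistent unit works — the moment radii are dimensionless).
    The wing axis runs from ``base_point`` to ``apex_point``; both must lie
    on the polygon boundary.
    """

    vertices: np.ndarray
    base_point: np.ndarray
    apex_point: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.base_point = np.asarray(self.base_point, dtype=float)
        self.apex_point = np.asarray(self.apex_point, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError(
                f"vertices must be an (m, 2) array, got {self.vertices.shape}"
            )
        # drop an explicitly repeated closing vertex
        if len(self.vertices) > 1 and np.allclose(
            self.vertices[0], self.vertices[-1]
        ):
            self.vertices = self.vertices[:-1]

    def validate(self) -> None:
        """Raise :class:`GeometryError` unless the outline is usable."""
        if len(self.vertices) < 3:
            raise GeometryError("outline needs at least 3 vertices")
        poly = shapely.Polygon(self.vertices)
        if poly.area <= 0:
            raise GeometryError("outline encloses zero area")
        if not poly.is_valid:
            raise GeometryError("outline polygon is self-intersecting")
        diam = float(np.ptp(self.vertices, axis=0).max())
        if np.allclose(self.base_point, self.apex_point, atol=1e-12 * max(diam, 1.0)):
            raise GeometryError("base and apex coincide")
        boundary = poly.exterior
        tol = 1e-6 * diam
        for name, pt in (("base", self.base_point), ("apex", self.apex_point)):
            if boundary.distance(shapely.Point(pt)) > tol:
                raise GeometryError(f"{name} point does not lie on the outline")

    @property
    def wing_length(self) -> float:
        """R: Euclidean base-to-apex distance."""
        return float(np.linalg.norm(self.apex_point - self.base_point))

    def axis_frame(self) -> np.ndarray:
        """Vertices in the wing-axis frame: x along base->apex, origin at base."""
        u = (self.apex_point - self.base_point) / self.wing_length
        nvec = np.array([-u[1], u[0]])
        rel = self.vertices - self.base_point
        return np.column_stack([rel @ u, rel @ nvec])


@dataclass
class ChordProfile:
    """Normalized chord distribution along the wing axis.

    ``r_hat`` holds the n_strips + 1 strip edges (r_hat[0] = 0,
    r_hat[-1] = 1); ``c_hat`` the n_strips per-strip normalized chords
    (strip area / strip width, divided by the mean chord S/R). With this
    pairing the rectangle-rule integral of c_hat is exactly 1.
    """

    r_hat: np.ndarray  # strip edges, length n+1
    c_hat: np.ndarray  # per-strip chords, length n
    wing_length_R: float
    area_S: float

    def __post_init__(self):
        self.r_hat = np.asarray(self.r_hat, dtype=float)
        self.c_hat = np.asarray(self.c_hat, dtype=float)
        if len(self.c_hat) != len(self.r_hat) - 1:
            raise ValidationError(
                "c_hat must hold one chord per strip "
                f"(len(r_hat) - 1 = {len(self.r_hat) - 1}, got {len(self.c_hat)})"
            )
        if not (self.r_hat[0] == 0.0 and abs(self.r_hat[-1] - 1.0) < 1e-12):
            raise ValidationError("r_hat must span [0, 1]")
        if np.any(np.diff(self.r_hat) <= 0):
            raise ValidationError("r_hat must be strictly increasing")
        if np.any(self.c_hat < 0):
            raise ValidationError("negative chord")
        if not (self.wing_length_R > 0 and self.area_S > 0):
            raise ValidationError("wing length and area must be positive")

    @property
    def n_strips(self) -> int:
        return len(self.c_hat)

    def integrate(self, k: int = 0) -> float:
        """Exact integral of c_hat * r_hat^k over [0, 1] for the stored
        piecewise-constant chord (k = 0 gives the normalization, == 1)."""
        a, b = self.r_hat[:-1], self.r_hat[1:]
        return float(np.sum(self.c_hat * (b ** (k + 1) - a ** (k + 1)) / (k + 1)))


@dataclass
class MomentRadii:
    """The first three non-dimensional moment radii of wing area."""

    r1: float
    r2: float
    r3: float

    def __post_init__(self):
        if not (0 < self.r1 < 1 and 0 < self.r2 < 1 and 0 < self.r3 < 1):
            raise ValidationError("moment radii must lie in (0, 1)")
        if not (self.r1 <= self.r2 + 1e-12 and self.r2 <= self.r3 + 1e-12):
            raise ValidationError("moment radii must be ordered r1 <= r2 <= r3")


def _cumulative_area(axis_verts: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Area of the polygon part with x <= t, for each threshold t.

    Analytic per-edge integration (Green's theorem, -contour integral of
    y dx for a counter-clockwise boundary) with the integration limit
    clipped at t. Vectorized over edges x thresholds.
    """
    v = axis_verts
    # enforce counter-clockwise orientation (positive shoelace area)
    x, y = v[:, 0], v[:, 1]
    shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if shoelace < 0:
        v = v[::-1]
        x, y = v[:, 0], v[:, 1]

    x1, y1 = x, y
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    d = x2 - x1
    nonvert = d != 0
    x1, y1, x2, y2, d = (a[nonvert] for a in (x1, y1, x2, y2, d))
    m = (y2 - y1) / d

    t = thresholds[:, None]  # (T, 1) against (E,) edges
    fwd = d > 0
    lo = np.where(fwd, x1, x2)
    hi = np.where(fwd, x2, x1)
    c = np.clip(t, lo, hi)
    # forward edge: integral from x1 to c; backward: from c down to x2
    u_f = c - x1
    u_b = c - x2
    contrib = np.where(
        fwd,
        y1 * u_f + 0.5 * m * u_f**2,
        -(y2 * u_b + 0.5 * m * u_b**2),
    )
    return -contrib.sum(axis=1)


def chord_profile(outline: WingOutline, n_strips: int = 500) -> ChordProfile:
    """Strip-decompose a wing outline into its normalized chord profile.

    The wing is partitioned into ``n_strips`` equal-width strips
    perpendicular to the base->apex axis; the chord of strip i is its
    exact area divided by the strip width, normalized by the mean chord
    S/R. Rigid motions of the outline leave the result unchanged.
    """
    if n_strips < 10:
        raise ValidationError(f"n_strips must be >= 10, got {n_strips}")
    outline.validate()
    v = outline.axis_frame()
    R = outline.wing_length

    edges = np.linspace(0.0, R, n_strips + 1)
    cum = _cumulative_area(v, edges)
    areas = np.diff(cum)
    S = cum[-1] - cum[0]
    if S <= 0:
        raise GeometryError("no wing area between base and apex")
    # numerical slop from cancellation can leave tiny negative strips
    areas = np.clip(areas, 0.0, None)
    c_hat = areas * n_strips / areas.sum()
    return ChordProfile(
        r_hat=np.linspace(0.0, 1.0, n_strips + 1),
        c_hat=c_hat,
        wing_length_R=R,
        area_S=float(S),
    )


def moment_radius(profile: ChordProfile, k: int) -> float:
    """k-th non-dimensional moment radius r_k(S) = (int c_hat r_hat^k)^{1/k}.

    k = 2 is the RSM. Within each strip the chord is constant, so the
    r_hat^k factor is integrated exactly.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k}")
    return float(profile.integrate(k) ** (1.0 / k))


def moment_radii(profile: ChordProfile) -> MomentRadii:
    """All three moment radii of one profile (r1 <= r2 <= r3 by power-mean
    monotonicity)."""
    return MomentRadii(*(moment_radius(profile, k) for k in (1, 2, 3)))


def rsm_from_outline(outline: WingOutline, n_strips: int = 500) -> float:
    """Radius of the second moment of wing area, straight from an outline."""
    return moment_radius(chord_profile(outline, n_strips), 2)


def mask_to_outline(
    binary_mask: np.ndarray,
    pixel_scale: float,
    base_hint,
    apex_hint,
) -> WingOutline:
    """Trace a binary wing mask into a :class:`WingOutline`.

    Optional adapter for scanned-image input: the single foreground
    component is traced by marching squares (scikit-image) and scaled to
    physical units. ``base_hint`` / ``apex_hint`` are (x, y) positions in
    pixel units (x = column, y = row) and are snapped to the nearest
    boundary vertex. The mask's row axis is treated as a plain Cartesian
    coordinate (no image-row flipping); the moment radii are unaffected
    by that reflection.
    """
    try:
        from skimage import measure
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError(
            "mask input requires scikit-image (install extra 'wingshape[image]')"
        ) from exc

    mask = np.asarray(binary_mask).astype(bool)
    if pixel_scale <= 0:
        raise ValidationError("pixel_scale must be positive")
    if not mask.any():
        raise GeometryError("mask is empty")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise GeometryError(
            f"mask must contain exactly one connected component, found {n_comp}"
        )
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # outer boundary; ignore interior holes
    verts_px = np.column_stack([contour[:, 1], contour[:, 0]])  # (x=col, y=row)
    verts = verts_px * pixel_scale

    def snap(hint):
        hint = np.asarray(hint, dtype=float)
        return verts[np.argmin(np.sum((verts_px - hint) ** 2, axis=1))]

    return WingOutline(
        vertices=verts, base_point=snap(base_hint), apex_point=snap(apex_hint)
    )
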