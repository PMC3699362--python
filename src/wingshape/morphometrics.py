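"""Geometric morphometrics: Procrustes superimposition and shape variables.

The analysis chain is the classical landmark-based one:

1. each specimen's k x 2 landmark configuration is centered, scaled to
   unit centroid size and rotated onto an iteratively updated consensus
   (Generalized Procrustes Analysis);
2. designated semilandmarks — curve points without point-to-point
   homology — are allowed to slide along their local tangent directions
   so as to minimize the Procrustes distance to the consensus;
3. aligned specimens are projected into the tangent space at the
   consensus and expressed as partial-warp scores (eigenvectors of the
   thin-plate-spline bending-energy matrix) plus the two-dimensional
   uniform (affine) component, 2k - 4 shape variables in total;
4. thin-plate-spline deformation grids visualize the consensus-to-target
   mapping, and univariate shape scores are obtained by projecting
   specimens onto the regression vector of the aligned coordinates on a
   covariate (the Drake-Klingenberg allometric shape score).

Reflections are disallowed during alignment by default (wings of one body
side); pass ``allow_reflection=True`` for mixed-side data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "LandmarkSet",
    "ShapeSpace",
    "DeformationGrid",
    "centroid_size",
    "procrustes_distance",
    "gpa",
    "shape_variables",
    "tps_grid",
    "shape_scores",
]


@dataclass
class LandmarkSet:
    """One specimen's landmark configuration with semilandmark flags."""

    coords: np.ndarray  # (k, 2), physical units
    semilandmark_indices: tuple[int, ...] = ()
    specimen_id: str = ""
    taxon_id: str = ""
    wing: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        k = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or k < 3:
            raise ValidationError(
                f"coords must be (k >= 3, 2), got {self.coords.shape}"
            )
        self.semilandmark_indices = tuple(sorted(set(int(i) for i in self.semilandmark_indices)))
        if self.semilandmark_indices:
            if min(self.semilandmark_indices) < 0 or max(self.semilandmark_indices) >= k:
                raise ValidationError("semilandmark index out of range")
            if len(self.semilandmark_indices) >= k:
                raise ValidationError("cannot flag every landmark as sliding")
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        scale = max(float(np.ptp(self.coords)), 1.0)
        if dist.min() < 1e-12 * scale:
            raise ValidationError(
                f"coincident landmarks in specimen {self.specimen_id!r}"
            )


@dataclass
class ShapeSpace:
    """Output of GPA: consensus, aligned specimens, sizes, shape variables."""

    consensus: np.ndarray  # (k, 2), centered, unit centroid size
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,), sizes of the raw configurations
    semilandmark_indices: tuple[int, ...] = ()
    specimen_ids: tuple[str, ...] = ()
    taxon_ids: tuple[str, ...] = ()
    wings: tuple[str, ...] = ()
    ss_history: list = field(default_factory=list)
    n_iterations: int = 0
    # filled lazily by shape_variables()
    bending_energy_eigenvalues: np.ndarray | None = None
    _tangent_basis: np.ndarray | None = field(default=None, repr=False)
    _similarity_basis: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_specimens(self) -> int:
        return len(self.aligned)

    @property
    def n_landmarks(self) -> int:
        return len(self.consensus)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to the centroid.

    The standard geometric-morphometric size measure; log-transformed it
    serves as the body-size proxy in the allometric analyses.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or len(X) < 3:
        raise ValidationError(f"need a (k >= 3, 2) configuration, got {X.shape}")
    c = X - X.mean(axis=0)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0.0:
        raise ValidationError("degenerate configuration: all landmarks coincide")
    return cs


def _normalize(X: np.ndarray) -> np.ndarray:
    c = X - X.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def _optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal R minimizing ||A @ R - B||_F (det(R) = +1 unless allowed)."""
    U, s, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.diag([1.0, -1.0])
        R = U @ D @ Vt
    return R


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size; the distance is the
    Frobenius norm of the residual after the optimal rotation.
    """
    A, B = _normalize(np.asarray(a, float)), _normalize(np.asarray(b, float))
    R = _optimal_rotation(A, B, allow_reflection)
    return float(np.linalg.norm(A @ R - B))


def _tangent_estimates(X: np.ndarray, idx: Sequence[int]) -> dict[int, np.ndarray]:
    """Unit tangent per semilandmark: the chord between its two index
    neighbors (single adjacent chord at the ends)."""
    k = len(X)
    out = {}
    for j in idx:
        lo = j - 1 if j > 0 else j
        hi = j + 1 if j < k - 1 else j
        t = X[hi] - X[lo]
        n = np.linalg.norm(t)
        out[j] = t / n if n > 0 else np.array([1.0, 0.0])
    return out


def gpa(
    specimens: Sequence[LandmarkSet] | Sequence[np.ndarray],
    slide: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
    slide_iterations: int = 10,
    allow_reflection: bool = False,
) -> ShapeSpace:
    """Generalized Procrustes Analysis, optionally with sliding semilandmarks.

    Specimens are centered, scaled to unit centroid size and rotated to the
    running consensus (the mean of the aligned configurations, renormalized
    each round). When ``slide`` is true, semilandmarks are displaced along
    their neighbor-chord tangent directions by the amount that minimizes
    the distance to the current consensus, alternating with
    re-superimposition. A slide that fails to reduce a specimen's
    Procrustes distance (possible after the re-normalization it entails)
    is rolled back, so the total Procrustes sum of squares descends
    monotonically.

    Sliding runs during the first ``slide_iterations`` rounds only: the
    minimized-distance criterion leaves the position of the consensus
    semilandmarks along their own curve essentially unidentified (a gauge
    direction), so fully iterated sliding drifts instead of converging.
    Displacements are far below digitizing noise after a few rounds; the
    remaining rounds are plain GPA, which converges geometrically to the
    ``tol`` on consensus change.

    Raises :class:`ConvergenceError` (with the consensus-change history in
    ``diagnostics``) if ``max_iter`` rounds do not reach ``tol``.
    """
    sets = [
        s if isinstance(s, LandmarkSet) else LandmarkSet(coords=np.asarray(s, float))
        for s in specimens
    ]
    if not sets:
        raise ValidationError("no specimens")
    k = len(sets[0].coords)
    semi = sets[0].semilandmark_indices
    for s in sets[1:]:
        if len(s.coords) != k:
            raise ValidationError(
                f"landmark count mismatch: {len(s.coords)} vs {k}"
            )
        if slide and s.semilandmark_indices != semi:
            raise ValidationError("semilandmark sets differ between specimens")
    if slide and not semi:
        slide = False

    sizes = np.array([centroid_size(s.coords) for s in sets])
    A = np.stack([_normalize(s.coords) for s in sets])
    n = len(A)

    if n == 1:
        return ShapeSpace(
            consensus=A[0].copy(),
            aligned=A.copy(),
            centroid_sizes=sizes,
            semilandmark_indices=semi,
            specimen_ids=tuple(s.specimen_id for s in sets),
            taxon_ids=tuple(s.taxon_id for s in sets),
            wings=tuple(s.wing for s in sets),
            n_iterations=0,
        )

    consensus = A[0].copy()
    ss_history: list[float] = []
    deltas: list[float] = []
    for it in range(max_iter):
        # superimpose on the current consensus
        for i in range(n):
            A[i] = A[i] @ _optimal_rotation(A[i], consensus, allow_reflection)

        if slide and it < slide_iterations:
            for i in range(n):
                before = float(((A[i] - consensus) ** 2).sum())
                candidate = A[i].copy()
                tangents = _tangent_estimates(candidate, semi)
                for j, t in tangents.items():
                    shift = float(t @ (consensus[j] - candidate[j]))
                    candidate[j] = candidate[j] + shift * t
                candidate = _normalize(candidate)
                candidate = candidate @ _optimal_rotation(
                    candidate, consensus, allow_reflection
                )
                if float(((candidate - consensus) ** 2).sum()) < before:
                    A[i] = candidate

        new_consensus = A.mean(axis=0)
        ss_history.append(float(((A - new_consensus) ** 2).sum()))
        new_consensus = _normalize(new_consensus)
        # keep orientation stable across iterations
        new_consensus = new_consensus @ _optimal_rotation(
            new_consensus, consensus, allow_reflection
        )
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        deltas.append(delta)
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {deltas[-1]:.3e} > tol {tol:.1e})",
            diagnostics={"deltas": deltas, "ss_history": ss_history},
        )

    for i in range(n):
        A[i] = A[i] @ _optimal_rotation(A[i], consensus, allow_reflection)

    return ShapeSpace(
        consensus=consensus,
        aligned=A,
        centroid_sizes=sizes,
        semilandmark_indices=semi,
        specimen_ids=tuple(s.specimen_id for s in sets),
        taxon_ids=tuple(s.taxon_id for s in sets),
        wings=tuple(s.wing for s in sets),
        ss_history=ss_history,
        n_iterations=it + 1,
    )


# ---------------------------------------------------------------------------
# Shape variables: partial warps + uniform component
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _bending_energy_matrix(C: np.ndarray) -> np.ndarray:
    """Upper-left k x k block of the inverse bordered TPS system at C."""
    k = len(C)
    d2 = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2)
    Q = np.column_stack([np.ones(k), C])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)  # symmetrize against round-off


def _similarity_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4 x 2k) of the similarity directions at centered C:
    two translations, infinitesimal rotation, scaling."""
    k = len(C)
    tx = np.zeros((k, 2))
    tx[:, 0] = 1.0
    ty = np.zeros((k, 2))
    ty[:, 1] = 1.0
    rot = np.column_stack([-C[:, 1], C[:, 0]])
    scl = C.copy()
    vecs = [v.ravel() for v in (tx, ty, rot, scl)]
    return np.stack([v / np.linalg.norm(v) for v in vecs])


def _shape_basis(space: ShapeSpace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(basis (2k x 2k-4), similarity basis (4 x 2k), bending eigenvalues).

    Columns: partial warps ordered by decreasing bending energy (x then y
    score for each warp), followed by the two uniform columns. The whole
    basis is orthonormal, so projections are plain dot products and the
    total variance of the scores equals the tangent-space variance.
    """
    C = space.consensus
    k = len(C)
    if k < 4:
        raise ValidationError(f"need k >= 4 landmarks for shape variables, got {k}")
    B = _bending_energy_matrix(C)
    w, E = np.linalg.eigh(B)
    keep = w > max(w.max(), 1.0) * 1e-10
    if keep.sum() != k - 3:
        raise ValidationError(
            f"bending-energy matrix rank {int(keep.sum())} != k - 3 = {k - 3} "
            "(nearly collinear landmarks?)"
        )
    order = np.argsort(w[keep])[::-1]
    evals = w[keep][order]
    E = E[:, keep][:, order]  # (k, k-3), columns by decreasing energy

    cols = []
    for i in range(E.shape[1]):
        e = E[:, i]
        vx = np.zeros((k, 2))
        vx[:, 0] = e
        vy = np.zeros((k, 2))
        vy[:, 1] = e
        cols.append(vx.ravel())
        cols.append(vy.ravel())

    sim = _similarity_basis(C)
    # uniform component: affine deformations of the consensus minus the
    # similarity part (shear and anisotropic stretch directions)
    A1 = np.array([[1.0, 0.0], [0.0, -1.0]])
    A2 = np.array([[0.0, 1.0], [1.0, 0.0]])
    uni = []
    for Am in (A1, A2):
        u = (C @ Am).ravel()
        u = u - sim.T @ (sim @ u)
        for prev in uni:
            u = u - (prev @ u) * prev
        u = u / np.linalg.norm(u)
        uni.append(u)
    cols.extend(uni)
    basis = np.column_stack(cols)  # (2k, 2k-4)
    return basis, sim, evals


def shape_variables(space: ShapeSpace) -> np.ndarray:
    """Partial-warp + uniform scores, the n x (2k - 4) shape-variable matrix.

    Residuals from the consensus are orthogonally projected into the
    tangent space before scoring, so an affine-only deformation loads
    exclusively on the two uniform columns. The basis and the bending
    eigenvalues are cached on the ShapeSpace.
    """
    if space._tangent_basis is None:
        basis, sim, evals = _shape_basis(space)
        space._tangent_basis = basis
        space._similarity_basis = sim
        space.bending_energy_eigenvalues = evals
    basis, sim = space._tangent_basis, space._similarity_basis
    n, k = space.n_specimens, space.n_landmarks
    V = (space.aligned - space.consensus).reshape(n, 2 * k)
    V = V - (V @ sim.T) @ sim  # tangent projection
    return V @ basis


def tangent_residuals(space: ShapeSpace) -> np.ndarray:
    """Tangent-projected residuals (n, k, 2) from the consensus; the exact
    quantity the shape variables encode."""
    shape_variables(space)  # ensure basis cached
    n, k = space.n_specimens, space.n_landmarks
    V = (space.aligned - space.consensus).reshape(n, 2 * k)
    V = V - (V @ space._similarity_basis.T) @ space._similarity_basis
    return V.reshape(n, k, 2)


# ---------------------------------------------------------------------------
# Thin-plate spline deformation grids
# ---------------------------------------------------------------------------


@dataclass
class DeformationGrid:
    """An interpolating TPS map from a reference to a target configuration."""

    source_landmarks: np.ndarray  # (k, 2)
    target_landmarks: np.ndarray  # (k, 2)
    weights: np.ndarray  # (k, 2) warp coefficients
    affine: np.ndarray  # (3, 2): row 0 offset, rows 1-2 linear part
    source_grid: np.ndarray  # (g*g, 2)
    mapped_grid: np.ndarray  # (g*g, 2)

    def transform(self, points: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((P[:, None, :] - self.source_landmarks[None, :, :]) ** 2).sum(-1)
        U = _tps_kernel(d2)
        out = (
            self.affine[0]
            + P @ self.affine[1:]
            + U @ self.weights
        )
        return out

    @property
    def bending_energy(self) -> float:
        d2 = (
            (self.source_landmarks[:, None, :] - self.source_landmarks[None, :, :]) ** 2
        ).sum(-1)
        K = _tps_kernel(d2)
        return float(np.trace(self.weights.T @ K @ self.weights))


def tps_grid(
    consensus: np.ndarray,
    target: np.ndarray,
    grid_density: int = 20,
) -> DeformationGrid:
    """Interpolating thin-plate spline from ``consensus`` to ``target``.

    Solves the bordered kernel system (kernel U(r) = r^2 log r^2) so that
    each consensus landmark maps exactly onto its target partner; the
    deformation is visualized on a grid_density x grid_density lattice
    spanning the consensus bounding box (10% margin).
    """
    C = np.asarray(consensus, dtype=float)
    T = np.asarray(target, dtype=float)
    if C.shape != T.shape or C.ndim != 2 or C.shape[1] != 2:
        raise ValidationError(f"configurations must share a (k, 2) shape: {C.shape} vs {T.shape}")
    k = len(C)
    d2 = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2)
    Q = np.column_stack([np.ones(k), C])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = T
    cond = np.linalg.cond(L)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "TPS system is singular — the landmarks are (nearly) collinear, "
            "so the interpolant is not unique"
        )
    params = np.linalg.solve(L, rhs)
    W, Aff = params[:k], params[k:]

    lo, hi = C.min(axis=0), C.max(axis=0)
    margin = 0.1 * (hi - lo)
    gx = np.linspace(lo[0] - margin[0], hi[0] + margin[0], grid_density)
    gy = np.linspace(lo[1] - margin[1], hi[1] + margin[1], grid_density)
    XX, YY = np.meshgrid(gx, gy)
    grid = np.column_stack([XX.ravel(), YY.ravel()])

    deform = DeformationGrid(
        source_landmarks=C,
        target_landmarks=T,
        weights=W,
        affine=Aff,
        source_grid=grid,
        mapped_grid=np.empty_like(grid),
    )
    deform.mapped_grid = deform.transform(grid)
    return deform


# ---------------------------------------------------------------------------
# Allometric shape scores (Drake-Klingenberg)
# ---------------------------------------------------------------------------


def shape_scores(space: ShapeSpace, covariate: np.ndarray) -> np.ndarray:
    """Project each specimen onto the shape-on-covariate regression vector.

    Every aligned-coordinate column is regressed on the covariate; the
    score of a specimen is the dot product of its (centered) coordinate
    vector with the unit regression vector, which keeps the residual
    variation lying along that direction of shape space. Identical
    specimens yield identical (zero) scores.
    """
    x = np.asarray(covariate, dtype=float)
    n, k = space.n_specimens, space.n_landmarks
    if len(x) != n:
        raise ValidationError(f"covariate length {len(x)} != {n} specimens")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValidationError("constant covariate: regression is degenerate")
    Y = space.aligned.reshape(n, 2 * k)
    Yc = Y - Y.mean(axis=0)
    b = Yc.T @ xc / sxx
    nb = np.linalg.norm(b)
    if nb == 0.0:
        return np.zeros(n)
    return Yc @ (b / nb)
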