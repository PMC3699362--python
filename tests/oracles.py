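"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a route deliberately
different from the library implementation (dense GLS algebra, direct
determinant ratios, brute-force grid search, quadrature), so agreement
is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np
import scipy.integrate
import scipy.stats


def bm_covariance(phylogeny) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance among tips: shared root-to-MRCA path length."""
    tree = phylogeny.tree
    labels = phylogeny.tip_labels
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    # depth of every node
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + node.edge.length
    # ancestor sets
    anc = {}
    for lab, leaf in leaves.items():
        path = set()
        node = leaf
        while node is not None:
            path.add(node)
            node = node.parent_node
        anc[lab] = path
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                C[i, j] = depth[leaves[a]]
            else:
                shared = anc[a] & anc[b]
                C[i, j] = max(depth[nd] for nd in shared)
    return C, labels


def gls_slope(phylogeny, x: dict, y: dict) -> float:
    """GLS slope of y on x (with intercept) under the BM tip covariance —
    algebraically identical to the through-origin contrast slope."""
    C, labels = bm_covariance(phylogeny)
    Ci = np.linalg.inv(C)
    X = np.column_stack([np.ones(len(labels)), [x[l] for l in labels]])
    Y = np.array([y[l] for l in labels])
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ Y)
    return float(beta[1])


def wilks_det_ratio(Y: np.ndarray, X_full: np.ndarray, term_cols: list[int]) -> float:
    """Wilks' lambda = det(E) / det(E + H) by direct projection algebra."""

    def resid_cross(Y, X):
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ B
        return R.T @ R

    E = resid_cross(Y, X_full)
    X_red = np.delete(X_full, term_cols, axis=1)
    E_red = resid_cross(Y, X_red)
    H = E_red - E
    return float(np.linalg.det(E) / np.linalg.det(E + H))


def normal_equation_coefficients(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS coefficients straight from the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def grid_search_rotation(A: np.ndarray, B: np.ndarray, step: float = 0.001) -> float:
    """Minimum ||A R(theta) - B|| by brute force over the rotation angle:
    a 0.001-rad global grid followed by a fine scan around its best cell."""

    def dist(thetas):
        c, s = np.cos(thetas), np.sin(thetas)
        # ||A R - B||^2 expanded: rotation enters through two dot products
        m = A.T @ B
        cross = (m[0, 0] + m[1, 1]) * c + (m[1, 0] - m[0, 1]) * s
        return np.sqrt((A**2).sum() + (B**2).sum() - 2 * cross)

    coarse = np.arange(0.0, 2 * np.pi, step)
    d = dist(coarse)
    best = coarse[np.argmin(d)]
    fine = np.linspace(best - step, best + step, 4001)
    return float(dist(fine).min())


def beta_rsm_quadrature(alpha: float, beta: float) -> float:
    """sqrt(int r^2 Beta_pdf(r) dr) by adaptive quadrature (independent of
    the closed-form moment formula)."""
    val, _ = scipy.integrate.quad(
        lambda r: r**2 * scipy.stats.beta.pdf(r, alpha, beta), 0.0, 1.0
    )
    return float(np.sqrt(val))


def tps_bordered_solve(C: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense solve of the bordered TPS kernel system, written independently."""
    k = len(C)
    r2 = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    P = np.hstack([np.ones((k, 1)), C])
    top = np.hstack([K, P])
    bot = np.hstack([P.T, np.zeros((3, 3))])
    L = np.vstack([top, bot])
    rhs = np.vstack([T, np.zeros((3, 2))])
    sol = np.linalg.lstsq(L, rhs, rcond=None)[0]
    return sol[:k], sol[k:]
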