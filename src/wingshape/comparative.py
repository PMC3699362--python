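"""Statistical machinery for the allometric and phylogenetic analyses.

Conventional (species-level) side: ordinary least squares with linear and
quadratic size terms, MANCOVA on shape variables with Wilks' lambda,
ANCOVA across Odonata groups, a general linear model of the RSM on
coloration group plus size covariates, and non-allometric residuals.
Ordinary model fits run through :mod:`statsmodels`.

Phylogenetic side: Felsenstein's independent contrasts (with the usual
branch-length extension v' = v + v_l v_r / (v_l + v_r) at each ancestor),
branch-length transformations for contrast standardization diagnostics,
through-origin regression on positivized contrasts, Brownian-motion
simulation on a tree, and the simulation-null phylogenetic ANOVA whose
null F distribution comes from traits evolved under Brownian motion on
the study tree rather than from the F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA

from .exceptions import ValidationError
from .io import Phylogeny

__all__ = [
    "TaxonTraits",
    "FitResult",
    "ContrastSet",
    "IndependentContrasts",
    "PhyloAnovaResult",
    "species_means",
    "polynomial_regression",
    "mancova_wilks",
    "ancova",
    "glm_coloration",
    "nonallometric_residuals",
    "transform_branch_lengths",
    "independent_contrasts",
    "contrast_set",
    "contrast_regression",
    "brownian_simulate",
    "phylogenetic_anova",
    "standardization_diagnostic",
]


@dataclass
class TaxonTraits:
    """Per-taxon species means for one wing (the unit of replication)."""

    taxon_id: str
    wing: str
    rsm_mean: float
    log_centroid_size_mean: float
    coloration_group: int
    n_specimens: int

    def __post_init__(self):
        if not 1 <= int(self.coloration_group) <= 6:
            raise ValidationError(
                f"coloration_group must be in 1..6, got {self.coloration_group}"
            )
        if self.n_specimens < 1:
            raise ValidationError("n_specimens must be >= 1")


@dataclass
class FitResult:
    """A fitted model summary: coefficients, the overall test, and an
    optional per-term table (ANOVA / MANCOVA rows)."""

    kind: str
    coefficients: np.ndarray | None = None
    r_squared: float | None = None
    f_statistic: float | None = None
    df: tuple[int, int] | None = None
    p_value: float | None = None
    table: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Species means
# ---------------------------------------------------------------------------


def species_means(specimen_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-specimen table to per-taxon x wing arithmetic means.

    Expects columns ``taxon``, ``wing``, ``rsm``, ``log_centroid_size`` and
    optionally ``coloration_group`` (which must be constant within a
    taxon x wing cell). Species are the unit of replication downstream.
    """
    required = ["taxon", "wing", "rsm", "log_centroid_size"]
    missing = [c for c in required if c not in specimen_table.columns]
    if missing:
        raise ValidationError(f"specimen table is missing columns {missing}")
    g = specimen_table.groupby(["taxon", "wing"], sort=True)
    out = g.agg(
        rsm_mean=("rsm", "mean"),
        log_centroid_size_mean=("log_centroid_size", "mean"),
        n_specimens=("rsm", "size"),
    ).reset_index()
    if "coloration_group" in specimen_table.columns:
        cg = g["coloration_group"].agg(["min", "max", "first"]).reset_index()
        if (cg["min"] != cg["max"]).any():
            raise ValidationError(
                "coloration_group varies within a taxon x wing cell"
            )
        out["coloration_group"] = cg["first"].astype(int)
    return out


def taxon_traits_records(means: pd.DataFrame) -> list[TaxonTraits]:
    """Convert a species-means frame into :class:`TaxonTraits` records."""
    return [
        TaxonTraits(
            taxon_id=row.taxon,
            wing=row.wing,
            rsm_mean=row.rsm_mean,
            log_centroid_size_mean=row.log_centroid_size_mean,
            coloration_group=int(getattr(row, "coloration_group", 1)),
            n_specimens=int(row.n_specimens),
        )
        for row in means.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Conventional regressions and linear models
# ---------------------------------------------------------------------------


def polynomial_regression(y, x, degree: int) -> FitResult:
    """OLS of y on x (degree 1) or on x and x^2 (degree 2).

    Reports R^2 and the overall F with (degree, n - degree - 1) df — the
    linear/quadratic size regressions of the species means.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    n = len(y)
    if n <= degree + 1:
        raise ValidationError(f"need n > degree + 1 observations, got n = {n}")
    X = np.column_stack([x**d for d in range(1, degree + 1)])
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear design (x values carry no curvature)")
    fit = sm.OLS(y, design).fit()
    coef_table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["intercept"] + [f"x^{d}" if d > 1 else "x" for d in range(1, degree + 1)],
    )
    return FitResult(
        kind=f"polynomial(degree={degree})",
        coefficients=np.asarray(fit.params),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        table=coef_table,
        extra={"model": fit},
    )


def mancova_wilks(
    Y: np.ndarray,
    factor,
    covariate=None,
    include_interaction: bool = False,
) -> FitResult:
    """MANCOVA on multivariate responses: Wilks' lambda per model term.

    ``Y`` is the n x p shape-variable matrix; ``factor`` a categorical
    (e.g. fore/hind wing) and ``covariate`` a continuous regressor (e.g.
    the RSM). Each term's Wilks' lambda, Rao F approximation and df come
    from the multivariate linear model with all other terms retained.
    The interaction is omitted unless requested.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    factor = np.asarray(factor)
    levels = pd.unique(factor)
    if len(levels) < 2:
        raise ValidationError("factor needs >= 2 levels")
    dummies = pd.get_dummies(pd.Categorical(factor, categories=levels), drop_first=True)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    fac_idx = []
    for c in dummies.columns:
        fac_idx.append(len(cols))
        cols.append(dummies[c].to_numpy(dtype=float))
        names.append(f"factor[{c}]")
    cov_idx = []
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        cov_idx.append(len(cols))
        cols.append(cov)
        names.append("covariate")
        if include_interaction:
            for j, c in zip(fac_idx, dummies.columns):
                cov_idx_i = len(cols)
                cols.append(cols[j] * cov)
                names.append(f"factor[{c}]:covariate")
    X = np.column_stack(cols)
    q = X.shape[1]
    if p >= n - q:
        raise np.linalg.LinAlgError(
            f"within-group covariance is singular: p = {p} responses but only "
            f"{n - q} error df — reduce the number of shape variables"
        )
    term_columns = {"factor": fac_idx}
    if covariate is not None:
        term_columns["covariate"] = cov_idx[:1]
        if include_interaction:
            term_columns["factor:covariate"] = list(range(q - len(fac_idx), q))
    rows = []
    if p == 1:
        # univariate case: Wilks' lambda is the residual-SS ratio and the
        # Rao approximation reduces to the exact partial F test
        yv = Y[:, 0]
        for term, idx in term_columns.items():
            ss_full = _resid_ss(yv, X)
            ss_red = _resid_ss(yv, np.delete(X, idx, axis=1))
            lam = ss_full / ss_red
            df1, df2 = len(idx), n - q
            F = (ss_red - ss_full) / df1 / (ss_full / df2)
            rows.append(
                {
                    "term": term,
                    "wilks_lambda": lam,
                    "F": F,
                    "df_num": float(df1),
                    "df_den": float(df2),
                    "p": float(scipy.stats.f.sf(F, df1, df2)),
                }
            )
    else:
        mv = MANOVA(endog=Y, exog=X)
        hypotheses = []
        for term, idx in term_columns.items():
            L = np.zeros((len(idx), q))
            for r, j in enumerate(idx):
                L[r, j] = 1.0
            hypotheses.append((term, L, None))
        res = mv.mv_test(hypotheses=hypotheses)
        for term, _, _ in hypotheses:
            wrow = res.results[term]["stat"].loc["Wilks' lambda"]
            rows.append(
                {
                    "term": term,
                    "wilks_lambda": float(wrow["Value"]),
                    "F": float(wrow["F Value"]),
                    "df_num": float(wrow["Num DF"]),
                    "df_den": float(wrow["Den DF"]),
                    "p": float(wrow["Pr > F"]),
                }
            )
    table = pd.DataFrame(rows).set_index("term")
    return FitResult(kind="mancova", table=table, extra={"n": n, "p": p})


def _resid_ss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def ancova(y, group, covariate) -> FitResult:
    """ANCOVA: y ~ group (fixed factor) + covariate, no interaction.

    The layout of the Odonata-wide comparison: RSM against group
    (calopterygids / other damselflies / dragonflies) with body length as
    the covariate. Per-term F tests adjust each term for the other.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "grp": pd.Categorical(np.asarray(group)),
            "cov": np.asarray(covariate, dtype=float),
        }
    )
    if df["grp"].nunique() < 2:
        raise ValidationError("need >= 2 groups")
    fit = smf.ols("y ~ C(grp) + cov", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2).rename(
        index={"C(grp)": "group", "cov": "covariate"}
    )
    return FitResult(
        kind="ancova",
        r_squared=float(fit.rsquared),
        table=table,
        extra={"model": fit},
    )


def glm_coloration(
    rsm,
    coloration_group,
    log_centroid_size,
    start_with_interactions: bool = False,
    alpha: float = 0.05,
) -> FitResult:
    """General linear model of the RSM on coloration group and size.

    Response: RSM species means. Fixed factor: coloration group (1..6).
    Covariates: log centroid size and its square (the quadratic allometry).
    Each term's sum of squares is adjusted for all other terms. With
    ``start_with_interactions`` the group x size interactions are included
    and then removed one by one (least significant first) while
    non-significant at ``alpha``, mirroring stepwise simplification.
    """
    df = pd.DataFrame(
        {
            "rsm": np.asarray(rsm, dtype=float),
            "grp": pd.Categorical(np.asarray(coloration_group)),
            "lcs": np.asarray(log_centroid_size, dtype=float),
        }
    )
    if df["grp"].value_counts().min() < 1:
        raise ValidationError("empty coloration group")
    base_terms = ["C(grp)", "lcs", "I(lcs ** 2)"]
    inter_terms = ["C(grp):lcs", "C(grp):I(lcs ** 2)"] if start_with_interactions else []
    dropped: list[str] = []
    while True:
        formula = "rsm ~ " + " + ".join(base_terms + inter_terms)
        fit = smf.ols(formula, data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        if not inter_terms:
            break
        inter_p = table.loc[inter_terms, "PR(>F)"]
        worst = inter_p.idxmax()
        if inter_p.max() > alpha:
            inter_terms.remove(worst)
            dropped.append(worst)
        else:
            break
    pretty = {
        "C(grp)": "coloration_group",
        "lcs": "log_centroid_size",
        "I(lcs ** 2)": "log_centroid_size^2",
        "Residual": "Error",
    }
    table = table.rename(index=pretty)
    return FitResult(
        kind="glm_coloration",
        r_squared=float(fit.rsquared),
        table=table,
        extra={"model": fit, "dropped_interactions": dropped},
    )


def nonallometric_residuals(rsm, log_centroid_size) -> np.ndarray:
    """Residuals of the RSM from its quadratic size regression.

    The non-allometric component of the RSM: zero-mean and orthogonal to
    1, log centroid size and its square. Used as the size-corrected trait
    for the phylogenetic ANOVA on coloration groups.
    """
    y = np.asarray(rsm, dtype=float)
    x = np.asarray(log_centroid_size, dtype=float)
    if len(y) <= 3:
        raise ValidationError("need n > 3 observations for a quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# Branch-length transformations
# ---------------------------------------------------------------------------

_TRANSFORMS = ("none", "log", "sqrt", "exp")


def transform_branch_lengths(phylogeny: Phylogeny, method: str = "none") -> Phylogeny:
    """Return a copy of the tree with transformed branch lengths.

    ``log`` and ``sqrt`` apply the elementwise map; ``exp`` first rescales
    the tree to unit height (so the transform is scale-free) and then maps
    b -> exp(b). Used to make standardized contrasts homoscedastic: after
    an adequate transform, |contrast| should be uncorrelated with its
    standard deviation (see :func:`standardization_diagnostic`).
    """
    if method not in _TRANSFORMS:
        raise ValueError(f"method must be one of {_TRANSFORMS}, got {method!r}")
    out = phylogeny.copy()
    if method == "none":
        return out
    tree = out.tree
    root = tree.seed_node
    edges = [n.edge for n in tree.preorder_node_iter() if n is not root]
    if method == "log":
        if any(e.length <= 0 for e in edges):
            raise ValidationError("log transform requires strictly positive branch lengths")
        for e in edges:
            e.length = float(np.log(e.length))
    elif method == "sqrt":
        for e in edges:
            e.length = float(np.sqrt(e.length))
    elif method == "exp":
        h = out.height
        if h <= 0:
            raise ValidationError("tree height must be positive for exp transform")
        for e in edges:
            e.length = float(np.exp(e.length / h))
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------


@dataclass
class IndependentContrasts:
    """Standardized contrasts of one trait plus their expected variances."""

    contrasts: np.ndarray  # (tips - 1,), standardized
    raw_contrasts: np.ndarray  # unstandardized differences
    variances: np.ndarray  # branch-length sums v_l + v_r per contrast
    node_depths: np.ndarray  # postorder index of the contrast's ancestor
    root_value: float  # weighted ancestral estimate at the root

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def sigma2_reml(self) -> float:
        """REML-style Brownian rate: the mean squared standardized contrast."""
        return float(np.mean(self.contrasts**2))


def independent_contrasts(
    phylogeny: Phylogeny, trait: Mapping[str, float]
) -> IndependentContrasts:
    """Felsenstein's independent contrasts of one continuous trait.

    Postorder recursion: the contrast at each internal node is the
    difference of its two children's values divided by the square root of
    the summed branch lengths; the ancestral value is the branch-length
    weighted average and the ancestor's own branch is lengthened by
    v_l v_r / (v_l + v_r). Yields exactly tips - 1 contrasts on a fully
    bifurcating tree; polytomies are an explicit error (no silent
    resolution).
    """
    if phylogeny.has_polytomy:
        raise ValidationError(
            "independent contrasts require a fully bifurcating tree; "
            "resolve polytomies explicitly before calling"
        )
    missing = [t for t in phylogeny.tip_labels if t not in trait]
    if missing:
        raise ValidationError(f"trait values missing for tips: {missing}")

    vals: dict = {}
    vs: dict = {}
    raw, var, depth = [], [], []
    for i, node in enumerate(phylogeny.tree.postorder_node_iter()):
        if node.is_leaf():
            vals[node] = float(trait[node.taxon.label])
            vs[node] = float(node.edge.length)
        else:
            c1, c2 = node.child_nodes()
            v1, v2 = vs[c1], vs[c2]
            if v1 + v2 <= 0:
                raise ValidationError(
                    "zero expected contrast variance (two zero-length sister branches)"
                )
            raw.append(vals[c1] - vals[c2])
            var.append(v1 + v2)
            depth.append(i)
            vals[node] = (v2 * vals[c1] + v1 * vals[c2]) / (v1 + v2)
            extra = v1 * v2 / (v1 + v2)
            edge = node.edge.length if node.parent_node is not None else 0.0
            vs[node] = float(edge) + extra
    raw = np.asarray(raw)
    var = np.asarray(var)
    return IndependentContrasts(
        contrasts=raw / np.sqrt(var),
        raw_contrasts=raw,
        variances=var,
        node_depths=np.asarray(depth),
        root_value=vals[phylogeny.tree.seed_node],
    )


@dataclass
class ContrastSet:
    """Paired standardized contrasts of two traits, positivized on x.

    Sign convention: each contrast pair is jointly flipped so that the
    x (predictor) contrast is non-negative; the through-origin fit is
    invariant to these flips.
    """

    contrasts_x: np.ndarray
    contrasts_y: np.ndarray
    contrast_sd: np.ndarray
    positivized: np.ndarray  # bool flags: True where the pair was flipped

    def __len__(self) -> int:
        return len(self.contrasts_x)


def contrast_set(
    phylogeny: Phylogeny,
    trait_x: Mapping[str, float],
    trait_y: Mapping[str, float],
) -> ContrastSet:
    """Standardized, positivized contrast pairs of two traits on one tree."""
    icx = independent_contrasts(phylogeny, trait_x)
    icy = independent_contrasts(phylogeny, trait_y)
    flip = icx.contrasts < 0
    sgn = np.where(flip, -1.0, 1.0)
    return ContrastSet(
        contrasts_x=icx.contrasts * sgn,
        contrasts_y=icy.contrasts * sgn,
        contrast_sd=icx.sd,
        positivized=flip,
    )


def contrast_regression(contrasts: ContrastSet) -> FitResult:
    """Least-squares regression of y-contrasts on x-contrasts through the origin.

    The origin-constrained fit is the correct one for contrasts (their
    expectation is zero under Brownian motion); R^2 is computed about the
    origin, with the about-the-mean version reported alongside. df are
    (1, n_contrasts - 1).
    """
    x, y = contrasts.contrasts_x, contrasts.contrasts_y
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 contrasts, got {n}")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValidationError("x-contrasts are all zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2_origin = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df = (1, n - 1)
    if ss_res == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_tot - ss_res) / (ss_res / df[1])
        p = float(scipy.stats.f.sf(f_stat, *df))
    yc = y - y.mean()
    ss_tot_mean = float(yc @ yc)
    r2_mean = 1.0 - ss_res / ss_tot_mean if ss_tot_mean > 0 else 0.0
    return FitResult(
        kind="contrast_regression",
        coefficients=np.array([slope]),
        r_squared=r2_origin,
        f_statistic=float(f_stat),
        df=df,
        p_value=p,
        extra={"r_squared_about_mean": r2_mean, "n_contrasts": n},
    )


def standardization_diagnostic(ic: IndependentContrasts) -> float:
    """Pearson correlation of |standardized contrast| with its standard
    deviation — near zero when branch lengths standardize adequately."""
    a = np.abs(ic.contrasts)
    if a.std() == 0 or ic.sd.std() == 0:
        return 0.0
    return float(np.corrcoef(a, ic.sd)[0, 1])


# ---------------------------------------------------------------------------
# Brownian-motion simulation and phylogenetic ANOVA
# ---------------------------------------------------------------------------


def brownian_simulate(
    phylogeny: Phylogeny,
    sigma2: float,
    seed: int | np.random.Generator,
    n_rep: int = 1,
    root_value: float = 0.0,
) -> np.ndarray:
    """Simulate Brownian trait evolution on the tree.

    Each edge adds an independent normal increment with variance
    sigma2 x branch length. Returns an (n_rep, n_tips) matrix with columns
    ordered like ``phylogeny.tip_labels``; reproducible under a fixed seed.
    """
    if sigma2 < 0:
        raise ValidationError(f"sigma2 must be >= 0, got {sigma2}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values: dict = {}
    tips = []
    for node in phylogeny.tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.full(n_rep, float(root_value))
        else:
            bl = float(node.edge.length)
            step = (
                rng.normal(0.0, np.sqrt(sigma2 * bl), size=n_rep)
                if sigma2 * bl > 0
                else 0.0
            )
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            tips.append(node)
    order = {leaf.taxon.label: i for i, leaf in enumerate(phylogeny.tree.leaf_node_iter())}
    out = np.empty((n_rep, len(tips)))
    for node in tips:
        out[:, order[node.taxon.label]] = values[node]
    return out


def _oneway_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F, vectorized over the leading axis of ``values``."""
    V = np.atleast_2d(values)
    n = V.shape[1]
    G = np.zeros((n, n_groups))
    G[np.arange(n), codes] = 1.0
    counts = G.sum(axis=0)
    means = (V @ G) / counts
    grand = V.mean(axis=1, keepdims=True)
    ssb = (counts * (means - grand) ** 2).sum(axis=1)
    sst = ((V - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    return F if values.ndim > 1 else float(F[0])


@dataclass
class PhyloAnovaResult:
    f_observed: float
    p_phylogenetic: float
    p_parametric: float
    df: tuple[int, int]
    sigma2: float
    n_sim: int
    f_null: np.ndarray = field(repr=False, default=None)


def phylogenetic_anova(
    phylogeny: Phylogeny,
    trait: Mapping[str, float],
    groups: Mapping[str, object],
    n_sim: int = 1000,
    seed: int | None = 0,
    sigma2: float | None = None,
    conservative_p: bool = True,
) -> PhyloAnovaResult:
    """One-way ANOVA with a Brownian-motion simulation null.

    The observed F compares the trait across groups at the tips; its
    reference distribution is built by re-simulating the trait under
    Brownian motion on the study tree ``n_sim`` times (rate estimated
    from the data by REML on contrasts unless supplied) and recomputing F
    with the group labels fixed. The phylogenetic p-value is
    (count(F_sim >= F_obs) + 1) / (n_sim + 1); set ``conservative_p=False``
    for the plain proportion.
    """
    tips = phylogeny.tip_labels
    missing = [t for t in tips if t not in trait or t not in groups]
    if missing:
        raise ValidationError(f"trait or group missing for tips: {missing}")
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100 for a usable null")
    y = np.array([float(trait[t]) for t in tips])
    labels = pd.Categorical([groups[t] for t in tips])
    n_groups = len(labels.categories)
    if n_groups < 2:
        raise ValidationError("need >= 2 groups")
    counts = pd.Series(labels).value_counts()
    if counts.min() < 1:
        raise ValidationError("every group needs >= 1 tip")
    codes = np.asarray(labels.codes)

    f_obs = _oneway_f(y, codes, n_groups)
    if sigma2 is None:
        sigma2 = independent_contrasts(phylogeny, dict(zip(tips, y))).sigma2_reml
    sims = brownian_simulate(phylogeny, sigma2, seed=seed, n_rep=n_sim)
    f_null = _oneway_f(sims, codes, n_groups)
    exceed = int(np.sum(f_null >= f_obs))
    if conservative_p:
        p_phylo = (exceed + 1) / (n_sim + 1)
    else:
        p_phylo = exceed / n_sim
    df = (n_groups - 1, len(y) - n_groups)
    return PhyloAnovaResult(
        f_observed=float(f_obs),
        p_phylogenetic=float(p_phylo),
        p_parametric=float(scipy.stats.f.sf(f_obs, *df)),
        df=df,
        sigma2=float(sigma2),
        n_sim=n_sim,
        f_null=f_null,
    )
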