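"""Fully synthetic wing datasets with analytically known ground truth.

The generator emulates the statistical structure of a museum-specimen
study of territorial calopterygid damselflies without using any real
measurements: a Yule phylogeny of ~37 taxa, Brownian-motion evolution of
log wing size, an RSM that declines linearly with size plus a separate
offset for the basal clade (the device that produces a hump across raw
species means while contrasts recover the negative linear trend), Beta-
family chord profiles whose second-moment radius is known in closed
form, polygon outlines realizing those profiles, and per-specimen
landmark configurations with digitizing noise.

The Beta family is a modeling convenience, not a biological claim: its
moments are exact, so every downstream RSM computation has an oracle.
All randomness flows from the single mandatory ``seed``; a dataset is
bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .exceptions import GeometryError, ValidationError
from .io import Phylogeny, TpsRecord, write_newick, write_tps
from .morphometrics import LandmarkSet
from .wing_geometry import WingOutline

__all__ = [
    "SimulationSpec",
    "SyntheticTaxon",
    "SyntheticSpecimen",
    "SyntheticDataset",
    "simulate_tree",
    "basal_clade",
    "simulate_traits",
    "rsm_to_beta",
    "beta_rsm",
    "outline_from_profile",
    "landmarks_from_outline",
    "generate_dataset",
    "write_dataset",
]

#: perimeter arc-length fractions of the 12 landmark template (base at 0,
#: leading edge, apex region near 0.5, trailing edge back to the base)
DEFAULT_TEMPLATE_FRACTIONS = (
    0.00, 0.09, 0.20, 0.31, 0.40, 0.47, 0.52, 0.60, 0.70, 0.80, 0.89, 0.96,
)
#: the two curve points treated as sliding semilandmarks
DEFAULT_SEMILANDMARKS = (3, 8)

_WINGS = ("fore", "hind")


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with study-scale defaults.

    Defaults describe a 37-taxon study with 5-10 specimens per taxon.
    Sizes are log centroid sizes (log mm); the Brownian rate yields a
    tip standard deviation of 0.25 on the height-1 tree. The RSM declines
    with size at ``rsm_slope`` per log-size unit, and the basal clade
    carries both a negative RSM offset and a negative size shift — the
    small-bodied, low-RSM basal genus that bends the raw species-mean
    relationship into a hump.
    """

    seed: int
    n_taxa: int = 37
    birth_rate: float = 1.0
    tree_newick: str | None = None
    root_log_size: float = 4.0
    bm_sigma2_size: float = 0.0625
    rsm_intercept: float = 0.56
    rsm_slope: float = -0.06
    clade_offset: float = -0.045
    basal_size_shift: float = -0.9
    residual_sd: float = 0.008
    specimens_min: int = 5
    specimens_max: int = 10
    specimen_size_sd: float = 0.05
    specimen_rsm_sd: float = 0.004
    beta_concentration: float = 4.0
    aspect_ratio: float = 5.5
    wing_length_per_size: float = 0.55
    hindwing_length_factor: float = 0.95
    n_vertices: int = 400
    n_strips: int = 500
    landmark_noise_sd: float = 0.15
    link_color_to_basal: bool = False
    max_basal_fraction: float = 0.15

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.n_taxa < 4:
            raise ValidationError(f"n_taxa must be >= 4, got {self.n_taxa}")
        if not (1 <= self.specimens_min <= self.specimens_max <= 50):
            raise ValidationError(
                "specimen range must satisfy 1 <= min <= max <= 50"
            )
        if self.residual_sd < 0 or self.bm_sigma2_size < 0:
            raise ValidationError("noise scales must be non-negative")


@dataclass
class SyntheticTaxon:
    """Ground truth for one taxon (per-wing RSM and chord-profile params)."""

    taxon_id: str
    true_log_size: float
    is_basal: bool
    true_rsm: dict  # wing -> float
    beta_params: dict  # wing -> (alpha, beta)
    coloration_group: dict  # wing -> int in 1..6
    n_specimens: int


@dataclass
class SyntheticSpecimen:
    """One simulated wing: outline plus digitized landmarks."""

    specimen_id: str
    taxon_id: str
    wing: str
    true_rsm: float
    true_log_size: float
    outline: WingOutline
    landmarks: LandmarkSet


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    phylogeny: Phylogeny
    taxa: list[SyntheticTaxon]
    specimens: list[SyntheticSpecimen]

    @property
    def taxa_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.taxa:
            for wing in _WINGS:
                rows.append(
                    {
                        "taxon": t.taxon_id,
                        "wing": wing,
                        "true_log_size": t.true_log_size,
                        "true_rsm": t.true_rsm[wing],
                        "is_basal": t.is_basal,
                        "coloration_group": t.coloration_group[wing],
                        "n_specimens": t.n_specimens,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(spec: SimulationSpec) -> Phylogeny:
    """A fully bifurcating Yule tree, rescaled to unit height.

    Pure-birth process: with k lineages the next speciation waits an
    Exp(k * birth_rate) time and splits a uniformly chosen lineage; after
    the n-th lineage appears one further waiting time elapses, so no
    terminal branch has zero length. Tips are labeled t01..tNN.
    Deterministic under the spec seed.

    The topology is conditioned on a small basal clade: trees are redrawn
    until the smaller child subtree of the root holds at most
    ``max_basal_fraction`` of the tips, mirroring study systems where the
    basal lineage is a genus of a few taxa rather than half the family.
    """
    if spec.tree_newick is not None:
        phy = Phylogeny.from_newick(spec.tree_newick)
        if phy.n_tips != spec.n_taxa:
            raise ValidationError(
                f"fixed tree has {phy.n_tips} tips, spec says {spec.n_taxa}"
            )
        return phy
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    max_basal = max(1, int(np.floor(spec.max_basal_fraction * spec.n_taxa)))
    for _ in range(1000):
        phy = _yule_tree(spec, rng)
        if len(basal_clade(phy)) <= max_basal:
            return phy
    raise ValidationError(
        f"could not draw a tree with basal clade <= {max_basal} tips in 1000 tries"
    )


def _yule_tree(spec: SimulationSpec, rng: np.random.Generator) -> Phylogeny:
    n = spec.n_taxa
    lam = spec.birth_rate

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    root.birth_time = 0.0
    # the root is the first speciation at time 0; its children are lineages
    c1, c2 = dendropy.Node(), dendropy.Node()
    t = 0.0
    for c in (c1, c2):
        c.birth_time = 0.0
        root.add_child(c)
    active = [c1, c2]
    while len(active) < n:
        k = len(active)
        t += float(rng.exponential(1.0 / (k * lam)))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    t += float(rng.exponential(1.0 / (n * lam)))  # final interval to present

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        end = getattr(node, "split_time", t)
        node.edge.length = end - node.birth_time
    # unit height, stable tip labels
    width = len(str(n))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_namespace.new_taxon(f"t{i + 1:0{width}d}")
    phy = Phylogeny(tree)
    h = phy.height
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = node.edge.length / h
    return Phylogeny(tree)


def basal_clade(phylogeny: Phylogeny) -> frozenset[str]:
    """Tip labels of the smaller child subtree of the root (first on ties)."""
    children = phylogeny.tree.seed_node.child_nodes()
    subtrees = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
    return min(subtrees, key=len)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------


def simulate_traits(
    phylogeny: Phylogeny, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-taxon true log sizes and per-wing true RSM values.

    log size evolves by Brownian motion from ``root_log_size``; the basal
    clade is shifted by ``basal_size_shift``. The RSM is linear in
    (log size - root log size) with slope ``rsm_slope``, offset by
    ``clade_offset`` in the basal clade, plus N(0, residual_sd^2) noise
    drawn independently per wing.
    """
    from .comparative import brownian_simulate

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 202]))
    tips = phylogeny.tip_labels
    basal = basal_clade(phylogeny)
    sizes = brownian_simulate(
        phylogeny, spec.bm_sigma2_size, seed=rng, n_rep=1,
        root_value=spec.root_log_size,
    )[0]
    is_basal = np.array([t in basal for t in tips])
    sizes = sizes + spec.basal_size_shift * is_basal

    rows = []
    for i, taxon in enumerate(tips):
        row = {"taxon": taxon, "true_log_size": sizes[i], "is_basal": bool(is_basal[i])}
        for wing in _WINGS:
            row[f"true_rsm_{wing}"] = (
                spec.rsm_intercept
                + spec.rsm_slope * (sizes[i] - spec.root_log_size)
                + (spec.clade_offset if is_basal[i] else 0.0)
                + float(rng.normal(0.0, spec.residual_sd))
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chord-profile family: Beta densities with closed-form moment radii
# ---------------------------------------------------------------------------


def beta_rsm(alpha: float, beta: float) -> float:
    """Closed-form second-moment radius of a Beta(alpha, beta) chord profile:
    sqrt(E[r^2]) with E[r^2] = Var + mean^2."""
    nu = alpha + beta
    m = alpha / nu
    return float(np.sqrt(m * (1 - m) / (nu + 1) + m**2))


def attainable_rsm_range(concentration: float = 4.0) -> tuple[float, float]:
    """RSM values reachable by Beta(m*nu, (1-m)*nu) with both parameters > 1
    (the unimodal profiles whose chord vanishes at base and apex)."""
    nu = concentration
    lo_m, hi_m = 1.0 / nu, 1.0 - 1.0 / nu

    def g(m):
        return m * (1 - m) / (nu + 1) + m**2

    return float(np.sqrt(g(lo_m))), float(np.sqrt(g(hi_m)))


def rsm_to_beta(target_rsm: float, concentration: float = 4.0) -> tuple[float, float]:
    """Invert the closed-form Beta second moment: find (alpha, beta) with
    alpha + beta = concentration whose profile has the requested RSM.

    Monotone root-finding on the Beta mean. Raises a domain error listing
    the attainable range when the target falls outside it.
    """
    nu = float(concentration)
    if nu <= 2.0:
        raise ValidationError("concentration must exceed 2 (alpha, beta > 1)")
    lo, hi = attainable_rsm_range(nu)
    if not (lo <= target_rsm <= hi):
        raise ValidationError(
            f"target RSM {target_rsm:.4f} outside the attainable range "
            f"[{lo:.4f}, {hi:.4f}] at concentration {nu:g}"
        )
    t2 = target_rsm**2

    def g(m):
        return m * (1 - m) / (nu + 1) + m**2 - t2

    m = scipy.optimize.brentq(g, 1.0 / nu, 1.0 - 1.0 / nu, xtol=1e-14)
    return float(nu * m), float(nu * (1.0 - m))


def outline_from_profile(
    alpha: float,
    beta: float,
    wing_length: float,
    n_vertices: int = 400,
    aspect_ratio: float = 5.5,
) -> WingOutline:
    """A symmetric polygon whose chord profile is the Beta(alpha, beta) density.

    The wing axis runs from the base (0, 0) to the apex (R, 0); at span
    fraction r the polygon spans +-c(r)/2 with c = pdf * S / R and
    S = R^2 / aspect_ratio. Doubling the wing length leaves every moment
    radius unchanged.
    """
    if wing_length <= 0:
        raise GeometryError("wing_length must be positive")
    if n_vertices < 10:
        raise GeometryError(f"need n_vertices >= 10, got {n_vertices}")
    if not (alpha > 1 and beta > 1):
        raise GeometryError("alpha and beta must exceed 1 (chord must vanish at ends)")
    R = float(wing_length)
    S = R**2 / aspect_ratio
    m = n_vertices // 2
    r = np.linspace(0.0, 1.0, m + 1)
    c = scipy.stats.beta.pdf(r, alpha, beta) * S / R
    half = c / 2.0
    upper = np.column_stack([r * R, half])
    lower = np.column_stack([r[::-1][1:-1] * R, -half[::-1][1:-1]])
    verts = np.vstack([upper, lower])
    return WingOutline(
        vertices=verts, base_point=np.array([0.0, 0.0]), apex_point=np.array([R, 0.0])
    )


# ---------------------------------------------------------------------------
# Landmark placement
# ---------------------------------------------------------------------------


def landmarks_from_outline(
    outline: WingOutline,
    template_fractions=DEFAULT_TEMPLATE_FRACTIONS,
    semilandmark_indices=DEFAULT_SEMILANDMARKS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    specimen_id: str = "",
    taxon_id: str = "",
    wing: str = "",
) -> LandmarkSet:
    """Place landmarks at fixed arc-length fractions of the outline.

    Emulates digitization: 12 template positions along the boundary
    (starting at the base vertex) plus isotropic Gaussian noise with
    standard deviation ``noise_sd`` in physical units. With zero noise
    the landmarks of a taxon are identical across its specimens.
    """
    fr = np.asarray(template_fractions, dtype=float)
    if np.any(fr < 0) or np.any(fr >= 1):
        raise ValidationError("template fractions must lie in [0, 1)")
    verts = outline.vertices
    closed = np.vstack([verts, verts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    pos = fr * total
    x = np.interp(pos, arc, closed[:, 0])
    y = np.interp(pos, arc, closed[:, 1])
    pts = np.column_stack([x, y])
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return LandmarkSet(
        coords=pts,
        semilandmark_indices=tuple(semilandmark_indices),
        specimen_id=specimen_id,
        taxon_id=taxon_id,
        wing=wing,
    )


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Tree, traits, outlines and landmarks for the whole synthetic study."""
    phylogeny = simulate_tree(spec)
    traits = simulate_traits(phylogeny, spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 303]))
    lo, hi = attainable_rsm_range(spec.beta_concentration)
    margin = 0.02 * (hi - lo)

    taxa: list[SyntheticTaxon] = []
    specimens: list[SyntheticSpecimen] = []
    for row in traits.itertuples(index=False):
        n_spec = int(rng.integers(spec.specimens_min, spec.specimens_max + 1))
        if spec.link_color_to_basal and row.is_basal:
            group = 1
        else:
            group = int(rng.integers(1, 7))
        true_rsm = {w: float(getattr(row, f"true_rsm_{w}")) for w in _WINGS}
        beta_params = {
            w: rsm_to_beta(
                float(np.clip(true_rsm[w], lo + margin, hi - margin)),
                spec.beta_concentration,
            )
            for w in _WINGS
        }
        taxa.append(
            SyntheticTaxon(
                taxon_id=row.taxon,
                true_log_size=float(row.true_log_size),
                is_basal=bool(row.is_basal),
                true_rsm=true_rsm,
                beta_params=beta_params,
                coloration_group={w: group for w in _WINGS},
                n_specimens=n_spec,
            )
        )
        for i in range(n_spec):
            for wing in _WINGS:
                ls = float(row.true_log_size + rng.normal(0.0, spec.specimen_size_sd))
                target = float(
                    np.clip(
                        true_rsm[wing] + rng.normal(0.0, spec.specimen_rsm_sd),
                        lo + margin,
                        hi - margin,
                    )
                )
                a, b = rsm_to_beta(target, spec.beta_concentration)
                R = spec.wing_length_per_size * float(np.exp(ls))
                if wing == "hind":
                    R *= spec.hindwing_length_factor
                outline = outline_from_profile(
                    a, b, R, spec.n_vertices, spec.aspect_ratio
                )
                sid = f"{row.taxon}_s{i + 1:02d}"
                lms = landmarks_from_outline(
                    outline,
                    noise_sd=spec.landmark_noise_sd,
                    rng=rng,
                    specimen_id=sid,
                    taxon_id=row.taxon,
                    wing=wing,
                )
                specimens.append(
                    SyntheticSpecimen(
                        specimen_id=sid,
                        taxon_id=row.taxon,
                        wing=wing,
                        true_rsm=target,
                        true_log_size=ls,
                        outline=outline,
                        landmarks=lms,
                    )
                )
    return SyntheticDataset(
        spec=spec, phylogeny=phylogeny, taxa=taxa, specimens=specimens
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the dataset in the exact input formats the pipeline reads.

    Emits ``tree.nwk``, ``traits.csv``, one TPS file per wing, a long-form
    ``outlines.csv`` and a ``manifest.json`` recording the spec and seed.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_newick(dataset.phylogeny, outdir / "tree.nwk")

    traits = dataset.taxa_frame[
        ["taxon", "wing", "coloration_group", "n_specimens"]
    ]
    traits.to_csv(outdir / "traits.csv", index=False, encoding="utf-8")

    for wing in _WINGS:
        records = [
            TpsRecord(
                landmark_count=len(s.landmarks.coords),
                coordinates=s.landmarks.coords,
                id_label=f"{s.taxon_id}|{s.specimen_id}",
            )
            for s in dataset.specimens
            if s.wing == wing
        ]
        write_tps(records, outdir / f"landmarks_{wing}.tps")

    rows = []
    for s in dataset.specimens:
        verts = s.outline.vertices
        nb = np.argmin(np.linalg.norm(verts - s.outline.base_point, axis=1))
        na = np.argmin(np.linalg.norm(verts - s.outline.apex_point, axis=1))
        for j, (x, y) in enumerate(verts):
            rows.append(
                (s.taxon_id, s.specimen_id, s.wing, j, x, y, int(j == nb), int(j == na))
            )
    pd.DataFrame(
        rows,
        columns=["taxon", "specimen", "wing", "vertex", "x", "y", "is_base", "is_apex"],
    ).to_csv(outdir / "outlines.csv", index=False, encoding="utf-8")

    manifest = {
        "generator": "wingshape.synthetic_data",
        "spec": dataclasses.asdict(dataset.spec),
        "n_specimens_total": len(dataset.specimens),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest
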