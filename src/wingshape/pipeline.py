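"""End-to-end analysis pipeline: simulate/load -> RSM -> GPA -> statistics.

One call to :func:`run_pipeline` reproduces the full analysis chain on a
dataset (synthetic or loaded from files): per-specimen moment radii and
centroid sizes, a joint Procrustes superimposition of fore- and
hindwings, species means, linear and quadratic size regressions,
allometric shape scores and a MANCOVA on the shape variables,
coloration-group linear models, independent-contrast regressions on a
branch-length-transformed tree, and the simulation-null phylogenetic
ANOVA on the non-allometric RSM residuals. Fore- and hindwings run as
independent analysis lanes sharing the tree.

Every random step derives from explicit seeds, and result tables are
written with fixed float formatting, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative as cmp
from . import morphometrics as mm
from . import synthetic_data as syn
from .exceptions import ValidationError
from .io import Phylogeny, read_newick, read_tps, read_trait_table, write_newick
from .wing_geometry import chord_profile, moment_radius

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_dataset", "report"]

_WINGS = ("fore", "hind")
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimulationSpec`) or
    ``input_dir`` (a directory holding ``tree.nwk``, ``traits.csv``,
    ``landmarks_{fore,hind}.tps`` and ``outlines.csv`` as written by
    :func:`wingshape.synthetic_data.write_dataset`) must be set.
    """

    simulation: syn.SimulationSpec | None = None
    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    slide_semilandmarks: bool = True
    semilandmark_indices: tuple[int, ...] = syn.DEFAULT_SEMILANDMARKS
    branch_transform: str = "exp"
    n_strips: int = 500
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one of 'simulation' and 'input_dir' must be given"
            )


@dataclass
class PipelineResult:
    """All tables and fitted models of one run."""

    config: RunConfig
    phylogeny: Phylogeny
    specimen_table: pd.DataFrame  # taxon, specimen, wing, rsm, r1, r3, log_centroid_size
    species_means: pd.DataFrame  # per taxon x wing
    shape_space: mm.ShapeSpace  # joint fore+hind GPA
    shape_variables: np.ndarray
    regressions: dict  # wing -> {"linear": FitResult, "quadratic": FitResult}
    shape_score_fits: dict  # wing -> FitResult (score ~ RSM)
    mancova: cmp.FitResult
    glm: dict  # wing -> FitResult
    contrast_sets: dict  # wing -> ContrastSet
    contrast_fits: dict  # wing -> FitResult
    phylo_anova: dict  # wing -> PhyloAnovaResult
    report_text: str = ""


def load_dataset(input_dir: str | Path, config: RunConfig) -> syn.SyntheticDataset:
    """Load a dataset from the on-disk layout that ``write_dataset`` emits."""
    d = Path(input_dir)
    phylogeny = read_newick(d / "tree.nwk")
    traits = read_trait_table(d / "traits.csv")
    outlines = pd.read_csv(d / "outlines.csv", encoding="utf-8")

    specimens: list[syn.SyntheticSpecimen] = []
    lm_by_key: dict[tuple, np.ndarray] = {}
    for wing in _WINGS:
        for rec in read_tps(d / f"landmarks_{wing}.tps"):
            taxon, _, spec_id = rec.id_label.partition("|")
            lm_by_key[(taxon, spec_id, wing)] = rec.coordinates

    from .wing_geometry import WingOutline

    for (taxon, spec_id, wing), g in outlines.groupby(
        ["taxon", "specimen", "wing"], sort=True
    ):
        g = g.sort_values("vertex")
        verts = g[["x", "y"]].to_numpy(dtype=float)
        base = verts[g["is_base"].to_numpy(dtype=bool)][0]
        apex = verts[g["is_apex"].to_numpy(dtype=bool)][0]
        key = (taxon, spec_id, wing)
        if key not in lm_by_key:
            raise ValidationError(f"no landmarks for outline {key}")
        lms = mm.LandmarkSet(
            coords=lm_by_key[key],
            semilandmark_indices=config.semilandmark_indices,
            specimen_id=spec_id,
            taxon_id=taxon,
            wing=wing,
        )
        specimens.append(
            syn.SyntheticSpecimen(
                specimen_id=spec_id,
                taxon_id=taxon,
                wing=wing,
                true_rsm=float("nan"),
                true_log_size=float("nan"),
                outline=WingOutline(vertices=verts, base_point=base, apex_point=apex),
                landmarks=lms,
            )
        )
    tree_taxa = set(phylogeny.tip_labels)
    data_taxa = set(s.taxon_id for s in specimens)
    if tree_taxa != data_taxa:
        raise ValidationError(
            "taxon mismatch between tree and specimens — only in tree: "
            f"{sorted(tree_taxa - data_taxa)}; only in data: {sorted(data_taxa - tree_taxa)}"
        )
    taxa = []
    for taxon, g in traits.groupby("taxon", sort=True):
        row = {w: int(g.loc[g.wing == w, "coloration_group"].iloc[0]) for w in _WINGS}
        taxa.append(
            syn.SyntheticTaxon(
                taxon_id=taxon,
                true_log_size=float("nan"),
                is_basal=False,
                true_rsm={w: float("nan") for w in _WINGS},
                beta_params={},
                coloration_group=row,
                n_specimens=int(g["n_specimens"].iloc[0]) if "n_specimens" in g else 0,
            )
        )
    return syn.SyntheticDataset(
        spec=None, phylogeny=phylogeny, taxa=taxa, specimens=specimens
    )


def _specimen_table(dataset: syn.SyntheticDataset, n_strips: int) -> pd.DataFrame:
    rows = []
    for s in dataset.specimens:
        prof = chord_profile(s.outline, n_strips)
        rows.append(
            {
                "taxon": s.taxon_id,
                "specimen": s.specimen_id,
                "wing": s.wing,
                "wing_length_R": prof.wing_length_R,
                "area_S": prof.area_S,
                "r1": moment_radius(prof, 1),
                "rsm": moment_radius(prof, 2),
                "r3": moment_radius(prof, 3),
                "log_centroid_size": float(np.log(mm.centroid_size(s.landmarks.coords))),
            }
        )
    return pd.DataFrame(rows).sort_values(["wing", "taxon", "specimen"], ignore_index=True)


def _mean_shape_scores(space: mm.ShapeSpace, keys: list[tuple]) -> tuple[pd.DataFrame, np.ndarray]:
    """Average aligned coordinates per (taxon, wing), then recompute shape
    variables from the joint-GPA basis."""
    mm.shape_variables(space)  # ensure basis cached
    df = pd.DataFrame(keys, columns=["taxon", "wing"])
    n, k = space.n_specimens, space.n_landmarks
    flat = space.aligned.reshape(n, 2 * k)
    groups = df.groupby(["taxon", "wing"], sort=True).indices
    labels, means = [], []
    for key, idx in groups.items():
        labels.append(key)
        means.append(flat[idx].mean(axis=0))
    M = np.vstack(means)
    V = M - space.consensus.ravel()
    V = V - (V @ space._similarity_basis.T) @ space._similarity_basis
    sv = V @ space._tangent_basis
    out = pd.DataFrame(labels, columns=["taxon", "wing"])
    return out, sv


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis chain; see the module docstring."""
    if config.simulation is not None:
        dataset = syn.generate_dataset(config.simulation)
    else:
        dataset = load_dataset(config.input_dir, config)
    phylogeny = dataset.phylogeny

    # --- wing geometry lane -----------------------------------------
    spec_table = _specimen_table(dataset, config.n_strips)

    # --- morphometrics lane (joint GPA over both wings) ---------------
    space = mm.gpa(
        [s.landmarks for s in dataset.specimens],
        slide=config.slide_semilandmarks,
    )
    shape_vars = mm.shape_variables(space)

    # --- species means -------------------------------------------------
    color_map = {
        (t.taxon_id, w): t.coloration_group[w] for t in dataset.taxa for w in _WINGS
    }
    spec_table["coloration_group"] = [
        color_map[(r.taxon, r.wing)] for r in spec_table.itertuples()
    ]
    means = cmp.species_means(spec_table)

    missing = set(means.taxon) ^ set(phylogeny.tip_labels)
    if missing:
        raise ValidationError(f"taxa not shared by tree and data: {sorted(missing)}")

    # --- conventional statistics per wing ------------------------------
    regressions, glm_fits, score_fits = {}, {}, {}
    for wing in _WINGS:
        mw = means[means.wing == wing]
        x = mw.log_centroid_size_mean.to_numpy()
        y = mw.rsm_mean.to_numpy()
        regressions[wing] = {
            "linear": cmp.polynomial_regression(y, x, 1),
            "quadratic": cmp.polynomial_regression(y, x, 2),
        }
        glm_fits[wing] = cmp.glm_coloration(y, mw.coloration_group.to_numpy(), x)

    # --- shape scores and MANCOVA on species-mean shapes ----------------
    keys = [(s.taxon_id, s.wing) for s in dataset.specimens]
    mean_labels, mean_sv = _mean_shape_scores(space, keys)
    merged = mean_labels.merge(
        means[["taxon", "wing", "rsm_mean"]], on=["taxon", "wing"], validate="1:1"
    )
    rsm_cov = merged.rsm_mean.to_numpy()
    # the MANCOVA needs p < n - q error df; small studies use the leading
    # shape variables (columns are ordered by decreasing bending energy)
    n_means, p_all = mean_sv.shape
    p_use = min(p_all, n_means - 3 - 1)
    if p_use < 1:
        raise ValidationError("too few species means for a MANCOVA")
    mancova = cmp.mancova_wilks(mean_sv[:, :p_use], merged.wing.to_numpy(), rsm_cov)
    mancova.extra["n_shape_variables_used"] = p_use

    mm.shape_variables(space)
    for wing in _WINGS:
        sel = (mean_labels.wing == wing).to_numpy()
        sub_space = mm.ShapeSpace(
            consensus=space.consensus,
            aligned=(mean_sv[sel] @ space._tangent_basis.T
                     + space.consensus.ravel()).reshape(-1, space.n_landmarks, 2),
            centroid_sizes=np.ones(int(sel.sum())),
        )
        scores = mm.shape_scores(sub_space, rsm_cov[sel])
        score_fits[wing] = cmp.polynomial_regression(scores, rsm_cov[sel], 1)

    # --- phylogenetic lane ---------------------------------------------
    ttree = cmp.transform_branch_lengths(phylogeny, config.branch_transform)
    contrast_sets, contrast_fits, panova = {}, {}, {}
    for iw, wing in enumerate(_WINGS):
        mw = means[means.wing == wing]
        size_map = dict(zip(mw.taxon, mw.log_centroid_size_mean))
        rsm_map = dict(zip(mw.taxon, mw.rsm_mean))
        cs = cmp.contrast_set(ttree, size_map, rsm_map)
        contrast_sets[wing] = cs
        contrast_fits[wing] = cmp.contrast_regression(cs)

        resid = cmp.nonallometric_residuals(
            mw.rsm_mean.to_numpy(), mw.log_centroid_size_mean.to_numpy()
        )
        resid_map = dict(zip(mw.taxon, resid))
        group_map = dict(zip(mw.taxon, mw.coloration_group))
        panova[wing] = cmp.phylogenetic_anova(
            phylogeny,
            resid_map,
            group_map,
            n_sim=config.n_sim,
            seed=int(config.seed) + iw,
        )

    result = PipelineResult(
        config=config,
        phylogeny=phylogeny,
        specimen_table=spec_table,
        species_means=means,
        shape_space=space,
        shape_variables=shape_vars,
        regressions=regressions,
        shape_score_fits=score_fits,
        mancova=mancova,
        glm=glm_fits,
        contrast_sets=contrast_sets,
        contrast_fits=contrast_fits,
        phylo_anova=panova,
    )
    result.report_text = report(result)
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir), ttree)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, ttree: Phylogeny) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.specimen_table.to_csv(
        outdir / "specimen_rsm.csv", index=False, float_format=_FLOAT_FMT
    )
    result.species_means.to_csv(
        outdir / "species_means.csv", index=False, float_format=_FLOAT_FMT
    )
    k = result.shape_space.n_landmarks
    sv_cols = [f"pw{i//2 + 1}{'xy'[i % 2]}" for i in range(2 * k - 6)] + ["uni1", "uni2"]
    sv = pd.DataFrame(result.shape_variables, columns=sv_cols)
    sv.insert(0, "specimen", result.shape_space.specimen_ids)
    sv.insert(0, "taxon", result.shape_space.taxon_ids)
    sv.insert(2, "wing", result.shape_space.wings)
    sv.to_csv(outdir / "shape_variables.csv", index=False, float_format=_FLOAT_FMT)
    for wing in _WINGS:
        cs = result.contrast_sets[wing]
        pd.DataFrame(
            {
                "contrast_size": cs.contrasts_x,
                "contrast_rsm": cs.contrasts_y,
                "contrast_sd": cs.contrast_sd,
                "flipped": cs.positivized.astype(int),
            }
        ).to_csv(outdir / f"contrasts_{wing}.csv", index=False, float_format=_FLOAT_FMT)
    write_newick(ttree, outdir / "tree_transformed.nwk")
    (outdir / "report.txt").write_text(result.report_text, encoding="utf-8")


def _fmt_fit(fit: cmp.FitResult) -> str:
    d1, d2 = fit.df
    return (
        f"R^2 = {fit.r_squared:.3f}, F_{int(d1)},{int(d2)} = "
        f"{fit.f_statistic:.3f}, P = {fit.p_value:.4g}"
    )


def report(result: PipelineResult) -> str:
    """Plain-text summary mirroring the analysis blocks of the pipeline."""
    if result.species_means.empty:
        raise ValidationError("no results to report")
    lines: list[str] = []
    add = lines.append
    add("wingshape pipeline report")
    add("=" * 60)
    add(f"taxa: {result.phylogeny.n_tips}; specimens: {len(result.specimen_table)}")
    add(f"shape variables per specimen: {result.shape_variables.shape[1]}")
    add("")
    add("RSM and size (species means)")
    add("-" * 60)
    for wing in _WINGS:
        r = result.regressions[wing]
        add(f"{wing}wings: linear regression: {_fmt_fit(r['linear'])}")
        add(f"{wing}wings: quadratic regression: {_fmt_fit(r['quadratic'])}")
    add("")
    add("Shape scores on RSM")
    add("-" * 60)
    for wing in _WINGS:
        add(f"{wing}wings: {_fmt_fit(result.shape_score_fits[wing])}")
    add("")
    add("MANCOVA on shape variables (factor: wing; covariate: RSM)")
    add("-" * 60)
    for term, row in result.mancova.table.iterrows():
        add(
            f"{term}: Wilks' lambda = {row.wilks_lambda:.3f}, "
            f"F_{int(row.df_num)},{int(row.df_den)} = {row.F:.3f}, P = {row.p:.4g}"
        )
    add("")
    add("Independent contrasts (RSM on size, through the origin)")
    add("-" * 60)
    for wing in _WINGS:
        fit = result.contrast_fits[wing]
        add(
            f"{wing}wings: slope = {fit.coefficients[0]:.4f}, {_fmt_fit(fit)}"
        )
    add("")
    add("GLM: RSM ~ coloration group + size + size^2")
    add("-" * 60)
    for wing in _WINGS:
        add(f"{wing.capitalize()}wings:")
        t = result.glm[wing].table
        for term, row in t.iterrows():
            if term == "Error":
                add(f"  Error: df {int(row.df)}, SS {row.sum_sq:.5f}")
            else:
                add(
                    f"  {term}: df {int(row.df)}, SS {row.sum_sq:.5f}, "
                    f"F = {row.F:.3f}, P = {row['PR(>F)']:.4g}"
                )
    add("")
    add("Phylogenetic ANOVA on non-allometric RSM (coloration groups)")
    add("-" * 60)
    for wing in _WINGS:
        pa = result.phylo_anova[wing]
        add(
            f"{wing}wings: F_{pa.df[0]},{pa.df[1]} = {pa.f_observed:.3f}, "
            f"phylogenetic-P = {pa.p_phylogenetic:.4g} "
            f"(parametric P = {pa.p_parametric:.4g}, {pa.n_sim} BM simulations)"
        )
    add("")
    return "\n".join(lines)
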