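"""Readers and writers for the standard formats the pipeline touches.

Supported formats:

* TPS landmark files (``LM=``, optional ``SCALE=``, ``ID=``, ``IMAGE=`` lines)
  as produced by the tpsDig family of digitizers;
* Newick trees with branch lengths (parsed with :mod:`dendropy`);
* CSV trait tables (one row per taxon x wing with a coloration group);
* CSV wing outlines (ordered x,y vertices plus base/apex flags).

Coordinates are treated as 2D Cartesian, y-up; no image-row flipping is
performed. If a digitizer stored image coordinates (y-down) the caller is
responsible for flipping. All tabular I/O is UTF-8 CSV with a header row and
decimal points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "TpsRecord",
    "Phylogeny",
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "write_trait_table",
    "read_outline_csv",
    "write_outline_csv",
]

_WINGS = ("fore", "hind")


@dataclass
class TpsRecord:
    """One digitized specimen from a TPS landmark file.

    ``coordinates`` are stored in physical units: if the file carried a
    ``SCALE=`` line the raw coordinates have already been multiplied by it.
    """

    landmark_count: int
    coordinates: np.ndarray  # (k, 2), physical units
    id_label: str = ""
    scale: float | None = None
    image: str | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.landmark_count, 2):
            raise ValidationError(
                f"TpsRecord '{self.id_label}': expected {self.landmark_count} "
                f"(x, y) pairs, got array of shape {self.coordinates.shape}"
            )
        if self.scale is not None and not self.scale > 0:
            raise ValidationError(
                f"TpsRecord '{self.id_label}': scale must be > 0, got {self.scale}"
            )


class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping :class:`dendropy.Tree`.

    Invariants enforced at construction: unique tip labels and a branch
    length on every non-root edge. Polytomy status is recorded, not
    rejected — downstream methods that require a bifurcating tree raise
    their own errors.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Parse Newick from a path or a literal string."""
        text = _newick_text(source)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate tip labels in Newick: {exc}") from exc
            raise FormatError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise FormatError(
                    "missing branch length on a non-root edge "
                    f"(above node {node.taxon.label if node.taxon else '<internal>'})"
                )
            if node.edge.length < 0:
                raise ValidationError("negative branch length")

    # -- properties ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def is_bifurcating(self) -> bool:
        root = self._tree.seed_node
        for node in self._tree.preorder_internal_node_iter():
            n_children = len(node.child_nodes())
            if node is root:
                if n_children != 2:
                    return False
            elif n_children != 2:
                return False
        return True

    @property
    def has_polytomy(self) -> bool:
        return not self.is_bifurcating

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return max(
            leaf.distance_from_root() for leaf in self._tree.leaf_node_iter()
        )

    # -- output --------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def branch_lengths(self) -> list[float]:
        root = self._tree.seed_node
        return [
            n.edge.length
            for n in self._tree.preorder_node_iter()
            if n is not root
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "bifurcating" if self.is_bifurcating else "polytomous"
        return f"<Phylogeny: {self.n_tips} tips, {kind}>"


def _newick_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    s = str(source)
    if "(" in s and ";" in s:
        return s
    p = Path(s)
    if p.exists():
        return p.read_text(encoding="utf-8")
    raise FormatError(f"not a Newick string and not an existing file: {s!r}")


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------


def read_tps(path: str | Path) -> list[TpsRecord]:
    """Read a TPS landmark file into a list of :class:`TpsRecord`.

    Honors ``LM=``, ``SCALE=``, ``ID=`` and ``IMAGE=`` keys; ``CURVES=`` /
    ``POINTS=`` blocks are skipped with a warning. Coordinates are
    multiplied by the scale factor when one is present, so the returned
    records are in physical units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    records: list[TpsRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise FormatError(
                f"{path.name}:{i}: expected 'LM=<count>' record header, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{i}: malformed count line {line!r}") from exc
        if k < 0:
            raise FormatError(f"{path.name}:{i}: negative landmark count")

        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n:
                raise FormatError(
                    f"{path.name}: record truncated — expected {k} coordinate "
                    f"lines, file ended after {j}"
                )
            parts = lines[i].split()
            i += 1
            if len(parts) != 2:
                raise FormatError(
                    f"{path.name}:{i}: expected 'x y' pair, got {lines[i - 1]!r}"
                )
            try:
                coords[j] = (float(parts[0]), float(parts[1]))
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{i}: non-numeric coordinate {lines[i - 1]!r}"
                ) from exc

        id_label, scale, image = "", None, None
        while i < n:
            meta = lines[i].strip()
            if not meta or "=" not in meta or meta.upper().startswith("LM="):
                break
            key, _, value = meta.partition("=")
            key = key.strip().upper()
            i += 1
            if key == "ID":
                id_label = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}:{i}: malformed SCALE line {meta!r}"
                    ) from exc
            elif key == "IMAGE":
                image = value.strip()
            elif key in ("CURVES", "POINTS"):
                warnings.warn(
                    f"{path.name}: ignoring {key} block (only fixed landmarks "
                    "and semilandmarks are supported)",
                    stacklevel=2,
                )
            # unknown keys silently tolerated (VARIABLES=, COMMENT=, ...)

        if scale is not None:
            coords = coords * scale
        records.append(
            TpsRecord(
                landmark_count=k,
                coordinates=coords,
                id_label=id_label,
                scale=scale,
                image=image,
            )
        )
    return records


def write_tps(records: Sequence[TpsRecord], path: str | Path) -> None:
    """Write records to a TPS file re-readable by :func:`read_tps`.

    Coordinates are written divided by the record's scale (when present) so
    that a read-back — which re-applies the scale — reproduces the stored
    physical coordinates bit-identically at the written precision.
    """
    path = Path(path)
    out: list[str] = []
    for rec in records:
        coords = rec.coordinates
        if rec.scale is not None:
            coords = coords / rec.scale
        out.append(f"LM={rec.landmark_count}")
        for x, y in coords:
            out.append(f"{x:.12g} {y:.12g}")
        if rec.image:
            out.append(f"IMAGE={rec.image}")
        if rec.id_label:
            out.append(f"ID={rec.id_label}")
        if rec.scale is not None:
            out.append(f"SCALE={rec.scale:.12g}")
    path.write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a Newick tree (path or literal string) into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(source)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.to_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

_TRAIT_COLUMNS = ("taxon", "wing", "coloration_group")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the per-taxon trait CSV (taxon, wing, coloration_group[, n_specimens]).

    The coloration group is the six-level categorical coding of wing-pigment
    position and extent; it may legitimately differ between the fore- and
    hindwing of one taxon. Returns a validated DataFrame (empty file -> empty
    frame with the canonical columns).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(_TRAIT_COLUMNS))
    if df.empty and df.columns.empty:
        return pd.DataFrame(columns=list(_TRAIT_COLUMNS))
    missing = [c for c in _TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    bad_wing = set(df["wing"].unique()) - set(_WINGS)
    if bad_wing:
        raise ValidationError(
            f"{path.name}: wing must be one of {_WINGS}, found {sorted(bad_wing)}"
        )
    groups = pd.to_numeric(df["coloration_group"], errors="raise")
    if ((groups < 1) | (groups > 6) | (groups != groups.astype(int))).any():
        raise ValidationError(
            f"{path.name}: coloration_group must be an integer in 1..6"
        )
    df["coloration_group"] = groups.astype(int)
    dupes = df.duplicated(subset=["taxon", "wing"])
    if dupes.any():
        raise ValidationError(
            f"{path.name}: duplicate taxon x wing rows: "
            f"{df.loc[dupes, ['taxon', 'wing']].to_records(index=False).tolist()}"
        )
    if "n_specimens" in df.columns:
        if (pd.to_numeric(df["n_specimens"]) < 1).any():
            raise ValidationError(f"{path.name}: n_specimens must be >= 1")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Outline CSV
# ---------------------------------------------------------------------------


def read_outline_csv(path: str | Path):
    """Read a single wing outline CSV (columns x, y, is_base, is_apex).

    Exactly one row must be flagged as base and one as apex; vertices are
    taken in file order. Returns a :class:`wingshape.wing_geometry.WingOutline`.
    """
    from .wing_geometry import WingOutline  # local import: avoid cycle

    df = pd.read_csv(path, encoding="utf-8")
    for col in ("x", "y", "is_base", "is_apex"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    base_rows = df.index[df["is_base"].astype(bool)].tolist()
    apex_rows = df.index[df["is_apex"].astype(bool)].tolist()
    if len(base_rows) != 1 or len(apex_rows) != 1:
        raise FormatError(
            f"{Path(path).name}: need exactly one base and one apex row, "
            f"got {len(base_rows)} / {len(apex_rows)}"
        )
    verts = df[["x", "y"]].to_numpy(dtype=float)
    return WingOutline(
        vertices=verts,
        base_point=verts[base_rows[0]],
        apex_point=verts[apex_rows[0]],
    )


def write_outline_csv(outline, path: str | Path) -> None:
    verts = np.asarray(outline.vertices, dtype=float)
    is_base = np.all(np.isclose(verts, outline.base_point), axis=1)
    is_apex = np.all(np.isclose(verts, outline.apex_point), axis=1)
    # flag only the first matching vertex for each role
    for flags in (is_base, is_apex):
        hits = np.flatnonzero(flags)
        flags[:] = False
        if hits.size:
            flags[hits[0]] = True
    pd.DataFrame(
        {
            "x": verts[:, 0],
            "y": verts[:, 1],
            "is_base": is_base.astype(int),
            "is_apex": is_apex.astype(int),
        }
    ).to_csv(path, index=False, encoding="utf-8")
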