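"""Reading, validation and writing of 3D astrocyte skeletons in SWC format.

A skeleton is a rooted tree of nodes, each carrying a 3D position (in
micrometres), a radius and a structure-type code (1 = soma, anything else is
a process point).  One SWC file holds exactly one astrocyte; cells are never
pooled across files.  Multi-node somas (several contiguous type-1 nodes) are
accepted; the root type-1 node is taken as the soma centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOMA_TYPE = 1

GENOTYPES = ("WT", "TAU")
AGE_GROUPS = (3, 9, 23)
SUBREGIONS = ("CA1so", "CA1sr", "Sub")

MANIFEST_COLUMNS = (
    "cell_id",
    "swc_path",
    "mouse_id",
    "genotype",
    "age_group",
    "subregion",
)


class SWCParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SkeletonValidationError(ValueError):
    """A skeleton violates a structural invariant (tree-ness, radii, root)."""


class ManifestError(ValueError):
    """A cohort manifest is malformed or references unreadable files."""


@dataclass
class AstrocyteSkeleton:
    """A rooted 3D tree of skeleton nodes in topological (parent-first) order.

    Attributes
    ----------
    cell_id : str
        Identifier of the cell, carried through to outputs.
    ids : (N,) int array
        Original node identifiers (unique within the skeleton).
    type_code : (N,) int array
        SWC structure codes; 1 marks soma nodes.
    xyz : (N, 3) float array
        Node positions in micrometres.
    radius : (N,) float array
        Node radii in micrometres (strictly positive).
    parent_index : (N,) int array
        Index of each node's parent within these arrays, -1 for the root.
    soma_diameter_src : float or None
        Externally measured soma diameter (um) if the manifest supplied one;
        otherwise ``None`` and morphometry derives it from the root radius.
    """

    cell_id: str
    ids: np.ndarray
    type_code: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent_index: np.ndarray
    soma_diameter_src: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_index == -1)[0])

    def children(self) -> list[list[int]]:
        """Adjacency list: children[i] = indices of nodes whose parent is i."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent_index):
            if p >= 0:
                out[p].append(i)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Node table as a DataFrame (id, type, x, y, z, radius, parent_id)."""
        parent_id = np.where(
            self.parent_index >= 0, self.ids[self.parent_index], -1
        )
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": self.type_code,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent_id": parent_id,
            }
        )


def _topological_order(ids: np.ndarray, parent_ids: np.ndarray) -> np.ndarray:
    """Return a permutation placing every parent before its children.

    Raises
    ------
    SkeletonValidationError
        If the parent relation has a cycle or a missing parent.
    """
    id_to_pos = {int(i): k for k, i in enumerate(ids)}
    children: dict[int, list[int]] = {k: [] for k in range(len(ids))}
    roots = []
    for k, p in enumerate(parent_ids):
        p = int(p)
        if p == -1:
            roots.append(k)
        else:
            if p not in id_to_pos:
                raise SkeletonValidationError(
                    f"missing parent: node {int(ids[k])} references parent "
                    f"{p} which is not in the file"
                )
            children[id_to_pos[p]].append(k)
    if len(roots) == 0:
        raise SkeletonValidationError("no root: no node has parent_id = -1")
    if len(roots) > 1:
        raise SkeletonValidationError(
            f"multiple roots: nodes {[int(ids[r]) for r in roots]} "
            "all have parent_id = -1"
        )
    order = []
    stack = [roots[0]]
    while stack:
        k = stack.pop()
        order.append(k)
        stack.extend(reversed(children[k]))
    if len(order) != len(ids):
        unreachable = sorted(set(range(len(ids))) - set(order))
        raise SkeletonValidationError(
            f"cycle: nodes {[int(ids[k]) for k in unreachable[:5]]} are not "
            "reachable from the root (parent links form a cycle)"
        )
    return np.asarray(order, dtype=np.intp)


def make_skeleton(
    cell_id: str,
    ids: np.ndarray,
    type_code: np.ndarray,
    xyz: np.ndarray,
    radius: np.ndarray,
    parent_ids: np.ndarray,
    soma_diameter_src: float | None = None,
) -> AstrocyteSkeleton:
    """Validate raw node columns and assemble a topologically ordered skeleton.

    ``parent_ids`` are original SWC parent identifiers (-1 for the root);
    they are converted to positional indices after topological sorting.
    """
    ids = np.asarray(ids, dtype=np.int64)
    type_code = np.asarray(type_code, dtype=np.int64)
    xyz = np.asarray(xyz, dtype=float).reshape(len(ids), 3)
    radius = np.asarray(radius, dtype=float)
    parent_ids = np.asarray(parent_ids, dtype=np.int64)

    uniq, counts = np.unique(ids, return_counts=True)
    if (counts > 1).any():
        dup = int(uniq[counts > 1][0])
        raise SkeletonValidationError(f"duplicate id: node id {dup} appears twice")
    if (radius <= 0).any():
        bad = int(ids[np.argmax(radius <= 0)])
        raise SkeletonValidationError(
            f"non-positive radius: node {bad} has radius <= 0"
        )
    if not np.isfinite(xyz).all() or not np.isfinite(radius).all():
        raise SkeletonValidationError("non-finite coordinate or radius")
    if (ids == parent_ids).any():
        bad = int(ids[np.argmax(ids == parent_ids)])
        raise SkeletonValidationError(f"cycle: node {bad} is its own parent")

    order = _topological_order(ids, parent_ids)
    ids = ids[order]
    type_code = type_code[order]
    xyz = xyz[order]
    radius = radius[order]
    parent_ids = parent_ids[order]

    id_to_pos = {int(i): k for k, i in enumerate(ids)}
    parent_index = np.array(
        [-1 if int(p) == -1 else id_to_pos[int(p)] for p in parent_ids],
        dtype=np.intp,
    )
    if type_code[0] != SOMA_TYPE:
        raise SkeletonValidationError(
            f"root type: root node {int(ids[0])} has type {int(type_code[0])}, "
            f"expected soma type {SOMA_TYPE}"
        )
    return AstrocyteSkeleton(
        cell_id=cell_id,
        ids=ids,
        type_code=type_code,
        xyz=xyz,
        radius=radius,
        parent_index=parent_index,
        soma_diameter_src=soma_diameter_src,
    )


def read_swc(path: str | Path, cell_id: str | None = None) -> AstrocyteSkeleton:
    """Read a classic 7-column SWC file into a validated skeleton.

    Both space- and tab-delimited files are accepted; ``#`` comment lines and
    blank lines are ignored.  Node order is topological after loading
    regardless of the order in the file.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.stem
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise SWCParseError(f"{path}: no data lines")
    arr = np.asarray(rows, dtype=float)
    return make_skeleton(
        cell_id=cell_id,
        ids=arr[:, 0].astype(np.int64),
        type_code=arr[:, 1].astype(np.int64),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parent_ids=arr[:, 6].astype(np.int64),
    )


def write_swc(skeleton: AstrocyteSkeleton, path: str | Path) -> None:
    """Write a skeleton as standard 7-column SWC.

    Node ids are renumbered 1..N in topological order; a ``#`` header comment
    records the cell id.  Geometry is preserved exactly (repr-round-trip
    float formatting), so write -> read -> write is byte-identical.
    """
    path = Path(path)
    new_ids = np.arange(1, skeleton.n_nodes + 1)
    new_parent = np.where(
        skeleton.parent_index >= 0, skeleton.parent_index + 1, -1
    )
    with open(path, "w") as fh:
        fh.write(f"# cell_id: {skeleton.cell_id}\n")
        fh.write("# id type x y z radius parent\n")
        for i in range(skeleton.n_nodes):
            x, y, z = (float(v) for v in skeleton.xyz[i])
            fh.write(
                f"{int(new_ids[i])} {int(skeleton.type_code[i])} "
                f"{x!r} {y!r} {z!r} {float(skeleton.radius[i])!r} "
                f"{int(new_parent[i])}\n"
            )


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a cohort manifest table and normalise dtypes."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {missing}")
    manifest = manifest.copy()
    manifest["age_group"] = manifest["age_group"].astype(int)
    if manifest["cell_id"].duplicated().any():
        dup = manifest.loc[manifest["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ManifestError(f"duplicate cell_id in manifest: {dup!r}")
    for col, allowed in (
        ("genotype", GENOTYPES),
        ("age_group", AGE_GROUPS),
        ("subregion", SUBREGIONS),
    ):
        bad = set(manifest[col]) - set(allowed)
        if bad:
            raise ManifestError(
                f"unknown {col} token(s) {sorted(map(str, bad))}; "
                f"allowed: {list(allowed)}"
            )
    return manifest


def load_cohort(
    manifest_path: str | Path,
) -> list[tuple[AstrocyteSkeleton, dict]]:
    """Load every cell listed in a manifest CSV with its metadata attached.

    SWC paths are resolved relative to the manifest's directory.  Cells whose
    SWC files fail to load are collected and reported together in a single
    :class:`ManifestError` naming the failing cell ids.
    """
    manifest_path = Path(manifest_path)
    manifest = validate_manifest(pd.read_csv(manifest_path))
    base = manifest_path.parent
    cells: list[tuple[AstrocyteSkeleton, dict]] = []
    failures: list[str] = []
    for row in manifest.itertuples(index=False):
        swc = Path(row.swc_path)
        if not swc.is_absolute():
            swc = base / swc
        try:
            skel = read_swc(swc, cell_id=row.cell_id)
        except (OSError, ValueError) as exc:
            failures.append(f"{row.cell_id}: {exc}")
            continue
        meta = {
            "cell_id": row.cell_id,
            "mouse_id": row.mouse_id,
            "genotype": row.genotype,
            "age_group": int(row.age_group),
            "subregion": row.subregion,
        }
        cells.append((skel, meta))
    if failures:
        raise ManifestError(
            f"{len(failures)} cell(s) failed to load:\n" + "\n".join(failures)
        )
    breakdown = (
        manifest.groupby(["genotype", "age_group", "subregion"])
        .size()
        .to_dict()
    )
    logger.info(
        "loaded %d cells; genotype x age x subregion counts: %s",
        len(cells),
        breakdown,
    )
    return cells
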