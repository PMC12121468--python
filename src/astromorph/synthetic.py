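"""Synthetic 3D astrocyte skeleton cohorts with known morphotype structure.

The growth model is a stochastic branching process, not a biophysical one:
primary processes leave the soma in quasi-uniform directions and elongate
in small steps with angular jitter, bifurcating as a Poisson process along
their length, and stopping at the territory boundary or when a sampled
branch-length budget is exhausted.  It is sufficient to produce the
feature covariance structure the clustering stages assume.

Three default archetypes ("simple", "medium", "complex") have graded
branching complexity — ordered in number of branches, branching points and
ramification index — and cohorts mix them in proportions that differ by
genotype and age, emulating a study of two genotypes (wild-type and a
tauopathy model) at 3, 9 and 23 months with 2-3 mice per group, three
hippocampal subregions and ~20 cells per mouse and subregion.  A
mouse-level multiplicative random effect on the bifurcation rate makes
nested-ANOVA testing meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .skeleton import AstrocyteSkeleton, make_skeleton, write_swc

logger = logging.getLogger(__name__)

MAX_NODES = 100_000


@dataclass
class MorphotypeParams:
    """Growth parameters of one morphotype archetype (lengths in um)."""

    n_primary: float = 5.0  # Poisson mean, floored at 2
    branch_rate: float = 0.05  # bifurcations per um of process
    segment_step: float = 1.0
    mean_branch_length: float = 30.0  # exponential branch-length budget
    territory_radius: float = 40.0
    tortuosity: float = 0.25  # sd of per-step angular perturbation (rad)
    soma_radius: float = 3.5
    taper: float = 0.02  # per-step fractional radius decay
    half_angle: float = 0.5  # daughter divergence at bifurcations (rad)
    radial_bias: float = 0.3  # pull of the growth direction toward radial
    soma_sd: float = 0.08  # lognormal sd of per-cell soma-size variability

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if name not in ("taper", "radial_bias", "soma_sd") and val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 0 <= self.taper < 1:
            raise ValueError("taper must lie in [0, 1)")
        if not 0 <= self.radial_bias < 1:
            raise ValueError("radial_bias must lie in [0, 1)")

    def expected_node_bound(self) -> float:
        """Crude upper bound on the expected node count before growth."""
        doublings = self.branch_rate * self.territory_radius
        per_primary = (
            self.territory_radius / self.segment_step
        ) * 2.0 ** min(doublings, 40)
        return (self.n_primary + 3) * per_primary


#: Default archetypes of graded branching complexity.
ARCHETYPES: dict[str, MorphotypeParams] = {
    "simple": MorphotypeParams(
        n_primary=4.5, branch_rate=0.005, mean_branch_length=10.0,
        territory_radius=16.0, soma_radius=2.1, tortuosity=0.14,
    ),
    "medium": MorphotypeParams(
        n_primary=14.0, branch_rate=0.04, mean_branch_length=16.0,
        territory_radius=30.0, soma_radius=3.7, tortuosity=0.40,
        half_angle=1.1,
    ),
    "complex": MorphotypeParams(
        n_primary=11.0, branch_rate=0.10, mean_branch_length=24.0,
        territory_radius=45.0, soma_radius=5.4, tortuosity=0.18,
    ),
}

#: Morphotype mixture proportions per (genotype, age group), in the order
#: (simple, medium, complex).  They mirror the shifting balance of low-,
#: medium- and high-complexity morphotypes across age and genotype in a
#: tauopathy cohort: early simplification in the transgenics, a mid-life
#: complexity peak in wild-types, and a late-stage complex subpopulation
#: persisting only in the transgenics.
DEFAULT_MIXTURES: dict[tuple[str, int], tuple[float, float, float]] = {
    ("WT", 3): (0.757, 0.171, 0.072),
    ("TAU", 3): (0.953, 0.028, 0.019),
    ("WT", 9): (0.007, 0.660, 0.333),
    ("TAU", 9): (0.634, 0.060, 0.306),
    ("WT", 23): (0.838, 0.153, 0.009),
    ("TAU", 23): (0.693, 0.092, 0.215),
}


@dataclass
class CohortSpec:
    """Design of a simulated cohort."""

    genotypes: tuple[str, ...] = ("WT", "TAU")
    age_groups: tuple[int, ...] = (3, 9, 23)
    subregions: tuple[str, ...] = ("CA1so", "CA1sr", "Sub")
    mice_per_group: int = 3
    # 2 genotypes x 3 ages x 3 mice x 3 subregions x 15 cells = 810 cells,
    # matching the scale of a full study census
    cells_per_mouse_subregion: int = 15
    mixtures: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURES))
    archetypes: dict = field(default_factory=lambda: dict(ARCHETYPES))
    mouse_effect_sd: float = 0.1  # lognormal sd, multiplicative on branch_rate
    seed: int = 0

    def __post_init__(self) -> None:
        for key, mix in self.mixtures.items():
            if abs(sum(mix) - 1.0) > 1e-6:
                raise ValueError(f"mixture for {key} does not sum to 1: {mix}")
        if self.mice_per_group < 1 or self.cells_per_mouse_subregion < 1:
            raise ValueError("counts must be positive")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _perturb(direction: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, sd, size=3))


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.normal(size=3)
    p = r - np.dot(r, v) * v
    nrm = np.linalg.norm(p)
    if nrm < 1e-12:
        return _perpendicular(v, rng)
    return p / nrm


def simulate_skeleton(
    params: MorphotypeParams,
    seed: int | np.random.Generator | None = None,
    cell_id: str = "sim",
) -> AstrocyteSkeleton:
    """Grow one astrocyte skeleton from a stochastic branching process.

    Deterministic for a fixed seed.  Raises before growth if the parameter
    combination implies an expected node count beyond the safety bound.
    """
    if params.expected_node_bound() > MAX_NODES:
        raise ValueError(
            "parameter combination exceeds the node bound: expected about "
            f"{params.expected_node_bound():.0f} nodes (max {MAX_NODES})"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    soma_radius = params.soma_radius * float(
        rng.lognormal(0.0, params.soma_sd)
    )
    nodes_xyz: list[np.ndarray] = [np.zeros(3)]
    nodes_radius: list[float] = [soma_radius]
    nodes_type: list[int] = [1]
    nodes_parent: list[int] = [-1]

    def add_node(pos, radius, parent) -> int:
        nodes_xyz.append(np.asarray(pos, float))
        nodes_radius.append(float(radius))
        nodes_type.append(3)
        nodes_parent.append(parent)
        return len(nodes_xyz) - 1

    n_primary = max(2, int(rng.poisson(params.n_primary)))
    dirs = _fibonacci_directions(n_primary)
    # (position, direction, radius, remaining budget, parent node index)
    tips = []
    for d in dirs:
        budget = rng.exponential(params.mean_branch_length)
        start_dir = _perturb(d, 0.1, rng)
        pos = start_dir * soma_radius
        radius = max(0.1, soma_radius * 0.25)
        idx = add_node(pos, radius, 0)
        tips.append((pos, start_dir, radius, budget, idx))

    p_bifurcate = 1.0 - math.exp(-params.branch_rate * params.segment_step)
    while tips:
        pos, direction, radius, budget, parent = tips.pop()
        while budget > 0:
            direction = _perturb(direction, params.tortuosity, rng)
            nrm = np.linalg.norm(pos)
            if nrm > 1e-9 and params.radial_bias > 0:
                direction = _unit(
                    (1.0 - params.radial_bias) * direction
                    + params.radial_bias * (pos / nrm)
                )
            new_pos = pos + direction * params.segment_step
            if np.linalg.norm(new_pos) >= params.territory_radius:
                break  # growth stops at the territory boundary
            radius = max(0.1, radius * (1.0 - params.taper))
            parent = add_node(new_pos, radius, parent)
            if len(nodes_xyz) > MAX_NODES:
                raise ValueError("node bound exceeded during growth")
            pos = new_pos
            budget -= params.segment_step
            # every grown step carries bifurcation exposure (Poisson process)
            if rng.random() < p_bifurcate:
                axis = _perpendicular(direction, rng)
                jitter = rng.normal(0.0, 0.1)
                angle = params.half_angle + jitter
                d1 = _unit(
                    math.cos(angle) * direction + math.sin(angle) * axis
                )
                d2 = _unit(
                    math.cos(angle) * direction - math.sin(angle) * axis
                )
                for d_child in (d1, d2):
                    tips.append(
                        (
                            pos,
                            d_child,
                            radius,
                            rng.exponential(params.mean_branch_length),
                            parent,
                        )
                    )
                break  # current branch ends at the bifurcation point

    n = len(nodes_xyz)
    return make_skeleton(
        cell_id=cell_id,
        ids=np.arange(1, n + 1),
        type_code=np.asarray(nodes_type),
        xyz=np.vstack(nodes_xyz),
        radius=np.asarray(nodes_radius),
        parent_ids=np.asarray(
            [-1 if p == -1 else p + 1 for p in nodes_parent]
        ),
    )


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, list[tuple[AstrocyteSkeleton, dict]], pd.DataFrame]:
    """Simulate a full cohort: skeletons, manifest and ground-truth labels.

    Every cell draws its morphotype from its (genotype, age) mixture; each
    mouse carries a multiplicative lognormal random effect on the
    bifurcation rate.  With ``out_dir`` set, SWC files, ``manifest.csv``,
    ``truth.csv`` and the resolved spec (YAML) are written there.

    Returns (manifest, cells, truth) where cells is a list of
    (skeleton, metadata) pairs and truth holds per-cell morphotype labels
    and mouse effects.
    """
    master = np.random.SeedSequence(spec.seed)
    archetype_names = list(spec.archetypes)
    cells: list[tuple[AstrocyteSkeleton, dict]] = []
    manifest_rows = []
    truth_rows = []
    cell_counter = 0
    group_streams = master.spawn(len(spec.genotypes) * len(spec.age_groups))
    gi = 0
    for genotype in spec.genotypes:
        for age in spec.age_groups:
            mix = np.asarray(spec.mixtures[(genotype, age)], dtype=float)
            rng_group = np.random.default_rng(group_streams[gi])
            gi += 1
            for m in range(spec.mice_per_group):
                mouse_id = f"{genotype}_{age}m_m{m + 1}"
                mouse_effect = float(
                    rng_group.lognormal(0.0, spec.mouse_effect_sd)
                )
                for subregion in spec.subregions:
                    for _ in range(spec.cells_per_mouse_subregion):
                        cell_counter += 1
                        cell_id = f"cell{cell_counter:05d}"
                        morphotype = archetype_names[
                            rng_group.choice(len(mix), p=mix)
                        ]
                        base = spec.archetypes[morphotype]
                        params = MorphotypeParams(
                            **{
                                **asdict(base),
                                "branch_rate": base.branch_rate * mouse_effect,
                            }
                        )
                        skel = simulate_skeleton(
                            params,
                            seed=np.random.default_rng(
                                rng_group.integers(2**31)
                            ),
                            cell_id=cell_id,
                        )
                        meta = {
                            "cell_id": cell_id,
                            "mouse_id": mouse_id,
                            "genotype": genotype,
                            "age_group": age,
                            "subregion": subregion,
                        }
                        cells.append((skel, meta))
                        manifest_rows.append(
                            {**meta, "swc_path": f"swc/{cell_id}.swc"}
                        )
                        truth_rows.append(
                            {
                                "cell_id": cell_id,
                                "true_morphotype": morphotype,
                                "mouse_effect": mouse_effect,
                            }
                        )
    manifest = pd.DataFrame(manifest_rows)[
        ["cell_id", "swc_path", "mouse_id", "genotype", "age_group", "subregion"]
    ]
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "simulated %d cells (%d per genotype x age group)",
        len(cells),
        spec.mice_per_group
        * len(spec.subregions)
        * spec.cells_per_mouse_subregion,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "swc").mkdir(parents=True, exist_ok=True)
        for skel, meta in cells:
            write_swc(skel, out_dir / "swc" / f"{meta['cell_id']}.swc")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)
        resolved = {
            "genotypes": list(spec.genotypes),
            "age_groups": list(spec.age_groups),
            "subregions": list(spec.subregions),
            "mice_per_group": spec.mice_per_group,
            "cells_per_mouse_subregion": spec.cells_per_mouse_subregion,
            "mixtures": {
                f"{g}_{a}": list(map(float, v))
                for (g, a), v in spec.mixtures.items()
            },
            "archetypes": {k: asdict(v) for k, v in spec.archetypes.items()},
            "mouse_effect_sd": spec.mouse_effect_sd,
            "seed": spec.seed,
        }
        with open(out_dir / "cohort_spec.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=False)
    return manifest, cells, truth


def three_archetype_cohort(
    n_cells: int = 300,
    mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    mice: int = 3,
) -> tuple[list[tuple[AstrocyteSkeleton, dict]], pd.Series]:
    """Single-group cohort of the three default archetypes (for validation).

    Returns (cells, truth) with ``truth`` a per-cell morphotype Series.
    Cells are split evenly over ``mice`` synthetic mice of one genotype.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = list(ARCHETYPES)
    cells = []
    truth = []
    for i in range(n_cells):
        morphotype = names[rng.choice(3, p=np.asarray(mixture))]
        skel = simulate_skeleton(
            ARCHETYPES[morphotype],
            seed=np.random.default_rng(rng.integers(2**31)),
            cell_id=f"cell{i:04d}",
        )
        meta = {
            "cell_id": f"cell{i:04d}",
            "mouse_id": f"m{i % mice + 1}",
            "genotype": "WT",
            "age_group": 9,
            "subregion": "CA1sr",
        }
        cells.append((skel, meta))
        truth.append(morphotype)
    return cells, pd.Series(truth, name="true_morphotype")
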