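"""End-to-end orchestration of the morphometry / clustering / statistics flow.

Each age group is analysed independently (three separate clusterings), so
cluster labels are not comparable across ages and no cross-age label
matching is attempted.  Within an age group the stages run in order:
feature extraction -> optional log10 -> z-scaling -> correlation-matrix PCA
with Kaiser + Horn retention -> k selection by index vote -> algorithm
selection by internal validation -> variable contribution filter -> DAPC
refinement -> cluster proportions and chi-square per genotype ->
Kruskal-Wallis/Dunn cluster characterisation -> complexity ranking ->
nested-ANOVA genotype contrasts per feature and subregion -> Sholl-profile
comparison.  A single master seed fans out to named substreams, making the
pipeline a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dapc, dimreduce, group_stats, morphometry, synthetic
from .skeleton import load_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "input": {"manifest": None, "simulate": None},
    "features": {
        "sholl_step": 1.0,
        # right-skewed features are log-transformed before scaling;
        # counts that may be zero use log10(1 + x)
        "log10": [
            "total_process_length",
            "n_branches",
            "sholl_peak_count",
            "n_primary_branches",
            "ramification_index",
        ],
        "log10p": [
            "n_branching_points",
            "sholl_median",
            "branch_depth_median",
            "branch_level_median",
        ],
    },
    "pca": {"n_iter": 1000, "quantile": 0.95, "min_components": 2},
    "cluster": {
        "k_range": [2, 8],
        "linkage": "ward",
        "algorithms": list(clustering.ALGORITHMS),
        "panel": list(clustering.DEFAULT_PANEL),
        "gap_n_ref": 50,
    },
    "dapc": {"contribution_threshold": 0.7, "alpha": 0.05},
    "stats": {"sholl_alpha": 0.01},
    "age_groups": None,  # None = every age group present in the data
    "seed": 0,
    "out_dir": None,
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key in user and user[key] is not None:
            if not isinstance(user[key], dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_validate(dval, user[key], f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + u for u in unknown)}")
    return out


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    settings: dict

    @classmethod
    def from_dict(cls, user: dict | None = None) -> "PipelineConfig":
        return cls(settings=_merge_validate(DEFAULT_CONFIG, user or {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.settings[key]


@dataclass
class AgeGroupResult:
    """All artifacts of one age group's analysis."""

    age_group: int
    n_cells: int
    feature_table: pd.DataFrame
    eigenvalues: np.ndarray
    kaiser_k: int
    horn_k: int
    retained_k: int
    k_report: clustering.ValidationReport
    algorithm_report: clustering.ValidationReport
    solution: clustering.ClusterSolution
    retained_features: list[str]
    contribution_report: pd.DataFrame
    dapc_model: dapc.DAPCModel
    refined_labels: np.ndarray
    proportions: pd.DataFrame
    chi_square: group_stats.StatTestResult | None
    cluster_tests: dict[str, dict]
    complexity: pd.DataFrame
    nested_tests: list[dict]
    sholl_tests: dict[str, dict]
    sholl_summary: pd.DataFrame | None = None


@dataclass
class RunReport:
    """Full pipeline output across age groups."""

    config: dict
    seed: int
    per_age: dict[int, AgeGroupResult] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named deterministic child stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def _substream_int(master_seed: int, name: str) -> int:
    return int(substream(master_seed, name).integers(2**31))


def run_pipeline(config: PipelineConfig | dict | None = None) -> RunReport:
    """Run the full analysis on a manifest cohort or a simulated one."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    cfg = config.settings
    seed = int(cfg["seed"])
    t0 = time.time()

    if cfg["input"]["manifest"]:
        cells = load_cohort(cfg["input"]["manifest"])
    else:
        sim_cfg = dict(cfg["input"]["simulate"] or {})
        sim_cfg.setdefault("seed", _substream_int(seed, "simulation"))
        spec = synthetic.CohortSpec(**sim_cfg)
        _, cells, _ = synthetic.simulate_cohort(spec)
    report = RunReport(config=cfg, seed=seed)
    report.timings["load"] = time.time() - t0

    step = float(cfg["features"]["sholl_step"])
    features = morphometry.profiles_table(cells, sholl_step=step)
    curves = {
        meta["cell_id"]: morphometry.sholl_curve(skel, step=step)
        for skel, meta in cells
    }
    report.timings["features"] = time.time() - t0

    ages = cfg["age_groups"] or sorted(features["age_group"].unique())
    for age in ages:
        report.per_age[int(age)] = _run_age_group(
            features[features["age_group"] == age].reset_index(drop=True),
            curves,
            cfg,
            seed,
        )
    report.timings["total"] = time.time() - t0

    if cfg["out_dir"]:
        _write_artifacts(report, features, Path(cfg["out_dir"]))
    return report


def _run_age_group(
    table: pd.DataFrame,
    curves: dict,
    cfg: dict,
    seed: int,
) -> AgeGroupResult:
    age = int(table["age_group"].iloc[0])
    # drop cells with an undefined ramification index
    missing = ~np.isfinite(table["ramification_index"].to_numpy(float))
    if missing.any():
        logger.info(
            "age %d: dropping %d cell(s) with undefined ramification index",
            age, int(missing.sum()),
        )
        table = table[~missing].reset_index(drop=True)

    feats = table[morphometry.FEATURE_COLUMNS]
    scaled = dimreduce.zscale(
        feats,
        log10_features=cfg["features"]["log10"],
        log10p_features=cfg["features"]["log10p"],
    )
    pca_out = dimreduce.pca(scaled)
    k_kaiser = dimreduce.kaiser(pca_out.eigenvalues)
    k_horn, thresholds = dimreduce.horn_parallel(
        scaled,
        n_iter=int(cfg["pca"]["n_iter"]),
        quantile=float(cfg["pca"]["quantile"]),
        seed=substream(seed, f"horn_{age}"),
    )
    pca_out.horn_thresholds = thresholds
    pca_out = dimreduce.retain(
        pca_out, k_kaiser, k_horn, min_components=cfg["pca"]["min_components"]
    )
    scores = pca_out.retained_scores

    k_lo, k_hi = cfg["cluster"]["k_range"]
    k_hi = min(int(k_hi), len(scores) - 1)
    k_report = clustering.select_k(
        scores,
        k_range=(int(k_lo), k_hi),
        panel=tuple(cfg["cluster"]["panel"]),
        algorithm="hierarchical",
        linkage_method=cfg["cluster"]["linkage"],
        seed=_substream_int(seed, f"select_k_{age}"),
        n_ref=int(cfg["cluster"]["gap_n_ref"]),
    )
    solution, algo_report = clustering.select_algorithm(
        scores,
        k_report.chosen_k,
        candidates=tuple(cfg["cluster"]["algorithms"]),
        seed=_substream_int(seed, f"select_algorithm_{age}"),
        linkage_method=cfg["cluster"]["linkage"],
    )

    z_table = pd.DataFrame(
        scaled.values, columns=scaled.columns, index=table.index
    )
    retained_feats, contrib_report = dapc.variable_contribution_filter(
        z_table,
        solution.labels,
        threshold=float(cfg["dapc"]["contribution_threshold"]),
        alpha=float(cfg["dapc"]["alpha"]),
    )

    model = dapc.fit_dapc(scores, solution.labels)
    refined = dapc.refine_partition(model, solution.labels)
    model.variable_contributions = contrib_report

    meta = table[["cell_id", "mouse_id", "genotype", "subregion"]]
    proportions = group_stats.cluster_proportions(refined, meta)
    ctab = group_stats.contingency_table(refined, meta)
    try:
        chi2 = group_stats.chi_square_distribution(ctab)
    except ValueError as exc:
        logger.warning("age %d: chi-square skipped (%s)", age, exc)
        chi2 = None

    cluster_tests: dict[str, dict] = {}
    for feat in retained_feats:
        groups = [
            table.loc[refined == c, feat].to_numpy(float)
            for c in np.unique(refined)
        ]
        kw = group_stats.kruskal_wallis(groups, names=np.unique(refined))
        dunns = group_stats.dunn_bh(groups, names=np.unique(refined))
        cluster_tests[feat] = {"kruskal_wallis": kw, "dunn": dunns}

    complexity = group_stats.complexity_score(refined, z_table)

    nested_tests = []
    for subregion in sorted(table["subregion"].unique()):
        sub = table[table["subregion"] == subregion]
        if sub["genotype"].nunique() < 2:
            continue
        for feat in morphometry.FEATURE_COLUMNS:
            vals = sub[feat].to_numpy(float)
            ok = np.isfinite(vals)
            try:
                res = group_stats.nested_anova(
                    vals[ok],
                    sub["genotype"].to_numpy()[ok],
                    sub["mouse_id"].to_numpy()[ok],
                )
            except ValueError as exc:
                logger.info(
                    "nested ANOVA skipped (%s, %s): %s", subregion, feat, exc
                )
                continue
            nested_tests.append(
                {"subregion": subregion, "feature": feat, "result": res}
            )

    # per-genotype Sholl mean +/- SEM over the cohort's radius range
    all_curves = [curves[cid] for cid in table["cell_id"]]
    r_max = max((len(c.counts) for c in all_curves), default=0)
    sholl_rows = []
    for genotype in sorted(table["genotype"].unique()):
        cids = table.loc[table["genotype"] == genotype, "cell_id"]
        mat = group_stats.align_sholl_curves(
            [curves[cid] for cid in cids], r_max=r_max
        )
        for j in range(r_max):
            col = mat[:, j]
            sholl_rows.append(
                {
                    "genotype": genotype,
                    "radius": float(j + 1),
                    "mean": float(col.mean()),
                    "sem": float(col.std(ddof=1) / np.sqrt(len(col)))
                    if len(col) > 1
                    else 0.0,
                }
            )
    sholl_summary = pd.DataFrame(sholl_rows)

    sholl_tests: dict[str, dict] = {}
    genotypes = sorted(table["genotype"].unique())
    if len(genotypes) == 2:
        for subregion in sorted(table["subregion"].unique()):
            sub = table[table["subregion"] == subregion]
            by_geno = {
                g: [curves[cid] for cid in sub.loc[sub["genotype"] == g, "cell_id"]]
                for g in genotypes
            }
            if any(len(v) < 2 for v in by_geno.values()):
                continue
            sholl_tests[subregion] = group_stats.sholl_profile_compare(
                by_geno, alpha=float(cfg["stats"]["sholl_alpha"])
            )

    logger.info(
        "age %d: retained %d PCs (kaiser=%d horn=%d), chose k=%d via %s, "
        "refined with DAPC",
        age, pca_out.retained_k, k_kaiser, k_horn,
        k_report.chosen_k, solution.algorithm,
    )
    return AgeGroupResult(
        age_group=age,
        n_cells=len(table),
        feature_table=table,
        eigenvalues=pca_out.eigenvalues,
        kaiser_k=k_kaiser,
        horn_k=k_horn,
        retained_k=pca_out.retained_k,
        k_report=k_report,
        algorithm_report=algo_report,
        solution=solution,
        retained_features=retained_feats,
        contribution_report=contrib_report,
        dapc_model=model,
        refined_labels=refined,
        proportions=proportions,
        chi_square=chi2,
        cluster_tests=cluster_tests,
        complexity=complexity,
        nested_tests=nested_tests,
        sholl_tests=sholl_tests,
        sholl_summary=sholl_summary,
    )


# ---------------------------------------------------------------------------
# serialisation and rendering
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def summarise(report: RunReport) -> dict:
    """JSON-serialisable summary of a run report."""
    out = {"seed": report.seed, "timings": report.timings, "per_age": {}}
    for age, res in report.per_age.items():
        out["per_age"][str(age)] = {
            "n_cells": res.n_cells,
            "eigenvalues": _jsonify(np.round(res.eigenvalues, 6)),
            "kaiser_k": res.kaiser_k,
            "horn_k": res.horn_k,
            "retained_k": res.retained_k,
            "k_votes": _jsonify(res.k_report.votes),
            "chosen_k": res.k_report.chosen_k,
            "chosen_algorithm": res.solution.algorithm,
            "retained_features": res.retained_features,
            "refinement_moved_fraction": float(
                (res.refined_labels != res.solution.labels).mean()
            ),
            "proportions": _jsonify(res.proportions),
            "chi_square": (
                {
                    "statistic": res.chi_square.statistic,
                    "p_value": res.chi_square.p_value,
                    "df": _jsonify(res.chi_square.df),
                }
                if res.chi_square
                else None
            ),
            "complexity": _jsonify(res.complexity),
            "n_nested_tests": len(res.nested_tests),
            "significant_sholl_radii": {
                sr: _jsonify(t["significant_radii"])
                for sr, t in res.sholl_tests.items()
            },
        }
    return out


def _write_artifacts(
    report: RunReport, features: pd.DataFrame, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fpath = out_dir / "features.csv"
    features.to_csv(fpath, index=False)
    report.artifacts["features"] = str(fpath)
    labels_rows = []
    for age, res in report.per_age.items():
        post_max = res.dapc_model.posteriors.max(axis=1)
        for i, cid in enumerate(res.feature_table["cell_id"]):
            labels_rows.append(
                {
                    "cell_id": cid,
                    "age_group": age,
                    "cluster": int(res.solution.labels[i]),
                    "refined_cluster": int(res.refined_labels[i]),
                    "max_posterior": float(post_max[i]),
                }
            )
    lpath = out_dir / "labels.csv"
    pd.DataFrame(labels_rows).to_csv(lpath, index=False)
    report.artifacts["labels"] = str(lpath)
    jpath = out_dir / "report.json"
    with open(jpath, "w") as fh:
        json.dump(summarise(report), fh, indent=2)
    report.artifacts["report"] = str(jpath)
    try:
        _render_figures(report, out_dir)
    except Exception as exc:  # plotting must never abort an analysis run
        logger.warning("figure rendering failed: %s", exc)
    mpath = out_dir / "report.md"
    mpath.write_text(report_render(report))
    report.artifacts["markdown"] = str(mpath)


def _render_figures(report: RunReport, out_dir: Path) -> None:
    """Per age group: scree plot, cluster-proportion pies, Sholl curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for age, res in sorted(report.per_age.items()):
        fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
        ax = axes[0]
        ranks = np.arange(1, len(res.eigenvalues) + 1)
        ax.plot(ranks, res.eigenvalues, "o-", label="observed")
        ax.axhline(1.0, color="grey", ls="--", lw=0.8, label="Kaiser")
        ax.axvline(res.retained_k + 0.5, color="red", ls=":", lw=0.8)
        ax.set_xlabel("component")
        ax.set_ylabel("eigenvalue")
        ax.set_title(f"{age} mo: scree (retained {res.retained_k})")
        ax.legend(fontsize=7)

        ax = axes[1]
        genotypes = sorted(res.proportions["genotype"].unique())
        width = 0.8 / len(genotypes)
        clusters = sorted(res.proportions["cluster"].unique())
        for i, g in enumerate(genotypes):
            sub = res.proportions[res.proportions["genotype"] == g]
            pct = [
                float(sub.loc[sub["cluster"] == c, "percent"].sum())
                for c in clusters
            ]
            ax.bar(np.arange(len(clusters)) + i * width, pct, width, label=g)
        ax.set_xticks(np.arange(len(clusters)) + width / 2)
        ax.set_xticklabels([f"c{c}" for c in clusters])
        ax.set_ylabel("% of cells")
        ax.set_title("cluster distribution by genotype")
        ax.legend(fontsize=7)

        ax = axes[2]
        if res.sholl_summary is not None and len(res.sholl_summary):
            for g, sub in res.sholl_summary.groupby("genotype"):
                ax.errorbar(
                    sub["radius"], sub["mean"], yerr=sub["sem"],
                    label=g, lw=1.0, elinewidth=0.5,
                )
            ax.legend(fontsize=7)
        ax.set_xlabel("radius (um)")
        ax.set_ylabel("Sholl intersections (mean +/- SEM)")
        ax.set_title("Sholl profiles")
        fig.tight_layout()
        fpath = out_dir / f"figures_age{age}.png"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        report.artifacts[f"figures_age{age}"] = str(fpath)


def report_render(report: RunReport) -> str:
    """Human-readable markdown summary of a run report."""
    lines = ["# astromorph run report", ""]
    lines.append(f"Seed: {report.seed}")
    for age, res in sorted(report.per_age.items()):
        lines += ["", f"## Age group {age} months ({res.n_cells} cells)", ""]
        lines.append(
            f"PCA eigenvalues: {np.round(res.eigenvalues, 3).tolist()}"
        )
        lines.append(
            f"Retention: Kaiser {res.kaiser_k}, Horn {res.horn_k}, "
            f"retained {res.retained_k}"
        )
        lines.append(
            f"k votes: {res.k_report.votes} -> k = {res.k_report.chosen_k}; "
            f"algorithm: {res.solution.algorithm}"
        )
        if res.retained_features:
            lines.append(
                "Variables retained for cluster comparison: "
                + ", ".join(res.retained_features)
            )
        else:
            lines.append("No retained variables (all filtered out).")
        lines += ["", "### Cluster proportions", ""]
        lines.append(res.proportions.to_string(index=False))
        if res.chi_square is not None:
            lines.append(
                f"\nGenotype x cluster chi-square = "
                f"{res.chi_square.statistic:.3f} "
                f"(df {res.chi_square.df:g}, p = {res.chi_square.p_value:.3g})"
            )
        lines += ["", "### Complexity ranking", ""]
        lines.append(res.complexity.to_string())
        if res.sholl_tests:
            lines += ["", "### Sholl profile contrasts", ""]
            for sr, t in sorted(res.sholl_tests.items()):
                lines.append(
                    f"- {sr}: significant radii {t['significant_radii']}"
                )
    lines.append("")
    return "\n".join(lines)
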