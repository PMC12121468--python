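"""Group-comparison statistics for astrocyte morphometry cohorts.

Covers the tests used to characterise morphotype clusters and cohort
contrasts: Kruskal-Wallis with Dunn's post hoc (Benjamini-Hochberg FDR
within each family), two-level nested ANOVA with mouse as a random factor
nested in genotype (cells are not independent replicates of genotype),
Pearson chi-square on genotype x cluster contingency tables, per-radius
Sholl-profile comparison (two-way ANOVA then Bonferroni-corrected
per-radius contrasts), cluster complexity scoring, and cluster-proportion
tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COMPLEXITY_FEATURES = ("n_branching_points", "n_branches", "ramification_index")


@dataclass
class StatTestResult:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    df: tuple | float | None = None
    adjusted_p: float | None = None
    groups: tuple | None = None
    note: str | None = None
    descriptives: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def _descriptives(groups: list[np.ndarray], names=None) -> pd.DataFrame:
    names = names if names is not None else list(range(1, len(groups) + 1))
    rows = []
    for name, g in zip(names, groups):
        g = np.asarray(g, dtype=float)
        n = len(g)
        rows.append(
            {
                "group": name,
                "n": n,
                "mean": g.mean() if n else math.nan,
                "sem": g.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan,
                "median": float(np.median(g)) if n else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def kruskal_wallis(groups: list[np.ndarray], names=None) -> StatTestResult:
    """Kruskal-Wallis rank test with tie correction (chi-square p, k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(pooled) == 0:
        return StatTestResult(
            "kruskal_wallis", 0.0, 1.0, df=len(groups) - 1,
            note="all values identical",
            descriptives=_descriptives(groups, names),
        )
    h, p = sps.kruskal(*groups)
    return StatTestResult(
        "kruskal_wallis", float(h), float(p), df=len(groups) - 1,
        descriptives=_descriptives(groups, names),
    )


def dunn_bh(groups: list[np.ndarray], names=None) -> list[StatTestResult]:
    """Dunn's pairwise post hoc z tests on pooled ranks, BH-adjusted.

    The BH family is the full set of pairwise comparisons within this call
    (one Kruskal-Wallis family).  Tie correction uses the pooled tie counts.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    names = names if names is not None else list(range(1, len(groups) + 1))
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term
    results = []
    raw_ps = []
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        se = math.sqrt(base_var * (1.0 / len(gi) + 1.0 / len(gj)))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw_ps.append(p)
        results.append(
            StatTestResult(
                "dunn", float(z), float(p), groups=(names[i], names[j])
            )
        )
    if results:
        adjusted = multipletests(raw_ps, method="fdr_bh")[1]
        for res, ap in zip(results, adjusted):
            res.adjusted_p = float(ap)
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in the raw p-value ranks)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def nested_anova(
    values, genotype, mouse_id
) -> StatTestResult:
    """Two-level nested ANOVA: genotype fixed, mouse random nested in genotype.

    Sums of squares are partitioned sequentially into genotype,
    mouse-within-genotype and residual strata.  The genotype F uses the
    mouse-within-genotype mean square as its denominator with (g-1, m-g)
    degrees of freedom, so mice — not cells — are the effective replicates
    of genotype.  Unbalanced designs use the same sequential decomposition
    (group-size-weighted means), which is logged.
    """
    y = np.asarray(values, dtype=float)
    geno = np.asarray(genotype)
    mouse = np.asarray(mouse_id)
    if len(y) != len(geno) or len(y) != len(mouse):
        raise ValueError("values, genotype and mouse_id must align")
    geno_of_mouse = {}
    for g, m in zip(geno, mouse):
        if m in geno_of_mouse and geno_of_mouse[m] != g:
            raise ValueError(f"mouse {m!r} appears in more than one genotype")
        geno_of_mouse[m] = g
    g_levels = np.unique(geno)
    if len(g_levels) < 2:
        raise ValueError("need >= 2 genotypes")
    mice_per_geno = {
        g: len({m for m, gg in geno_of_mouse.items() if gg == g})
        for g in g_levels
    }
    if any(c < 2 for c in mice_per_geno.values()):
        raise ValueError(
            "need >= 2 mice per genotype to test genotype against "
            f"mouse-within-genotype variance (got {mice_per_geno})"
        )
    n_mice = len(geno_of_mouse)
    grand = y.mean()
    ss_geno = sum(
        (geno == g).sum() * (y[geno == g].mean() - grand) ** 2
        for g in g_levels
    )
    ss_mouse = 0.0
    ss_res = 0.0
    for m, g in geno_of_mouse.items():
        ym = y[mouse == m]
        ss_mouse += len(ym) * (ym.mean() - y[geno == g].mean()) ** 2
        ss_res += ((ym - ym.mean()) ** 2).sum()
    df_geno = len(g_levels) - 1
    df_mouse = n_mice - len(g_levels)
    df_res = len(y) - n_mice
    counts = np.array([np.sum(mouse == m) for m in geno_of_mouse])
    if len(np.unique(counts)) > 1:
        logger.info(
            "unbalanced nested design (cells/mouse %s); sequential SS used",
            dict(zip(geno_of_mouse, counts.tolist())),
        )
    if ss_geno + ss_mouse + ss_res == 0:
        return StatTestResult(
            "nested_anova", math.nan, math.nan, df=(df_geno, df_mouse),
            note="all values identical; F undefined",
        )
    ms_geno = ss_geno / df_geno
    ms_mouse = ss_mouse / df_mouse if df_mouse > 0 else math.nan
    ms_res = ss_res / df_res if df_res > 0 else math.nan
    f_geno = ms_geno / ms_mouse if ms_mouse and ms_mouse > 0 else math.inf
    p_geno = float(sps.f.sf(f_geno, df_geno, df_mouse))
    f_mouse = (
        ms_mouse / ms_res if ms_res and ms_res > 0 and df_mouse > 0 else math.nan
    )
    p_mouse = (
        float(sps.f.sf(f_mouse, df_mouse, df_res))
        if np.isfinite(f_mouse)
        else math.nan
    )
    groups_desc = _descriptives([y[geno == g] for g in g_levels], g_levels)
    return StatTestResult(
        "nested_anova",
        float(f_geno),
        p_geno,
        df=(df_geno, df_mouse),
        descriptives=groups_desc,
        extra={
            "ss_genotype": float(ss_geno),
            "ss_mouse": float(ss_mouse),
            "ss_residual": float(ss_res),
            "df": (df_geno, df_mouse, df_res),
            "f_mouse": f_mouse,
            "p_mouse": p_mouse,
        },
    )


def chi_square_distribution(table: pd.DataFrame | np.ndarray) -> StatTestResult:
    """Pearson chi-square of independence on a genotype x cluster table.

    Zero-margin rows/columns are dropped with a warning; a warning is also
    recorded when any expected count is below 5.
    """
    tab = (
        table.to_numpy(dtype=float)
        if isinstance(table, pd.DataFrame)
        else np.asarray(table, dtype=float)
    )
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    note = None
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping zero-margin rows/columns from chi-square table")
        note = "zero-margin rows/columns dropped"
        tab = tab[keep_r][:, keep_c]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")
    chi2, p, dof, expected = sps.chi2_contingency(tab, correction=False)
    if (expected < 5).any():
        msg = "some expected counts < 5; chi-square approximation is rough"
        logger.warning(msg)
        note = f"{note}; {msg}" if note else msg
    return StatTestResult(
        "pearson_chi2", float(chi2), float(p), df=float(dof), note=note,
        extra={"expected": expected},
    )


def align_sholl_curves(
    curves: list, r_max: int | None = None, step: float = 1.0
) -> np.ndarray:
    """Stack per-cell Sholl curves into a cells x radii matrix.

    Cells are zero-padded beyond their own maximum radius: absent processes
    are true zero intersections.
    """
    lengths = [len(c.counts) for c in curves]
    R = r_max if r_max is not None else (max(lengths) if lengths else 0)
    out = np.zeros((len(curves), R))
    for i, c in enumerate(curves):
        m = min(len(c.counts), R)
        out[i, :m] = c.counts[:m]
    return out


def sholl_profile_compare(
    curves_by_genotype: dict[str, list],
    alpha: float = 0.01,
    step: float = 1.0,
) -> dict:
    """Compare Sholl profiles between two genotypes radius by radius.

    A two-way ANOVA (genotype x radius, cells as replicates) provides the
    omnibus test; per-radius genotype contrasts (pooled-variance t tests)
    are then Bonferroni-corrected across radii, and the radii passing the
    corrected threshold are returned.
    """
    names = list(curves_by_genotype)
    if len(names) != 2:
        raise ValueError("expected exactly 2 genotypes")
    r_max = max(
        (len(c.counts) for cs in curves_by_genotype.values() for c in cs),
        default=0,
    )
    mats = {g: align_sholl_curves(cs, r_max=r_max) for g, cs in curves_by_genotype.items()}
    radii = step * np.arange(1, r_max + 1)

    # two-way ANOVA on the long table (fixed effects, interaction)
    y, f_geno, f_rad = [], [], []
    for g in names:
        m = mats[g]
        y.append(m.ravel())
        f_geno.append(np.repeat(g, m.size))
        f_rad.append(np.tile(radii, m.shape[0]))
    long = pd.DataFrame(
        {
            "count": np.concatenate(y),
            "genotype": np.concatenate(f_geno),
            "radius": np.concatenate(f_rad),
        }
    )
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("count ~ C(genotype) * C(radius)", data=long).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)

    per_radius: list[StatTestResult] = []
    n_tests = 0
    for j, r in enumerate(radii):
        a, b = mats[names[0]][:, j], mats[names[1]][:, j]
        if len(a) < 2 or len(b) < 2:
            logger.info("radius %.0f excluded: <2 cells per genotype", r)
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
        per_radius.append(
            StatTestResult(
                "sholl_radius_contrast", float(t), float(p),
                groups=(names[0], names[1]), extra={"radius": float(r)},
            )
        )
        n_tests += 1
    for res in per_radius:
        res.adjusted_p = min(1.0, res.p_value * n_tests)
    significant = [
        res.extra["radius"] for res in per_radius if res.adjusted_p < alpha
    ]
    return {
        "anova": anova_table,
        "per_radius": per_radius,
        "significant_radii": significant,
        "alpha": alpha,
    }


def complexity_score(
    labels: np.ndarray, feature_table_z: pd.DataFrame
) -> pd.DataFrame:
    """Rank clusters from low to high morphological complexity.

    The score of a cluster is the mean of the z-scores of the number of
    branching points, total number of branches and ramification index over
    its cells (missing ramification indices are excluded pairwise).
    """
    labels = np.asarray(labels)
    feats = [f for f in COMPLEXITY_FEATURES if f in feature_table_z.columns]
    if len(feats) < len(COMPLEXITY_FEATURES):
        missing = set(COMPLEXITY_FEATURES) - set(feats)
        logger.warning("complexity score missing features: %s", missing)
    rows = []
    for c in np.unique(labels):
        sub = feature_table_z.loc[labels == c, feats]
        rows.append({"cluster": int(c), "complexity_score": float(np.nanmean(sub.to_numpy()))})
    out = pd.DataFrame(rows).set_index("cluster")
    out["complexity_rank"] = out["complexity_score"].rank(method="first").astype(int)
    n = len(out)
    names = {1: "low", n: "high"}
    out["complexity_label"] = [
        names.get(r, "medium") for r in out["complexity_rank"]
    ]
    return out.sort_values("complexity_rank")


def cluster_proportions(
    labels: np.ndarray, metadata: pd.DataFrame, by: tuple[str, ...] = ("genotype",)
) -> pd.DataFrame:
    """Counts and percentages of cells per cluster within metadata groups."""
    labels = np.asarray(labels)
    df = metadata.copy().reset_index(drop=True)
    df["cluster"] = labels
    counts = (
        df.groupby([*by, "cluster"], observed=True).size().rename("count").reset_index()
    )
    totals = counts.groupby(list(by), observed=True)["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts


def contingency_table(
    labels: np.ndarray, metadata: pd.DataFrame, row: str = "genotype"
) -> pd.DataFrame:
    """Genotype (rows) x cluster (columns) cell-count table."""
    labels = np.asarray(labels)
    return pd.crosstab(metadata[row].to_numpy(), labels)
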