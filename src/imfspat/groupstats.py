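"""Group-level inference on per-participant spatial metrics.

Implements the standard age x sex comparison workflow for cohort tables of
Delaunay/Ripley summaries: Shapiro-Wilk normality and Levene (median-centered,
Brown-Forsythe) variance homogeneity checks select between a parametric branch
(two-way ANOVA with Type-II sums of squares + Tukey HSD) and a nonparametric
branch (Friedman across muscles, Kruskal-Wallis across groups, Dunn's post-hoc
with Bonferroni correction). Hedges' g quantifies pairwise effect sizes
independent of sample size. Alpha is 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05
COHORT_COLUMNS = ["participant_id", "age_group", "sex", "muscle", "metric_name", "value"]


@dataclass
class CohortTable:
    """Long-format cohort of per-participant metric values.

    One row per (participant, muscle, metric); age_group in {young, older},
    sex in {male, female}.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        dup = self.data.duplicated(["participant_id", "muscle", "metric_name"])
        if dup.any():
            raise ValueError("duplicate (participant, muscle, metric) rows")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def subset(self, muscle: str, metric: str) -> pd.DataFrame:
        d = self.data
        return d[(d.muscle == muscle) & (d.metric_name == metric)].copy()

    @property
    def muscles(self) -> list[str]:
        return sorted(self.data.muscle.unique())


def assumption_checks(groups: dict[str, np.ndarray]) -> tuple[dict[str, float], float]:
    """Shapiro-Wilk p per group and a single Levene p across groups.

    Levene uses median centering (Brown-Forsythe). Groups must have n >= 3
    and non-zero variance.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, a in arrays.items():
        if a.size < 3:
            raise ValueError(f"group {name!r} has n < 3")
        if np.ptp(a) == 0:
            raise ValueError(f"group {name!r} is constant; tests are degenerate")
    shapiro_p = {name: float(stats.shapiro(a).pvalue) for name, a in arrays.items()}
    levene_p = float(stats.levene(*arrays.values(), center="median").pvalue)
    return shapiro_p, levene_p


def choose_branch(shapiro_p: dict[str, float], levene_p: float) -> str:
    """Parametric iff every Shapiro-Wilk p > alpha and Levene p > alpha."""
    ok = all(p > ALPHA for p in shapiro_p.values()) and levene_p > ALPHA
    return "parametric" if ok else "nonparametric"


def two_way_anova(df: pd.DataFrame, typ: int = 2) -> pd.DataFrame:
    """Two-way age x sex ANOVA with Type-II sums of squares (unbalanced-safe).

    ``df`` needs columns value, age_group, sex. Returns a table indexed by
    effect (age, sex, age:sex) with columns F and p.
    """
    for fac in ("age_group", "sex"):
        counts = df.groupby([ "age_group", "sex"], observed=True).size()
        if (counts == 0).any() or counts.size < 4:
            raise ValueError("empty age x sex cell")
    model = smf.ols("value ~ C(age_group) * C(sex)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=typ)
    rename = {
        "C(age_group)": "age",
        "C(sex)": "sex",
        "C(age_group):C(sex)": "age:sex",
    }
    out = tab.rename(index=rename).loc[["age", "sex", "age:sex"], ["F", "PR(>F)"]]
    return out.rename(columns={"PR(>F)": "p"})


def hedges_g(group_a, group_b) -> float:
    """Bias-corrected standardized mean difference (mean_a - mean_b).

    g = J * (mean_a - mean_b) / s_pooled with
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)) and
    small-sample correction J = 1 - 3 / (4 (n_a + n_b) - 9).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(sp2))


def _dunn_bonferroni(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank test with tie correction, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    sizes = {n: groups[n].size for n in names}
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_rank, start = {}, 0
    for n in names:
        mean_rank[n] = ranks[start:start + sizes[n]].mean()
        start += sizes[n]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, min(1.0, p * len(pairs))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_adj"])


def posthoc(df: pd.DataFrame, branch: str = "parametric") -> pd.DataFrame:
    """All pairwise comparisons among the four age x sex groups.

    Parametric branch: Tukey HSD; nonparametric branch: Dunn with Bonferroni.
    Each row also reports the raw mean difference and Hedges' g.
    """
    d = df.copy()
    d["group"] = d.age_group.astype(str) + "_" + d.sex.astype(str)
    groups = {name: sub.value.to_numpy(dtype=float)
              for name, sub in d.groupby("group", observed=True)}
    if branch == "parametric":
        res = pairwise_tukeyhsd(d.value.to_numpy(dtype=float),
                                d.group.to_numpy(), alpha=ALPHA)
        pairs = list(combinations(res.groupsunique, 2))  # statsmodels pair order
        tab = pd.DataFrame({
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "statistic": res.meandiffs,
            "p_adj": res.pvalues,
        })
    elif branch == "nonparametric":
        tab = _dunn_bonferroni(groups)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    tab["mean_diff"] = [groups[a].mean() - groups[b].mean()
                        for a, b in zip(tab.group_a, tab.group_b)]
    tab["hedges_g"] = [hedges_g(groups[a], groups[b])
                       for a, b in zip(tab.group_a, tab.group_b)]
    return tab


def friedman_across_muscles(table: CohortTable, metric: str) -> tuple[float, float]:
    """Friedman test of the metric across muscles, treating each participant
    as a block (repeated measures). Participants missing any muscle are
    dropped."""
    d = table.data[table.data.metric_name == metric]
    wide = d.pivot(index="participant_id", columns="muscle", values="value").dropna()
    if wide.shape[1] < 3 or wide.shape[0] < 3:
        raise ValueError("Friedman test needs >= 3 muscles and >= 3 complete participants")
    stat, p = stats.friedmanchisquare(*[wide[c].to_numpy() for c in wide.columns])
    return float(stat), float(p)


@dataclass
class StatReport:
    """Inference summary for one (muscle, metric)."""

    muscle: str
    metric: str
    shapiro_p: dict[str, float]
    levene_p: float
    branch_taken: str
    effects: pd.DataFrame = field(repr=False, default=None)
    omnibus: tuple[float, float] | None = None
    posthoc_table: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"{self.metric} in {self.muscle}",
            "=" * 40,
            "Shapiro-Wilk p: "
            + ", ".join(f"{k}={v:.3g}" for k, v in self.shapiro_p.items()),
            f"Levene p: {self.levene_p:.3g}",
            f"Branch: {self.branch_taken}",
        ]
        if self.effects is not None:
            lines.append(self.effects.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.omnibus is not None:
            lines.append(f"Kruskal-Wallis H={self.omnibus[0]:.4g}, p={self.omnibus[1]:.3g}")
        if self.posthoc_table is not None:
            lines.append(self.posthoc_table.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "muscle": self.muscle,
            "metric": self.metric,
            "shapiro_p": self.shapiro_p,
            "levene_p": self.levene_p,
            "branch_taken": self.branch_taken,
        }
        if self.effects is not None:
            out["effects"] = {
                idx: {"F": float(row.F), "p": float(row.p)}
                for idx, row in self.effects.iterrows()
            }
        if self.omnibus is not None:
            out["kruskal"] = {"H": self.omnibus[0], "p": self.omnibus[1]}
        if self.posthoc_table is not None:
            out["posthoc"] = self.posthoc_table.to_dict(orient="records")
        return out


def analyze_metric(table: CohortTable, metric: str, muscle: str) -> StatReport:
    """Run the full inference workflow for one metric within one muscle.

    Assumption checks on the four age x sex groups pick the branch; small
    groups (n < 3) force the nonparametric branch.
    """
    d = table.subset(muscle, metric)
    d["group"] = d.age_group.astype(str) + "_" + d.sex.astype(str)
    groups = {name: sub.value.to_numpy(dtype=float)
              for name, sub in d.groupby("group", observed=True)}
    try:
        shapiro_p, levene_p = assumption_checks(groups)
        branch = choose_branch(shapiro_p, levene_p)
    except ValueError:
        shapiro_p, levene_p = {g: np.nan for g in groups}, np.nan
        branch = "nonparametric"
    report = StatReport(muscle, metric, shapiro_p, levene_p, branch)
    if branch == "parametric":
        report.effects = two_way_anova(d)
    else:
        h, p = stats.kruskal(*groups.values())
        report.omnibus = (float(h), float(p))
    report.posthoc_table = posthoc(d, branch)
    return report
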