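"""Relative fitness from competition assays and phenotypic-contingency
statistics.

Relative fitness of an evolved line E against a reference competitor A over
one competition cycle is the ratio of realized doublings::

    w_r = log2(N_f^E / N_i^E) / log2(N_f^A / N_i^A)

Downstream statistics mirror the standard analysis of a two-phase evolution
experiment: one-sample deviation-from-1 tests with a normality screen,
nested ANOVA partitioning variance by adaptive pathway and founder genotype,
ANCOVA with founder fitness as covariate, per-pathway founder-slope
regressions (OLS and major-axis Model II), and cross-environment trade-off
summaries.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutations import GroupLabeling

ASSAY_CSV_COLUMNS = [
    "population_id",
    "competitor_id",
    "environment",
    "replicate",
    "n_i_evolved",
    "n_f_evolved",
    "n_i_reference",
    "n_f_reference",
]


@dataclass(frozen=True)
class CompetitionAssay:
    """Paired initial/final densities for an evolved line and its reference."""

    population_id: str
    competitor_id: str
    environment: str
    n_i_evolved: float
    n_f_evolved: float
    n_i_reference: float
    n_f_reference: float
    replicate: int = 0
    failed: bool = False

    def validate(self) -> None:
        for name in ("n_i_evolved", "n_f_evolved", "n_i_reference", "n_f_reference"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name}={v} must be positive and finite")
        if self.n_f_reference == self.n_i_reference:
            raise ValueError(
                "reference fold-growth of exactly 1: w_r denominator undefined"
            )


@dataclass(frozen=True)
class FitnessEstimate:
    population_id: str
    environment: str
    w_r: float
    replicate: int = 0
    competitor_id: str = ""


def relative_fitness(assay: CompetitionAssay) -> FitnessEstimate:
    """w_r = log2(evolved fold-growth) / log2(reference fold-growth)."""
    assay.validate()
    w = math.log2(assay.n_f_evolved / assay.n_i_evolved) / math.log2(
        assay.n_f_reference / assay.n_i_reference
    )
    return FitnessEstimate(
        population_id=assay.population_id,
        environment=assay.environment,
        w_r=w,
        replicate=assay.replicate,
        competitor_id=assay.competitor_id,
    )


def estimate_fitness(assays: Sequence[CompetitionAssay]) -> list[FitnessEstimate]:
    """Relative fitness per assay; assays flagged as failed are skipped."""
    return [relative_fitness(a) for a in assays if not a.failed]


def read_assay_csv(path) -> list[CompetitionAssay]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ASSAY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay CSV missing required column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CompetitionAssay(
                population_id=str(row.population_id),
                competitor_id=str(row.competitor_id),
                environment=str(row.environment),
                replicate=int(row.replicate),
                n_i_evolved=float(row.n_i_evolved),
                n_f_evolved=float(row.n_f_evolved),
                n_i_reference=float(row.n_i_reference),
                n_f_reference=float(row.n_f_reference),
                failed=bool(getattr(row, "failed", False)),
            )
        )
    return out


def write_assay_csv(assays: Sequence[CompetitionAssay], path) -> None:
    df = pd.DataFrame([vars(a) for a in assays])
    cols = ASSAY_CSV_COLUMNS + ["failed"]
    df[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class GroupTestResult:
    mean: float
    n: int
    test: str
    p_value: float | None
    flagged: str | None = None


def group_fitness_test(
    estimates: Sequence[FitnessEstimate] | Sequence[float],
    null_value: float = 1.0,
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """One-sample deviation test with a Shapiro-Wilk normality screen.

    If normality is not rejected at ``alpha_normality``, a one-sample t-test
    against ``null_value`` is used; otherwise a one-sample Wilcoxon
    signed-rank test.  Degenerate samples (all values identical) return the
    mean with an undefined p, flagged.
    """
    values = np.asarray(
        [e.w_r if isinstance(e, FitnessEstimate) else float(e) for e in estimates]
    )
    if len(values) < 3:
        raise ValueError("need >=3 estimates")
    mean = float(values.mean())
    if np.ptp(values) == 0:
        return GroupTestResult(
            mean=mean, n=len(values), test="none",
            p_value=None, flagged="all values identical",
        )
    _, p_norm = stats.shapiro(values)
    if p_norm >= alpha_normality:
        t, p = stats.ttest_1samp(values, null_value)
        return GroupTestResult(mean=mean, n=len(values), test="t-test", p_value=float(p))
    diffs = values - null_value
    if np.all(diffs == 0):
        return GroupTestResult(
            mean=mean, n=len(values), test="wilcoxon",
            p_value=None, flagged="all differences zero",
        )
    _, p = stats.wilcoxon(diffs)
    return GroupTestResult(mean=mean, n=len(values), test="wilcoxon", p_value=float(p))


@dataclass(frozen=True)
class VariancePartition:
    factors: tuple[str, ...]
    sum_sq: tuple[float, ...]
    fraction: tuple[float, ...]
    p_values: tuple[float | None, ...]
    method: str
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            f: {"sum_sq": s, "fraction": fr, "p_value": p}
            for f, s, fr, p in zip(
                self.factors, self.sum_sq, self.fraction, self.p_values
            )
        }


def _estimates_frame(
    estimates: Sequence[FitnessEstimate], labeling: GroupLabeling
) -> pd.DataFrame:
    rows = [
        {
            "population_id": e.population_id,
            "w_r": e.w_r,
            "pathway": labeling.pathway(e.population_id),
            "founder": labeling.founder(e.population_id),
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def nested_anova(
    estimates: Sequence[FitnessEstimate],
    labeling: GroupLabeling,
) -> VariancePartition:
    """Sequential (Type-I) nested ANOVA: pathway, then founder within pathway.

    Fractions of variance are SS_factor / SS_total.  F-tests follow the
    classic nested design: pathway MS over founder-within-pathway MS, founder
    MS over residual MS.  A singular design (one founder per pathway) drops
    the founder term with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _estimates_frame(estimates, labeling)
    if df["pathway"].nunique() < 2:
        raise ValueError("need >=2 pathways")
    founders_per = df.groupby("pathway")["founder"].nunique()
    warn: list[str] = []
    nested = (founders_per > 1).any()
    if not nested:
        warn.append("one founder per pathway: founder term dropped")

    formula = "w_r ~ C(pathway)"
    if nested:
        formula += " + C(pathway):C(founder)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols(formula, data=df).fit()
        aov = sm.stats.anova_lm(model, typ=1)

    ss_total = float(aov["sum_sq"].sum())
    # guard against pure floating-point fuzz on constant responses
    if ss_total <= 1e-20 * max(1.0, float((df["w_r"] ** 2).sum())):
        ss_total = 0.0
        aov["sum_sq"] = 0.0
    ss_path = float(aov.loc["C(pathway)", "sum_sq"])
    df_path = float(aov.loc["C(pathway)", "df"])
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])

    factors = ["pathway"]
    sums = [ss_path]
    if nested:
        key = "C(pathway):C(founder)"
        ss_found = float(aov.loc[key, "sum_sq"])
        df_found = float(aov.loc[key, "df"])
        ms_path, ms_found = ss_path / df_path, ss_found / df_found
        ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
        if ss_total == 0:
            p_path = p_found = None
        else:
            p_path = float(stats.f.sf(ms_path / ms_found, df_path, df_found)) \
                if ms_found > 0 else None
            p_found = float(stats.f.sf(ms_found / ms_resid, df_found, df_resid)) \
                if df_resid > 0 and ms_resid > 0 else None
        factors.append("founder(pathway)")
        sums.append(ss_found)
        ps = [p_path, p_found, None]
    else:
        ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
        p_path = float(
            stats.f.sf((ss_path / df_path) / ms_resid, df_path, df_resid)
        ) if df_resid > 0 and ms_resid > 0 else None
        ps = [p_path, None]
    factors.append("residual")
    sums.append(ss_resid)
    fracs = [s / ss_total if ss_total > 0 else 0.0 for s in sums]
    return VariancePartition(
        factors=tuple(factors),
        sum_sq=tuple(sums),
        fraction=tuple(fracs),
        p_values=tuple(ps),
        method="nested-ANOVA",
        warnings=tuple(warn),
    )


def kruskal_eta2(
    values: Sequence[float] | Sequence[FitnessEstimate],
    groups: Sequence[str],
) -> VariancePartition:
    """Kruskal-Wallis H with the eta-squared effect size
    eta2_H = (H - k + 1) / (n - k), clipped at 0."""
    vals = np.asarray(
        [v.w_r if isinstance(v, FitnessEstimate) else float(v) for v in values]
    )
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >=2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    samples = [vals[groups == g] for g in uniq]
    h, p = stats.kruskal(*samples)
    n, k = len(vals), len(uniq)
    eta2 = max((h - k + 1) / (n - k), 0.0)
    return VariancePartition(
        factors=("group",),
        sum_sq=(float(h),),
        fraction=(float(eta2),),
        p_values=(float(p),),
        method="Kruskal-Wallis-eta2",
    )


@dataclass(frozen=True)
class AncovaResult:
    pathway_p: float
    covariate_p: float | None
    coefficients: dict
    warnings: tuple[str, ...] = ()


def ancova_pathway(
    estimates: Sequence[FitnessEstimate],
    labeling: GroupLabeling,
    covariate: Mapping[str, float],
) -> AncovaResult:
    """ANCOVA: w_r ~ founder-fitness covariate + pathway (Type-I, covariate
    first), reporting the pathway effect adjusted for the covariate.

    ``covariate`` maps founder id -> founder fitness.  A constant covariate
    triggers a collinearity warning and a pathway-only fallback.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _estimates_frame(estimates, labeling)
    try:
        df["cov"] = [covariate[f] for f in df["founder"]]
    except KeyError as e:
        raise ValueError(f"covariate undefined for founder {e.args[0]!r}") from e
    warn: list[str] = []
    if df["cov"].nunique() == 1:
        warn.append("constant covariate: pathway-only model used")
        formula = "w_r ~ C(pathway)"
    else:
        formula = "w_r ~ cov + C(pathway)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols(formula, data=df).fit()
        # Type-II: each term adjusted for the other, so the pathway test is
        # the covariate-adjusted one regardless of term ordering
        aov = sm.stats.anova_lm(model, typ=2)
    cov_p = float(aov.loc["cov", "PR(>F)"]) if "cov" in aov.index else None
    return AncovaResult(
        pathway_p=float(aov.loc["C(pathway)", "PR(>F)"]),
        covariate_p=cov_p,
        coefficients=dict(model.params),
        warnings=tuple(warn),
    )


def major_axis_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Model II major-axis slope: orientation of the first principal axis of
    the (x, y) covariance matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0:
        raise ValueError("zero variance in x: slope undefined")
    if sxy == 0:
        # principal axis aligned with a coordinate axis
        return 0.0 if sxx >= syy else math.inf
    return (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


@dataclass(frozen=True)
class SlopeRegressionResult:
    per_group: pd.DataFrame  # group, n, slope_ols, p_ols, slope_ma, intercept_ols
    heterogeneity_p: float | None


def founder_slope_regression(
    points: pd.DataFrame,
    x: str = "founder_w_r",
    y: str = "delta_w_r",
    group: str = "pathway",
) -> SlopeRegressionResult:
    """Per-group slope of fitness change on founder fitness.

    Reports ordinary least squares (slope, p for slope=0) and major-axis
    Model II slopes per group, plus a slope-heterogeneity test between groups
    via the OLS interaction term.
    """
    import statsmodels.formula.api as smf

    rows = []
    for g, sub in points.groupby(group):
        if len(sub) < 3:
            raise ValueError(f"need >=3 points per group (group {g!r})")
        xs, ys = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.ptp(xs) == 0:
            raise ValueError(f"zero variance in x for group {g!r}")
        res = stats.linregress(xs, ys)
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "slope_ols": res.slope,
                "intercept_ols": res.intercept,
                "p_ols": res.pvalue,
                "slope_ma": major_axis_slope(xs, ys),
            }
        )
    per_group = pd.DataFrame(rows)

    het_p = None
    if points[group].nunique() >= 2:
        df = points.rename(columns={x: "_x", y: "_y", group: "_g"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.ols("_y ~ _x * C(_g)", data=df).fit()
            reduced = smf.ols("_y ~ _x + C(_g)", data=df).fit()
            ftest = full.compare_f_test(reduced)
        het_p = float(ftest[1])
    return SlopeRegressionResult(per_group=per_group, heterogeneity_p=het_p)


def tradeoff_summary(
    estimates_a: Sequence[FitnessEstimate],
    estimates_b: Sequence[FitnessEstimate],
    labeling: GroupLabeling,
    severe_threshold: float = 0.6,
    pathways: tuple[str, str] = ("rho", "rpoB"),
) -> dict:
    """Cross-environment trade-off table.

    Per founder and environment: mean w_r and a deviation-from-1 test
    (``group_fitness_test``).  The pathway contrast at environment B uses a
    rank-based two-sample test (Mann-Whitney U).  Founders whose mean w_r at
    B falls below ``severe_threshold`` are flagged as severe trade-offs.
    """
    pops_a = {e.population_id for e in estimates_a}
    pops_b = {e.population_id for e in estimates_b}
    if not (pops_a & pops_b):
        raise ValueError("no overlap in population ids between environments")

    rows = []
    for env, ests in (("A", estimates_a), ("B", estimates_b)):
        by_founder: dict[str, list[float]] = {}
        for e in ests:
            by_founder.setdefault(labeling.founder(e.population_id), []).append(e.w_r)
        for founder, vals in sorted(by_founder.items()):
            res = group_fitness_test(vals) if len(vals) >= 3 else None
            rows.append(
                {
                    "founder": founder,
                    "environment": env,
                    "n": len(vals),
                    "mean_w_r": float(np.mean(vals)),
                    "test": res.test if res else "none",
                    "p_value": res.p_value if res else None,
                    "severe_tradeoff": env == "B"
                    and float(np.mean(vals)) < severe_threshold,
                }
            )
    table = pd.DataFrame(rows)

    b_vals: dict[str, list[float]] = {pw: [] for pw in pathways}
    for e in estimates_b:
        pw = labeling.pathway(e.population_id)
        if pw in b_vals:
            b_vals[pw].append(e.w_r)
    contrast_p = None
    if all(len(v) >= 2 for v in b_vals.values()):
        _, contrast_p = stats.mannwhitneyu(
            b_vals[pathways[0]], b_vals[pathways[1]], alternative="two-sided"
        )
        contrast_p = float(contrast_p)
    return {"table": table, "pathway_contrast_p": contrast_p}
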