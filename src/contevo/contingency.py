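"""Genotypic-contingency statistics on binary mutation profiles.

Dice similarity between populations' mutated-region sets, within- vs
between-pathway contrasts with a label-permutation null, Clarke's ANOSIM on a
distance matrix, per-region 2x2 Fisher enrichment with Benjamini-Hochberg
FDR, and mutation-type proportion contrasts.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mutations import GroupLabeling, PresenceAbsenceMatrix


def dice_coefficient(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Dice's similarity coefficient 2|A n B| / (|A| + |B|).

    Undefined (ValueError) when both sets are empty; the caller applies the
    configured empty-pair policy.
    """
    na, nb = len(set_a), len(set_b)
    if na == 0 and nb == 0:
        raise ValueError("Dice coefficient undefined for two empty sets")
    return 2.0 * len(set_a & set_b) / (na + nb)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of pairwise Dice coefficients.

    Pairs where both profiles are empty hold NaN; downstream contrasts apply
    the empty-pair policy (exclude, or score 0).
    """

    table: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def value(self, a: str, b: str) -> float:
        return float(self.table.at[a, b])


def similarity_matrix(pa: PresenceAbsenceMatrix) -> SimilarityMatrix:
    """All-pairs Dice similarity from a presence-absence matrix."""
    b = pa.table.to_numpy(dtype=np.int64)
    sizes = b.sum(axis=1)
    inter = b @ b.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        dsc = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1), np.nan)
    # diagonal: 1 for non-empty profiles, NaN (undefined) for empty ones
    np.fill_diagonal(dsc, np.where(sizes > 0, 1.0, np.nan))
    table = pd.DataFrame(dsc, index=pa.populations, columns=pa.populations)
    return SimilarityMatrix(table=table)


def _pair_values(
    sim: SimilarityMatrix,
    labels: Sequence[str],
    empty_pair_policy: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Condensed upper-triangle similarities with pair label arrays."""
    m = sim.table.to_numpy(dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = m[iu, ju]
    if empty_pair_policy == "zero":
        vals = np.where(np.isnan(vals), 0.0, vals)
    elif empty_pair_policy != "exclude":
        raise ValueError(f"unknown empty_pair_policy {empty_pair_policy!r}")
    return vals, iu, ju


@dataclass(frozen=True)
class DscContrast:
    within_mean: float
    between_mean: float
    difference: float
    n_within_pairs: int
    n_between_pairs: int
    per_class_means: dict[str, float] = field(default_factory=dict)


def dsc_contrast(
    sim: SimilarityMatrix,
    labeling: GroupLabeling,
    pathways: tuple[str, str] = ("rho", "rpoB"),
    empty_pair_policy: str = "exclude",
) -> DscContrast:
    """Mean Dice similarity within vs between the two adaptive pathways.

    Pairs involving populations outside ``pathways`` (ancestor controls) are
    excluded from the within/between means but reported per comparison class
    in ``per_class_means``.
    """
    pops = sim.populations
    labels = np.array([labeling.pathway(p) for p in pops])
    vals, iu, ju = _pair_values(sim, labels, empty_pair_policy)
    ok = ~np.isnan(vals)

    la, lb = labels[iu], labels[ju]
    in_pair = np.isin(la, pathways) & np.isin(lb, pathways)
    within = ok & in_pair & (la == lb)
    between = ok & in_pair & (la != lb)
    if within.sum() == 0 or between.sum() == 0:
        raise ValueError("need >=2 populations in each of two pathways")

    per_class: dict[str, float] = {}
    class_key = np.array(
        ["|".join(sorted((a, b))) for a, b in zip(la, lb)]
    )
    for cls in np.unique(class_key):
        mask = ok & (class_key == cls)
        if mask.any():
            per_class[cls] = float(vals[mask].mean())

    wm = float(vals[within].mean())
    bm = float(vals[between].mean())
    return DscContrast(
        within_mean=wm,
        between_mean=bm,
        difference=wm - bm,
        n_within_pairs=int(within.sum()),
        n_between_pairs=int(between.sum()),
        per_class_means=per_class,
    )


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    p_value: float
    p_value_smoothed: float
    n_iterations: int
    seed: int | None
    exact: bool = False
    null_sample: np.ndarray | None = None


def _contrast_stat(vals, ok, la, lb, pathways):
    in_pair = np.isin(la, pathways) & np.isin(lb, pathways)
    within = ok & in_pair & (la == lb)
    between = ok & in_pair & (la != lb)
    if within.sum() == 0 or between.sum() == 0:
        return np.nan
    return vals[within].mean() - vals[between].mean()


def dsc_randomization_test(
    sim: SimilarityMatrix,
    labeling: GroupLabeling,
    n_iter: int = 5000,
    seed: int | None = None,
    pathways: tuple[str, str] = ("rho", "rpoB"),
    empty_pair_policy: str = "exclude",
    permute: str = "labels",
) -> PermutationTestResult:
    """Randomization test of (within - between) mean Dice similarity.

    The null is generated by shuffling population -> pathway labels (the
    exchangeable unit) and recomputing the contrast; ``permute="values"``
    instead shuffles the pairwise similarities themselves.  ``p_value`` is the
    raw proportion of null statistics >= observed (can be 0);
    ``p_value_smoothed`` is (b + 1) / (B + 1).  When the number of distinct
    label arrangements is below 10, the full enumeration is used instead and
    the result is marked ``exact``.
    """
    pops = sim.populations
    labels = np.array([labeling.pathway(p) for p in pops])
    vals, iu, ju = _pair_values(sim, labels, empty_pair_policy)
    ok = ~np.isnan(vals)

    sel = np.isin(labels, pathways)
    sel_idx = np.flatnonzero(sel)
    sub_labels = labels[sel_idx]
    observed = _contrast_stat(vals, ok, labels[iu], labels[ju], pathways)
    if np.isnan(observed):
        raise ValueError("contrast not computable for observed labeling")

    rng = np.random.default_rng(seed)
    n_sel = len(sel_idx)
    k = int((sub_labels == pathways[0]).sum())
    from math import comb

    null: list[float] = []
    exact = comb(n_sel, k) < 10
    if exact:
        arrangements = itertools.combinations(range(n_sel), k)
    else:
        arrangements = (
            tuple(rng.choice(n_sel, size=k, replace=False))
            for _ in range(n_iter)
        )

    for arr in arrangements:
        perm = labels.copy()
        if permute == "labels":
            sub = np.full(n_sel, pathways[1], dtype=object)
            sub[list(arr)] = pathways[0]
            perm[sel_idx] = sub
            null.append(_contrast_stat(vals, ok, perm[iu], perm[ju], pathways))
        elif permute == "values":
            shuf = vals.copy()
            idx = np.flatnonzero(ok)
            shuf[idx] = shuf[rng.permutation(idx)]
            null.append(_contrast_stat(shuf, ok, labels[iu], labels[ju], pathways))
        else:
            raise ValueError(f"unknown permute mode {permute!r}")

    null_arr = np.asarray(null, dtype=float)
    b = int(np.sum(null_arr >= observed))
    n_done = len(null_arr)
    return PermutationTestResult(
        observed=float(observed),
        p_value=b / n_done,
        p_value_smoothed=(b + 1) / (n_done + 1),
        n_iterations=n_done,
        seed=seed,
        exact=exact,
        null_sample=null_arr,
    )


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    grouping: str
    seed: int | None = None


def anosim(
    distances: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    n_permutations: int = 9999,
    seed: int | None = None,
    grouping_name: str = "pathway",
) -> AnosimResult:
    """Clarke's analysis of similarities on a square distance matrix.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M / 2) with M = n(n-1)/2, ranks averaged over ties.  The
    permutation p-value uses the (b + 1)/(B + 1) convention, so the smallest
    attainable p at 9,999 permutations is 1e-4.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    groups = np.asarray(groups)
    n = d.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per row required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups of size >=2")

    iu, ju = np.triu_indices(n, k=1)
    vals = d[iu, ju]
    m = len(vals)
    ranks = stats.rankdata(vals)  # average ranks over ties

    def r_stat(g: np.ndarray) -> float:
        within = g[iu] == g[ju]
        if vals.std() == 0:
            return 0.0
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(groups)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(groups)) >= observed:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    if vals.std() == 0:
        p = 1.0
    return AnosimResult(
        r=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        grouping=grouping_name,
        seed=seed,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def region_enrichment(
    pa: PresenceAbsenceMatrix,
    labeling: GroupLabeling,
    pathways: tuple[str, str] = ("rho", "rpoB"),
) -> pd.DataFrame:
    """Per-region 2x2 Fisher's exact tests between two pathways.

    For each region mutated in at least one population of either pathway, a
    2x2 table of (populations with / without a mutation in the region) x
    (pathway A / B) is tested two-sided (summing hypergeometric tables with
    probability <= the observed table).  Rows are sorted by raw p; the
    ``q_value`` column is BH-FDR over all tested regions in the run.
    """
    pop_in = {
        pw: [p for p in pa.populations if labeling.pathway(p) == pw]
        for pw in pathways
    }
    n_a, n_b = len(pop_in[pathways[0]]), len(pop_in[pathways[1]])
    if n_a == 0 or n_b == 0:
        raise ValueError(f"no populations for one of the pathways {pathways}")
    sub_a = pa.table.loc[pop_in[pathways[0]]]
    sub_b = pa.table.loc[pop_in[pathways[1]]]

    rows = []
    for region in pa.regions:
        a = int(sub_a[region].sum())
        b = int(sub_b[region].sum())
        if a + b == 0:
            continue  # absent from both selected pathways: not tested
        table = [[a, n_a - a], [b, n_b - b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        enriched = pathways[0] if a / n_a >= b / n_b else pathways[1]
        rows.append(
            {
                "region_id": region,
                "pathway_enriched": enriched,
                "n_mutated_a": a,
                "n_total_a": n_a,
                "n_mutated_b": b,
                "n_total_b": n_b,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"])
    df = df.sort_values(["p_value", "region_id"], kind="mergesort")
    return df.reset_index(drop=True)


def type_proportion_test(
    spectrum: pd.DataFrame,
    n_monte_carlo: int = 10000,
    seed: int = 0,
) -> dict:
    """Chi-square homogeneity test of mutation-type proportions across groups.

    ``spectrum`` is an effects x groups count table.  Zero-margin rows and
    columns are dropped (with a warning field in the result).  When any
    expected cell count falls below 5 the p-value is computed by Monte-Carlo
    permutation conditional on the margins (seeded, >=10,000 draws), using
    the (b + 1)/(B + 1) convention.
    """
    table = spectrum.to_numpy(dtype=np.int64)
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    dropped = int((~row_ok).sum() + (~col_ok).sum())
    table = table[np.ix_(row_ok, col_ok)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a >=2 x >=2 table after dropping zero margins")

    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    method = "chi-square"
    if (expected < 5).any():
        method = "chi-square (Monte-Carlo p)"
        rng = np.random.default_rng(seed)
        # expand to per-observation row/column labels, permute columns
        row_lab = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
        col_lab = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
        b = 0
        for _ in range(n_monte_carlo):
            perm = rng.permutation(col_lab)
            sim_tab = np.zeros_like(table)
            np.add.at(sim_tab, (row_lab, perm), 1)
            sim_exp = np.outer(sim_tab.sum(1), sim_tab.sum(0)) / sim_tab.sum()
            sim_chi2 = ((sim_tab - sim_exp) ** 2 / sim_exp).sum()
            if sim_chi2 >= chi2 - 1e-12:
                b += 1
        p = (b + 1) / (n_monte_carlo + 1)
    return {
        "statistic": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "method": method,
        "n_dropped_margins": dropped,
    }
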