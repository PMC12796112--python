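"""Differential enrichment between groups, FDR control and overlap reports.

Two-group comparisons use the equal-variance two-sample t test by default
(Welch available); multi-group designs use one-way ANOVA with Tukey HSD
pairwise p-values from the studentized-range distribution, substituting the
Bonferroni-corrected pairwise t p whenever the computed Tukey p underflows
10^-8.5 (the reference pipeline's guard against imprecise extreme Tukey
tails). Multiple testing is controlled by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import IntensityMatrix, SampleDesign

TUKEY_BONFERRONI_CUTOFF = 10.0 ** -8.5

_SMALLEST_P = np.nextafter(0.0, 1.0)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_matrix(m: IntensityMatrix, d: SampleDesign, group: str) -> np.ndarray:
    cols = [m.sample_index(s) for s in d.samples_in_group(group)]
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    return m.values[:, cols]


def two_group_test(
    m: IntensityMatrix,
    d: SampleDesign,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein two-sided t test of group_a vs group_b.

    Returns a table with per-group means, log2fc = mean(A) - mean(B),
    unadjusted and BH-adjusted p, and a significance flag at ``alpha``
    (strict inequality, on the unadjusted p). Zero pooled variance is
    resolved to p=1 for equal means and the smallest positive double for
    unequal means, with a flag column.
    """
    d = d.aligned_to(m)
    A, B = _group_matrix(m, d, group_a), _group_matrix(m, d, group_b)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("need >=2 samples per group")
    if not m.mask.all():
        raise ValueError("two_group_test requires a complete matrix; impute first")

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (A.var(axis=1) + B.var(axis=1)) == 0
    degenerate |= ~np.isfinite(p) | (p == 0)
    flag = np.array([""] * m.n_proteins, dtype=object)
    eq = degenerate & np.isclose(mean_a, mean_b)
    p[eq] = 1.0
    flag[eq] = "zero_variance_equal_means"
    ne = degenerate & ~np.isclose(mean_a, mean_b)
    p[ne] = _SMALLEST_P
    flag[ne] = "zero_variance_unequal_means"

    log2fc = mean_a - mean_b
    out = pd.DataFrame({
        "protein": m.protein_ids,
        f"mean_{group_a}": mean_a,
        f"mean_{group_b}": mean_b,
        "log2fc": log2fc,
        "p_unadj": p,
        "p_adj": bh_adjust(p),
        "flag": flag,
    }).set_index("protein")
    out["significant"] = out["p_unadj"] < alpha
    return out


def anova_posthoc(
    m: IntensityMatrix,
    d: SampleDesign,
    groups: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD post hoc, one row per protein x pair.

    Pairwise p comes from the studentized-range distribution; when that
    estimate falls below 10^-8.5 it is replaced by the Bonferroni-corrected
    two-sample t p for the pair (method column records which was used).
    """
    d = d.aligned_to(m)
    if groups is None:
        groups = d.groups()
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    mats = {g: _group_matrix(m, d, g) for g in groups}
    for g, M in mats.items():
        if M.shape[1] < 2:
            raise ValueError(f"group {g!r} has <2 samples")
    if not m.mask.all():
        raise ValueError("anova_posthoc requires a complete matrix; impute first")

    ns = {g: M.shape[1] for g, M in mats.items()}
    N = sum(ns.values())
    k = len(groups)
    df_within = N - k

    means = {g: M.mean(axis=1) for g, M in mats.items()}
    grand = sum(ns[g] * means[g] for g in groups) / N
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(((mats[g] - means[g][:, None]) ** 2).sum(axis=1) for g in groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = ss_within / df_within
        F = (ss_between / (k - 1)) / mse
    anova_p = stats.f.sf(F, k - 1, df_within)

    n_pairs = k * (k - 1) // 2
    rows = []
    for ga, gb in combinations(groups, 2):
        diff = means[ga] - means[gb]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[ga] + 1.0 / ns[gb]))
            q = np.abs(diff) / se
        tukey_p = stats.studentized_range.sf(q, k, df_within)
        tukey_p = np.where(np.isfinite(tukey_p), tukey_p, 1.0)

        use_bonf = tukey_p < TUKEY_BONFERRONI_CUTOFF
        p_pair = tukey_p.copy()
        method = np.where(use_bonf, "bonferroni", "tukey").astype(object)
        if use_bonf.any():
            # pooled-variance pairwise t with the within-group MSE
            with np.errstate(divide="ignore", invalid="ignore"):
                t_se = np.sqrt(mse * (1.0 / ns[ga] + 1.0 / ns[gb]))
                t_stat = diff / t_se
            t_p = 2.0 * stats.t.sf(np.abs(t_stat), df_within)
            p_pair[use_bonf] = np.minimum(t_p[use_bonf] * n_pairs, 1.0)
            p_pair[use_bonf] = np.maximum(p_pair[use_bonf], _SMALLEST_P)

        rows.append(pd.DataFrame({
            "protein": m.protein_ids,
            "comparison": f"{ga}_vs_{gb}",
            f"mean_a": means[ga],
            f"mean_b": means[gb],
            "log2fc": diff,
            "anova_F": F,
            "anova_p": anova_p,
            "p_unadj": np.clip(p_pair, _SMALLEST_P, 1.0),
            "method": method,
        }))
    out = pd.concat(rows, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p_unadj"].to_numpy())
    out["significant"] = out["p_unadj"] < alpha
    return out


def volcano_table(t: pd.DataFrame, p_threshold: float = 0.05,
                  fc_threshold: float = 0.0) -> pd.DataFrame:
    """Annotate a DEA table with -log10(p) and an enrichment direction label.

    Direction uses the *unadjusted* p at a strict threshold (p = threshold
    exactly is not significant); the default threshold 0.05 corresponds to
    the -log10 = 1.3 candidate line.
    """
    out = t.copy()
    out["neg_log10_p"] = -np.log10(out["p_unadj"])
    sig = (out["p_unadj"] < p_threshold) & (out["log2fc"].abs() > fc_threshold)
    direction = np.where(~sig, "not_significant",
                         np.where(out["log2fc"] > 0, "enriched_in_A",
                                  "enriched_in_B"))
    out["direction"] = direction
    out.attrs["threshold_neg_log10"] = round(-np.log10(p_threshold), 1)
    out.attrs["counts"] = pd.Series(direction).value_counts().to_dict()
    return out


def overlap_sets(lists: Mapping[str, Sequence[str]]) -> dict:
    """UpSet-style exclusive-region counts and pairwise Venn overlaps.

    Exclusive region counts sum to the size of the union of all lists.
    """
    if len(lists) < 2:
        raise ValueError("need >=2 lists")
    names = list(lists)
    sets = {n: set(lists[n]) for n in names}
    universe = set().union(*sets.values())

    exclusive: dict[tuple[str, ...], int] = {}
    for x in universe:
        membership = tuple(n for n in names if x in sets[n])
        exclusive[membership] = exclusive.get(membership, 0) + 1

    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    return {
        "names": names,
        "sizes": {n: len(sets[n]) for n in names},
        "union_size": len(universe),
        "exclusive_regions": exclusive,
        "pairwise": pairwise,
    }


def fc_concordance(t_a: pd.DataFrame, t_b: pd.DataFrame) -> dict:
    """Sign concordance of log2 fold changes across two DEA tables.

    Considers proteins significant in either table and quantified in both;
    concordant iff both fold changes are nonzero and share a sign. Zero fold
    changes are excluded and counted separately.
    """
    shared = t_a.index.intersection(t_b.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between tables")
    a = t_a.loc[shared]
    b = t_b.loc[shared]
    either_sig = a["significant"].to_numpy() | b["significant"].to_numpy()
    fa, fb = a["log2fc"].to_numpy(), b["log2fc"].to_numpy()
    nonzero = (fa != 0) & (fb != 0)
    eligible = either_sig & nonzero
    concord = eligible & (np.sign(fa) == np.sign(fb))
    table = pd.DataFrame({
        "log2fc_a": fa, "log2fc_b": fb,
        "eligible": eligible,
        "concordant": concord,
        "zero_fc_excluded": either_sig & ~nonzero,
    }, index=shared)
    return {
        "n_concordant": int(concord.sum()),
        "n_discordant": int((eligible & ~concord).sum()),
        "n_zero_excluded": int((either_sig & ~nonzero).sum()),
        "table": table,
    }
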