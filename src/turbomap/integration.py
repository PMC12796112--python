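"""Cross-dataset synthesis: interactome and insoluble-proteome lists versus
network modules, module composition, and abundance trends across Braak
stages."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import normalize_ids
from .coexpression import NetworkModel
from .enrichment import fet_grid, fet_one_tailed, stars

EXACT_RANKSUM_MAX_N = 8


def _module_partitions(model: NetworkModel, include_m0: bool = False) -> dict[str, list[str]]:
    mods = model.modules() + (["M0"] if include_m0 else [])
    return {m: model.members(m) for m in mods if model.members(m)}


def genelist_module_fet(
    lists: Mapping[str, Sequence[str]],
    model: NetworkModel,
    background: Sequence[str] | None = None,
    adjust: str = "bh",
) -> dict[str, pd.DataFrame]:
    """FET grid of named gene lists against module membership.

    BH is applied within each input list (per-dataset), matching how
    module-enrichment heatmaps report FDR.
    """
    if background is None:
        background = model.protein_ids
    return fet_grid(lists, _module_partitions(model), background, adjust=adjust)


def insoluble_mapping(
    model: NetworkModel,
    insoluble_list: Sequence[str],
    background: Sequence[str] | None = None,
) -> dict:
    """Flag module members found in the detergent-insoluble list and report
    per-module one-tailed FET with *unadjusted* p as -log10 p (barplot
    convention)."""
    if background is None:
        background = model.protein_ids
    bg = set(normalize_ids(background))
    insol = set(normalize_ids(insoluble_list)) & bg
    N, n = len(bg), len(insol)

    flags = pd.Series(
        [pid in insol for pid in model.protein_ids],
        index=model.protein_ids, name="insoluble",
    )
    rows = []
    for mod, members in _module_partitions(model).items():
        mem = set(members) & bg
        k = len(mem & insol)
        p, fold = fet_one_tailed(k, n, len(mem), N)
        rows.append((mod, len(mem), k, k / len(mem) if mem else 0.0,
                     p, -np.log10(p), fold))
    table = pd.DataFrame(rows, columns=[
        "module", "n_members", "n_insoluble", "frac_insoluble",
        "p_unadj", "neg_log10_p", "fold"])
    return {"flags": flags, "table": table}


def module_composition(
    model: NetworkModel,
    annotations: Mapping[str, Sequence[str]],
    precedence: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exclusive class composition of each module.

    ``annotations`` maps class name -> gene list; ``precedence`` orders the
    classes so that a member matching several lists is counted once, under
    the first matching class; members matching none fall into 'unannotated'.
    Counts and percentages (2 d.p.) per module; fractions sum to 100%.
    """
    if precedence is None:
        precedence = list(annotations)
    missing = set(precedence) - set(annotations)
    if missing:
        raise ValueError(f"precedence names unknown classes: {sorted(missing)}")
    if set(annotations) - set(precedence):
        raise ValueError("every annotation class must appear in precedence")

    ann = {c: set(normalize_ids(annotations[c])) for c in precedence}
    classes = list(precedence) + ["unannotated"]
    rows = []
    for mod, members in _module_partitions(model).items():
        counts = dict.fromkeys(classes, 0)
        for pid in members:
            for c in precedence:
                if pid in ann[c]:
                    counts[c] += 1
                    break
            else:
                counts["unannotated"] += 1
        n = len(members)
        row = {"module": mod, "n_members": n}
        for c in classes:
            row[f"n_{c}"] = counts[c]
            row[f"pct_{c}"] = round(100.0 * counts[c] / n, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p (small samples; ties handled by the
    permutation distribution of the rank-sum statistic)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    idx = range(len(pooled))
    tots = np.array([ranks[list(c)].sum() for c in combinations(idx, n_x)])
    mean = tots.mean()
    more_extreme = np.abs(tots - mean) >= np.abs(obs - mean) - 1e-12
    return float(more_extreme.mean())


def braak_trend(
    abundance: Sequence[float],
    stages: Sequence,
    min_per_stage: int = 2,
) -> dict:
    """Kruskal-Wallis across ordinal stage groups plus pairwise rank-sum tests.

    Pairwise p is exact (enumeration of rank configurations) when both groups
    have <= 8 samples, otherwise the normal approximation with tie
    correction. Stages with fewer than ``min_per_stage`` samples are excluded
    from pairwise testing (flagged). Pairwise p-values are reported
    unadjusted.
    """
    abundance = np.asarray(abundance, dtype=float)
    stages = np.asarray(stages)
    levels = sorted(set(stages.tolist()))
    groups = {lev: abundance[stages == lev] for lev in levels}
    usable = [lev for lev in levels if len(groups[lev]) >= min_per_stage]
    if len(usable) < 2:
        raise ValueError("need >= 2 stages with enough samples")
    excluded = [lev for lev in levels if lev not in usable]

    kw = stats.kruskal(*[groups[lev] for lev in usable])

    pairs = []
    for a, b in combinations(usable, 2):
        x, y = groups[a], groups[b]
        if len(x) <= EXACT_RANKSUM_MAX_N and len(y) <= EXACT_RANKSUM_MAX_N:
            p = _exact_ranksum_p(x, y)
            method = "exact"
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic").pvalue)
            method = "normal_approx"
        pairs.append((a, b, p, stars(p), method))

    return {
        "kw_H": float(kw.statistic),
        "kw_p": float(kw.pvalue),
        "kw_stars": stars(float(kw.pvalue)),
        "pairwise": pd.DataFrame(
            pairs, columns=["stage_a", "stage_b", "p", "stars", "method"]),
        "excluded_stages": excluded,
    }
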