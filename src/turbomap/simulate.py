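"""Synthetic AP-MS and cohort data generators with known ground truth.

Two generators emulate the statistical structure the downstream analysis
assumes, so every stage can be validated against planted truth:

* :func:`simulate_apms` — a streptavidin-enrichment experiment: a bait/mock
  design with spiked true interactors, two strongly enriched bait rows,
  endogenously biotinylated background proteins equal in both groups, batch
  offsets, and missing-not-at-random left censoring (missingness probability
  a logistic function decreasing in true log2 intensity).

* :func:`simulate_cohort` — a brain-cohort TMT-style matrix: planted
  co-expression modules driven by latent seed signals, traits (Braak, CERAD,
  MFTau, diagnosis) linked linearly to those seeds, age/sex/PMI covariate
  effects on all proteins, per-batch offsets, and one noiseless
  global-internal-standard (GIS) sample per batch.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import GeneSet, GeneSetCollection, IntensityMatrix, SampleDesign, TraitTable


@dataclass
class ApmsSimConfig:
    n_proteins: int = 2000
    n_per_group: int = 4
    groups: tuple[str, str] = ("mock", "bait")
    n_true: int = 50
    effect_log2fc: float = 2.0
    bait_log2fc: float = 8.0
    n_endogenous: int = 30
    background_mean: float = 20.0
    background_sd: float = 2.0
    noise_sd: float = 0.5
    n_batches: int = 2
    batch_sd: float = 0.3
    censor_midpoint: float = 17.5
    censor_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true >= self.n_proteins:
            raise ValueError("n_true must be < n_proteins")
        if not np.isfinite(self.effect_log2fc) or not np.isfinite(self.bait_log2fc):
            raise ValueError("effect sizes must be finite")


def _censor_prob(intensity: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    # logistic in (midpoint - intensity); non-finite argument => no censoring
    with np.errstate(invalid="ignore"):
        z = slope * (midpoint - intensity)
    finite = np.isfinite(z)
    return np.where(finite, expit(np.where(finite, z, 0.0)), 0.0)


def simulate_apms(config: ApmsSimConfig) -> tuple[IntensityMatrix, SampleDesign, pd.Series]:
    """Generate an AP-MS bait/mock dataset with left-censored missingness.

    Returns (matrix, design, truth) where truth labels each protein as
    'background', 'interactor', 'bait', or 'endogenous_biotin'.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_p, n_s = cfg.n_proteins, cfg.n_per_group * len(cfg.groups)

    protein_ids = [f"P{i:05d}" for i in range(n_p)]
    labels = np.array(["background"] * n_p, dtype=object)
    # first two rows are the ligase-fragment baits; then interactors; then
    # endogenously biotinylated carboxylases
    labels[0:2] = "bait"
    labels[2:2 + cfg.n_true] = "interactor"
    labels[2 + cfg.n_true:2 + cfg.n_true + cfg.n_endogenous] = "endogenous_biotin"

    sample_ids, group_col, batch_col = [], [], []
    for g in cfg.groups:
        for r in range(cfg.n_per_group):
            sample_ids.append(f"{g}_{r + 1}")
            group_col.append(g)
            batch_col.append(f"b{(r % cfg.n_batches) + 1}")

    base = rng.normal(cfg.background_mean, cfg.background_sd, size=n_p)
    true_mat = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_p, n_s))

    bait_group = cfg.groups[1]
    in_bait = np.array([g == bait_group for g in group_col])
    true_mat[np.ix_(labels == "interactor", in_bait)] += cfg.effect_log2fc
    true_mat[np.ix_(labels == "bait", in_bait)] += cfg.bait_log2fc
    # endogenously biotinylated rows: strong in BOTH groups (equal means)
    true_mat[labels == "endogenous_biotin", :] += 3.0

    batch_names = sorted(set(batch_col))
    offsets = {b: rng.normal(0.0, cfg.batch_sd) for b in batch_names}
    true_mat += np.array([offsets[b] for b in batch_col])[None, :]

    if not np.all(np.isfinite(true_mat)):
        raise ValueError("simulated intensities are non-finite; check effect sizes")

    p_miss = _censor_prob(true_mat, cfg.censor_midpoint, cfg.censor_slope)
    mask = rng.random(size=true_mat.shape) >= p_miss

    design = SampleDesign(pd.DataFrame(
        {"group": group_col, "batch": batch_col, "is_gis": False},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = pd.Series(labels, index=protein_ids, name="truth")
    return IntensityMatrix(protein_ids, sample_ids, true_mat, mask), design, truth


@dataclass
class CohortSimConfig:
    n_proteins: int = 1000
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CTL": 46, "AD": 49, "PSP": 26})
    module_sizes: tuple[int, ...] = (150, 100, 60, 30)
    within_module_cor: float = 0.9
    trait_effects: dict[str, Sequence[float]] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.1, "pmi": 0.005})
    n_batches: int = 2
    batch_sd: float = 1.0
    gis_per_batch: int = 1
    base_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_module_cor < 1.0):
            raise ValueError("within_module_cor must be in (0, 1)")
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("sum of module_sizes exceeds n_proteins")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[IntensityMatrix, SampleDesign, TraitTable, pd.Series]:
    """Generate a cohort matrix with planted modules, traits and covariates.

    Module members are loading * seed_signal + unit noise with the loading
    chosen so the expected pairwise within-module correlation equals
    ``within_module_cor``. Traits are linear in the module seed signals.
    Ground-truth module labels are 0 for noise proteins and 1..k otherwise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_p = cfg.n_proteins
    k = len(cfg.module_sizes)

    sample_ids, group_col = [], []
    for g, n in cfg.n_per_group.items():
        for r in range(n):
            sample_ids.append(f"{g}_{r + 1}")
            group_col.append(g)
    n_bio = len(sample_ids)

    groups = np.array(group_col)

    # latent seed signal per module, per biological sample; diagnosis effects
    # enter as group shifts on the seeds so module abundance tracks diagnosis
    seeds = rng.standard_normal((k, n_bio))
    for dx in ("dx_AD", "dx_PSP"):
        e = cfg.trait_effects.get(dx)
        if e is not None:
            ind = (groups == dx.split("_", 1)[1]).astype(float)
            seeds += np.outer(np.asarray(list(e), dtype=float), ind)

    r = cfg.within_module_cor
    loading = np.sqrt(r / (1.0 - r))  # pairwise cor of lam*s+eps is lam^2/(lam^2+1)

    truth = np.zeros(n_p, dtype=int)
    X = rng.standard_normal((n_p, n_bio))  # unit noise for every protein
    pos = 0
    for mi, size in enumerate(cfg.module_sizes):
        X[pos:pos + size] += loading * seeds[mi]
        truth[pos:pos + size] = mi + 1
        pos += size

    # covariates
    age = rng.uniform(55, 95, size=n_bio)
    sex = rng.integers(0, 2, size=n_bio).astype(float)
    pmi = rng.uniform(2, 24, size=n_bio)
    cov = {"age": age, "sex": sex, "pmi": pmi}
    for name, slope in cfg.covariate_effects.items():
        c = cov[name]
        X += slope * (c - c.mean())[None, :]

    # continuous / ordinal traits from seeds; Braak and CERAD are a latent
    # Gaussian discretized by quantile into their ordinal ranges
    cont_traits = ["braak", "cerad", "mftau"]
    effects = {t: np.zeros(k) for t in cont_traits}
    for t, e in cfg.trait_effects.items():
        if t in effects:
            effects[t] = np.asarray(list(e), dtype=float)

    latent = {t: effects[t] @ seeds + rng.standard_normal(n_bio)
              for t in cont_traits}
    braak = np.clip(np.digitize(latent["braak"], np.quantile(
        latent["braak"], np.linspace(1 / 7, 6 / 7, 6))), 0, 6)
    cerad = np.clip(np.digitize(latent["cerad"], np.quantile(
        latent["cerad"], [0.25, 0.5, 0.75])), 0, 3)
    traits = pd.DataFrame(
        {
            "braak": braak.astype(float),
            "cerad": cerad.astype(float),
            "mftau": latent["mftau"],
            "dx_AD": (groups == "AD").astype(float),
            "dx_PSP": (groups == "PSP").astype(float),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    X += cfg.base_mean

    # batches with offsets, plus noiseless GIS anchors per batch
    batch_ids = np.array([f"b{(i % cfg.n_batches) + 1}" for i in range(n_bio)])
    batch_names = sorted(set(batch_ids))
    offsets = {b: rng.normal(0.0, cfg.batch_sd) for b in batch_names}
    X += np.array([offsets[b] for b in batch_ids])[None, :]

    grand = np.median(X - np.array([offsets[b] for b in batch_ids])[None, :],
                      axis=1)
    gis_cols, gis_ids, gis_batches = [], [], []
    for b in batch_names:
        for g in range(cfg.gis_per_batch):
            gis_cols.append(grand + offsets[b])
            gis_ids.append(f"GIS_{b}_{g + 1}")
            gis_batches.append(b)

    all_ids = sample_ids + gis_ids
    values = np.column_stack([X] + [c[:, None] for c in gis_cols]) \
        if gis_cols else X
    design = SampleDesign(pd.DataFrame(
        {
            "group": group_col + ["GIS"] * len(gis_ids),
            "batch": list(batch_ids) + gis_batches,
            "is_gis": [False] * n_bio + [True] * len(gis_ids),
            "age": list(age) + [np.nan] * len(gis_ids),
            "sex": list(sex) + [np.nan] * len(gis_ids),
            "pmi": list(pmi) + [np.nan] * len(gis_ids),
        },
        index=pd.Index(all_ids, name="sample_id"),
    ))

    protein_ids = [f"G{i:05d}" for i in range(n_p)]
    mask = np.ones_like(values, dtype=bool)
    m = IntensityMatrix(protein_ids, all_ids, values, mask)
    truth_s = pd.Series(truth, index=protein_ids, name="module_truth")
    return m, design, TraitTable(traits), truth_s


def simulate_genesets(
    truth: pd.Series,
    overlap_fracs: Sequence[float] | float = 0.8,
    n_decoy_sets: int = 5,
    set_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """Marker sets for each ground-truth module plus uniform decoy sets.

    Each marker set draws ``overlap_frac`` of its members from the module and
    the rest from the non-module background; decoys are uniform draws.
    """
    rng = np.random.default_rng(seed)
    modules = sorted(int(x) for x in set(truth.values) if int(x) != 0)
    if np.isscalar(overlap_fracs):
        overlap_fracs = [float(overlap_fracs)] * len(modules)
    if any(not (0.0 <= f <= 1.0) for f in overlap_fracs):
        raise ValueError("overlap fractions must be in [0, 1]")

    all_ids = np.asarray(truth.index, dtype=object)
    sets: list[GeneSet] = []
    for mi, frac in zip(modules, overlap_fracs):
        members = all_ids[truth.values == mi]
        background = all_ids[truth.values != mi]
        n_in = min(int(round(frac * set_size)), len(members))
        n_out = set_size - n_in
        chosen = list(rng.choice(members, size=n_in, replace=False)) + \
            list(rng.choice(background, size=min(n_out, len(background)),
                            replace=False))
        sets.append(GeneSet(f"marker_M{mi}", f"synthetic markers module {mi}",
                            sorted(chosen)))
    for d in range(n_decoy_sets):
        chosen = rng.choice(all_ids, size=min(set_size, len(all_ids)),
                            replace=False)
        sets.append(GeneSet(f"decoy_{d + 1}", "uniform decoy", sorted(chosen)))
    return GeneSetCollection(sets)
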