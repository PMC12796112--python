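"""Filtering, imputation and normalization applied before inference.

The imputation follows the Perseus down-shift convention for left-censored
label-free data: per sample, missing cells are drawn from a Gaussian centered
at the noise level nu_s = mu_s - shift * sigma_s with SD = width * sigma_s,
where mu_s and sigma_s are the observed mean and SD of that sample's log2
intensities. Defaults shift=1.8, width=0.3.

Batch normalization for the cohort matrix is a two-step median polish of
log2 ratios anchored on global-internal-standard (GIS) samples: it alternates
removing the per-protein, per-batch median offset relative to the GIS central
tendency and the per-sample median, until the GIS central tendency converges
to 0 relative log2 abundance.

Covariate removal uses nonparametric bootstrap regression: per protein, OLS
coefficients are re-estimated on bootstrap resamples of samples and the
median coefficient over resamples is used to subtract each removed
covariate's (centered) contribution; protected variables (e.g. diagnosis)
are modeled but their contribution is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import IntensityMatrix, SampleDesign

logger = logging.getLogger("turbomap")


@dataclass
class ImputeParams:
    shift: float = 1.8   # down-shift from observed mean, in observed-SD units
    width: float = 0.3   # imputation SD, in observed-SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift <= 0 or self.width <= 0:
            raise ValueError("shift and width must be positive")


@dataclass
class RegressSpec:
    covariates: Sequence[str] = ("age", "sex", "pmi")
    protected: Sequence[str] = ()
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        clash = set(self.covariates) & set(self.protected)
        if clash:
            raise ValueError(f"variables both removed and protected: {sorted(clash)}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def filter_by_missingness(
    m: IntensityMatrix,
    d: SampleDesign | None = None,
    max_frac: float = 0.5,
    mode: Literal["global", "groupwise"] = "global",
) -> IntensityMatrix:
    """Drop proteins by missing fraction.

    global: drop a protein iff its missing fraction over all samples is
    >= max_frac (a protein absent in exactly 50% of samples is removed under
    the default, matching the "50% or more" rule).
    groupwise: keep a protein iff at least one group has missing fraction
    < max_frac.
    """
    if not (0.0 < max_frac <= 1.0):
        raise ValueError("max_frac must be in (0, 1]")
    if mode == "global":
        miss_frac = 1.0 - m.mask.mean(axis=1)
        keep = miss_frac < max_frac
    elif mode == "groupwise":
        if d is None:
            raise ValueError("groupwise filtering requires a design")
        d = d.aligned_to(m)
        keep = np.zeros(m.n_proteins, dtype=bool)
        for g in d.groups():
            cols = [m.sample_index(s) for s in d.samples_in_group(g)]
            miss_frac = 1.0 - m.mask[:, cols].mean(axis=1)
            keep |= miss_frac < max_frac
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_drop = int((~keep).sum())
    logger.info("missingness filter (%s, %.2f): kept %d, dropped %d",
                mode, max_frac, int(keep.sum()), n_drop)
    if not keep.any():
        raise ValueError("all proteins dropped; relax max_frac")
    return m.subset_proteins(keep)


def impute_missing(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Sample-wise left-censored imputation from a down-shifted Gaussian.

    For each sample s, missing cells become independent draws from
    Normal(mu_s - shift*sigma_s, (width*sigma_s)^2). Observed cells are
    untouched; the returned mask is all-observed. Deterministic given seed.
    """
    if p is None:
        p = ImputeParams()
    if m.mask.all():
        return m.copy()
    rng = np.random.default_rng(p.seed)
    values = m.values.copy()
    for j, sid in enumerate(m.sample_ids):
        obs = m.mask[:, j]
        n_obs = int(obs.sum())
        if n_obs < 3:
            raise ValueError(
                f"sample {sid!r} has only {n_obs} observed values; cannot impute")
        miss = ~obs
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        mu = values[obs, j].mean()
        sigma = values[obs, j].std(ddof=1)
        values[miss, j] = rng.normal(mu - p.shift * sigma, p.width * sigma,
                                     size=n_miss)
    return IntensityMatrix(list(m.protein_ids), list(m.sample_ids), values,
                           np.ones_like(m.mask))


def bait_normalize(m: IntensityMatrix, bait_ids: Sequence[str]) -> IntensityMatrix:
    """Equalize the per-sample mean of the bait rows across samples.

    Per sample, subtract the mean of the bait-row log2 intensities, then add
    back the grand mean of those per-sample means so the output stays on the
    original scale. After normalization the bait-row mean is constant across
    samples.
    """
    idx = []
    for b in bait_ids:
        if b not in m.protein_ids:
            raise ValueError(f"bait {b!r} not in matrix")
        idx.append(m.protein_index(b))
    if not m.mask[idx].all():
        bad = [m.sample_ids[j] for j in np.flatnonzero(~m.mask[idx].all(axis=0))]
        raise ValueError(f"bait rows unobserved in samples: {bad}")
    bait_means = m.values[idx].mean(axis=0)
    shift = bait_means - bait_means.mean()
    out = m.copy()
    out.values = out.values - shift[None, :]
    return out


def median_polish_normalize(
    m: IntensityMatrix,
    d: SampleDesign,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> IntensityMatrix:
    """GIS-anchored median polish of log2 ratios across batches.

    Alternates (a) subtracting, per protein and batch, the batch's GIS-sample
    median log2 ratio to the global GIS central tendency, and (b) subtracting
    the per-sample median, until the largest absolute adjustment falls below
    ``tol`` or ``max_iter`` is reached. The output is relative log2 abundance:
    on convergence the median GIS relative abundance is 0 within tol.

    Batches with no GIS sample fall back to the batch median as a pseudo-GIS
    reference (logged).
    """
    d = d.aligned_to(m)
    if not m.mask.all():
        raise ValueError("median polish requires a complete matrix; impute first")
    X = m.values.copy()
    batches = d.table["batch"].to_numpy()
    is_gis = d.table["is_gis"].to_numpy()

    batch_names = list(pd.unique(batches))
    gis_cols_by_batch: dict[str, np.ndarray] = {}
    for b in batch_names:
        in_b = batches == b
        g = in_b & is_gis
        if g.any():
            gis_cols_by_batch[b] = np.flatnonzero(g)
        else:
            logger.warning("batch %s has no GIS sample; using batch median as "
                           "pseudo-GIS", b)
            gis_cols_by_batch[b] = np.flatnonzero(in_b)

    all_gis = np.concatenate(list(gis_cols_by_batch.values()))
    for _ in range(max_iter):
        # global GIS central tendency per protein
        center = np.median(X[:, all_gis], axis=1)
        ratios = X - center[:, None]
        max_adj = 0.0
        for b in batch_names:
            cols = np.flatnonzero(batches == b)
            adj = np.median(ratios[:, gis_cols_by_batch[b]], axis=1)
            X[:, cols] -= adj[:, None]
            max_adj = max(max_adj, float(np.abs(adj).max(initial=0.0)))
        col_med = np.median(X - np.median(X[:, all_gis], axis=1)[:, None], axis=0)
        X -= col_med[None, :]
        max_adj = max(max_adj, float(np.abs(col_med).max(initial=0.0)))
        if max_adj < tol:
            break
    else:
        logger.warning("median polish did not converge in %d iterations "
                       "(final residual %.3g)", max_iter, max_adj)

    # return relative abundance: subtract the converged GIS central tendency
    X -= np.median(X[:, all_gis], axis=1)[:, None]
    return IntensityMatrix(list(m.protein_ids), list(m.sample_ids), X,
                           np.ones_like(m.mask))


def _design_matrix(d: SampleDesign, variables: Sequence[str],
                   sample_ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Build an OLS design (intercept + variables); categoricals one-hot with
    the first level as reference."""
    t = d.table.loc[list(sample_ids)]
    cols: list[np.ndarray] = [np.ones(len(t))]
    names = ["intercept"]
    for v in variables:
        if v not in t.columns:
            raise ValueError(f"design has no column {v!r}")
        s = t[v]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(v)
        else:
            levels = list(pd.unique(s))
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{v}[{lev}]")
    return np.column_stack(cols), names


def bootstrap_regress(
    m: IntensityMatrix,
    d: SampleDesign,
    spec: RegressSpec,
) -> IntensityMatrix:
    """Remove covariate effects via median-of-bootstraps OLS.

    For b in 1..n_boot, samples are resampled with replacement and OLS of
    abundance on (covariates + protected) is fit for every protein at once;
    the final per-protein coefficient for each variable is the median over
    bootstraps. The returned abundance subtracts only the removed covariates'
    centered contributions; protected variables are retained. GIS samples are
    excluded from fitting and passed through unchanged.
    """
    d = d.aligned_to(m)
    if not m.mask.all():
        raise ValueError("bootstrap regression requires a complete matrix")
    is_gis = d.table["is_gis"].to_numpy()
    fit_cols = np.flatnonzero(~is_gis)
    fit_ids = [m.sample_ids[j] for j in fit_cols]

    variables = list(spec.covariates) + list(spec.protected)
    X, names = _design_matrix(d, variables, fit_ids)
    n_s, n_v = X.shape
    if np.linalg.matrix_rank(X) < n_v:
        raise ValueError("design matrix is rank deficient on the full data")

    Y = m.values[:, fit_cols].T  # samples x proteins

    rng = np.random.default_rng(spec.seed)
    coefs = np.empty((spec.n_boot, n_v, m.n_proteins))
    b = 0
    skipped = 0
    while b < spec.n_boot:
        ok = False
        for _ in range(10):  # bounded redraws for rank-deficient resamples
            idx = rng.integers(0, n_s, size=n_s)
            Xb = X[idx]
            if np.linalg.matrix_rank(Xb) == n_v:
                ok = True
                break
        if not ok:
            skipped += 1
            if skipped > spec.n_boot:
                raise ValueError("could not draw full-rank bootstrap resamples")
            continue
        coefs[b] = np.linalg.lstsq(Xb, Y[idx], rcond=None)[0]
        b += 1
    if skipped:
        logger.warning("skipped %d rank-deficient bootstrap draws", skipped)

    med = np.median(coefs, axis=0)  # n_v x n_proteins

    # subtract removed covariates' centered contributions
    removed_cols = [i for i, nm in enumerate(names)
                    if nm != "intercept" and nm.split("[")[0] in set(spec.covariates)]
    out = m.copy()
    if removed_cols:
        Xc = X[:, removed_cols] - X[:, removed_cols].mean(axis=0, keepdims=True)
        correction = Xc @ med[removed_cols]  # samples x proteins
        out.values[:, fit_cols] -= correction.T
    return out
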