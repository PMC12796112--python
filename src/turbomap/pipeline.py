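"""End-to-end workflow orchestration.

Two workflows, each driven by a single :class:`RunConfig`:

* :func:`run_apms_pipeline` — missingness filter -> Perseus-style imputation
  -> optional bait normalization / bootstrap batch regression -> two-group
  differential enrichment -> volcano table -> optional GO-style enrichment
  of the candidate list.

* :func:`run_cohort_pipeline` — GIS-anchored median-polish normalization ->
  bootstrap covariate regression (age/sex/PMI removed, diagnosis protected)
  -> co-expression module detection, merging, kME -> module-trait
  correlation -> FET grids for marker/interactome/insoluble lists ->
  module composition -> Braak-stage trend tests on top hub proteins.

Stages communicate via on-disk TSV artifacts. Every output starts with a
header line recording the config hash and the seed so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import (GeneSetCollection, IntensityMatrix, SampleDesign,
                   TraitTable, write_intensity_table)
from .coexpression import CoexprConfig, detect_modules, module_trait_correlation
from .dea import two_group_test, volcano_table
from .enrichment import enrich_against_collection
from .integration import (braak_trend, genelist_module_fet, insoluble_mapping,
                          module_composition)
from .preprocess import (ImputeParams, RegressSpec, bait_normalize,
                         bootstrap_regress, filter_by_missingness,
                         impute_missing, median_polish_normalize)

logger = logging.getLogger("turbomap")


@dataclass
class RunConfig:
    out_dir: str | Path = "turbomap_out"
    seed: int = 0
    # preprocessing
    filter_max_frac: float = 0.5
    filter_mode: str = "global"
    impute: ImputeParams | None = None
    bait_ids: list[str] = field(default_factory=list)
    regress: RegressSpec | None = None
    # DEA
    contrast: tuple[str, str] = ("bait", "mock")
    alpha: float = 0.05
    # network
    coexpr: CoexprConfig = field(default_factory=CoexprConfig)
    n_hub_trend: int = 3

    def config_hash(self) -> str:
        def enc(o: Any):
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(x) for x in o]
            if isinstance(o, Path):
                return str(o)
            return o
        fields = {k: v for k, v in vars(self).items() if k != "out_dir"}
        payload = json.dumps({k: enc(v) for k, v in fields.items()},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (f"turbomap v{__version__} | config {cfg.config_hash()} | "
            f"seed {cfg.seed}")


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_manifest(out: Path, cfg: RunConfig, stages: list[str]) -> None:
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_apms_pipeline(
    cfg: RunConfig,
    matrix: IntensityMatrix,
    design: SampleDesign,
    genesets: GeneSetCollection | None = None,
) -> Path:
    """AP-MS differential-interactome workflow. Returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    m = filter_by_missingness(matrix, design, cfg.filter_max_frac,
                              cfg.filter_mode)
    stages.append(f"filter:{m.n_proteins}x{m.n_samples}")

    impute = cfg.impute or ImputeParams(seed=cfg.seed)
    m = impute_missing(m, impute)
    stages.append("impute")

    if cfg.bait_ids:
        m = bait_normalize(m, cfg.bait_ids)
        stages.append("bait_normalize")
    if cfg.regress is not None:
        m = bootstrap_regress(m, design, cfg.regress)
        stages.append("bootstrap_regress")
    write_intensity_table(m, out / "preprocessed.tsv", header_meta=_header(cfg))

    group_a, group_b = cfg.contrast
    t = two_group_test(m, design, group_a, group_b, alpha=cfg.alpha)
    _write_table(t, out / "dea_results.tsv", cfg)
    v = volcano_table(t, p_threshold=cfg.alpha)
    _write_table(v, out / "volcano.tsv", cfg)
    stages.append(f"dea:{int(t['significant'].sum())}_significant")

    if genesets is not None and len(genesets):
        candidates = list(v.index[(v["direction"] == "enriched_in_A")])
        if candidates:
            enr = enrich_against_collection(candidates, m.protein_ids, genesets)
            _write_table(enr, out / "enrichment.tsv", cfg, index=False)
            stages.append("enrichment")

    _write_manifest(out, cfg, stages)
    logger.info("AP-MS pipeline done: %s", "; ".join(stages))
    return out


def run_cohort_pipeline(
    cfg: RunConfig,
    matrix: IntensityMatrix,
    design: SampleDesign,
    traits: TraitTable,
    gene_lists: Mapping[str, list[str]] | None = None,
    insoluble_list: list[str] | None = None,
) -> Path:
    """Cohort network workflow. Returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    m = median_polish_normalize(matrix, design)
    stages.append("median_polish")

    regress = cfg.regress or RegressSpec(covariates=("age", "sex", "pmi"),
                                         protected=("group",),
                                         seed=cfg.seed)
    m = bootstrap_regress(m, design, regress)
    stages.append("bootstrap_regress")
    write_intensity_table(m, out / "normalized.tsv", header_meta=_header(cfg))

    model = detect_modules(m, cfg.coexpr, design=design)
    mods = model.modules()
    stages.append(f"network:{len(mods)}_modules")

    assign = model.module_of.to_frame("module")
    own_kme = [
        model.kme.loc[p, mod] if mod != "M0" and mod in model.kme.columns else np.nan
        for p, mod in model.module_of.items()
    ]
    assign["kme_own"] = own_kme
    _write_table(assign, out / "modules.tsv", cfg)
    _write_table(model.eigengenes, out / "eigengenes.tsv", cfg)
    _write_table(model.kme, out / "kme.tsv", cfg)

    mt = module_trait_correlation(model, traits)
    _write_table(mt, out / "module_trait.tsv", cfg, index=False)
    stages.append("module_trait")

    if gene_lists:
        grid = genelist_module_fet(gene_lists, model)
        _write_table(grid["neg_log10"], out / "module_fet.tsv", cfg)
        stages.append("module_fet")
    if insoluble_list:
        insol = insoluble_mapping(model, insoluble_list)
        _write_table(insol["table"], out / "insoluble_mapping.tsv", cfg,
                     index=False)
        ann = dict(gene_lists or {})
        ann["insoluble"] = insoluble_list
        comp = module_composition(model, ann)
        _write_table(comp, out / "composition.tsv", cfg, index=False)
        stages.append("composition")

    # Braak trend on top hubs of the most trait-correlated module
    if mods and "braak" in traits.trait_names:
        braak = traits.aligned_to(model.sample_ids)["braak"]
        ok = ~braak.isna()
        best = mt.loc[mt["trait"] == "braak"].sort_values("p").iloc[0]["module"] \
            if (mt["trait"] == "braak").any() else mods[0]
        hubs = model.kme.loc[model.members(best), best].nlargest(cfg.n_hub_trend)
        rows = []
        for pid in hubs.index:
            vals = m.values[m.protein_index(pid)][
                [m.sample_index(s) for s in model.sample_ids]]
            res = braak_trend(np.asarray(vals)[ok.to_numpy()],
                              braak[ok].to_numpy())
            rows.append((pid, best, res["kw_H"], res["kw_p"], res["kw_stars"]))
        _write_table(pd.DataFrame(
            rows, columns=["protein", "module", "kw_H", "kw_p", "stars"]),
            out / "braak_trend.tsv", cfg, index=False)
        stages.append("braak_trend")

    _write_manifest(out, cfg, stages)
    logger.info("cohort pipeline done: %s", "; ".join(stages))
    return out
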