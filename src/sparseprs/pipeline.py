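"""End-to-end pipeline: simulate → QC → fit → score → evaluate → h² → report.

Each stage reads its inputs from, and writes its outputs to, a single
artifact directory, so CLI subcommands compose to exactly the same result
as :func:`run_pipeline`. All tables are TSV; every run writes a JSON
sidecar with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate_qc, heritability, phenome_report, prs_fit, score_eval, simulate
from .io import read_plink_bed, read_score_file, read_tsv, write_json, write_score_file, write_tsv

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclasses.dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    trait_name: str = "trait1"
    simulation: simulate.SimulationConfig | None = None
    fit: prs_fit.FitConfig = dataclasses.field(default_factory=prs_fit.FitConfig)
    qc: annotate_qc.QCThresholds = dataclasses.field(
        default_factory=annotate_qc.QCThresholds
    )
    ld_window: int = 50

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # hash the analysis, not its location
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a declarative YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulation", None)
    fit = raw.pop("fit", {})
    qc = raw.pop("qc", {})
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        cfg.simulation = simulate.SimulationConfig(**sim)
    cfg.fit = prs_fit.FitConfig(**fit)
    cfg.qc = annotate_qc.QCThresholds(**qc)
    return cfg


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> None:
    if config.simulation is None:
        raise ValueError("no simulation config; provide input files instead")
    data = simulate.simulate_dataset(config.simulation)
    simulate.write_dataset(data, config.output_dir)


def _load_genotypes(outdir: Path):
    return read_plink_bed(outdir / "genotypes")


def _load_tables(outdir: Path):
    phe = read_tsv(outdir / "phenotype.tsv")
    cov = read_tsv(outdir / "covariates.tsv")
    split = read_tsv(outdir / "split.tsv")
    return phe, cov, split


def _dev_population_rows(phe: pd.DataFrame, split: pd.DataFrame) -> np.ndarray:
    dev_iids = set(split["IID"].astype(str))
    return np.flatnonzero(phe["IID"].astype(str).isin(dev_iids).to_numpy())


def stage_qc(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    G = _load_genotypes(outdir)
    phe, _, split = _load_tables(outdir)
    annotation = read_tsv(outdir / "annotation.tsv")
    dev_rows = _dev_population_rows(phe, split)
    keep, report = annotate_qc.variant_qc(G, config.qc, sample_index=dev_rows)
    write_tsv(report, outdir / "qc_report.tsv")
    kept = annotation[keep.tolist()].copy()
    kept["penalty_factor"] = annotate_qc.assign_penalty_factors(kept)
    write_tsv(kept, outdir / "variants_kept.tsv")
    logger.info("qc: kept %d of %d variants", int(keep.sum()), len(keep))


def stage_fit(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    G = _load_genotypes(outdir)
    phe, cov, split = _load_tables(outdir)
    kept = read_tsv(outdir / "variants_kept.tsv")
    keep_ids = set(kept["id"].astype(str))
    keep_mask = G.variants["id"].astype(str).isin(keep_ids).to_numpy()
    Gk = type(G)(
        X=G.X[:, keep_mask],
        variants=G.variants[keep_mask].reset_index(drop=True),
        samples=G.samples,
    )
    pf = kept["penalty_factor"].to_numpy(dtype=float)

    dev_rows = _dev_population_rows(phe, split)
    iid_to_row = {iid: i for i, iid in enumerate(phe["IID"].astype(str))}
    split_rows = {
        name: np.array(
            [iid_to_row[iid] for iid in split[split["split"] == name]["IID"].astype(str)]
        )
        for name in ("train", "validation", "test")
    }
    y = phe["phenotype"].to_numpy(dtype=float)
    covariates = cov[list(simulate.COVARIATE_COLUMNS)]

    path = prs_fit.basil_fit(
        Gk, covariates, y, pf, config.fit,
        train_idx=split_rows["train"], valid_idx=split_rows["validation"],
    )
    k = prs_fit.select_lambda(path)
    dev_idx = np.sort(np.concatenate([split_rows["train"], split_rows["validation"]]))
    model = prs_fit.refit_final(
        Gk, covariates, y, float(path.lambdas[k]), pf, config.fit, dev_idx,
        variant_meta=Gk.variants,
    )
    write_score_file(model, outdir / "score.tsv")
    log = pd.DataFrame(
        {
            "lambda": path.lambdas,
            "active_count": path.active_counts,
            "validation_metric": path.validation_metric,
            "selected": [i == k for i in range(len(path.lambdas))],
        }
    )
    write_tsv(log, outdir / "path_log.tsv")


def stage_score(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    G = _load_genotypes(outdir)
    phe, _, _ = _load_tables(outdir)
    model = read_score_file(outdir / "score.tsv")
    prs = score_eval.compute_prs(G, model)
    out = pd.DataFrame(
        {
            "FID": phe["FID"],
            "IID": phe["IID"],
            "population": phe["population"],
            "prs": prs,
        }
    )
    write_tsv(out, outdir / "prs.tsv", float_format="%.17g")


def stage_evaluate(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    phe, cov, split = _load_tables(outdir)
    prs = read_tsv(outdir / "prs.tsv")["prs"].to_numpy(dtype=float)
    family = (config.simulation.family if config.simulation else "gaussian")
    y = phe["phenotype"].to_numpy(dtype=float)
    covariates = cov[list(simulate.COVARIATE_COLUMNS)]

    iid_to_row = {iid: i for i, iid in enumerate(phe["IID"].astype(str))}
    dev_idx = np.array(
        [
            iid_to_row[iid]
            for iid in split[split["split"] != "test"]["IID"].astype(str)
        ]
    )
    test_idx = np.array(
        [iid_to_row[iid] for iid in split[split["split"] == "test"]["IID"].astype(str)]
    )
    cov_model = score_eval.fit_covariate_model(covariates, y, family, dev_idx)

    results = []
    pops = phe["population"].astype(str).to_numpy()
    dev_pop = pops[dev_idx[0]]
    for pop in pd.unique(pops):
        rows = test_idx if pop == dev_pop else np.flatnonzero(pops == pop)
        label = "test" if pop == dev_pop else pop
        cov_score = cov_model.score(covariates.iloc[rows])
        results.extend(
            score_eval.evaluate_trait(
                config.trait_name, label, prs[rows], cov_score, y[rows], family
            )
        )
    write_tsv(score_eval.results_to_frame(results), outdir / "evaluation.tsv")


def stage_h2(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    G = _load_genotypes(outdir)
    phe, cov, split = _load_tables(outdir)
    kept = read_tsv(outdir / "variants_kept.tsv")
    keep_mask = G.variants["id"].astype(str).isin(set(kept["id"].astype(str))).to_numpy()
    family = (config.simulation.family if config.simulation else "gaussian")
    y = phe["phenotype"].to_numpy(dtype=float)
    iid_to_row = {iid: i for i, iid in enumerate(phe["IID"].astype(str))}
    dev_idx = np.array([iid_to_row[iid] for iid in split["IID"].astype(str)])

    D = G.dosages(impute_freq=G.allele_frequencies())[np.ix_(dev_idx, np.flatnonzero(keep_mask))]
    covariates = cov[list(simulate.COVARIATE_COLUMNS)].iloc[dev_idx]
    assoc = heritability.gwas_scan(
        D, y[dev_idx], covariates, family, quantile_normalize_pheno=(family == "gaussian")
    )
    write_tsv(
        assoc.to_frame(G.variants["id"][keep_mask].to_numpy()), outdir / "gwas.tsv"
    )
    l = heritability.ld_scores(D, window_size=config.ld_window)
    est = heritability.ldsc_fit(assoc.chi2, l, N=assoc.n, M=D.shape[1])
    write_tsv(
        heritability.heritability_table(
            {config.trait_name: est}, {config.trait_name: family}
        ),
        outdir / "heritability.tsv",
    )


def stage_report(config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    ev = read_tsv(outdir / "evaluation.tsv")
    score = read_tsv(outdir / "score.tsv")
    family = (config.simulation.family if config.simulation else "gaussian")
    results = [
        score_eval.EvaluationResult(
            trait=str(r.trait), population=str(r.population), model_type=str(r.model),
            metric=str(r.metric), value=float(r.value),
            ci_low=float(r.ci_low) if pd.notna(r.ci_low) else np.nan,
            ci_high=float(r.ci_high) if pd.notna(r.ci_high) else np.nan,
            p_value=float(r.p_value) if pd.notna(r.p_value) else np.nan,
        )
        for r in ev.itertuples()
    ]
    summary = phenome_report.build_phenome_table(
        results,
        model_sizes={config.trait_name: len(score)},
        families={config.trait_name: family},
    )
    write_tsv(summary.table, outdir / "phenome_summary.tsv")
    write_json(
        {
            "n_significant": summary.n_significant,
            "spearman": {k: list(v) for k, v in summary.spearman.items()},
            "transfer_slopes": {k: list(v) for k, v in summary.transfer_slopes.items()},
        },
        outdir / "phenome_summary.json",
    )


_STAGES = [
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("fit", stage_fit),
    ("score", stage_score),
    ("evaluate", stage_evaluate),
    ("h2", stage_h2),
    ("report", stage_report),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the artifact directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(
        {"config_hash": config.config_hash(), "seed": config.seed},
        outdir / "run_info.json",
    )
    for name, fn in _STAGES:
        if name == "simulate" and config.simulation is None:
            continue  # inputs supplied externally
        t0 = time.time()
        try:
            fn(config)
        except Exception as exc:  # noqa: BLE001 - label and re-raise
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
    return outdir
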