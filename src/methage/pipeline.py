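"""End-to-end orchestration: counts in, twelve result tables out.

``run_pipeline`` chains preprocess → differential methylation → VMP
screen → entropy → clock → enrichment under a single validated
:class:`PipelineConfig`, logging every filter's in/out counts (the
analysis's audit trail) and writing a manifest with the config hash.
Outputs are pure functions of (inputs, config, seed): a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import (age_acceleration, clock_design_matrix, evaluate_clock,
                    fit_elastic_net, predict_age, rank_sum_test)
from .diffmeth import (call_dmps, classify_consistent, gene_level_dm,
                       weighted_methylation_summary)
from .drift import detect_vmps, entropy_age_model, entropy_per_sample, vmp_frame
from .enrichment import (enrichment_frame, hypergeometric_enrichment,
                         methylated_background)
from .errors import DataError, MethageError, ValidationError
from .io import (read_annotations, read_coverage_file, read_sample_sheet)
from .preprocess import (call_methylated, estimate_conversion_error,
                         filter_by_coverage, normalize_coverage)
from .io import unite
from .types import GeneFeature, MethylationMatrix, SampleRecord, format_site

log = logging.getLogger("methage")

OUTPUT_FILES = (
    "matrix.tsv", "calls.tsv", "dmp.tsv", "genes_dm.tsv", "consistent_sets.tsv",
    "vmp.tsv", "entropy.tsv", "entropy_model.txt", "clock_model.tsv",
    "predictions.tsv", "evaluation.txt", "enrichment.tsv", "run_log.txt",
)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place (study defaults)."""

    sample_sheet: str = ""
    genes: str | None = None
    go_map: str | None = None
    outdir: str = "methage_out"
    lambda_chrom: str = "lambda"
    min_cov: int = 10
    upper_pct: float = 99.0
    call_fdr: float = 0.05
    dmp_q: float = 0.05
    min_delta: float = 0.15
    vmp_alpha: float = 0.05
    enrich_q: float = 0.05
    background_threshold: float = 0.05
    clock_alpha: float = 0.5
    clock_folds: int = 3
    seed: int = 1

    def validate(self) -> None:
        for name in ("call_fdr", "dmp_q", "vmp_alpha", "enrich_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 < self.min_delta < 1.0):
            raise ValidationError(f"min_delta must lie in (0, 1), got {self.min_delta}")
        if not (0.0 <= self.clock_alpha <= 1.0):
            raise ValidationError(f"clock_alpha must lie in [0, 1]")
        if not (0.0 < self.background_threshold < 1.0):
            raise ValidationError("background_threshold must lie in (0, 1)")
        if self.min_cov < 1:
            raise ValidationError(f"min_cov must be >= 1, got {self.min_cov}")
        if not (0.0 < self.upper_pct <= 100.0):
            raise ValidationError(f"upper_pct must lie in (0, 100]")
        if self.clock_folds < 2:
            raise ValidationError("clock_folds must be >= 2")
        if not self.sample_sheet:
            raise ValidationError("sample_sheet path is required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles on everything the run produced."""

    config: PipelineConfig
    samples: list[SampleRecord]
    conversion_rate: float
    matrix: MethylationMatrix          # normalized united matrix (all sites)
    methylated: MethylationMatrix      # restricted to methylated-in-any sites
    dmp_calls: object
    consistent: dict
    vmps: list
    entropies: list
    entropy_model: object
    clock_model: object
    clock_eval: object
    acceleration: np.ndarray
    ranksum: tuple
    gene_dm: pd.DataFrame
    enrichment: pd.DataFrame
    counts: dict


class _RunLog:
    """Collects audit-trail lines and mirrors them to the logger."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        self.lines.append(msg)
        log.info(msg)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def _fail_manifest(outdir: Path, config: PipelineConfig, stage: str) -> None:
    manifest = {
        "complete": False,
        "failed_stage": stage,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; returns handles and writes all outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog()
    stage = "setup"
    try:
        # ---------------- preprocess ----------------
        stage = "preprocess"
        samples = read_sample_sheet(config.sample_sheet)
        runlog.info(f"samples: {len(samples)} libraries from {config.sample_sheet}")
        site_lists, lambda_sites = [], []
        for s in samples:
            if not s.path:
                raise DataError(f"sample {s.sample_id} has no count-file path")
            sites = read_coverage_file(s.path)
            lam = [x for x in sites if x.chrom == config.lambda_chrom]
            gen = [x for x in sites if x.chrom != config.lambda_chrom]
            lambda_sites.extend(lam)
            kept = filter_by_coverage(gen, config.min_cov, config.upper_pct)
            runlog.info(
                f"coverage filter {s.sample_id}: {len(gen)} -> {len(kept)} sites "
                f"(+{len(lam)} lambda)"
            )
            site_lists.append(kept)
        err = estimate_conversion_error(lambda_sites)
        runlog.info(
            f"conversion error: {err.rate:.6f} "
            f"({err.total_meth}/{err.total_coverage} lambda reads)"
        )
        matrix = unite(site_lists, samples, require_all=True)
        runlog.info(f"united matrix: {matrix.n_sites} sites x {matrix.n_samples} samples")
        matrix = normalize_coverage(matrix)
        calls = call_methylated(matrix, err, fdr=config.call_fdr)
        methylated = matrix.subset_sites(calls.methylated_sites())
        runlog.info(
            f"binomial call: {methylated.n_sites}/{matrix.n_sites} sites "
            f"methylated in >= 1 sample (FDR {config.call_fdr})"
        )
        matrix.write_tsv(outdir / "matrix.tsv")
        pd.DataFrame({
            "chrom": [c for c, _ in matrix.sites],
            "pos": [p for _, p in matrix.sites],
            "methylated_in_any": calls.methylated_in_any,
            "n_samples_methylated": calls.methylated.sum(axis=1),
            "min_q": calls.q.min(axis=1),
        }).to_csv(outdir / "calls.tsv", sep="\t", index=False)

        # ---------------- differential methylation ----------------
        stage = "dmp"
        dmp_calls = call_dmps(methylated, q_max=config.dmp_q,
                              min_delta=config.min_delta)
        dmp_calls.frame.to_csv(outdir / "dmp.tsv", sep="\t", index=False)
        n_sig = (dmp_calls.frame["status"] != "ns").sum()
        runlog.info(
            f"dmp: {n_sig} significant site x comparison calls; "
            f"{len(dmp_calls.union_sites)} age-significant CpGs in >= 1 comparison"
        )
        consistent = {}
        cons_rows = []
        for sex in ("F", "M"):
            parts = classify_consistent(dmp_calls, sex)
            consistent[sex] = parts
            for category, sites in parts.items():
                for chrom, pos in sorted(sites):
                    cons_rows.append((sex, category, chrom, pos))
            runlog.info(
                f"consistent {sex}: hyper {len(parts['consistent_hyper'])}, "
                f"hypo {len(parts['consistent_hypo'])}, other {len(parts['other'])}"
            )
        pd.DataFrame(cons_rows, columns=["sex", "category", "chrom", "pos"]).to_csv(
            outdir / "consistent_sets.tsv", sep="\t", index=False
        )
        weighted_methylation_summary(methylated).to_csv(
            outdir / "weighted_methylation.tsv", sep="\t", index=False
        )

        genes: list[GeneFeature] = []
        gomap = {}
        if config.genes and config.go_map:
            genes, gomap = read_annotations(config.genes, config.go_map)
            runlog.info(f"annotation: {len(genes)} genes, {len(gomap)} with GO terms")
        gene_dm = gene_level_dm(dmp_calls, genes, methylated,
                                min_weighted_delta=config.min_delta) if genes else pd.DataFrame()
        gene_dm.to_csv(outdir / "genes_dm.tsv", sep="\t", index=False)
        if len(gene_dm):
            runlog.info(f"gene-level dm: {(gene_dm['status'] == 'dm').sum()} calls")

        # ---------------- drift ----------------
        stage = "vmp"
        vmps = detect_vmps(methylated, alpha=config.vmp_alpha)
        vdf = vmp_frame(vmps)
        vdf.to_csv(outdir / "vmp.tsv", sep="\t", index=False)
        runlog.info(
            f"vmp: {int(vdf['is_vmp'].sum()) if len(vdf) else 0} of {len(vdf)} "
            f"tested sites significant after Holm (alpha {config.vmp_alpha})"
        )

        stage = "entropy"
        if not dmp_calls.union_sites:
            raise DataError("no age-significant CpGs; entropy site set is empty")
        entropies = entropy_per_sample(methylated, dmp_calls.union_sites)
        ent_model = entropy_age_model(entropies, samples)
        by_id = {s.sample_id: s for s in samples}
        pd.DataFrame({
            "sample_id": [e.sample_id for e in entropies],
            "sex": [by_id[e.sample_id].sex for e in entropies],
            "age_days": [by_id[e.sample_id].age_days for e in entropies],
            "entropy": [e.entropy for e in entropies],
            "n_sites": [e.n_sites for e in entropies],
        }).to_csv(outdir / "entropy.tsv", sep="\t", index=False)
        (outdir / "entropy_model.txt").write_text(ent_model.summary() + "\n")
        runlog.info(
            f"entropy over {entropies[0].n_sites} DM CpGs; interaction "
            f"chi2 = {ent_model.interaction_chi2:.3f} (p = {ent_model.interaction_p:.3g})"
        )

        # ---------------- clock ----------------
        stage = "clock"
        ages = np.array([s.age_days for s in samples], dtype=float)
        X = clock_design_matrix(methylated, dmp_calls.union_sites)
        model = fit_elastic_net(
            X, ages, site_keys=dmp_calls.union_sites, mixing=config.clock_alpha,
            cv_folds=config.clock_folds, seed=config.seed,
        )
        predicted = predict_age(model, X)
        evaluation = evaluate_clock(predicted, ages)
        accel = age_acceleration(predicted, ages)
        evaluation.acceleration = accel
        f_idx = [i for i, s in enumerate(samples) if s.sex == "F"]
        m_idx = [i for i, s in enumerate(samples) if s.sex == "M"]
        ranksum = rank_sum_test(accel[f_idx], accel[m_idx])
        runlog.info(
            f"clock: {model.n_selected} CpGs selected (lambda {model.lam:.4g}); "
            f"training rho = {evaluation.spearman_rho:.3f}, "
            f"rmse = {evaluation.rmse_days:.3f} d"
        )
        weights = pd.DataFrame({
            "site": ["(intercept)"] + [format_site(k) for k in model.selected_sites],
            "weight": [model.intercept] + [
                w for w in model.weights if w != 0.0
            ],
        })
        weights.to_csv(outdir / "clock_model.tsv", sep="\t", index=False)
        pd.DataFrame({
            "sample_id": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "age_days": ages.astype(int),
            "epigenetic_age": predicted,
            "cv_predicted_age": model.cv_predictions,
            "acceleration": accel,
        }).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        (outdir / "evaluation.txt").write_text(
            evaluation.summary()
            + f"\nage acceleration by sex (F vs M): W = {ranksum[0]:.1f}, "
            f"p = {ranksum[1]:.4f}\n"
        )

        # ---------------- enrichment ----------------
        stage = "enrichment"
        enr_frames = []
        if genes and gomap:
            meth_bg = methylated_background(methylated, genes,
                                            threshold=config.background_threshold)
            runlog.info(f"methylated background: {len(meth_bg)} genes")

            def genes_with_sites(site_keys) -> set:
                keys = set(site_keys)
                return {
                    g.gene_id for g in genes
                    if any(g.contains(c, p) for c, p in keys)
                }

            vmp_sites = [v.site for v in vmps if v.is_vmp]
            clock_sites = model.selected_sites
            dm_genes = genes_with_sites(dmp_calls.union_sites) & meth_bg

            studies = {
                "vmp_genes": (genes_with_sites(vmp_sites) & meth_bg, meth_bg),
                "clock_genes": (genes_with_sites(clock_sites) & meth_bg, meth_bg),
            }
            for sex in ("F", "M"):
                for cat in ("consistent_hyper", "consistent_hypo"):
                    gset = genes_with_sites(consistent[sex][cat]) & dm_genes
                    studies[f"{sex}_{cat}"] = (gset, dm_genes)
            for name, (study, bg) in studies.items():
                if not study or not bg:
                    runlog.info(f"enrichment {name}: empty study set; skipped")
                    continue
                res = hypergeometric_enrichment(study, bg, gomap, q_max=config.enrich_q)
                enr_frames.append(enrichment_frame(res, analysis=name))
                n_sig = sum(r.q < config.enrich_q for r in res)
                runlog.info(
                    f"enrichment {name}: {len(study)} genes vs {len(bg)}; "
                    f"{n_sig} terms at q < {config.enrich_q}"
                )
        enrichment = (
            pd.concat(enr_frames, ignore_index=True) if enr_frames
            else pd.DataFrame(columns=["analysis", "term", "k", "K", "n", "N", "p", "q"])
        )
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        # ---------------- manifest ----------------
        stage = "manifest"
        counts = {
            "n_samples": len(samples),
            "n_united_sites": matrix.n_sites,
            "n_methylated_sites": methylated.n_sites,
            "n_age_significant_cpgs": len(dmp_calls.union_sites),
            "n_vmps": int(vdf["is_vmp"].sum()) if len(vdf) else 0,
            "n_clock_cpgs": model.n_selected,
        }
        runlog.write(outdir / "run_log.txt")
        manifest = {
            "complete": True,
            "config": asdict(config),
            "config_sha256": config.sha256(),
            "version": __version__,
            "outputs": sorted(OUTPUT_FILES + ("weighted_methylation.tsv",)),
            "counts": counts,
            "conversion_error": err.rate,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except MethageError as exc:
        _fail_manifest(outdir, config, stage)
        raise type(exc)(f"stage {stage}: {exc}") from exc

    return PipelineResult(
        config=config, samples=samples, conversion_rate=err.rate,
        matrix=matrix, methylated=methylated, dmp_calls=dmp_calls,
        consistent=consistent, vmps=vmps, entropies=entropies,
        entropy_model=ent_model, clock_model=model, clock_eval=evaluation,
        acceleration=accel, ranksum=ranksum, gene_dm=gene_dm,
        enrichment=enrichment, counts=counts,
    )
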