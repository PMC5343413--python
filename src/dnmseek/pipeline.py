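"""Pipeline orchestration and the published-cohort reference report.

``run_pipeline`` chains detection -> cohort summary -> enrichment ->
burden/meta -> CNV on configured inputs and writes all reports.

``reference_cohort_report`` recomputes, from the bundled transcription of a
published 24-trio Hirschsprung disease exome cohort's validated DNM table
(src/dnmseek/data/hscr24_dnm_table.tsv) plus the published comparison-cohort
constants, every headline statistic of that study: total and per-class DNM
counts, the fitted Poisson rate and its goodness of fit, LOF rate
comparisons against healthy-trio and unaffected-sibling cohorts, RET
over-representation against the population expected rate, and the RET
diagnostic rate.  It is pure: no network, no external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden_meta, cnv_rules, enrichment_stats, variant_io
from .dnm_detection import (DEFAULT_MOSAIC_BAND, DnmCall, DnmFilterConfig,
                            classify_consequence, detect_dnms, lof_subtype)
from .enrichment_stats import ReferenceCohort
from .variant_io import GeneRateTable, TrioSite, VariantRecord

log = logging.getLogger(__name__)

# published comparison constants for the reference cohort
HEALTHY_TRIOS = ReferenceCohort(label="healthy trios", n_trios=54, n_events=4)
UNAFFECTED_SIBLINGS = ReferenceCohort(label="unaffected siblings",
                                      n_trios=677, n_events=54)
RET_EXPECTED_RATE = 1.33e-4  # expected RET DNMs per trio per generation
REFERENCE_N_TRIOS = 24


def load_reference_dnm_table() -> pd.DataFrame:
    """The bundled DNM table of the published 24-trio HSCR exome cohort."""
    with resources.files("dnmseek.data").joinpath("hscr24_dnm_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"trio": str})


def _parse_maf(cell) -> float | None:
    s = str(cell).strip()
    if s in ("N", "", "nan", "."):
        return None
    return float(s)


def reference_table_to_calls(table: pd.DataFrame | None = None) -> list[DnmCall]:
    """Lift the transcription's rows into classified DnmCall objects.

    Genomic coordinates are not part of the published table; each row gets a
    synthetic locus.  Read-level evidence was consumed upstream of the
    published table (all rows are validated calls), so the genotype
    observations carry the canonical de novo configuration.
    """
    if table is None:
        table = load_reference_dnm_table()
    calls: list[DnmCall] = []
    for i, row in enumerate(table.itertuples(), start=1):
        pop_afs = {}
        for db, col in (("dbSNP137", row.maf_dbsnp), ("ESP6500", row.maf_esp),
                        ("ExAC", row.maf_exac)):
            af = _parse_maf(col)
            if af is not None:
                pop_afs[db] = af
        variant = VariantRecord(
            chrom="1", pos=i * 1000, ref="N", alt="V", gene=row.gene,
            consequence_raw=row.type, pop_afs=pop_afs,
        )
        obs_child = variant_io.GenotypeObservation(genotype=(0, 1), depth=46,
                                                   alt_depth=23, gq=99)
        obs_parent = variant_io.GenotypeObservation(genotype=(0, 0), depth=46,
                                                    alt_depth=0, gq=99)
        site = TrioSite(variant=variant, proband=obs_child, father=obs_parent,
                        mother=obs_parent, trio_id=str(row.trio))
        calls.append(DnmCall(
            site=site, consequence_class=classify_consequence(variant),
            confidence_rank=1, mosaic_flag=bool(row.mosaic),
            passed_filters=True, filter_failures=frozenset(),
        ))
    return calls


def reference_cohort_report() -> dict:
    """Recompute the reference cohort's headline statistics from the table."""
    calls = reference_table_to_calls()
    trio_ids = [str(t) for t in range(1, REFERENCE_N_TRIOS + 1)]
    summary = enrichment_stats.summarize_cohort(calls, trio_ids)
    classes = enrichment_stats.classwise_summary(calls)

    gof_lambda_hat = enrichment_stats.poisson_gof(summary)
    gof_rounded = enrichment_stats.poisson_gof(summary,
                                               lam=summary.lambda_reported)

    lof_trios = enrichment_stats.trios_with_class(calls, "LOF")
    non_ret_lof_trios = {
        c.site.trio_id for c in calls
        if c.consequence_class == "LOF" and c.site.variant.gene != "RET"
    }
    p_healthy = enrichment_stats.cohort_rate_test(
        len(lof_trios), REFERENCE_N_TRIOS, HEALTHY_TRIOS)
    p_sibs = enrichment_stats.cohort_rate_test(
        len(lof_trios), REFERENCE_N_TRIOS, UNAFFECTED_SIBLINGS)
    p_non_ret_healthy = enrichment_stats.cohort_rate_test(
        len(non_ret_lof_trios), REFERENCE_N_TRIOS, HEALTHY_TRIOS)

    ret_calls = [c for c in calls if c.site.variant.gene == "RET"]
    rates = GeneRateTable({"RET": RET_EXPECTED_RATE})
    ret_enrich = enrichment_stats.gene_enrichment_test(
        "RET", len(ret_calls), REFERENCE_N_TRIOS, rates)
    ret_trios = {c.site.trio_id for c in ret_calls}

    genes = sorted({c.site.variant.gene for c in calls})
    mosaic_calls = [c for c in calls if c.mosaic_flag]

    return {
        "n_trios": REFERENCE_N_TRIOS,
        "total_dnms": summary.total,
        "n_genes": len(genes),
        "n_trios_with_dnm": sum(v > 0 for v in summary.per_trio_counts.values()),
        "n_mosaic": len(mosaic_calls),
        "class_counts": {k: classes[k] for k in
                         ("LOF", "missense", "inframe_indel", "synonymous")},
        "lof_subtypes": {k.removeprefix("LOF_"): v for k, v in classes.items()
                         if k.startswith("LOF_")},
        "lambda_hat": summary.lambda_hat,
        "lambda_reported": summary.lambda_reported,
        "ks": {
            "lambda_hat": {"statistic": gof_lambda_hat.ks_statistic,
                           "p": gof_lambda_hat.p_value},
            "lambda_rounded": {"statistic": gof_rounded.ks_statistic,
                               "p": gof_rounded.p_value},
        },
        "lof_trios": len(lof_trios),
        "non_ret_lof_trios": len(non_ret_lof_trios),
        "p_lof_vs_healthy": p_healthy,
        "p_lof_vs_siblings": p_sibs,
        "p_non_ret_lof_vs_healthy": p_non_ret_healthy,
        "ret_dnms": len(ret_calls),
        "ret_rate_per_trio": ret_enrich.rate_per_trio,
        "ret_expected_rate": RET_EXPECTED_RATE,
        "p_ret_enrichment": ret_enrich.p_value,
        "ret_diagnostic_rate": len(ret_trios) / REFERENCE_N_TRIOS,
    }


@dataclass
class PipelineConfig:
    """File-level configuration of a full pipeline run."""

    vcf_paths: dict[str, str]  # trio id -> VCF
    ped_path: str
    out_dir: str
    filter_config: DnmFilterConfig = field(default_factory=DnmFilterConfig)
    cnv_config: cnv_rules.CnvRuleConfig = field(default_factory=cnv_rules.CnvRuleConfig)
    mosaic_band: tuple[float, float] = DEFAULT_MOSAIC_BAND
    gene_rates_path: str | None = None
    annotation_path: str | None = None
    probe_track_path: str | None = None
    burden_studies: list[tuple[str, str]] = field(default_factory=list)  # (dosage, samples)
    reference_cohorts: list[ReferenceCohort] = field(
        default_factory=lambda: [HEALTHY_TRIOS, UNAFFECTED_SIBLINGS])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = DnmFilterConfig(**raw.get("filters", {}))
        cnv = cnv_rules.CnvRuleConfig(**raw.get("cnv", {}))
        refs = [ReferenceCohort(**r) for r in raw.get("reference_cohorts", [])]
        return cls(
            vcf_paths={str(k): v for k, v in raw["vcfs"].items()},
            ped_path=raw["ped"], out_dir=raw.get("out_dir", "dnmseek_out"),
            filter_config=filt, cnv_config=cnv,
            mosaic_band=tuple(raw.get("mosaic_band", DEFAULT_MOSAIC_BAND)),
            gene_rates_path=raw.get("gene_rates"),
            annotation_path=raw.get("annotation"),
            probe_track_path=raw.get("probe_track"),
            burden_studies=[tuple(s) for s in raw.get("burden_studies", [])],
            reference_cohorts=refs or [HEALTHY_TRIOS, UNAFFECTED_SIBLINGS],
            seed=int(raw.get("seed", 0)),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run detection through reporting; returns the report bundle dict.

    Writes to config.out_dir: the per-trio DNM report TSV, a cohort summary
    JSON (rate, goodness of fit, cohort comparisons, per-gene enrichment),
    burden/meta tables when studies are provided, CNV/ROH BED-like calls
    when a probe track is provided, and a run log with config hash and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        pedigrees = {p.family_id: p
                     for p in variant_io.read_pedigree(config.ped_path)}
        annotation = (variant_io.read_annotation_table(config.annotation_path)
                      if config.annotation_path else None)
    except Exception as e:
        raise StageError("inputs", e) from e

    try:
        calls: list[DnmCall] = []
        for trio_id, vcf_path in config.vcf_paths.items():
            ped = pedigrees.get(trio_id)
            if ped is None:
                raise variant_io.VariantIOError(
                    f"trio {trio_id} not present in pedigree file")
            sites = variant_io.read_trio_vcf(vcf_path, ped)
            if annotation is not None:
                sites = variant_io.annotate_sites(sites, annotation)
            calls.extend(detect_dnms(sites, cfg=config.filter_config,
                                     mosaic_band=config.mosaic_band))
        report_df = variant_io.write_dnm_report(calls, out / "dnm_report.tsv")
        bundle["dnm_report"] = report_df
    except StageError:
        raise
    except Exception as e:
        raise StageError("dnm_detection", e) from e

    try:
        summary = enrichment_stats.summarize_cohort(
            calls, list(config.vcf_paths))
        gof = enrichment_stats.poisson_gof(summary) if summary.n_trios >= 2 else None
        lof_trios = enrichment_stats.trios_with_class(calls, "LOF")
        cohort_tests = {
            ref.label: enrichment_stats.cohort_rate_test(
                len(lof_trios), summary.n_trios, ref)
            for ref in config.reference_cohorts
        }
        stats_block = {
            "n_trios": summary.n_trios,
            "total_dnms": summary.total,
            "lambda_hat": summary.lambda_hat,
            "lambda_reported": summary.lambda_reported,
            "class_counts": summary.class_counts,
            "ks_p": gof.p_value if gof else None,
            "lof_trios": len(lof_trios),
            "cohort_tests": cohort_tests,
        }
        if config.gene_rates_path:
            rates = variant_io.read_gene_rates(config.gene_rates_path)
            per_gene = {}
            for gene in sorted({c.site.variant.gene for c in calls
                                if c.site.variant.gene}):
                observed = sum(c.site.variant.gene == gene for c in calls)
                res = enrichment_stats.gene_enrichment_test(
                    gene, observed, summary.n_trios, rates)
                per_gene[gene] = {"observed": observed, "mu": res.mu,
                                  "p": res.p_value}
            stats_block["gene_enrichment"] = per_gene
        bundle["stats"] = stats_block
    except Exception as e:
        raise StageError("enrichment_stats", e) from e

    if config.burden_studies:
        try:
            scans = []
            for dosage_path, samples_path in config.burden_studies:
                matrix = burden_meta.read_genotype_matrix(dosage_path,
                                                          samples_path)
                scans.append(burden_meta.burden_scan(matrix))
            meta = burden_meta.meta_scan(scans)
            meta.to_csv(out / "burden_meta.tsv", sep="\t", index=False)
            bundle["burden_meta"] = meta
        except Exception as e:
            raise StageError("burden_meta", e) from e

    if config.probe_track_path:
        try:
            segments = []
            for track in cnv_rules.read_probe_track(config.probe_track_path):
                segments.extend(cnv_rules.call_cnv_segments(track,
                                                            config.cnv_config))
                segments.extend(cnv_rules.call_roh(track, config.cnv_config))
            seg_df = cnv_rules.write_segments_bed(segments,
                                                  out / "cnv_segments.tsv")
            bundle["cnv_segments"] = seg_df
        except Exception as e:
            raise StageError("cnv_rules", e) from e

    cfg_hash = hashlib.sha256(
        repr((sorted(config.vcf_paths.items()), config.filter_config,
              config.cnv_config, config.mosaic_band, config.seed)).encode()
    ).hexdigest()[:16]
    run_log = {"seed": config.seed, "config_hash": cfg_hash,
               "n_trios": len(config.vcf_paths),
               "stages": sorted(bundle.keys())}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle.get("stats", {})), fh, indent=2)
    bundle["run_log"] = run_log
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
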