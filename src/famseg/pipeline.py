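"""Pipeline orchestration: discovery -> QC -> segregation -> prioritization
-> risk-locus analyses -> power/LOH, with per-stage in/out logging and a
report bundle of TSV/JSON outputs."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from .filtering import FilterConfig, build_panel, filter_discovery, qc_targeted
from .loh import loh_screen, read_loh_inputs
from .pedigree import read_ped
from .power import PowerDesign, power_closed_form, power_mc
from .riskloci import co_occurrence, detection_summary, prs_compare, prs_table, read_risk_loci
from .segregation import PrioritizationCriteria, classify, prioritize
from .variants import CohortModel, read_annotations, read_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: Optional[str] = None
    ped: Optional[str] = None
    ped_meta: Optional[str] = None
    annotations: Optional[str] = None
    risk_loci: Optional[str] = None
    loh_counts: Optional[str] = None
    use_fixture: bool = False
    out_dir: str = "famseg_out"
    seed: int = 0
    prs_permutations: int = 1000
    power_p: float = 0.2
    power_n_families: Optional[int] = None
    power_sims: int = 100_000
    filter: FilterConfig = field(default_factory=FilterConfig)
    criteria: PrioritizationCriteria = field(default_factory=PrioritizationCriteria)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fcfg = FilterConfig(**raw.pop("filter", {}))
        ccfg = PrioritizationCriteria(**raw.pop("criteria", {}))
        cfg = cls(filter=fcfg, criteria=ccfg, **raw)
        return cfg

    def validate_inputs(self) -> None:
        if self.use_fixture:
            return
        for name in ("vcf", "ped", "annotations"):
            path = getattr(self, name)
            if path is None:
                raise FileNotFoundError(f"run config does not set {name!r}")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("ped_meta", "risk_loci", "loh_counts"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")


def load_cohort(cfg: RunConfig):
    """Load the configured cohort; returns (cohort, risk loci)."""
    if cfg.use_fixture:
        from .fixture import build_paper_fixture

        fx = build_paper_fixture()
        return fx.cohort, fx.risk_loci
    peds = read_ped(cfg.ped, sidecar=cfg.ped_meta)
    cohort = read_vcf(cfg.vcf, peds)
    ann = read_annotations(cfg.annotations)
    cohort = cohort.with_annotations(ann.loc[ann.index.intersection(cohort.variants.index)])
    loci = read_risk_loci(cfg.risk_loci) if cfg.risk_loci else []
    return cohort, loci


def run_pipeline(cfg: RunConfig) -> int:
    """Execute the full analysis; returns 0 on success.

    Stage order: discovery filtering, panel QC, per-family segregation,
    prioritization, risk-locus summaries/co-occurrence/PRS, detection power
    and (when read counts are provided) the LOH screen.  Every stage logs
    variants-in/variants-out and all outputs are deterministic given the
    configured seed.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    summary: dict = {"seed": cfg.seed}

    stage = "validate"
    try:
        cfg.validate_inputs()
        os.makedirs(cfg.out_dir, exist_ok=True)
        stage = "load"
        cohort, loci = load_cohort(cfg)
        n_var = len(cohort.variants)
        log.info("load: %d variants, %d samples, %d families",
                 n_var, len(cohort.samples), len(cohort.pedigrees))

        stage = "discover"
        filtered = filter_discovery(cohort, cfg.filter)
        log.info("discover: %d -> %d rare protein-altering variants", n_var, len(filtered))
        summary["n_variants"] = n_var
        summary["n_discovery_filtered"] = len(filtered)

        stage = "qc"
        kept, qc_report = qc_targeted(cohort, cfg.filter)
        qc_report.to_csv(os.path.join(cfg.out_dir, "qc_dropped.tsv"), sep="\t", index=False)
        log.info("qc: %d -> %d variants", n_var, len(kept))
        summary["n_after_qc"] = len(kept)

        stage = "segregate"
        seg_rows = []
        analysed = sorted(
            filtered & kept,
            key=lambda k: (cohort.variants.loc[k, "gene"] or "", k),
        )
        for key in analysed:
            for fam in cohort.pedigrees:
                counts = cohort.family_counts(key, fam)
                if counts["n_affected_carriers"] + counts["n_unaffected_carriers"] == 0:
                    continue
                res = classify(cohort, key, fam)
                seg_rows.append(res.__dict__)
        pd.DataFrame(seg_rows).to_csv(
            os.path.join(cfg.out_dir, "segregation.tsv"), sep="\t", index=False
        )

        stage = "prioritize"
        report = prioritize(cohort, cfg.criteria)
        report.variants.to_csv(os.path.join(cfg.out_dir, "candidates.tsv"), sep="\t", index=False)
        report.genes.to_csv(os.path.join(cfg.out_dir, "candidate_genes.tsv"), sep="\t", index=False)
        summary["candidate_genes"] = report.candidate_genes
        summary["n_candidate_variants"] = len(report.candidate_variants)

        stage = "riskloci"
        if loci:
            det = detection_summary(cohort, loci)
            det.to_csv(os.path.join(cfg.out_dir, "risk_detection.tsv"), sep="\t")
            co = co_occurrence(cohort, report, loci)
            co.to_csv(os.path.join(cfg.out_dir, "co_occurrence.tsv"), sep="\t", index=False)
            prs_table(cohort, loci).to_csv(os.path.join(cfg.out_dir, "prs.tsv"), sep="\t")
            try:
                cmp_ = prs_compare(cohort, loci, n_perm=cfg.prs_permutations, seed=cfg.seed)
                summary["prs_permutation_p"] = cmp_.p_value
                summary["prs_mean_affected"] = cmp_.mean_affected
                summary["prs_mean_unaffected"] = cmp_.mean_unaffected
            except ValueError as exc:
                log.warning("riskloci: PRS comparison skipped (%s)", exc)
            summary["n_cooccurrence_families"] = (
                int(co["family_id"].nunique()) if len(co) else 0
            )

        stage = "power"
        n_fam = cfg.power_n_families or len(cohort.pedigrees)
        summary["power_closed_form"] = power_closed_form(cfg.power_p, n_fam)
        est, ci = power_mc(
            PowerDesign(n_families_sequenced=n_fam, p_carrier_family=cfg.power_p),
            cfg.power_sims, seed=cfg.seed,
        )
        summary["power_mc"] = est
        summary["power_mc_ci"] = list(ci)

        stage = "loh"
        if cfg.loh_counts:
            loh = loh_screen(read_loh_inputs(cfg.loh_counts))
            loh.to_csv(os.path.join(cfg.out_dir, "loh.tsv"), sep="\t", index=False)
            summary["n_loh_flagged"] = int(loh["flagged"].sum())
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        return 1

    with open(os.path.join(cfg.out_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return 0
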