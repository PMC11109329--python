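"""Per-family segregation classification and all-criteria prioritization.

A variant is a candidate when, jointly: it is rare in the Finnish population
(AF < 0.01), it is shared by the genotyped affected members of its carrier
families, affected carriers occur in at least two families (counted at the
variant level or aggregated over a gene's qualifying variants), the allele
was inherited from the founder lineage with tumor history, in-silico
predictors call it damaging, and the gene is expressed in brain and/or
relevant to glioma.  Every enabled criterion must hold; the procedure is
criterion-based, no ranking score is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._gt import CARRIER_CODES, MISSING
from .pedigree import infer_inheritance_side
from .variants import CohortModel, predictor_counts

log = logging.getLogger(__name__)


@dataclass
class SegregationResult:
    family_id: str
    variant: str
    n_affected_genotyped: int
    n_affected_carriers: int
    shared_by_affected: bool
    n_unaffected_genotyped: int
    n_unaffected_carriers: int
    inheritance_side: str   # tumor_side / non_tumor_side / undetermined
    penetrance_class: str   # complete / incomplete / not_assessable


@dataclass
class PrioritizationCriteria:
    af_fin_max: float = 0.01
    min_families: int = 2
    require_shared: bool = True
    require_tumor_side: bool = True
    #: 'every_determinable': no supporting family may show non-tumor-side
    #: inheritance; 'any': at least one family must show tumor-side.
    tumor_side_mode: str = "every_determinable"
    damaging_rule: str = "majority"
    damaging_k: Optional[int] = None
    require_gene_relevance: bool = True
    gene_level_aggregation: bool = True

    def __post_init__(self) -> None:
        if self.min_families < 1:
            raise ValueError("min_families must be >= 1")
        if self.tumor_side_mode not in ("every_determinable", "any"):
            raise ValueError("tumor_side_mode must be every_determinable or any")


@dataclass
class CandidateReport:
    """Prioritized variants and genes with their per-family segregation."""
    variants: pd.DataFrame          # one row per (variant, supporting family)
    genes: pd.DataFrame             # gene, n_families, families, variants
    segregation: dict[tuple[str, str], SegregationResult] = field(default_factory=dict)

    @property
    def candidate_genes(self) -> list[str]:
        return list(self.genes["gene"])

    @property
    def candidate_variants(self) -> list[str]:
        return list(dict.fromkeys(self.variants["variant"])) if len(self.variants) else []


def classify(cohort: CohortModel, variant: str, family_id: str) -> SegregationResult:
    """Segregation of one variant within one family.

    Counts are over genotyped members only.  Penetrance is ``incomplete``
    when at least one unaffected member carries the allele, ``complete``
    when carriers exist and all are affected, ``not_assessable`` with zero
    carriers.  The inheritance side is inferred from the affected carriers'
    transmission paths when any exist.
    """
    counts = cohort.family_counts(variant, family_id)
    chrom = cohort.variants.loc[variant, "chrom"]
    n_carriers = counts["n_affected_carriers"] + counts["n_unaffected_carriers"]
    if n_carriers == 0:
        pen = "not_assessable"
    elif counts["n_unaffected_carriers"] >= 1:
        pen = "incomplete"
    else:
        pen = "complete"
    shared = (
        counts["n_affected_genotyped"] >= 1
        and counts["n_affected_carriers"] == counts["n_affected_genotyped"]
    )
    if counts["n_affected_carriers"] >= 1:
        side = infer_inheritance_side(
            cohort.pedigrees[family_id], cohort.genotypes_for(variant), chrom
        )
    else:
        side = "undetermined"
    return SegregationResult(
        family_id=family_id,
        variant=variant,
        n_affected_genotyped=counts["n_affected_genotyped"],
        n_affected_carriers=counts["n_affected_carriers"],
        shared_by_affected=shared,
        n_unaffected_genotyped=counts["n_unaffected_genotyped"],
        n_unaffected_carriers=counts["n_unaffected_carriers"],
        inheritance_side=side,
        penetrance_class=pen,
    )


def families_supporting(variant: str, cohort: CohortModel) -> int:
    """Number of distinct families with at least one affected carrier."""
    n = 0
    for fam in cohort.pedigrees:
        if cohort.family_counts(variant, fam)["n_affected_carriers"] >= 1:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Vectorised per-family statistics used by prioritize()
# ---------------------------------------------------------------------------

def _family_stats(cohort: CohortModel):
    """Per-family affected/unaffected carrier and genotyped counts.

    Returns (families, dict of (n_variants x n_families) int arrays).
    """
    meta = cohort.sample_meta()
    fams = list(cohort.pedigrees)
    C = cohort.carrier_matrix()
    T = cohort.genotyped_matrix()
    nv = cohort.G.shape[0]
    aff_car = np.zeros((nv, len(fams)), dtype=np.int32)
    aff_gen = np.zeros_like(aff_car)
    una_car = np.zeros_like(aff_car)
    una_gen = np.zeros_like(aff_car)
    sample_pos = {s: i for i, s in enumerate(cohort.samples)}
    for fj, fam in enumerate(fams):
        ids = [s for s in cohort.samples if meta.loc[s, "family_id"] == fam]
        aff_idx = [sample_pos[s] for s in ids if meta.loc[s, "affected"]]
        una_idx = [sample_pos[s] for s in ids if meta.loc[s, "unaffected"]]
        if aff_idx:
            aff_car[:, fj] = C[:, aff_idx].sum(axis=1)
            aff_gen[:, fj] = T[:, aff_idx].sum(axis=1)
        if una_idx:
            una_car[:, fj] = C[:, una_idx].sum(axis=1)
            una_gen[:, fj] = T[:, una_idx].sum(axis=1)
    return fams, {
        "aff_car": aff_car, "aff_gen": aff_gen,
        "una_car": una_car, "una_gen": una_gen,
    }


def _damaging_vector(cohort: CohortModel, criteria: PrioritizationCriteria) -> pd.Series:
    """Per-variant binary damaging call.

    Majority (or configured) consensus over available predictors; variants
    with no available predictor fall back to a ClinVar pathogenic
    classification at review status >= 2 stars (covers frameshifts that
    missense predictors do not score); otherwise not damaging.
    """
    ann = cohort.annotations
    out = pd.Series(False, index=cohort.variants.index)
    if not len(ann):
        return out
    for key, row in ann.iterrows():
        n_dam, n_av = predictor_counts(row)
        if n_av == 0:
            cls = str(row.get("clinvar_class") or "").lower()
            stars = row.get("clinvar_stars")
            out[key] = cls == "pathogenic" and stars is not None and stars >= 2
        elif criteria.damaging_rule == "majority":
            out[key] = 2 * n_dam > n_av
        elif criteria.damaging_rule == "all":
            out[key] = n_dam == n_av
        else:  # at_least_k
            out[key] = n_dam >= (criteria.damaging_k or 1)
    return out


def gene_support(
    gene: str, cohort: CohortModel, criteria: PrioritizationCriteria
) -> tuple[int, set[str]]:
    """Distinct supporting families for a gene and its qualifying variants.

    A variant qualifies when it passes every per-variant criterion except
    the family-count minimum; a family supports the gene when at least one
    qualifying variant of the gene has an affected carrier there, counted
    once per family over the union of qualifying variants.
    """
    report = _qualify(cohort, criteria)
    fams: set[str] = set()
    qual: set[str] = set()
    for key, rec in report.items():
        if cohort.variants.loc[key, "gene"] == gene and rec["qualifies"]:
            qual.add(key)
            fams |= rec["supporting_families"]
    return len(fams), qual


def _qualify(cohort: CohortModel, criteria: PrioritizationCriteria) -> dict[str, dict]:
    """Per-variant criterion evaluation shared by gene_support/prioritize.

    For each variant: the annotation-level criteria (rarity, damaging call,
    gene relevance), the supporting-family set (affected carrier + sharing)
    and the inheritance-side constraint.  ``qualifies`` is the AND of
    everything except the family-count minimum.
    """
    fams, stats = _family_stats(cohort)
    ann = cohort.annotations
    keys = cohort.variants.index
    af = ann["af_fin"].reindex(keys).fillna(0.0) if len(ann) else pd.Series(0.0, index=keys)
    rare = af < criteria.af_fin_max
    damaging = _damaging_vector(cohort, criteria)
    if criteria.require_gene_relevance and len(ann):
        relevant = (
            ann["brain_expressed"].reindex(keys).fillna(False).astype(bool)
            | ann["glioma_relevant"].reindex(keys).fillna(False).astype(bool)
        )
    else:
        relevant = pd.Series(not criteria.require_gene_relevance or not len(ann), index=keys)

    aff_car, aff_gen = stats["aff_car"], stats["aff_gen"]
    shared = (aff_car == aff_gen) & (aff_gen >= 1)
    supports = aff_car >= 1
    if criteria.require_shared:
        supports &= shared

    out: dict[str, dict] = {}
    for vi, key in enumerate(keys):
        fam_idx = np.flatnonzero(supports[vi])
        base_ok = bool(rare[key] and damaging[key] and relevant[key]) and len(fam_idx) > 0
        side_by_family: dict[str, str] = {}
        side_ok = True
        if base_ok and criteria.require_tumor_side:
            chrom = cohort.variants.loc[key, "chrom"]
            genos = cohort.genotypes_for(key)
            for fj in fam_idx:
                fam = fams[fj]
                side = infer_inheritance_side(cohort.pedigrees[fam], genos, chrom)
                side_by_family[fam] = side
            if criteria.tumor_side_mode == "every_determinable":
                side_ok = all(s != "non_tumor_side" for s in side_by_family.values())
            else:
                side_ok = any(s == "tumor_side" for s in side_by_family.values())
        out[key] = {
            "rare": bool(rare[key]),
            "damaging": bool(damaging[key]),
            "relevant": bool(relevant[key]),
            "supporting_families": {fams[fj] for fj in fam_idx} if (base_ok and side_ok) else set(),
            "sides": side_by_family,
            "qualifies": base_ok and side_ok,
        }
    return out


def prioritize(cohort: CohortModel, criteria: PrioritizationCriteria) -> CandidateReport:
    """Apply the full AND of the prioritization criteria over the cohort.

    Family support is satisfied at the variant level or, when
    ``gene_level_aggregation`` is on, over the union of a gene's qualifying
    variants' supporting families.  Output is deterministic, sorted by
    (gene, chrom, pos).
    """
    report = _qualify(cohort, criteria)

    gene_fams: dict[str, set[str]] = {}
    gene_vars: dict[str, set[str]] = {}
    for key, rec in report.items():
        if not rec["qualifies"]:
            continue
        gene = cohort.variants.loc[key, "gene"] or key
        gene_fams.setdefault(gene, set()).update(rec["supporting_families"])
        gene_vars.setdefault(gene, set()).add(key)

    candidate_genes = {
        g for g, f in gene_fams.items() if len(f) >= criteria.min_families
    }
    candidate_keys = []
    for key, rec in report.items():
        if not rec["qualifies"]:
            continue
        gene = cohort.variants.loc[key, "gene"] or key
        variant_level = len(rec["supporting_families"]) >= criteria.min_families
        gene_level = criteria.gene_level_aggregation and gene in candidate_genes
        if variant_level or gene_level:
            candidate_keys.append(key)

    def _order(key: str):
        v = cohort.variants.loc[key]
        return (str(v["gene"] or ""), str(v["chrom"]), int(v["pos"]))

    candidate_keys.sort(key=_order)

    seg: dict[tuple[str, str], SegregationResult] = {}
    var_rows = []
    for key in candidate_keys:
        v = cohort.variants.loc[key]
        ann = cohort.annotations.loc[key] if key in cohort.annotations.index else None
        for fam in sorted(report[key]["supporting_families"]):
            res = classify(cohort, key, fam)
            seg[(key, fam)] = res
            n_dam, n_av = predictor_counts(ann) if ann is not None else (0, 0)
            var_rows.append(
                {
                    "variant": key,
                    "gene": v["gene"],
                    "hgvs_c": v["hgvs_c"],
                    "hgvs_p": v["hgvs_p"],
                    "family_id": fam,
                    "n_affected_carriers": res.n_affected_carriers,
                    "n_unaffected_carriers": res.n_unaffected_carriers,
                    "shared_by_affected": res.shared_by_affected,
                    "inheritance_side": res.inheritance_side,
                    "penetrance_class": res.penetrance_class,
                    "af_fin": float(ann["af_fin"]) if ann is not None else np.nan,
                    "damaging_n": n_dam,
                    "damaging_total": n_av,
                    "cadd_phred": float(ann["cadd_phred"]) if ann is not None else np.nan,
                }
            )
    gene_rows = [
        {
            "gene": g,
            "n_families": len(gene_fams[g]),
            "families": ",".join(sorted(gene_fams[g])),
            "variants": ",".join(sorted(gene_vars[g])),
        }
        for g in sorted(candidate_genes)
    ]
    variants_df = pd.DataFrame(
        var_rows,
        columns=[
            "variant", "gene", "hgvs_c", "hgvs_p", "family_id",
            "n_affected_carriers", "n_unaffected_carriers", "shared_by_affected",
            "inheritance_side", "penetrance_class", "af_fin",
            "damaging_n", "damaging_total", "cadd_phred",
        ],
    )
    genes_df = pd.DataFrame(gene_rows, columns=["gene", "n_families", "families", "variants"])
    log.info("prioritize: %d candidate variants in %d genes",
             len(candidate_keys), len(candidate_genes))
    return CandidateReport(variants=variants_df, genes=genes_df, segregation=seg)
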