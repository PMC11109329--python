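"""Known risk-locus summaries, co-occurrence with rare candidates, and
polygenic risk scores with a permutation comparison of affected vs
unaffected relatives.

The polygenic risk score is the standard log-additive form: the sum over
loci of the risk-allele dosage times ln(OR).  Because family members are
related, the default permutation scheme shuffles affection labels within
families, preserving each family's label counts exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._gt import CARRIER_CODES, DOSAGE, HEMI_ALT, HEMI_REF, HET, HOM_ALT, MISSING
from .segregation import CandidateReport
from .variants import CohortModel

log = logging.getLogger(__name__)


@dataclass
class RiskLocus:
    variant: str          # variant key chrom:pos:ref:alt
    risk_allele: str
    odds_ratio: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.odds_ratio) and self.odds_ratio > 0):
            raise ValueError(f"odds ratio must be finite and > 0, got {self.odds_ratio}")


@dataclass
class PRSResult:
    scores: pd.DataFrame          # individual, family, affected, score, n_loci_genotyped
    mean_affected: float
    mean_unaffected: float
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int
    scheme: str


def read_risk_loci(path) -> list[RiskLocus]:
    """Read a risk-locus TSV: chrom, pos, ref, alt, risk_allele, odds_ratio, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    loci = []
    for row in df.itertuples(index=False):
        key = f"{row.chrom}:{int(row.pos)}:{row.ref}:{row.alt}"
        loci.append(
            RiskLocus(
                variant=key,
                risk_allele=row.risk_allele,
                odds_ratio=float(row.odds_ratio),
                source=getattr(row, "source", "") or "",
            )
        )
    return loci


def write_risk_loci(loci: Sequence[RiskLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\trisk_allele\todds_ratio\tsource\n")
        for l in loci:
            chrom, pos, ref, alt = l.variant.split(":")
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{l.risk_allele}\t{l.odds_ratio}\t{l.source}\n")


def _risk_dosage(code: int, risk_is_alt: bool) -> int:
    if code == MISSING:
        return 0
    d = DOSAGE[code]
    if risk_is_alt:
        return d
    ploidy = 1 if code in (HEMI_REF, HEMI_ALT) else 2
    return ploidy - d


def detection_summary(cohort: CohortModel, loci: Sequence[RiskLocus]) -> pd.DataFrame:
    """Per-locus detection summary over the cohort.

    Reports, per risk variant: the number of affected carriers and the
    distinct families they belong to, whether the variant was seen in any
    affected individual, whether it was seen only in unaffected members,
    and zygosity tallies among affected carriers (het/hom/hemi).
    """
    meta = cohort.sample_meta()
    rows = []
    for locus in loci:
        if locus.variant not in cohort.variants.index:
            rows.append(
                {
                    "variant": locus.variant, "n_affected_carriers": 0,
                    "n_families_affected": 0, "detected_in_affected": False,
                    "unaffected_only": False, "n_het_affected": 0,
                    "n_hom_affected": 0, "n_hemi_affected": 0,
                    "n_unaffected_carriers": 0,
                }
            )
            continue
        risk_is_alt = locus.variant.split(":")[3] == locus.risk_allele
        genos = cohort.genotypes_for(locus.variant)
        aff_fams: set[str] = set()
        n_aff = n_het = n_hom = n_hemi = n_una = 0
        for iid, code in genos.items():
            if code == MISSING or _risk_dosage(code, risk_is_alt) == 0:
                continue
            if meta.loc[iid, "affected"]:
                n_aff += 1
                aff_fams.add(meta.loc[iid, "family_id"])
                if code in (HEMI_ALT, HEMI_REF):
                    n_hemi += 1
                elif _risk_dosage(code, risk_is_alt) == 2:
                    n_hom += 1
                else:
                    n_het += 1
            elif meta.loc[iid, "unaffected"]:
                n_una += 1
        rows.append(
            {
                "variant": locus.variant,
                "n_affected_carriers": n_aff,
                "n_families_affected": len(aff_fams),
                "detected_in_affected": n_aff > 0,
                "unaffected_only": n_aff == 0 and n_una > 0,
                "n_het_affected": n_het,
                "n_hom_affected": n_hom,
                "n_hemi_affected": n_hemi,
                "n_unaffected_carriers": n_una,
            }
        )
    return pd.DataFrame(rows).set_index("variant")


def co_occurrence(
    cohort: CohortModel, candidates: CandidateReport, loci: Sequence[RiskLocus]
) -> pd.DataFrame:
    """Families where an affected member carries both a rare candidate variant
    and a risk allele (in the same individual)."""
    meta = cohort.sample_meta()
    cand_keys = candidates.candidate_variants
    rows = []
    for locus in loci:
        if locus.variant not in cohort.variants.index:
            continue
        risk_is_alt = locus.variant.split(":")[3] == locus.risk_allele
        genos = cohort.genotypes_for(locus.variant)
        for fam, ped in cohort.pedigrees.items():
            hits: set[str] = set()
            genes: set[str] = set()
            for ind in ped:
                iid = ind.individual_id
                if not ind.affected or iid not in genos:
                    continue
                if _risk_dosage(genos[iid], risk_is_alt) == 0:
                    continue
                for key in cand_keys:
                    if cohort.genotype_code(key, iid) in CARRIER_CODES:
                        hits.add(iid)
                        genes.add(str(cohort.variants.loc[key, "gene"]))
            if hits:
                rows.append(
                    {
                        "family_id": fam,
                        "risk_variant": locus.variant,
                        "candidate_genes": ",".join(sorted(genes)),
                        "individuals": ",".join(sorted(hits)),
                    }
                )
    return pd.DataFrame(rows, columns=["family_id", "risk_variant", "candidate_genes", "individuals"])


# ---------------------------------------------------------------------------
# Polygenic risk scores
# ---------------------------------------------------------------------------

def prs(individual_id: str, cohort: CohortModel, loci: Sequence[RiskLocus]) -> float:
    """Log-additive polygenic risk score for one individual.

    score = sum over loci of dosage(risk allele) * ln(OR); autosomal dosage
    in {0,1,2}, hemizygous male X dosage in {0,1} (one copy, no doubling).
    Missing genotypes contribute 0.  Raises when no locus is genotyped.
    """
    score, n_geno = _prs_one(individual_id, cohort, loci)
    if n_geno == 0:
        raise ValueError(f"{individual_id!r}: no risk locus genotyped")
    return score


def _prs_one(individual_id: str, cohort: CohortModel, loci: Sequence[RiskLocus]) -> tuple[float, int]:
    score = 0.0
    n_geno = 0
    for locus in loci:
        if locus.variant not in cohort.variants.index:
            continue
        code = cohort.genotype_code(locus.variant, individual_id)
        if code == MISSING:
            continue
        n_geno += 1
        risk_is_alt = locus.variant.split(":")[3] == locus.risk_allele
        score += _risk_dosage(code, risk_is_alt) * math.log(locus.odds_ratio)
    return score, n_geno


def prs_table(cohort: CohortModel, loci: Sequence[RiskLocus]) -> pd.DataFrame:
    """Per-individual PRS with completeness; ungenotyped individuals get NaN."""
    meta = cohort.sample_meta()
    rows = []
    for iid in cohort.samples:
        score, n_geno = _prs_one(iid, cohort, loci)
        rows.append(
            {
                "individual_id": iid,
                "family_id": meta.loc[iid, "family_id"],
                "affected": bool(meta.loc[iid, "affected"]),
                "unaffected": bool(meta.loc[iid, "unaffected"]),
                "score": score if n_geno else np.nan,
                "n_loci_genotyped": n_geno,
            }
        )
    return pd.DataFrame(rows).set_index("individual_id")


def permutation_test(
    scores: np.ndarray,
    affected: np.ndarray,
    families: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "within_family",
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of group mean scores.

    The statistic is mean(affected) - mean(unaffected); the null is built by
    permuting affection labels, either within each family (default, which
    preserves per-family label counts exactly and respects relatedness) or
    pooled across the cohort.  p = (1 + #|perm| >= |obs|) / (n_perm + 1).
    """
    scores = np.asarray(scores, dtype=float)
    affected = np.asarray(affected, dtype=bool)
    if affected.all() or (~affected).all():
        raise ValueError("need at least one affected and one unaffected score")
    obs = scores[affected].mean() - scores[~affected].mean()
    rng = np.random.default_rng(seed)
    n = scores.size

    perm_labels = np.empty((n_perm, n), dtype=bool)
    if scheme == "within_family":
        families = np.asarray(families)
        for fam in pd.unique(families):
            idx = np.flatnonzero(families == fam)
            keys = rng.random((n_perm, idx.size))
            order = np.argsort(keys, axis=1)
            perm_labels[:, idx] = affected[idx][order]
    elif scheme == "pooled":
        keys = rng.random((n_perm, n))
        order = np.argsort(keys, axis=1)
        perm_labels = affected[order]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    n_aff = perm_labels.sum(axis=1)
    n_una = n - n_aff
    # degenerate permutations cannot arise: label counts are preserved
    sum_aff = perm_labels @ scores
    total = scores.sum()
    diffs = sum_aff / n_aff - (total - sum_aff) / n_una
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= abs(obs) - 1e-12)) / (n_perm + 1.0)
    return float(obs), float(p)


def prs_compare(
    cohort: CohortModel,
    loci: Sequence[RiskLocus],
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "within_family",
    exclude: Iterable[str] = (),
) -> PRSResult:
    """Permutation comparison of PRS between affected and unaffected members.

    ``exclude`` drops loci by variant key or rsid (e.g. the strong CCDC26
    locus rs55705857) before scoring.  Individuals with unknown affection or
    with no genotyped locus are left out of the comparison.  Deterministic
    under a fixed seed.
    """
    excl = set(exclude)
    rsid_of = cohort.variants["rsid"].to_dict()
    used = [
        l for l in loci
        if l.variant not in excl and str(rsid_of.get(l.variant, "")) not in excl
    ]
    table = prs_table(cohort, used)
    table = table[(table["affected"] | table["unaffected"]) & table["score"].notna()]
    if not len(table) or table["affected"].all() or (~table["affected"]).all():
        raise ValueError("degenerate groups: need scored affected and unaffected members")
    obs, p = permutation_test(
        table["score"].to_numpy(),
        table["affected"].to_numpy(),
        table["family_id"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
    )
    return PRSResult(
        scores=table,
        mean_affected=float(table.loc[table["affected"], "score"].mean()),
        mean_unaffected=float(table.loc[~table["affected"], "score"].mean()),
        observed_diff=obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        scheme=scheme,
    )
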