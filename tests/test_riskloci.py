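"""Risk-locus summaries, co-occurrence, and PRS permutation machinery."""

import math

import numpy as np
import pytest

from famseg import (
    PrioritizationCriteria,
    RiskLocus,
    co_occurrence,
    detection_summary,
    permutation_test,
    prioritize,
    prs,
    prs_compare,
    prs_table,
    read_risk_loci,
    write_risk_loci,
)
from famseg._gt import CARRIER_CODES, HOM_REF, MISSING

from conftest import clone_with_genotypes

RS557 = "8:130645692:A:G"


def _rs557_locus(fx):
    return [l for l in fx.risk_loci if l.variant == RS557]


def test_risk_locus_validation():
    with pytest.raises(ValueError, match="odds ratio"):
        RiskLocus(variant="1:1:A:G", risk_allele="G", odds_ratio=0.0)


def test_risk_loci_tsv_roundtrip(tmp_path, fx):
    path = tmp_path / "risk.tsv"
    write_risk_loci(fx.risk_loci, path)
    back = read_risk_loci(path)
    assert [(l.variant, l.risk_allele, l.odds_ratio) for l in back] == [
        (l.variant, l.risk_allele, l.odds_ratio) for l in fx.risk_loci
    ]


# ---------------------------------------------------------------------------
# detection summary
# ---------------------------------------------------------------------------

def test_detection_summary_ccdc26(cohort, fx):
    det = detection_summary(cohort, _rs557_locus(fx)).loc[RS557]
    assert det["n_affected_carriers"] == 8
    assert det["n_families_affected"] == 6
    assert det["n_het_affected"] == 7
    assert det["n_hom_affected"] == 1
    assert det["detected_in_affected"]
    assert not det["unaffected_only"]


def test_detection_summary_absent_variant(cohort):
    det = detection_summary(
        cohort, [RiskLocus(variant="1:999:A:G", risk_allele="G", odds_ratio=1.5)]
    ).loc["1:999:A:G"]
    assert det["n_affected_carriers"] == 0
    assert not det["detected_in_affected"]


def test_detection_summary_unaffected_only(cohort, fx):
    # strip the affected carriers of rs55705857, leaving only unaffected ones
    G = cohort.G.copy()
    vi = cohort.variant_index(RS557)
    meta = cohort.sample_meta()
    for iid in cohort.samples:
        if meta.loc[iid, "affected"]:
            G[vi, cohort.sample_index(iid)] = HOM_REF
    det = detection_summary(clone_with_genotypes(cohort, G), _rs557_locus(fx)).loc[RS557]
    assert det["unaffected_only"]
    assert det["n_unaffected_carriers"] > 0


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def test_cooccurrence_reference_families(cohort, fx):
    rep = prioritize(cohort, PrioritizationCriteria())
    co = co_occurrence(cohort, rep, _rs557_locus(fx))
    assert set(co["family_id"]) == {"B", "C", "Q"}
    genes = dict(zip(co["family_id"], co["candidate_genes"]))
    assert genes == {"B": "MYO10", "C": "GALNT13", "Q": "AR"}


def test_cooccurrence_empty_without_risk_carriers(cohort, fx):
    rep = prioritize(cohort, PrioritizationCriteria())
    G = cohort.G.copy()
    G[cohort.variant_index(RS557), :] = HOM_REF
    co = co_occurrence(clone_with_genotypes(cohort, G), rep, _rs557_locus(fx))
    assert len(co) == 0


def test_cooccurrence_matches_exhaustive_scan(cohort, fx):
    rep = prioritize(cohort, PrioritizationCriteria())
    co = co_occurrence(cohort, rep, fx.risk_loci)
    # naive pairwise scan over (locus, family, affected individual)
    expect = set()
    for locus in fx.risk_loci:
        for fam, ped in cohort.pedigrees.items():
            for ind in ped:
                if not ind.affected:
                    continue
                g = cohort.genotype_code(locus.variant, ind.individual_id)
                if g not in CARRIER_CODES:
                    continue
                if any(
                    cohort.genotype_code(k, ind.individual_id) in CARRIER_CODES
                    for k in rep.candidate_variants
                ):
                    expect.add((fam, locus.variant))
    assert set(zip(co["family_id"], co["risk_variant"])) == expect


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------

def test_prs_single_locus_arithmetic(cohort, fx):
    # one heterozygous copy of a risk allele with OR 6.3 -> ln(6.3)
    assert prs("C_II-1", cohort, _rs557_locus(fx)) == pytest.approx(math.log(6.3))
    # homozygote counts two copies
    assert prs("Q_II-1", cohort, _rs557_locus(fx)) == pytest.approx(2 * math.log(6.3))
    # no risk alleles -> zero
    assert prs("A_II-1", cohort, _rs557_locus(fx)) == 0.0


def test_prs_two_locus_sum(cohort, fx):
    # P_II-1 is heterozygous for both TP53 risk loci (OR 1.4 and 1.3)
    assert prs("P_II-1", cohort, fx.risk_loci) == pytest.approx(
        math.log(1.4) + math.log(1.3)
    )
    # ln(6.3) is about 1.8405 for a single heterozygous high-OR copy
    assert math.log(6.3) == pytest.approx(1.8405, abs=5e-5)


def test_prs_additive_over_disjoint_locus_sets(cohort, fx):
    half = len(fx.risk_loci) // 2
    l1, l2 = fx.risk_loci[:half], fx.risk_loci[half:]
    for iid in ("Q_II-1", "P_II-1", "B_II-2", "A_I-1"):
        assert prs(iid, cohort, fx.risk_loci) == pytest.approx(
            prs(iid, cohort, l1) + prs(iid, cohort, l2)
        )


def test_prs_requires_genotyped_locus(cohort, fx):
    with pytest.raises(ValueError, match="no risk locus genotyped"):
        prs("J_I-2", cohort, fx.risk_loci)  # unsampled relative


def test_prs_table_completeness(cohort, fx):
    table = prs_table(cohort, fx.risk_loci)
    assert table.loc["J_I-2", "n_loci_genotyped"] == 0
    assert np.isnan(table.loc["J_I-2", "score"])
    assert table.loc["Q_II-1", "n_loci_genotyped"] == len(fx.risk_loci)


# ---------------------------------------------------------------------------
# permutation comparison
# ---------------------------------------------------------------------------

def test_prs_compare_deterministic_per_seed(cohort, fx):
    a = prs_compare(cohort, fx.risk_loci, n_perm=300, seed=9)
    b = prs_compare(cohort, fx.risk_loci, n_perm=300, seed=9)
    c = prs_compare(cohort, fx.risk_loci, n_perm=300, seed=10)
    assert a.p_value == b.p_value
    assert a.observed_diff == b.observed_diff == c.observed_diff
    assert 1.0 / 301 <= a.p_value <= 1.0


def test_prs_compare_extreme_separation():
    rng = np.random.default_rng(0)
    n = 60
    families = np.repeat(np.arange(10), 6)
    affected = np.tile([True, True, False, False, False, False], 10)
    scores = rng.normal(size=n) + np.where(affected, 50.0, 0.0)
    _, p = permutation_test(scores, affected, families, n_perm=400, seed=4)
    assert p == pytest.approx(1.0 / 401)


def test_within_family_scheme_preserves_family_label_counts():
    # scores indicate membership of one family: every within-family
    # permutation then reproduces the observed statistic exactly
    families = np.repeat(np.arange(5), 4)
    affected = np.tile([True, False, True, False], 5)
    affected[families == 2] = [True, True, True, False]
    scores = (families == 2).astype(float)
    obs, p = permutation_test(scores, affected, families, n_perm=200, seed=1,
                              scheme="within_family")
    assert p == 1.0
    # pooled permutation moves labels across families and breaks the tie
    _, p_pooled = permutation_test(scores, affected, families, n_perm=200,
                                   seed=1, scheme="pooled")
    assert p_pooled < 1.0


def test_prs_compare_exclusion_list(cohort, fx):
    res = prs_compare(cohort, fx.risk_loci, n_perm=300, seed=2,
                      exclude=["rs55705857"])
    full = prs_compare(cohort, fx.risk_loci, n_perm=300, seed=2)
    assert abs(res.observed_diff) < abs(full.observed_diff)


def test_prs_compare_degenerate_groups(cohort, fx):
    only_affected = {
        iid for iid in cohort.samples if cohort.individual(iid).affected
    }
    G = cohort.G.copy()
    for iid in cohort.samples:
        if iid not in only_affected:
            G[:, cohort.sample_index(iid)] = MISSING
    with pytest.raises(ValueError, match="degenerate"):
        prs_compare(clone_with_genotypes(cohort, G), fx.risk_loci, n_perm=50, seed=0)
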