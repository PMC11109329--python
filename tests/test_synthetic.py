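"""Synthetic-cohort generator: gene-drop fidelity, ascertainment, planting,
annotation structure and file round-trips."""

import numpy as np
import pytest
from scipy import stats

import famseg
from famseg import SimConfig, mendelian_violations, read_cohort, simulate_cohort, write_cohort
from famseg._gt import CARRIER_CODES, HEMI_ALT, HEMI_REF, HET, HOM_REF, MISSING


def test_config_validation():
    with pytest.raises(ValueError, match="penetrance"):
        SimConfig(penetrance=0.1, sporadic_rate=0.5)
    with pytest.raises(ValueError, match="outside"):
        SimConfig(missingness=1.5)
    with pytest.raises(ValueError, match="risk locus"):
        SimConfig(risk_loci=[(0.5, -1.0)])
    with pytest.raises(ValueError, match="causal_families"):
        simulate_cohort(SimConfig(n_families=2, causal_families=[0, 5]))


def test_reproducible_under_seed():
    a, _ = simulate_cohort(SimConfig(n_families=3, n_background=100, seed=42))
    b, _ = simulate_cohort(SimConfig(n_families=3, n_background=100, seed=42))
    assert (a.G == b.G).all()
    assert list(a.samples) == list(b.samples)
    assert a.annotations.equals(b.annotations)


def test_gene_drop_transmission_rate():
    """Offspring of het x hom-ref matings carry the allele at rate 1/2
    (allele frequency 1/4), checked with a binomial test over >= 1e4
    transmission events pooled across background loci."""
    cohort, _ = simulate_cohort(
        SimConfig(n_families=10, n_background=4000, missingness=0.0, seed=17)
    )
    carried = total = 0
    for fam, ped in cohort.pedigrees.items():
        for ind in ped:
            if ind.is_founder:
                continue
            fi = cohort.sample_index(ind.father_id)
            mi = cohort.sample_index(ind.mother_id)
            ci = cohort.sample_index(ind.individual_id)
            gf, gm, gc = cohort.G[:, fi], cohort.G[:, mi], cohort.G[:, ci]
            mask = ((gf == HET) & (gm == HOM_REF)) | ((gf == HOM_REF) & (gm == HET))
            total += int(mask.sum())
            carried += int(((gc == HET) | (gc == 2))[mask].sum())
    assert total >= 10_000
    assert stats.binomtest(carried, total, 0.5).pvalue > 1e-3


def test_affection_independent_of_carriage_when_penetrances_equal():
    """With f1 = f0 the carrier status is independent of affection
    (chi-square over several hundred carrier families)."""
    n_fam = 250
    cfg = SimConfig(
        n_families=n_fam,
        n_causal_variants=n_fam,
        causal_families=list(range(n_fam)),
        penetrance=0.35,
        sporadic_rate=0.35,
        n_background=0,
        risk_loci=[],
        missingness=0.0,
        seed=8,
    )
    cohort, truth = simulate_cohort(cfg)
    carriers = set()
    for ids in truth["carriers"].values():
        carriers.update(ids)
    table = np.zeros((2, 2))
    for ped in cohort.pedigrees.values():
        for ind in ped:
            table[int(ind.individual_id in carriers), int(ind.affected)] += 1
    chi2 = stats.chi2_contingency(table)
    assert chi2.pvalue > 1e-3


def test_multiplex_ascertainment():
    cohort, _ = simulate_cohort(SimConfig(n_families=10, n_background=10, seed=3))
    for ped in cohort.pedigrees.values():
        assert sum(ind.affected for ind in ped) >= 2


def test_x_linked_causal_has_no_male_het():
    cfg = SimConfig(n_families=6, causal_chrom="X", n_background=50, seed=5)
    cohort, truth = simulate_cohort(cfg)
    for key in truth["causal_variants"]:
        vi = cohort.variant_index(key)
        for iid in cohort.samples:
            ind = cohort.individual(iid)
            code = int(cohort.G[vi, cohort.sample_index(iid)])
            if ind.sex == "male" and code != MISSING:
                assert code in (HEMI_REF, HEMI_ALT)


def test_causal_allele_only_in_planted_families():
    cohort, truth = simulate_cohort(SimConfig(n_families=8, n_background=20, seed=9))
    for key, fam in truth["carrier_families"].items():
        vi = cohort.variant_index(key)
        for iid in cohort.samples:
            code = int(cohort.G[vi, cohort.sample_index(iid)])
            if code in CARRIER_CODES:
                assert cohort.individual(iid).family_id == fam
        planted = truth["planted_founders"][key]
        assert cohort.individual(planted).side_label == "tumor_side"


def test_simulated_cohorts_mendelian_clean_without_errors():
    cohort, _ = simulate_cohort(
        SimConfig(n_families=5, n_background=400, missingness=0.0,
                  genotype_error_rate=0.0, seed=13)
    )
    for key in cohort.variants.index:
        chrom = cohort.variants.loc[key, "chrom"]
        genos = cohort.genotypes_for(key)
        for ped in cohort.pedigrees.values():
            assert mendelian_violations(ped, genos, chrom) == []


def test_genotype_errors_produce_violations():
    cohort, _ = simulate_cohort(
        SimConfig(n_families=5, n_background=400, missingness=0.0,
                  genotype_error_rate=0.05, seed=13)
    )
    total = 0
    for key in cohort.variants.index[:200]:
        chrom = cohort.variants.loc[key, "chrom"]
        genos = cohort.genotypes_for(key)
        for ped in cohort.pedigrees.values():
            total += len(mendelian_violations(ped, genos, chrom))
    assert total > 0


def test_annotations_mark_causal_variants_damaging_and_relevant():
    cohort, truth = simulate_cohort(SimConfig(n_families=4, n_background=500, seed=21))
    ann = cohort.annotations
    for key in truth["causal_variants"]:
        assert ann.loc[key, "af_fin"] < 0.01
        assert bool(ann.loc[key, "glioma_relevant"])
        from famseg.variants import predictor_counts

        n_dam, n_av = predictor_counts(ann.loc[key])
        assert n_dam == n_av == 8
    assert (ann["af_fin"] <= 0.5 + 1e-9).all()


# ---------------------------------------------------------------------------
# serialisation round-trips
# ---------------------------------------------------------------------------

def _assert_cohorts_equal(a, b):
    assert set(a.variants.index) == set(b.variants.index)
    for key in a.variants.index:
        assert a.genotypes_for(key) == b.genotypes_for(key), key
    assert set(a.pedigrees) == set(b.pedigrees)
    for fam in a.pedigrees:
        for ind in a.pedigrees[fam]:
            got = b.pedigrees[fam][ind.individual_id]
            assert (got.father_id, got.mother_id, got.sex, got.affection,
                    got.sampled, got.side_label) == (
                ind.father_id, ind.mother_id, ind.sex, ind.affection,
                ind.sampled, ind.side_label,
            )
    for key in a.annotations.index:
        ra, rb = a.annotations.loc[key], b.annotations.loc[key]
        assert float(ra["af_fin"]) == pytest.approx(float(rb["af_fin"]))
        for col in ("pred_sift", "pred_metalr", "brain_expressed", "glioma_relevant"):
            assert ra[col] == rb[col]


def test_reference_cohort_roundtrip(tmp_path, fx):
    write_cohort(fx.cohort, tmp_path / "out", risk_loci=fx.risk_loci)
    back = read_cohort(tmp_path / "out")
    _assert_cohorts_equal(fx.cohort, back)


def test_large_simulated_cohort_roundtrip(tmp_path):
    cohort, _ = simulate_cohort(SimConfig(n_families=4, n_background=10_000, seed=2))
    write_cohort(cohort, tmp_path / "sim")
    back = read_cohort(tmp_path / "sim")
    assert len(back.variants) == len(cohort.variants)
    assert (back.G == cohort.G[
        [cohort.variant_index(k) for k in back.variants.index]
    ]).all()


def test_empty_cohort_roundtrip(tmp_path):
    from famseg import CohortModel
    from famseg.pedigree import Individual, Pedigree

    ped = Pedigree(family_id="Z")
    ped.members["z1"] = Individual("z1", "Z")
    empty = CohortModel(pedigrees={"Z": ped}, samples=[])
    write_cohort(empty, tmp_path / "empty")
    back = read_cohort(tmp_path / "empty")
    assert len(back.variants) == 0
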