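"""Pedigree structure, PED I/O, Mendelian checks and inheritance-side logic."""

import numpy as np
import pytest

import famseg
from famseg import (
    PedigreeError,
    Pedigree,
    Individual,
    founders,
    infer_inheritance_side,
    mendelian_violations,
    read_ped,
    side_of,
    write_ped,
)
from famseg._gt import HEMI_ALT, HEMI_REF, HET, HOM_ALT, HOM_REF, MISSING

from _oracles import oracle_inheritance_side


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

PED_A = """\
A I-1 0 0 1 1
A I-2 0 0 2 1
A II-1 I-1 I-2 2 2
A II-2 I-1 I-2 2 2
A II-3 I-1 I-2 2 1
"""


def test_read_ped_nuclear_family(tmp_path):
    p = tmp_path / "a.ped"
    p.write_text(PED_A)
    fams = read_ped(p)
    assert set(fams) == {"A"}
    ped = fams["A"]
    assert len(ped) == 5
    assert sum(ind.affected for ind in ped) == 2
    assert {f.individual_id for f in founders(ped)} == {"I-1", "I-2"}


def test_read_ped_sidecar_roundtrip(tmp_path, cohort):
    ped_path, meta_path = tmp_path / "c.ped", tmp_path / "c.meta.tsv"
    write_ped(cohort.pedigrees, ped_path, sidecar=meta_path)
    back = read_ped(ped_path, sidecar=meta_path)
    assert set(back) == set(cohort.pedigrees)
    for fam, ped in cohort.pedigrees.items():
        for ind in ped:
            got = back[fam][ind.individual_id]
            assert (got.sex, got.affection, got.sampled, got.side_label) == (
                ind.sex, ind.affection, ind.sampled, ind.side_label
            )
            if ind.diagnosis:
                assert got.diagnosis.histology == ind.diagnosis.histology
                assert got.diagnosis.age_band == ind.diagnosis.age_band


@pytest.mark.parametrize(
    "line,match",
    [
        ("A X X 0 1 1", "own father"),
        ("A X Y 0 1 1", "dangling"),
    ],
)
def test_read_ped_structural_errors(tmp_path, line, match):
    p = tmp_path / "bad.ped"
    p.write_text(line + "\n")
    with pytest.raises(PedigreeError, match=match):
        read_ped(p)


def test_read_ped_sex_role_conflict(tmp_path):
    p = tmp_path / "bad.ped"
    p.write_text("A P 0 0 2 1\nA C P 0 1 1\n")  # female listed as father
    with pytest.raises(PedigreeError, match="father"):
        read_ped(p)


def test_read_ped_empty_file(tmp_path):
    p = tmp_path / "empty.ped"
    p.write_text("")
    assert read_ped(p) == {}


def test_cycle_detection():
    ped = Pedigree(family_id="Z")
    ped.members["a"] = Individual("a", "Z", father_id="b", sex="female")
    ped.members["b"] = Individual("b", "Z", father_id="a", sex="male")
    # a is b's father and b is a's father: cyclic and a sex-role conflict
    with pytest.raises(PedigreeError):
        ped.validate()


# ---------------------------------------------------------------------------
# founders and sides
# ---------------------------------------------------------------------------

def test_founders_include_married_in_spouse(cohort):
    got = {f.individual_id for f in founders(cohort.pedigrees["B"])}
    # graph-traversal oracle: members unreachable from any parent edge
    g = cohort.pedigrees["B"].graph()
    expect = {n for n in g if g.in_degree(n) == 0}
    assert got == expect == {"B_I-1", "B_I-2", "B_II-1"}


def test_founders_singleton():
    ped = Pedigree(family_id="S")
    ped.members["only"] = Individual("only", "S")
    assert [f.individual_id for f in founders(ped)] == ["only"]


def test_side_of(cohort):
    a = cohort.pedigrees["A"]
    assert side_of(a, "A_I-1") == "tumor_side"
    assert side_of(a, "A_I-2") == "non_tumor_side"  # married-in spouse
    assert side_of(a, "A_II-1") == "mixed"  # one founder from each side


def test_side_of_unlabeled_founders():
    ped = Pedigree(family_id="U")
    ped.members["f"] = Individual("f", "U", sex="male")
    ped.members["m"] = Individual("m", "U", sex="female")
    ped.members["c"] = Individual("c", "U", father_id="f", mother_id="m")
    assert side_of(ped, "c") == "undetermined"


def test_side_of_swaps_under_relabeling(cohort):
    import copy

    for fam in ("A", "B", "Q"):
        ped = copy.deepcopy(cohort.pedigrees[fam])
        before = {i.individual_id: side_of(ped, i.individual_id) for i in ped}
        for ind in ped:
            if ind.side_label == "tumor_side":
                ind.side_label = "married_in"
            elif ind.side_label == "married_in":
                ind.side_label = "tumor_side"
        swap = {"tumor_side": "non_tumor_side", "non_tumor_side": "tumor_side"}
        for iid, side in before.items():
            assert side_of(ped, iid) == swap.get(side, side)


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

def test_de_novo_pattern_is_violation(cohort):
    ped = cohort.pedigrees["A"]
    genos = {"A_I-1": HOM_REF, "A_I-2": HOM_REF, "A_II-1": HET}
    v = mendelian_violations(ped, genos, "2")
    assert len(v) == 1 and v[0]["child"] == "A_II-1"


def test_x_linked_carrier_family_consistent(cohort):
    # mother het carrier, father hemizygous reference, son hemizygous carrier
    ped = cohort.pedigrees["Q"]
    genos = cohort.genotypes_for("X:66937326:G:T")
    assert mendelian_violations(ped, genos, "X") == []


def test_male_heterozygous_on_x_is_violation(cohort):
    ped = cohort.pedigrees["Q"]
    genos = {"Q_I-1": HEMI_REF, "Q_I-2": HET, "Q_II-1": HET}  # male II-1 het
    v = mendelian_violations(ped, genos, "X")
    assert any("heterozygous male" in r["reason"] for r in v)


def test_missing_parent_genotype_skips_trio(cohort):
    ped = cohort.pedigrees["A"]
    genos = {"A_I-1": HOM_REF, "A_II-1": HOM_ALT}  # mother missing
    assert mendelian_violations(ped, genos, "2") == []


def test_fixture_fully_mendelian(cohort):
    total = 0
    for key in cohort.variants.index:
        chrom = cohort.variants.loc[key, "chrom"]
        genos = cohort.genotypes_for(key)
        for ped in cohort.pedigrees.values():
            total += len(mendelian_violations(ped, genos, chrom))
    assert total == 0


# ---------------------------------------------------------------------------
# inheritance-side inference
# ---------------------------------------------------------------------------

def test_obligate_carrier_mother_gives_tumor_side(cohort):
    # genotyped wild-type father, affected carrier child, unsampled
    # tumor-side mother: the mother is the obligate transmitter
    side = infer_inheritance_side(
        cohort.pedigrees["J"], cohort.genotypes_for("5:16680150:A:G"), "5"
    )
    assert side == "tumor_side"


def test_married_in_carrier_parent_gives_non_tumor_side(cohort):
    side = infer_inheritance_side(
        cohort.pedigrees["O"], cohort.genotypes_for("17:7579472:G:A"), "17"
    )
    assert side == "non_tumor_side"


def test_x_hemizygous_male_receives_from_mother(cohort):
    side = infer_inheritance_side(
        cohort.pedigrees["Q"], cohort.genotypes_for("X:66937326:G:T"), "X"
    )
    assert side == "tumor_side"


def test_three_generation_trace_to_founder(cohort):
    # Family B: the grandchild's carrier parent is itself traced onward to
    # the carrier grandmother on the tumor-history side
    side = infer_inheritance_side(
        cohort.pedigrees["B"], cohort.genotypes_for("5:16680150:A:G"), "5"
    )
    assert side == "tumor_side"


def test_unsampled_unlabeled_parents_undetermined():
    ped = Pedigree(family_id="U")
    ped.members["f"] = Individual("f", "U", sex="male", sampled=False)
    ped.members["m"] = Individual("m", "U", sex="female", sampled=False)
    ped.members["c"] = Individual(
        "c", "U", father_id="f", mother_id="m", affection="brain_tumor"
    )
    assert infer_inheritance_side(ped, {"c": HET}, "2") == "undetermined"


def test_no_affected_carrier_raises(cohort):
    with pytest.raises(ValueError, match="no affected carrier"):
        infer_inheritance_side(cohort.pedigrees["A"], {"A_II-3": HET}, "2")


def _masked_cases(n_cohorts=8, mask_rate=0.3):
    """Small simulated families with random genotype masking, as
    (pedigree, genotypes, chrom) cases that satisfy the precondition."""
    rng = np.random.default_rng(2024)
    cases = []
    for s in range(n_cohorts):
        cfg = famseg.SimConfig(
            n_families=4, sibship_min=2, sibship_max=3, n_background=30,
            missingness=0.0, seed=300 + s,
        )
        c, _ = famseg.simulate_cohort(cfg)
        for key in c.variants.index[:40]:
            chrom = c.variants.loc[key, "chrom"]
            base = c.genotypes_for(key)
            for fam, ped in c.pedigrees.items():
                genos = {
                    i: (MISSING if rng.random() < mask_rate else g)
                    for i, g in base.items()
                    if i in ped
                }
                has_aff_carrier = any(
                    ped[i].affected and g in (HET, HOM_ALT, HEMI_ALT)
                    for i, g in genos.items()
                )
                if has_aff_carrier and len(ped) <= 8:
                    cases.append((ped, genos, chrom))
    return cases


def test_side_inference_matches_enumeration_oracle(cohort):
    """The recursive trace equals brute-force enumeration of all genotype
    assignments to ungenotyped members (pedigrees of <= 8 members)."""
    cases = _masked_cases()
    assert len(cases) > 100
    for ped, genos, chrom in cases:
        assert infer_inheritance_side(ped, genos, chrom) == oracle_inheritance_side(
            ped, genos, chrom
        ), (ped.family_id, genos, chrom)
    # plus the documented families at full observation
    for fam, key in [("A", "2:155099285:C:T"), ("B", "5:16680150:A:G"),
                     ("J", "5:16680150:A:G"), ("O", "17:7579472:G:A"),
                     ("Q", "X:66937326:G:T")]:
        ped = cohort.pedigrees[fam]
        genos = {i: g for i, g in cohort.genotypes_for(key).items() if i in ped}
        chrom = cohort.variants.loc[key, "chrom"]
        assert infer_inheritance_side(ped, genos, chrom) == oracle_inheritance_side(
            ped, genos, chrom
        )
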