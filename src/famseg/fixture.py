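"""Curated reference cohort of twelve Finnish multiplex brain-tumor families.

This deterministic fixture encodes the published genotype observations of a
familial glioma cohort: rare candidate variants in GALNT13 (R185C, L405Q),
MYO10 (N1483S, A504V) and AR (R727L) with their per-family segregation; the
CCDC26 risk SNP rs55705857 (eight affected carriers in six families, seven
heterozygous and one homozygous); the CHEK2 c.1100delC frameshift that was
not inherited from the tumor side; rare benign TP53-region variants; and a
15-locus glioma GWAS panel for risk-score analyses.

Only genotypes that are individually documented are encoded; everything
else defaults to homozygous reference for sampled members (hemizygous
reference for males on chrX) and missing for unsampled relatives.
Coordinates printed alongside the source observations (the five candidate
variants, rs55705857 chr8:130645692, CHEK2 chr22:29091856, TP53 rs78378222
chr17:7571752) are used verbatim; remaining TP53-region positions, the
indel allele spelling and the unnamed GWAS-panel coordinates/frequencies
are synthetic placeholders.  The family-level allocation of the four
rs55705857 affected carriers not individually described is fixed as E:2 and
L:2 heterozygotes, which satisfies the documented totals; Mendelian
consistency then forces one unaffected carrier parent in each of families
C, I, E and L (encoded as the generation-I tumor-side/married-in founders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gt import HEMI_ALT, HEMI_REF, HET, HOM_ALT, HOM_REF, MISSING
from .pedigree import Diagnosis, Individual, Pedigree
from .riskloci import RiskLocus
from .variants import (
    ANNOTATION_COLUMNS,
    CohortModel,
    PRED_COLS,
    PREDICTORS,
    VARIANT_COLUMNS,
    variant_key,
)

# family, iid, father, mother, sex, affected?, histology, grade, age_band,
# sampled, side_label   (A=astrocytoma, O=oligodendroglioma, PA=pilocytic
# astrocytoma, GBM=glioblastoma; age bands in years at diagnosis)
_MEMBERS = [
    ("A", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("A", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("A", "II-1", "I-1", "I-2", "female", "A", "PA", "I", "20-24", True, "none"),
    ("A", "II-2", "I-1", "I-2", "female", "A", "A", "II", "35-39", True, "none"),
    ("A", "II-3", "I-1", "I-2", "female", "U", None, None, None, True, "none"),

    ("B", "I-1", None, None, "female", "U", None, None, None, True, "tumor_side"),
    ("B", "I-2", None, None, "male", "U", None, None, None, True, "married_in"),
    ("B", "II-1", None, None, "male", "U", None, None, None, True, "married_in"),
    ("B", "II-2", "I-2", "I-1", "female", "A", "O", "II", "35-39", True, "none"),
    ("B", "II-3", "I-2", "I-1", "male", "U", None, None, None, True, "none"),
    ("B", "III-1", "II-1", "II-2", "male", "A", "PA", "I", "0-4", True, "none"),

    ("C", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("C", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("C", "II-1", "I-1", "I-2", "male", "A", "A", "II", "30-34", True, "none"),
    ("C", "II-2", "I-1", "I-2", "female", "A", "PA", "I", "5-10", True, "none"),

    ("F", "I-1", None, None, "male", "U", None, None, None, True, "married_in"),
    ("F", "I-2", None, None, "female", "U", None, None, None, False, "tumor_side"),
    ("F", "II-1", "I-1", "I-2", "female", "A", "A", "II", "30-34", True, "none"),

    ("J", "I-1", None, None, "male", "U", None, None, None, True, "married_in"),
    ("J", "I-2", None, None, "female", "U", None, None, None, False, "tumor_side"),
    ("J", "II-1", "I-1", "I-2", "male", "A", "GBM", "IV", "45-49", True, "none"),
    ("J", "II-2", "I-1", "I-2", "female", "U", None, None, None, True, "none"),

    ("O", "I-1", None, None, "male", "U", None, None, None, True, "married_in"),
    ("O", "I-2", None, None, "female", "U", None, None, None, True, "tumor_side"),
    ("O", "II-1", "I-1", "I-2", "female", "A", "PA", "I", None, True, "none"),
    ("O", "II-2", "I-1", "I-2", "male", "U", None, None, None, True, "none"),

    ("Q", "I-1", None, None, "male", "U", None, None, None, True, "married_in"),
    ("Q", "I-2", None, None, "female", "U", None, None, None, True, "tumor_side"),
    ("Q", "II-1", "I-1", "I-2", "male", "A", "A", "II", "20-24", True, "none"),

    ("I", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("I", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("I", "II-1", "I-1", "I-2", "female", "A", "O", "II", "30-34", True, "none"),
    ("I", "II-2", "I-1", "I-2", "male", "U", None, None, None, True, "none"),

    ("E", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("E", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("E", "II-1", "I-1", "I-2", "male", "A", "PA", "I", None, True, "none"),
    ("E", "II-2", "I-1", "I-2", "female", "A", "PA", "I", None, True, "none"),

    ("L", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("L", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("L", "II-1", "I-1", "I-2", "male", "A", "PA", "I", None, True, "none"),
    ("L", "II-2", "I-1", "I-2", "female", "A", "A", "II", None, True, "none"),

    ("P", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("P", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("P", "II-1", "I-1", "I-2", "female", "A", "O", "II", "10-14", True, "none"),
    ("P", "II-2", "I-1", "I-2", "male", "A", "ganglioglioma", "I", "30-34", True, "none"),
    ("P", "II-3", "I-1", "I-2", "female", "U", None, None, None, True, "none"),
    ("P", "II-4", "I-1", "I-2", "male", "U", None, None, None, True, "none"),

    ("N", "I-1", None, None, "male", "U", None, None, None, True, "tumor_side"),
    ("N", "I-2", None, None, "female", "U", None, None, None, True, "married_in"),
    ("N", "II-1", "I-1", "I-2", "male", "A", "glioma", None, None, True, "none"),
    ("N", "II-2", "I-1", "I-2", "female", "U", None, None, None, True, "none"),
]


def _preds(damaging=(), unavailable=()):
    out = {}
    for name, col in zip(PREDICTORS, PRED_COLS):
        if name in unavailable:
            out[col] = "unavailable"
        elif name in damaging or damaging == "all":
            out[col] = "damaging"
        else:
            out[col] = "tolerated"
    return out


_NO_PRED = _preds(unavailable=PREDICTORS)

# (chrom,pos,ref,alt,rsid,gene,hgvs_c,hgvs_p,consequence,source), annotation
_VARIANTS: list[tuple[tuple, dict]] = [
    (
        ("2", 155099285, "C", "T", None, "GALNT13", "c.553C>T", "p.R185C",
         "missense", "wes_candidate"),
        dict(af_fin=8.0e-5, af_nfe=7.7e-6, af_global=1.8e-5, **_preds("all"),
             cadd_phred=31.0, gerp_rs=5.6, phylop100=1.1, siphy=15.1,
             domain="glycosyltransferase substrate-binding site",
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("2", 155252560, "T", "A", None, "GALNT13", "c.1214T>A", "p.L405Q",
         "missense", "wes_candidate"),
        dict(af_fin=4.6e-5, af_nfe=0.0, af_global=4.0e-6, **_preds("all"),
             cadd_phred=27.7, gerp_rs=5.0, phylop100=7.9, siphy=13.9,
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("5", 16680150, "A", "G", None, "MYO10", "c.4448A>G", "p.N1483S",
         "missense", "wes_candidate"),
        dict(af_fin=9.3e-5, af_nfe=0.0, af_global=8.0e-6,
             **_preds(damaging=("PolyPhen", "MutationTaster", "MutationAssessor",
                                "FATHMM_MKL", "MetaSVM", "MetaLR"),
                      unavailable=("LRT",)),
             cadd_phred=23.0, gerp_rs=4.2, phylop100=1.7, siphy=12.8,
             domain="PH2", ctcf_site=True,
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("5", 16762730, "C", "T", None, "MYO10", "c.1511C>T", "p.A504V",
         "missense", "wes_candidate"),
        dict(af_fin=1.6e-3, af_nfe=8.3e-5, af_global=2.0e-4,
             **_preds(damaging=("SIFT", "PolyPhen", "MutationTaster",
                                "MutationAssessor", "FATHMM_MKL", "MetaSVM",
                                "MetaLR"),
                      unavailable=("LRT",)),
             cadd_phred=29.3, gerp_rs=5.6, phylop100=9.6, siphy=19.7,
             domain="myosin motor",
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("X", 66937326, "G", "T", None, "AR", "c.2180G>T", "p.R727L",
         "missense", "wes_candidate"),
        dict(af_fin=8.4e-3, af_nfe=3.1e-4, af_global=9.6e-4,
             **_preds(damaging=("SIFT", "PolyPhen", "LRT", "MutationTaster",
                                "FATHMM_MKL", "MetaSVM", "MetaLR"),
                      unavailable=("MutationAssessor",)),
             cadd_phred=29.7, gerp_rs=4.9, phylop100=9.9, siphy=14.5,
             domain="ligand-binding domain",
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("8", 130645692, "A", "G", "rs55705857", "CCDC26", None, None,
         "intronic", "literature"),
        dict(af_fin=0.09, af_nfe=0.05, af_global=0.04, **_NO_PRED,
             glioma_relevant=True),
    ),
    (
        # frameshift single-base deletion; allele spelling is a placeholder
        ("22", 29091856, "GC", "G", "rs555607708", "CHEK2", "c.1100delC", None,
         "frameshift", "literature"),
        dict(af_fin=0.009, af_nfe=0.002, af_global=0.002, **_NO_PRED,
             cadd_phred=24.0, clinvar_class="pathogenic", clinvar_stars=2,
             glioma_relevant=True),
    ),
    # TP53-region variants (positions below are synthetic placements inside
    # the gene; the rare trio is in complete LD and predicted benign)
    (
        ("17", 7579472, "G", "A", None, "TP53", "c.108G>A", "p.Pro36=",
         "synonymous", "tp53_region"),
        dict(af_fin=0.004, af_nfe=0.001, af_global=0.001, **_NO_PRED,
             cadd_phred=3.0, clinvar_class="benign", clinvar_stars=2,
             brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("17", 7578500, "T", "C", None, "TP53", "c.376-86T>C", None,
         "intronic", "tp53_region"),
        dict(af_fin=0.003, af_nfe=0.001, af_global=0.001, **_NO_PRED,
             cadd_phred=1.2, brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("17", 7576800, "T", "C", None, "TP53", "c.993+12T>C", None,
         "intronic", "tp53_region"),
        dict(af_fin=0.004, af_nfe=0.001, af_global=0.001, **_NO_PRED,
             cadd_phred=0.8, brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("17", 7571752, "A", "C", "rs78378222", "TP53", "c.*1175A>C", None,
         "utr3", "tp53_region"),
        dict(af_fin=0.02, af_nfe=0.01, af_global=0.01, **_NO_PRED,
             cadd_phred=10.0, brain_expressed=True, glioma_relevant=True),
    ),
    (
        ("17", 7578531, "G", "A", "rs_tp53_lead", "TP53", "c.376-117G>A", None,
         "intronic", "tp53_region"),
        dict(af_fin=0.03, af_nfe=0.02, af_global=0.02, **_NO_PRED,
             cadd_phred=2.0, brain_expressed=True, glioma_relevant=True),
    ),
]

# twelve further common GWAS loci completing the 15-variant risk panel;
# coordinates/frequencies are synthetic placeholders on the documented
# ranges (Finnish frequency 0.10-0.80, OR 1.2-1.5)
_GWAS_EXTRA = [
    ("5", 1286516, "A", "C", "rs2736100", "TERT", 0.41, 1.3),
    ("7", 55192256, "G", "A", "rs723527", "EGFR", 0.46, 1.25),
    ("7", 55075850, "A", "G", "rs11979158", "EGFR", 0.15, 1.2),
    ("9", 22068652, "A", "G", "rs4977756", "CDKN2B-AS1", 0.38, 1.3),
    ("11", 118477367, "G", "A", "rs498872", "PHLDB1", 0.33, 1.2),
    ("20", 62309839, "G", "A", "rs6010620", "RTEL1", 0.23, 1.4),
    ("3", 169514585, "A", "G", "rs1920116", "TERC", 0.70, 1.3),
    ("16", 50124399, "C", "T", "rs3751667", "HEATR3", 0.28, 1.2),
    ("11", 82398088, "T", "C", "rs_fam181b", "FAM181B", 0.51, 1.2),
    ("9", 22003367, "T", "C", "rs1063192", "CDKN2A", 0.44, 1.25),
    ("11", 113930306, "A", "G", "rs648044", "ZBTB16", 0.57, 1.2),
    ("1", 243863382, "G", "C", "rs12076373", "AKT3", 0.80, 1.3),
]

for chrom, pos, ref, alt, rsid, gene, af, _or in _GWAS_EXTRA:
    _VARIANTS.append(
        (
            (chrom, pos, ref, alt, rsid, gene, None, None, "intronic", "literature"),
            dict(af_fin=af, af_nfe=af, af_global=af, **_NO_PRED,
                 glioma_relevant=True),
        )
    )

# documented non-reference genotypes: variant key -> {(family, iid): code}
_GENO: dict[str, dict[tuple[str, str], int]] = {
    "2:155099285:C:T": {  # GALNT13 R185C, Family A
        ("A", "I-1"): HET, ("A", "II-1"): HET, ("A", "II-2"): HET,
    },
    "2:155252560:T:A": {  # GALNT13 L405Q, Family C
        ("C", "I-1"): HET, ("C", "II-1"): HET, ("C", "II-2"): HET,
    },
    "5:16680150:A:G": {  # MYO10 N1483S, Families B and J
        ("B", "I-1"): HET, ("B", "II-2"): HET, ("B", "II-3"): HET,
        ("B", "III-1"): HET, ("J", "II-1"): HET, ("J", "II-2"): HET,
    },
    "5:16762730:C:T": {  # MYO10 A504V, Families F and O
        ("F", "II-1"): HET, ("O", "I-1"): HET, ("O", "II-2"): HET,
    },
    "X:66937326:G:T": {  # AR R727L, Families A and Q
        ("A", "I-1"): HEMI_ALT, ("A", "II-1"): HET, ("A", "II-2"): HET,
        ("A", "II-3"): HET, ("Q", "I-2"): HET, ("Q", "II-1"): HEMI_ALT,
    },
    "8:130645692:A:G": {  # CCDC26 rs55705857
        ("B", "I-2"): HET, ("B", "II-2"): HET,
        ("C", "I-1"): HET, ("C", "II-1"): HET,
        ("Q", "I-1"): HET, ("Q", "I-2"): HET, ("Q", "II-1"): HOM_ALT,
        ("I", "I-1"): HET, ("I", "II-1"): HET,
        ("E", "I-1"): HET, ("E", "II-1"): HET, ("E", "II-2"): HET,
        ("L", "I-1"): HET, ("L", "II-1"): HET, ("L", "II-2"): HET,
    },
    "22:29091856:GC:G": {  # CHEK2 c.1100delC, Family I (married-in side)
        ("I", "I-2"): HET, ("I", "II-1"): HET, ("I", "II-2"): HET,
    },
    "17:7579472:G:A": {("O", "I-1"): HET, ("O", "II-1"): HET},
    "17:7578500:T:C": {("O", "I-1"): HET, ("O", "II-1"): HET},
    "17:7576800:T:C": {("O", "I-1"): HET, ("O", "II-1"): HET},
    "17:7571752:A:C": {
        ("P", "I-1"): HET, ("P", "II-1"): HET, ("P", "II-2"): HET,
        ("P", "II-3"): HET, ("P", "II-4"): HET,
        ("N", "I-2"): HET, ("N", "II-2"): HET,
    },
    "17:7578531:G:A": {
        ("P", "I-1"): HET, ("P", "II-1"): HET, ("P", "II-2"): HET,
        ("P", "II-3"): HET,
        ("N", "I-2"): HET, ("N", "II-2"): HET,
    },
}

#: odds ratios of the risk panel (rs55705857 at the oligodendroglioma OR)
_RISK_OR = {"8:130645692:A:G": 6.3, "17:7571752:A:C": 1.4, "17:7578531:G:A": 1.3}
for chrom, pos, ref, alt, _rsid, _gene, _af, _or in _GWAS_EXTRA:
    _RISK_OR[f"{chrom}:{pos}:{ref}:{alt}"] = _or


@dataclass
class FixtureCohort:
    """Reference cohort + its risk-locus panel and panel provenance."""
    cohort: CohortModel
    risk_loci: list[RiskLocus]
    literature_variants: set[str]
    tp53_regions: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("17", 7571720, 7590868)]
    )


def build_paper_fixture() -> FixtureCohort:
    """Assemble the deterministic reference cohort.

    The encoding is Mendelian-consistent by construction: every documented
    child genotype has a documented (or encoded unaffected-founder) carrier
    parent, unsampled relatives stay missing and are never imputed.
    """
    pedigrees: dict[str, Pedigree] = {}
    samples: list[str] = []
    for fam, iid, fa, mo, sex, aff, hist, grade, band, sampled, side in _MEMBERS:
        gid = f"{fam}_{iid}"
        ped = pedigrees.setdefault(fam, Pedigree(family_id=fam))
        diag = Diagnosis(histology=hist, grade=grade, age_band=band) if hist else None
        ped.members[gid] = Individual(
            individual_id=gid,
            family_id=fam,
            father_id=f"{fam}_{fa}" if fa else None,
            mother_id=f"{fam}_{mo}" if mo else None,
            sex=sex,
            affection="brain_tumor" if aff == "A" else "unaffected",
            diagnosis=diag,
            sampled=sampled,
            side_label=side,
        )
    for ped in pedigrees.values():
        ped.validate()

    samples = [f"{m[0]}_{m[1]}" for m in _MEMBERS]
    sex_of = {f"{m[0]}_{m[1]}": m[4] for m in _MEMBERS}
    sampled_of = {f"{m[0]}_{m[1]}": m[9] for m in _MEMBERS}

    var_rows = []
    ann_rows = []
    keys = []
    for fields, ann in _VARIANTS:
        chrom, pos, ref, alt, rsid, gene, hgvs_c, hgvs_p, csq, source = fields
        key = variant_key(chrom, pos, ref, alt)
        keys.append(key)
        var_rows.append(
            dict(chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid, gene=gene,
                 hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence=csq, source=source)
        )
        full = dict.fromkeys(ANNOTATION_COLUMNS)
        full.update(
            dict(af_nfe=0.0, af_global=0.0, cadd_phred=np.nan, gerp_rs=np.nan,
                 phylop100=np.nan, siphy=np.nan, clinvar_class=None,
                 clinvar_stars=None, domain=None, ctcf_site=False,
                 brain_expressed=False, glioma_relevant=False)
        )
        full.update(ann)
        full["gene"] = gene
        ann_rows.append(full)

    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS, index=keys)
    annotations = pd.DataFrame(ann_rows, index=keys)[["gene"] + ANNOTATION_COLUMNS]

    G = np.zeros((len(keys), len(samples)), dtype=np.int8)
    for vi, key in enumerate(keys):
        chrom = variants.iloc[vi]["chrom"]
        for si, gid in enumerate(samples):
            if not sampled_of[gid]:
                G[vi, si] = MISSING
            elif chrom in ("X", "Y") and sex_of[gid] == "male":
                G[vi, si] = HEMI_REF
        for (fam, iid), code in _GENO.get(key, {}).items():
            G[vi, samples.index(f"{fam}_{iid}")] = code

    cohort = CohortModel(
        pedigrees=pedigrees, variants=variants, G=G, samples=samples,
        annotations=annotations,
    )
    risk_loci = [
        RiskLocus(variant=key, risk_allele=variants.loc[key, "alt"],
                  odds_ratio=_RISK_OR[key], source="gwas")
        for key in keys
        if key in _RISK_OR
    ]
    literature = set(variants.index[variants["source"] == "literature"])
    return FixtureCohort(cohort=cohort, risk_loci=risk_loci,
                         literature_variants=literature)
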