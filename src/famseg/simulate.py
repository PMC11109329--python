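"""Synthetic multiplex-family cohort generator.

The generator emulates the statistical structure the segregation analysis
assumes: 2-3-generation families ascertained for two or more brain-tumor
cases; a rare, incompletely penetrant causal allele planted in one
tumor-side founder of each carrier family and transmitted by gene drop
(independent loci, fair meioses, X-linked rules when flagged); a background
of variants on a log-uniform allele-frequency spectrum with noisy predictor
annotations; and common risk alleles at stated frequencies (one locus at
Finnish frequency 0.09 by default).  Everything is reproducible from the
configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._gt import HEMI_REF, HET, HOM_REF, MISSING, is_x
from .pedigree import Individual, Pedigree
from .variants import (
    ANNOTATION_COLUMNS,
    CohortModel,
    PRED_COLS,
    VARIANT_COLUMNS,
    variant_key,
)
from .riskloci import RiskLocus


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_families: int = 19
    p_three_generation: float = 0.4
    sibship_min: int = 2
    sibship_max: int = 5
    #: multiplex ascertainment: minimum brain-tumor cases per family
    min_affected_per_family: int = 2

    # causal model
    causal_gene: str = "CAUSAL1"
    n_causal_variants: int = 2
    #: family index carrying each causal variant (default: variant i -> family i)
    causal_families: Optional[list[int]] = None
    causal_af: float = 1e-4           # annotated Finnish AF of the causal alleles
    causal_chrom: str = "2"           # set "X" for an X-linked causal gene
    penetrance: float = 0.6           # carrier penetrance f1
    sporadic_rate: float = 0.005      # non-carrier (phenocopy) rate f0

    # background model
    n_background: int = 10_000
    af_log10_min: float = -4.0
    af_log10_max: float = math.log10(0.5)
    protein_altering_fraction: float = 0.79
    predictor_damaging_rate: float = 0.1
    predictor_unavailable_rate: float = 0.05
    background_brain_expressed_rate: float = 0.5
    n_genes: int = 2000

    # risk-locus model: (allele frequency, odds ratio) pairs
    risk_loci: list[tuple[float, float]] = field(default_factory=lambda: [(0.09, 3.4)])

    missingness: float = 0.02
    genotype_error_rate: float = 0.0
    max_ascertainment_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_three_generation", "penetrance", "sporadic_rate", "missingness",
            "genotype_error_rate", "protein_altering_fraction",
            "predictor_damaging_rate", "predictor_unavailable_rate",
            "background_brain_expressed_rate", "causal_af",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.penetrance < self.sporadic_rate:
            raise ValueError("penetrance must be >= sporadic rate")
        if self.n_families < 1 or self.sibship_min < 1 or self.sibship_min > self.sibship_max:
            raise ValueError("invalid family-structure parameters")
        if self.n_causal_variants < 0:
            raise ValueError("n_causal_variants must be >= 0")
        for af, or_ in self.risk_loci:
            if not 0.0 <= af <= 1.0 or or_ <= 0:
                raise ValueError(f"invalid risk locus (af={af}, OR={or_})")


# ---------------------------------------------------------------------------
# family structure
# ---------------------------------------------------------------------------

class _Member:
    __slots__ = ("iid", "father", "mother", "sex", "side_label")

    def __init__(self, iid, father, mother, sex, side_label="none"):
        self.iid, self.father, self.mother = iid, father, mother
        self.sex, self.side_label = sex, side_label

    @property
    def is_founder(self):
        return self.father is None and self.mother is None


def _family_structure(rng: np.random.Generator, cfg: SimConfig, fam: str) -> list[_Member]:
    """Members in topological order; indices reference the returned list."""
    x_causal = is_x(cfg.causal_chrom)
    # the tumor-history founder must be female for an X-linked causal gene
    tum_father = not x_causal
    members: list[_Member] = [
        _Member(f"{fam}_I-1", None, None, "male",
                "tumor_side" if tum_father else "married_in"),
        _Member(f"{fam}_I-2", None, None, "female",
                "married_in" if tum_father else "tumor_side"),
    ]
    three_gen = rng.random() < cfg.p_three_generation
    sib = int(rng.integers(cfg.sibship_min, cfg.sibship_max + 1))
    if not three_gen:
        for k in range(sib):
            sex = "male" if rng.random() < 0.5 else "female"
            members.append(_Member(f"{fam}_II-{k + 1}", 0, 1, sex))
        return members
    # three generations: the first generation-II child marries in a spouse
    inner_sex = "male" if rng.random() < 0.5 else "female"
    members.append(_Member(f"{fam}_II-1", 0, 1, inner_sex))          # idx 2
    members.append(_Member(f"{fam}_II-2", 0, 1,
                           "male" if rng.random() < 0.5 else "female"))
    spouse_sex = "female" if inner_sex == "male" else "male"
    members.append(_Member(f"{fam}_II-3", None, None, spouse_sex, "married_in"))  # idx 4
    father_idx, mother_idx = (2, 4) if inner_sex == "male" else (4, 2)
    for k in range(max(2, sib - 1)):
        sex = "male" if rng.random() < 0.5 else "female"
        members.append(_Member(f"{fam}_III-{k + 1}", father_idx, mother_idx, sex))
    return members


def _tumor_side_founder(members: list[_Member], female: bool) -> int:
    want = "female" if female else "male"
    for i, m in enumerate(members):
        if m.is_founder and m.side_label == "tumor_side" and m.sex == want:
            return i
    for i, m in enumerate(members):  # fall back to any tumor-side founder
        if m.is_founder and m.side_label == "tumor_side":
            return i
    raise RuntimeError("no tumor-side founder in structure")


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _hw_drop(rng: np.random.Generator, members: list[_Member], af: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg founders + Mendelian transmission for autosomal loci.

    Returns dosage codes (m variants x n members), values 0/1/2.
    """
    m = af.size
    out = np.empty((m, len(members)), dtype=np.int8)
    for i, mem in enumerate(members):
        if mem.is_founder:
            out[:, i] = rng.binomial(2, af).astype(np.int8)
        else:
            gf = out[:, mem.father]
            gm = out[:, mem.mother]
            a = rng.random(m) < gf / 2.0
            b = rng.random(m) < gm / 2.0
            out[:, i] = a.astype(np.int8) + b.astype(np.int8)
    return out


def _causal_drop(
    rng: np.random.Generator, members: list[_Member], planted: int, xlinked: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Drop one planted allele (heterozygous founder) through the family.

    Returns (genotype codes, carrier bool) per member; X-linked males get
    hemizygous codes and inherit only the maternal X.
    """
    alleles: list[tuple[int, ...]] = []
    for i, mem in enumerate(members):
        if mem.is_founder:
            if xlinked:
                base = (0,) if mem.sex == "male" else (0, 0)
            else:
                base = (0, 0)
            if i == planted:
                base = (1,) + base[1:]
            alleles.append(base)
        else:
            fa = alleles[mem.father]
            mo = alleles[mem.mother]
            mat = mo[int(rng.integers(len(mo)))]
            if xlinked and mem.sex == "male":
                alleles.append((mat,))
            else:
                pat = fa[int(rng.integers(len(fa)))]
                alleles.append((pat, mat))
    codes = np.empty(len(members), dtype=np.int8)
    carrier = np.zeros(len(members), dtype=bool)
    for i, al in enumerate(alleles):
        carrier[i] = any(al)
        if len(al) == 1:
            codes[i] = HEMI_REF + al[0]     # hemi_ref / hemi_alt
        else:
            codes[i] = sum(al)
    return codes, carrier


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _background_variants(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_background
    af = 10.0 ** rng.uniform(cfg.af_log10_min, cfg.af_log10_max, n)
    chrom = rng.integers(1, 23, n).astype(str)
    pos = (np.arange(n) + 1) * 50 + rng.integers(0, 49, n)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    alt = bases[(np.char.index("ACGT", ref.astype("U1")) + rng.integers(1, 4, n)) % 4]
    altering = rng.random(n) < cfg.protein_altering_fraction
    silent = np.where(rng.random(n) < 0.5, "synonymous", "intronic")
    consequence = np.where(altering, "missense", silent)
    gene = np.array([f"G{g}" for g in rng.integers(0, cfg.n_genes, n)])
    df = pd.DataFrame(
        {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "rsid": None, "gene": gene, "hgvs_c": None, "hgvs_p": None,
            "consequence": consequence, "source": "wes_candidate",
            "af": af,
        }
    )
    df.index = [variant_key(c, p, r, a) for c, p, r, a in zip(chrom, pos, ref, alt)]
    return df


def _annotations(rng: np.random.Generator, cfg: SimConfig, variants: pd.DataFrame,
                 af: np.ndarray, causal_mask: np.ndarray) -> pd.DataFrame:
    n = len(variants)
    ann = pd.DataFrame(index=variants.index)
    ann["gene"] = variants["gene"].to_numpy()
    ann["af_fin"] = af
    ann["af_nfe"] = af
    ann["af_global"] = af
    missense = (variants["consequence"] == "missense").to_numpy()
    for col in PRED_COLS:
        r = rng.random(n)
        call = np.where(r < cfg.predictor_unavailable_rate, "unavailable",
                        np.where(rng.random(n) < cfg.predictor_damaging_rate,
                                 "damaging", "tolerated"))
        call = np.where(missense, call, "unavailable")
        call = np.where(causal_mask, "damaging", call)
        ann[col] = call
    ann["cadd_phred"] = np.where(causal_mask, rng.uniform(25, 35, n), rng.uniform(0, 25, n))
    ann["gerp_rs"] = rng.uniform(-2, 6, n)
    ann["phylop100"] = rng.uniform(-1, 10, n)
    ann["siphy"] = rng.uniform(0, 20, n)
    ann["clinvar_class"] = None
    ann["clinvar_stars"] = None
    ann["domain"] = None
    ann["ctcf_site"] = False
    ann["brain_expressed"] = np.where(
        causal_mask, True, rng.random(n) < cfg.background_brain_expressed_rate
    )
    ann["glioma_relevant"] = causal_mask
    return ann[["gene"] + ANNOTATION_COLUMNS]


def simulate_cohort(cfg: SimConfig) -> tuple[CohortModel, dict]:
    """Generate a synthetic cohort plus a truth record of what was planted.

    Founders draw Hardy-Weinberg genotypes at every locus except the causal
    alleles, which are planted heterozygous in one tumor-side founder of
    each designated carrier family and dropped through the pedigree;
    affection is sampled from the carrier/non-carrier penetrances and
    families are re-drawn until the multiplex ascertainment (>= 2 affected)
    holds.  The truth record lists the planted variants, their carrier
    families and the per-individual carrier status.
    """
    rng = np.random.default_rng(cfg.seed)
    xlinked = is_x(cfg.causal_chrom)

    causal_fams = cfg.causal_families
    if causal_fams is None:
        causal_fams = list(range(cfg.n_causal_variants))
    if len(causal_fams) != cfg.n_causal_variants or any(
        not 0 <= f < cfg.n_families for f in causal_fams
    ):
        raise ValueError("causal_families must name a valid family per causal variant")

    # variant tables ------------------------------------------------------
    causal_rows = []
    for v in range(cfg.n_causal_variants):
        pos = 1_000_000 + v * 1000
        causal_rows.append(
            {
                "chrom": "X" if xlinked else cfg.causal_chrom, "pos": pos,
                "ref": "C", "alt": "T", "rsid": None, "gene": cfg.causal_gene,
                "hgvs_c": None, "hgvs_p": None, "consequence": "missense",
                "source": "wes_candidate", "af": cfg.causal_af,
            }
        )
    causal_df = pd.DataFrame(causal_rows, columns=VARIANT_COLUMNS + ["af"])
    if len(causal_df):
        causal_df.index = [
            variant_key(r.chrom, r.pos, r.ref, r.alt) for r in causal_df.itertuples()
        ]

    risk_rows = []
    for j, (af_r, or_r) in enumerate(cfg.risk_loci):
        risk_rows.append(
            {
                "chrom": "8", "pos": 500_000 + j * 1000, "ref": "A", "alt": "G",
                "rsid": f"rsRISK{j}", "gene": f"RISK{j}", "hgvs_c": None,
                "hgvs_p": None, "consequence": "intronic", "source": "literature",
                "af": af_r,
            }
        )
    risk_df = pd.DataFrame(risk_rows, columns=VARIANT_COLUMNS + ["af"])
    if len(risk_df):
        risk_df.index = [
            variant_key(r.chrom, r.pos, r.ref, r.alt) for r in risk_df.itertuples()
        ]

    bg_df = _background_variants(rng, cfg)
    parts = [df for df in (causal_df, risk_df, bg_df) if len(df)]
    variants = pd.concat(parts) if parts else bg_df
    hw_af = np.concatenate([risk_df["af"].to_numpy(), bg_df["af"].to_numpy()])
    n_causal = len(causal_df)
    n_hw = hw_af.size

    # families ------------------------------------------------------------
    pedigrees: dict[str, Pedigree] = {}
    samples: list[str] = []
    columns: list[np.ndarray] = []
    truth_carriers: dict[str, list[str]] = {k: [] for k in causal_df.index}
    planted_founders: dict[str, str] = {}

    fam_of_variant: dict[int, list[int]] = {}
    for v, f in enumerate(causal_fams):
        fam_of_variant.setdefault(f, []).append(v)

    for fi in range(cfg.n_families):
        fam = f"F{fi:02d}"
        members = _family_structure(rng, cfg, fam)
        nm = len(members)
        my_causal = fam_of_variant.get(fi, [])

        causal_codes = np.full((n_causal, nm), HOM_REF, dtype=np.int8)
        if xlinked and n_causal:
            for i, mem in enumerate(members):
                if mem.sex == "male":
                    causal_codes[:, i] = HEMI_REF
        carrier_any = np.zeros(nm, dtype=bool)
        affected = np.zeros(nm, dtype=bool)

        ok = False
        for _try in range(cfg.max_ascertainment_tries):
            carrier_any[:] = False
            for v in my_causal:
                planted = _tumor_side_founder(members, female=xlinked)
                codes, carrier = _causal_drop(rng, members, planted, xlinked)
                causal_codes[v] = codes
                carrier_any |= carrier
                planted_founders[causal_df.index[v]] = members[planted].iid
            p_aff = np.where(carrier_any, cfg.penetrance, cfg.sporadic_rate)
            affected = rng.random(nm) < p_aff
            if affected.sum() >= cfg.min_affected_per_family:
                ok = True
                break
        if not ok:
            # ascertainment stand-in: multiplex clustering from causes outside
            # the model; forced cases are independent of all genotypes
            deficit = cfg.min_affected_per_family - int(affected.sum())
            pool = np.flatnonzero(~affected)
            affected[rng.choice(pool, size=deficit, replace=False)] = True

        for v in my_causal:
            key = causal_df.index[v]
            truth_carriers[key] = [members[i].iid for i in np.flatnonzero(
                (causal_codes[v] == 1) | (causal_codes[v] == 2) | (causal_codes[v] == 4)
            )]

        hw_codes = _hw_drop(rng, members, hw_af) if n_hw else np.zeros((0, nm), np.int8)
        fam_G = np.vstack([causal_codes, hw_codes]) if n_causal else hw_codes

        if cfg.genotype_error_rate > 0:
            err = rng.random(fam_G.shape) < cfg.genotype_error_rate
            fam_G = np.where(err, rng.integers(0, 3, fam_G.shape).astype(np.int8), fam_G)
        if cfg.missingness > 0:
            fam_G = np.where(
                rng.random(fam_G.shape) < cfg.missingness,
                np.int8(MISSING), fam_G,
            )

        ped = Pedigree(family_id=fam)
        for i, mem in enumerate(members):
            ped.members[mem.iid] = Individual(
                individual_id=mem.iid,
                family_id=fam,
                father_id=members[mem.father].iid if mem.father is not None else None,
                mother_id=members[mem.mother].iid if mem.mother is not None else None,
                sex=mem.sex,
                affection="brain_tumor" if affected[i] else "unaffected",
                sampled=True,
                side_label=mem.side_label if mem.is_founder else "none",
            )
        ped.validate()
        pedigrees[fam] = ped
        samples.extend(m.iid for m in members)
        columns.append(fam_G)

    G = np.hstack(columns)
    af_all = np.concatenate([np.full(n_causal, cfg.causal_af), hw_af])
    causal_mask = np.zeros(len(variants), dtype=bool)
    causal_mask[:n_causal] = True
    ann = _annotations(rng, cfg, variants, af_all, causal_mask)
    variants = variants[VARIANT_COLUMNS]

    cohort = CohortModel(
        pedigrees=pedigrees, variants=variants, G=G, samples=samples, annotations=ann
    )
    loci = [
        RiskLocus(variant=k, risk_allele=risk_df.loc[k, "alt"],
                  odds_ratio=cfg.risk_loci[j][1], source="gwas")
        for j, k in enumerate(risk_df.index)
    ]
    truth = {
        "causal_gene": cfg.causal_gene,
        "causal_variants": list(causal_df.index),
        "carrier_families": {
            causal_df.index[v]: f"F{f:02d}" for v, f in enumerate(causal_fams)
        },
        "planted_founders": planted_founders,
        "carriers": truth_carriers,
        "risk_loci": loci,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortModel, out_dir, risk_loci=None) -> dict[str, str]:
    """Write VCF + PED (+ metadata sidecar) + annotation TSV (+ risk TSV).

    The emitted files round-trip through :func:`read_cohort`.
    """
    import os

    from .pedigree import write_ped
    from .variants import write_annotations, write_vcf
    from .riskloci import write_risk_loci

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "ped": os.path.join(out_dir, "cohort.ped"),
        "meta": os.path.join(out_dir, "cohort.meta.tsv"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
    }
    write_vcf(cohort, paths["vcf"])
    write_ped(cohort.pedigrees, paths["ped"], sidecar=paths["meta"])
    write_annotations(cohort, paths["annotations"])
    if risk_loci is not None:
        paths["risk_loci"] = os.path.join(out_dir, "risk_loci.tsv")
        write_risk_loci(risk_loci, paths["risk_loci"])
    return paths


def read_cohort(out_dir) -> CohortModel:
    """Read a directory written by :func:`write_cohort` back into a cohort."""
    import os

    from .pedigree import read_ped
    from .variants import read_annotations, read_vcf

    peds = read_ped(
        os.path.join(out_dir, "cohort.ped"),
        sidecar=os.path.join(out_dir, "cohort.meta.tsv"),
    )
    cohort = read_vcf(os.path.join(out_dir, "cohort.vcf"), peds)
    ann = read_annotations(os.path.join(out_dir, "annotations.tsv"))
    return cohort.with_annotations(ann.loc[ann.index.intersection(cohort.variants.index)])
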