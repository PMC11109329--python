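"""Variant, genotype and annotation model plus VCF / annotation-table I/O.

The in-memory container is :class:`CohortModel`: pedigrees, a variant table,
a genotype-code matrix (variant x individual) and an annotation table, in the
matrix-plus-metadata style of the field's cohort containers.  Genotype codes
are defined in :mod:`famseg._gt`; hemizygous calls represent male chrX
(non-PAR) and chrY genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import pysam

from ._gt import (
    CARRIER_CODES,
    CODE_TO_NAME,
    DOSAGE,
    HET,
    HEMI_ALT,
    HEMI_REF,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NAME_TO_CODE,
    as_code,
    is_x,
    is_y,
)
from .pedigree import Individual, Pedigree

log = logging.getLogger(__name__)

CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y", "MT"]
_CHROM_ORDER = {c: i for i, c in enumerate(CHROMS)}

CONSEQUENCES = (
    "missense",
    "synonymous",
    "intronic",
    "utr3",
    "utr5",
    "frameshift",
    "stopgain",
    "splice",
    "downstream",
    "upstream",
    "intergenic",
    "other",
)
SOURCES = ("wes_candidate", "literature", "tp53_region")

#: in-silico pathogenicity predictors, in their conventional order
PREDICTORS = (
    "SIFT",
    "PolyPhen",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM_MKL",
    "MetaSVM",
    "MetaLR",
)
PRED_COLS = tuple(f"pred_{p.lower()}" for p in PREDICTORS)

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene", "hgvs_c", "hgvs_p",
    "consequence", "source",
]

ANNOTATION_COLUMNS = [
    "af_fin", "af_nfe", "af_global",
    *PRED_COLS,
    "cadd_phred", "gerp_rs", "phylop100", "siphy",
    "clinvar_class", "clinvar_stars", "domain", "ctcf_site",
    "brain_expressed", "glioma_relevant",
]

#: fixed header of the annotation TSV consumed by :func:`read_annotations`
ANNOTATION_HEADER = ["chrom", "pos", "ref", "alt", "gene"] + ANNOTATION_COLUMNS


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{normalize_chrom(chrom)}:{int(pos)}:{ref}:{alt}"


def normalize_chrom(chrom) -> str:
    c = str(chrom).removeprefix("chr")
    return "MT" if c.upper() in ("M", "MT") else c.upper() if c.upper() in ("X", "Y") else c


def chrom_sort_key(chrom) -> int:
    return _CHROM_ORDER.get(normalize_chrom(chrom), len(_CHROM_ORDER))


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    gene: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    consequence: str = "other"
    source: str = "wes_candidate"

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")
        if self.chrom not in _CHROM_ORDER:
            raise ValueError(f"unsupported chromosome {self.chrom!r}")

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeCall:
    individual_id: str
    genotype: str = "missing"
    depth: Optional[int] = None
    qual: Optional[float] = None

    @property
    def code(self) -> int:
        return NAME_TO_CODE[self.genotype]


def is_carrier(call) -> bool:
    """True iff the genotype carries >= 1 alternate allele (het/hom_alt/hemi_alt).

    Missing genotypes are not carriers; use :func:`is_genotyped` to tell a
    genotyped non-carrier apart from an unknown genotype.
    """
    code = call.code if isinstance(call, GenotypeCall) else as_code(call)
    return code in CARRIER_CODES


def is_genotyped(call) -> bool:
    code = call.code if isinstance(call, GenotypeCall) else as_code(call)
    return code != MISSING


def dosage(call, risk_is_alt: bool = True) -> int:
    """Allele dosage of a genotype; hemizygous genotypes count one copy."""
    code = call.code if isinstance(call, GenotypeCall) else as_code(call)
    if code == MISSING:
        raise ValueError("dosage of a missing genotype is undefined")
    d = DOSAGE[code]
    if risk_is_alt:
        return d
    ploidy = 1 if code in (HEMI_REF, HEMI_ALT) else 2
    return ploidy - d


def damaging_consensus(ann: Mapping, rule: str = "majority", k: Optional[int] = None) -> bool:
    """Aggregate the in-silico predictor calls into one binary call.

    ``ann`` is a mapping (annotation row) with the ``pred_*`` fields holding
    ``damaging`` / ``tolerated`` / ``unavailable``.  Only available predictors
    are counted; with zero available predictors a ``ValueError`` is raised.
    Rules: ``majority`` (strict, the default), ``all``, ``at_least_k``.
    """
    calls = [str(ann[c]) for c in PRED_COLS]
    available = [c for c in calls if c != "unavailable"]
    if not available:
        raise ValueError("no predictor call available for consensus")
    n_dam = sum(c == "damaging" for c in available)
    if rule == "majority":
        return 2 * n_dam > len(available)
    if rule == "all":
        return n_dam == len(available)
    if rule == "at_least_k":
        if k is None:
            raise ValueError("rule 'at_least_k' requires k")
        return n_dam >= k
    raise ValueError(f"unknown consensus rule {rule!r}")


def predictor_counts(ann: Mapping) -> tuple[int, int]:
    """(n damaging, n available) over the predictor panel."""
    calls = [str(ann[c]) for c in PRED_COLS]
    available = [c for c in calls if c != "unavailable"]
    return sum(c == "damaging" for c in available), len(available)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortModel:
    """Pedigrees + variant table + genotype matrix + annotations.

    ``G`` holds genotype codes (int8) with shape (n variants, n samples),
    rows aligned with ``variants.index`` (variant keys) and columns with
    ``samples`` (globally unique individual ids).  ``D`` optionally holds
    per-call read depths with the same shape.
    """

    pedigrees: dict[str, Pedigree] = field(default_factory=dict)
    variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_COLUMNS)
    )
    G: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=np.int8))
    samples: list[str] = field(default_factory=list)
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )
    D: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._var_idx = {k: i for i, k in enumerate(self.variants.index)}
        self._validate()

    def _validate(self) -> None:
        if self.G.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        known = {
            ind.individual_id for ped in self.pedigrees.values() for ind in ped
        }
        orphans = [s for s in self.samples if s not in known]
        if orphans:
            raise ValueError(f"samples absent from pedigrees: {orphans}")
        if len(self.annotations):
            unknown = self.annotations.index.difference(self.variants.index)
            if len(unknown):
                raise ValueError(
                    f"annotated variants absent from variant table: {list(unknown)[:5]}"
                )

    # -- lookups -----------------------------------------------------------

    @property
    def variant_keys(self) -> list[str]:
        return list(self.variants.index)

    def sample_index(self, individual_id: str) -> int:
        return self._sample_idx[individual_id]

    def variant_index(self, key: str) -> int:
        try:
            return self._var_idx[key]
        except KeyError:
            raise KeyError(f"variant {key!r} not in cohort") from None

    def individual(self, individual_id: str) -> Individual:
        for ped in self.pedigrees.values():
            if individual_id in ped:
                return ped[individual_id]
        raise KeyError(f"individual {individual_id!r} not in any pedigree")

    def genotype_code(self, key: str, individual_id: str) -> int:
        si = self._sample_idx.get(individual_id)
        if si is None:
            return MISSING
        return int(self.G[self.variant_index(key), si])

    def call(self, key: str, individual_id: str) -> GenotypeCall:
        code = self.genotype_code(key, individual_id)
        depth = None
        if self.D is not None and individual_id in self._sample_idx:
            d = self.D[self.variant_index(key), self._sample_idx[individual_id]]
            depth = None if d < 0 else int(d)
        return GenotypeCall(individual_id, CODE_TO_NAME[code], depth=depth)

    def genotypes_for(self, key: str) -> dict[str, int]:
        """Per-individual genotype codes for one variant (sampled members only)."""
        row = self.G[self.variant_index(key)]
        return {s: int(row[i]) for s, i in self._sample_idx.items()}

    # -- vectorised views --------------------------------------------------

    def carrier_matrix(self) -> np.ndarray:
        return (self.G == HET) | (self.G == HOM_ALT) | (self.G == HEMI_ALT)

    def genotyped_matrix(self) -> np.ndarray:
        return self.G != MISSING

    def sample_meta(self) -> pd.DataFrame:
        """Per-sample family id and affection, aligned with matrix columns."""
        rows = []
        for s in self.samples:
            ind = self.individual(s)
            rows.append(
                {
                    "individual_id": s,
                    "family_id": ind.family_id,
                    "affected": ind.affected,
                    "unaffected": ind.affection == "unaffected",
                    "sex": ind.sex,
                }
            )
        return pd.DataFrame(rows).set_index("individual_id")

    def family_sample_indices(self, family_id: str) -> np.ndarray:
        ped = self.pedigrees[family_id]
        return np.array(
            [self._sample_idx[i.individual_id] for i in ped if i.individual_id in self._sample_idx],
            dtype=int,
        )

    def family_counts(self, key: str, family_id: str) -> dict[str, int]:
        """Carrier/genotyped counts over a family for one variant."""
        ped = self.pedigrees[family_id]
        row = self.G[self.variant_index(key)]
        out = dict(
            n_affected_genotyped=0,
            n_affected_carriers=0,
            n_unaffected_genotyped=0,
            n_unaffected_carriers=0,
        )
        for ind in ped:
            si = self._sample_idx.get(ind.individual_id)
            if si is None:
                continue
            code = int(row[si])
            if code == MISSING:
                continue
            carrier = code in CARRIER_CODES
            if ind.affected:
                out["n_affected_genotyped"] += 1
                out["n_affected_carriers"] += carrier
            elif ind.affection == "unaffected":
                out["n_unaffected_genotyped"] += 1
                out["n_unaffected_carriers"] += carrier
        return out

    def with_annotations(self, ann: pd.DataFrame) -> "CohortModel":
        """Attach an annotation table (indexed by variant key); validates keys."""
        unknown = ann.index.difference(self.variants.index)
        if len(unknown):
            raise ValueError(f"annotations for unknown variants: {list(unknown)[:5]}")
        return CohortModel(
            pedigrees=self.pedigrees,
            variants=self.variants,
            G=self.G,
            samples=self.samples,
            annotations=ann,
            D=self.D,
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, pedigrees: Mapping[str, Pedigree]) -> CohortModel:
    """Load a VCF (v4.x, GT required) into a :class:`CohortModel` fragment.

    Sample names must match pedigree individual ids.  Multiallelic sites are
    decomposed into one record per alternate allele (other alternate alleles
    count as reference for that record).  Diploid male chrX calls are coerced
    to hemizygous with a logged warning; a heterozygous male chrX call is set
    to missing.  Haploid GT values map directly to hemizygous codes.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    known = {ind.individual_id: ind for ped in pedigrees.values() for ind in ped}
    unknown = [s for s in samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples absent from pedigrees: {unknown}")
    sex = {s: known[s].sex for s in samples}

    var_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    have_depth = False
    n_coerced = 0

    for rec in vf:
        chrom = normalize_chrom(rec.chrom)
        xchrom = is_x(chrom) or is_y(chrom)
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            row = np.full(len(samples), MISSING, dtype=np.int8)
            dep = np.full(len(samples), -1, dtype=np.int32)
            for si, s in enumerate(samples):
                sm = rec.samples[s]
                gt = sm.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                if sm.get("DP") is not None:
                    dep[si] = int(sm["DP"])
                    have_depth = True
                alleles = [a for a in gt if a is not None]
                n_alt = sum(a == ai for a in alleles)
                if len(alleles) == 1:
                    row[si] = HEMI_ALT if n_alt else HEMI_REF
                elif xchrom and sex[s] == "male":
                    if n_alt == 1:
                        log.warning(
                            "male %s heterozygous at %s:%d on %s; set to missing",
                            s, rec.pos, rec.pos, chrom,
                        )
                        continue
                    row[si] = HEMI_ALT if n_alt == 2 else HEMI_REF
                    n_coerced += 1
                else:
                    row[si] = (HOM_REF, HET, HOM_ALT)[n_alt]
            def _info(tag, default=None):
                # undeclared INFO tags raise in pysam rather than defaulting
                try:
                    return rec.info.get(tag, default)
                except (KeyError, ValueError):
                    return default

            var_rows.append(
                {
                    "chrom": chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "rsid": rec.id,
                    "gene": _info("GENE"),
                    "hgvs_c": _info("HGVSC"),
                    "hgvs_p": _info("HGVSP"),
                    "consequence": _info("CSQ", "other"),
                    "source": _info("SRC", "wes_candidate"),
                }
            )
            geno_rows.append(row)
            depth_rows.append(dep)
    vf.close()
    if n_coerced:
        log.warning("coerced %d diploid male sex-chromosome calls to hemizygous", n_coerced)

    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    if len(variants):
        variants.index = [
            variant_key(r.chrom, r.pos, r.ref, r.alt) for r in variants.itertuples()
        ]
    G = np.vstack(geno_rows) if geno_rows else np.zeros((0, len(samples)), dtype=np.int8)
    D = np.vstack(depth_rows) if (have_depth and depth_rows) else None
    return CohortModel(
        pedigrees=dict(pedigrees), variants=variants, G=G, samples=samples, D=D
    )


def write_vcf(cohort: CohortModel, path) -> None:
    """Write the cohort genotypes as a minimal VCF v4.2 (GT, optional DP)."""
    order = sorted(
        range(len(cohort.variants)),
        key=lambda i: (
            chrom_sort_key(cohort.variants["chrom"].iloc[i]),
            int(cohort.variants["pos"].iloc[i]),
        ),
    )
    chroms = []
    for i in order:
        c = cohort.variants["chrom"].iloc[i]
        if c not in chroms:
            chroms.append(c)
    fmt = "GT" if cohort.D is None else "GT:DP"
    gt_str = {
        HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1",
        HEMI_REF: "0", HEMI_ALT: "1", MISSING: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,Description="Variant provenance">\n')
        fh.write('##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS coding">\n')
        fh.write('##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if cohort.D is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in sorted(chroms, key=chrom_sort_key):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if cohort.samples:
            cols += "\tFORMAT\t" + "\t".join(cohort.samples)
        fh.write(cols + "\n")
        for i in order:
            v = cohort.variants.iloc[i]
            info = []
            for tag, col in (("GENE", "gene"), ("CSQ", "consequence"),
                             ("SRC", "source"), ("HGVSC", "hgvs_c"), ("HGVSP", "hgvs_p")):
                val = v[col]
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    info.append(f"{tag}={val}")
            cells = []
            for si in range(len(cohort.samples)):
                code = int(cohort.G[i, si])
                g = gt_str[code]
                if code == MISSING and cohort.variants["chrom"].iloc[i] in ("X", "Y"):
                    pass  # diploid-style missing kept; pysam reads ./. fine
                if cohort.D is not None:
                    d = int(cohort.D[i, si])
                    cells.append(f"{g}:{d if d >= 0 else '.'}")
                else:
                    cells.append(g)
            fields = [
                str(v["chrom"]), str(int(v["pos"])),
                str(v["rsid"]) if v["rsid"] else ".",
                str(v["ref"]), str(v["alt"]), ".", ".",
                ";".join(info) if info else ".",
            ]
            if cohort.samples:
                fields += [fmt, *cells]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Annotation-table I/O
# ---------------------------------------------------------------------------

_PRED_IN = {
    "d": "damaging", "damaging": "damaging",
    "t": "tolerated", "tolerated": "tolerated",
    "": "unavailable", ".": "unavailable", "na": "unavailable",
    "unavailable": "unavailable",
}


def _parse_bool(x: str) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes")


def read_annotations(path) -> pd.DataFrame:
    """Read the fixed-header annotation TSV into a keyed annotation table.

    One row per variant; predictor cells use D/T (or full words) with empty,
    '.' or NA meaning unavailable.  Population frequencies outside [0, 1]
    raise a validation error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    out_rows = []
    index = []
    for rowno, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        key = variant_key(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
        parsed: dict = {"gene": rec.get("gene") or None}
        for col in ("af_fin", "af_nfe", "af_global"):
            raw = rec[col].strip()
            val = float(raw) if raw not in ("", ".") else 0.0
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"row {rowno}: {col}={raw} outside [0, 1]")
            parsed[col] = val
        for col in PRED_COLS:
            raw = str(rec[col]).strip().lower()
            if raw not in _PRED_IN:
                raise ValueError(f"row {rowno}: bad predictor call {rec[col]!r} in {col}")
            parsed[col] = _PRED_IN[raw]
        for col in ("cadd_phred", "gerp_rs", "phylop100", "siphy"):
            raw = rec[col].strip()
            parsed[col] = float(raw) if raw not in ("", ".") else np.nan
        parsed["clinvar_class"] = rec["clinvar_class"].strip() or None
        stars = rec["clinvar_stars"].strip()
        parsed["clinvar_stars"] = int(float(stars)) if stars not in ("", ".") else None
        if parsed["clinvar_stars"] is not None and not 0 <= parsed["clinvar_stars"] <= 4:
            raise ValueError(f"row {rowno}: clinvar_stars outside 0..4")
        parsed["domain"] = rec["domain"].strip() or None
        parsed["ctcf_site"] = _parse_bool(rec["ctcf_site"])
        parsed["brain_expressed"] = _parse_bool(rec["brain_expressed"])
        parsed["glioma_relevant"] = _parse_bool(rec["glioma_relevant"])
        out_rows.append(parsed)
        index.append(key)
    out = pd.DataFrame(out_rows, index=index, columns=["gene"] + ANNOTATION_COLUMNS)
    return out


def write_annotations(cohort: CohortModel, path) -> None:
    """Write the cohort annotation table in the fixed TSV layout."""
    pred_out = {"damaging": "D", "tolerated": "T", "unavailable": "."}
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for key, ann in cohort.annotations.iterrows():
            v = cohort.variants.loc[key]
            cells = [str(v["chrom"]), str(int(v["pos"])), str(v["ref"]), str(v["alt"]),
                     str(v["gene"] or "")]
            for col in ANNOTATION_COLUMNS:
                val = ann[col]
                if col in PRED_COLS:
                    cells.append(pred_out[str(val)])
                elif col == "clinvar_stars":
                    cells.append(
                        "" if val is None or (isinstance(val, float) and np.isnan(val))
                        else str(int(val))
                    )
                elif isinstance(val, (bool, np.bool_)):
                    cells.append("1" if val else "0")
                elif val is None or (isinstance(val, float) and np.isnan(val)):
                    cells.append("")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")
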