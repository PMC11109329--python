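"""Pedigree data model, PED I/O, Mendelian checks and inheritance-side inference.

A pedigree is a directed acyclic family graph.  Founders (members without
recorded parents) carry an optional ``side_label`` derived from the reported
family history: ``tumor_side`` marks the lineage with brain/other tumors,
``married_in`` marks spouses joining from outside that lineage.  The central
genetic question answered here is, for a variant observed in affected family
members, which founder lineage the allele entered the family through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from ._gt import (
    CARRIER_CODES,
    MISSING,
    HET,
    HEMI_ALT,
    HEMI_REF,
    HOM_ALT,
    HOM_REF,
    TRANSMISSIBLE,
    as_code,
    is_x,
    is_y,
)

log = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
AFFECTIONS = ("brain_tumor", "unaffected", "unknown")
SIDE_LABELS = ("tumor_side", "married_in", "none")

_PED_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PED_AFF = {"2": "brain_tumor", "1": "unaffected", "0": "unknown"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, role conflict)."""


@dataclass
class Diagnosis:
    histology: Optional[str] = None
    grade: Optional[str] = None       # I..IV
    age_band: Optional[str] = None    # e.g. "20-24" (years at diagnosis)


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affection: str = "unknown"
    diagnosis: Optional[Diagnosis] = None
    sampled: bool = True
    side_label: str = "none"  # founders only

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def affected(self) -> bool:
        return self.affection == "brain_tumor"


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    proband_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.members:
            self.validate()

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self.members[individual_id]
        except KeyError:
            raise KeyError(
                f"individual {individual_id!r} not in family {self.family_id!r}"
            ) from None

    def add(self, ind: Individual) -> None:
        self.members[ind.individual_id] = ind

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph over the family."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.individual_id)
        return g

    def validate(self) -> None:
        if not self.members:
            raise PedigreeError(f"family {self.family_id!r} has no members")
        for ind in self:
            if ind.family_id != self.family_id:
                raise PedigreeError(
                    f"{ind.individual_id!r} carries family id {ind.family_id!r} "
                    f"inside family {self.family_id!r}"
                )
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                if pid == ind.individual_id:
                    raise PedigreeError(
                        f"{ind.individual_id!r} is recorded as its own {role}"
                    )
                if pid not in self.members:
                    raise PedigreeError(
                        f"dangling {role} id {pid!r} for {ind.individual_id!r} "
                        f"in family {self.family_id!r}"
                    )
                parent = self.members[pid]
                want = "male" if role == "father" else "female"
                if parent.sex not in ("unknown", want):
                    raise PedigreeError(
                        f"{pid!r} is {role} of {ind.individual_id!r} but has sex "
                        f"{parent.sex!r}"
                    )
            if not ind.is_founder and ind.side_label != "none":
                raise PedigreeError(
                    f"non-founder {ind.individual_id!r} has side_label "
                    f"{ind.side_label!r} (labels are founder annotations)"
                )
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise PedigreeError(f"family {self.family_id!r} contains a cycle")
        if not any(ind.is_founder for ind in self):
            raise PedigreeError(f"family {self.family_id!r} has no founder")

    def parents_of(self, individual_id: str) -> tuple[Optional[str], Optional[str]]:
        ind = self[individual_id]
        return ind.father_id, ind.mother_id


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

def read_ped(path, sidecar=None) -> dict[str, Pedigree]:
    """Read a whitespace-delimited 6-column PED file into pedigrees.

    Columns: family_id individual_id father_id mother_id sex affection with
    "0" for a missing parent, sex 1/2/0 = male/female/unknown and affection
    2/1/0 = affected (brain tumor)/unaffected/unknown.  ``sidecar`` is an
    optional tab-separated table keyed by (family_id, individual_id) adding
    histology, grade, age_band, sampled and founder side_label columns.

    Returns a dict family_id -> :class:`Pedigree`; an empty file yields an
    empty dict.  Structural problems raise :class:`PedigreeError`.
    """
    families: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            fam, iid, fid, mid, sex, aff = parts[:6]
            ind = Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_PED_SEX.get(sex, "unknown"),
                affection=_PED_AFF.get(aff, "unknown"),
            )
            families.setdefault(fam, Pedigree(family_id=fam)).members[iid] = ind

    if sidecar is not None:
        _apply_sidecar(families, sidecar)

    for ped in families.values():
        ped.validate()
    return families


def _apply_sidecar(families: dict[str, Pedigree], path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("family_id", "individual_id"):
            if req not in idx:
                raise PedigreeError(f"sidecar {path} lacks required column {req!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")

            def get(col):
                i = idx.get(col)
                if i is None or i >= len(parts):
                    return None
                return parts[i] or None

            fam, iid = parts[idx["family_id"]], parts[idx["individual_id"]]
            if fam not in families or iid not in families[fam]:
                raise PedigreeError(f"sidecar row for unknown individual {fam}/{iid}")
            ind = families[fam][iid]
            hist, grade, band = get("histology"), get("grade"), get("age_band")
            if hist or grade or band:
                ind.diagnosis = Diagnosis(histology=hist, grade=grade, age_band=band)
            sampled = get("sampled")
            if sampled is not None:
                ind.sampled = sampled.lower() in ("1", "true", "yes")
            side = get("side_label")
            if side is not None:
                if side not in SIDE_LABELS:
                    raise PedigreeError(f"bad side_label {side!r} for {fam}/{iid}")
                ind.side_label = side


def write_ped(families: Mapping[str, Pedigree] | Iterable[Pedigree], path, sidecar=None) -> None:
    """Write pedigrees as 6-column PED plus an optional metadata sidecar."""
    peds = list(families.values()) if isinstance(families, Mapping) else list(families)
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    aff_out = {"brain_tumor": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for ped in peds:
            for ind in ped:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            ind.individual_id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            sex_out[ind.sex],
                            aff_out[ind.affection],
                        ]
                    )
                    + "\n"
                )
    if sidecar is not None:
        cols = ["family_id", "individual_id", "histology", "grade", "age_band", "sampled", "side_label"]
        with open(sidecar, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for ped in peds:
                for ind in ped:
                    d = ind.diagnosis or Diagnosis()
                    fh.write(
                        "\t".join(
                            [
                                ped.family_id,
                                ind.individual_id,
                                d.histology or "",
                                d.grade or "",
                                d.age_band or "",
                                "1" if ind.sampled else "0",
                                ind.side_label,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Lineage bookkeeping
# ---------------------------------------------------------------------------

def founders(ped: Pedigree) -> list[Individual]:
    """Members with no recorded parents."""
    return [ind for ind in ped if ind.is_founder]


def _founder_side(ind: Individual) -> Optional[str]:
    if ind.side_label == "tumor_side":
        return "tumor_side"
    if ind.side_label == "married_in":
        return "non_tumor_side"
    return None


def founder_ancestors(ped: Pedigree, individual_id: str) -> set[str]:
    """Founder ids reachable upward from an individual (itself if a founder)."""
    ind = ped[individual_id]
    if ind.is_founder:
        return {individual_id}
    out: set[str] = set()
    stack = [p for p in (ind.father_id, ind.mother_id) if p is not None]
    seen = set()
    while stack:
        pid = stack.pop()
        if pid in seen:
            continue
        seen.add(pid)
        p = ped[pid]
        if p.is_founder:
            out.add(pid)
        else:
            stack.extend(q for q in (p.father_id, p.mother_id) if q is not None)
    return out


def side_of(ped: Pedigree, individual_id: str) -> str:
    """Founder-lineage side of an individual.

    Founders report their own label (married_in maps to ``non_tumor_side``);
    non-founders aggregate the labels of their founder ancestors: both sides
    represented gives ``mixed``, unlabeled founders give ``undetermined``.
    """
    ind = ped[individual_id]
    if ind.is_founder:
        return {"tumor_side": "tumor_side", "married_in": "non_tumor_side"}.get(
            ind.side_label, "undetermined"
        )
    labels = {ped[f].side_label for f in founder_ancestors(ped, individual_id)}
    has_t = "tumor_side" in labels
    has_m = "married_in" in labels
    if has_t and has_m:
        return "mixed"
    if "none" in labels:
        return "undetermined"
    if has_t:
        return "tumor_side"
    if has_m:
        return "non_tumor_side"
    return "undetermined"


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

def _code_of(genotypes: Mapping[str, object], iid: Optional[str]) -> int:
    if iid is None:
        return MISSING
    g = genotypes.get(iid, MISSING)
    return as_code(g)


def mendelian_violations(ped: Pedigree, genotypes: Mapping[str, object], chrom: str) -> list[dict]:
    """Trios whose genotypes are impossible under Mendelian transmission.

    ``genotypes`` maps individual id to a genotype code or name for a single
    variant; absent or missing members skip the trio check.  On chrX (treated
    as non-PAR) males are hemizygous and a heterozygous male call is itself
    reported as a violation.
    """
    violations: list[dict] = []
    x = is_x(chrom)
    y = is_y(chrom)

    for ind in ped:
        code = _code_of(genotypes, ind.individual_id)
        if code == MISSING:
            continue
        if x and ind.sex == "male" and code == HET:
            violations.append(
                {
                    "child": ind.individual_id,
                    "father": ind.father_id,
                    "mother": ind.mother_id,
                    "chrom": chrom,
                    "reason": "heterozygous male genotype on chrX",
                }
            )
            continue
        if ind.father_id is None or ind.mother_id is None:
            continue
        fcode = _code_of(genotypes, ind.father_id)
        mcode = _code_of(genotypes, ind.mother_id)
        if fcode == MISSING or mcode == MISSING:
            continue

        if y:
            if ind.sex != "male":
                continue
            allele = 1 if fcode in (HOM_ALT, HEMI_ALT) else None
            child_allele = 1 if code in (HOM_ALT, HEMI_ALT) else 0
            f_alleles = TRANSMISSIBLE.get(fcode, (0,))
            ok = child_allele in f_alleles
        elif x and ind.sex == "male":
            child_allele = 1 if code in (HOM_ALT, HEMI_ALT) else 0
            ok = child_allele in TRANSMISSIBLE[mcode]
        elif x and ind.sex == "female":
            ok = _diploid_possible(code, fcode, mcode)
        else:
            ok = _diploid_possible(code, fcode, mcode)
        if not ok:
            violations.append(
                {
                    "child": ind.individual_id,
                    "father": ind.father_id,
                    "mother": ind.mother_id,
                    "chrom": chrom,
                    "reason": "genotype impossible under Mendelian transmission",
                }
            )
    return violations


def _diploid_possible(child: int, father: int, mother: int) -> bool:
    tf = TRANSMISSIBLE[father]
    tm = TRANSMISSIBLE[mother]
    if child in (HOM_REF, HEMI_REF):
        return 0 in tf and 0 in tm
    if child in (HOM_ALT, HEMI_ALT):
        return 1 in tf and 1 in tm
    # heterozygous child
    return (0 in tf and 1 in tm) or (1 in tf and 0 in tm)


# ---------------------------------------------------------------------------
# Inheritance-side inference
# ---------------------------------------------------------------------------

def _trace_entry_side(
    ped: Pedigree,
    genotypes: Mapping[str, object],
    chrom: str,
    individual_id: str,
    _depth: int = 0,
) -> Optional[str]:
    """Founder-lineage side the carrier's allele entered through, or None.

    The individual is taken to be a carrier (observed or obligate).  The
    transmitting parent is identified by exclusion: a genotyped reference
    parent cannot transmit, an X-hemizygous male receives from his mother.
    When a unique chain of transmitters leads to a labeled founder the
    founder's side is returned; any residual ambiguity (two candidate
    parents whose own traces disagree, an unrecorded parent, an unlabeled
    founder) yields None.  De novo origin is never invoked.
    """
    if _depth > len(ped) + 2:  # defensive; pedigrees are acyclic
        return None
    ind = ped[individual_id]
    if ind.is_founder:
        return _founder_side(ind)

    if is_x(chrom) and ind.sex == "male":
        if ind.mother_id is None:
            return None
        mcode = _code_of(genotypes, ind.mother_id)
        if mcode != MISSING and mcode not in CARRIER_CODES:
            return None  # inconsistent observation; no safe call
        return _trace_entry_side(ped, genotypes, chrom, ind.mother_id, _depth + 1)

    # enumerate parental allele pairs consistent with the child's genotype
    # (ungenotyped parents may transmit either allele)
    def _tset(pid):
        if pid is None:
            return (0, 1)
        code = _code_of(genotypes, pid)
        return (0, 1) if code == MISSING else TRANSMISSIBLE[code]

    g_obs = _code_of(genotypes, individual_id)
    if g_obs == HET:
        pairs = [(1, 0), (0, 1)]
    elif g_obs in (HOM_ALT, HEMI_ALT):
        pairs = [(1, 1)]
    else:  # obligate carrier of unknown zygosity
        pairs = [(1, 0), (0, 1), (1, 1)]
    tf, tm = _tset(ind.father_id), _tset(ind.mother_id)
    valid = [(a, b) for a, b in pairs if a in tf and b in tm]
    if not valid:
        return None  # apparent de novo pattern; not assumed, so undetermined
    transmitters: set[Optional[str]] = set()
    for a, b in valid:
        if a == 1:
            transmitters.add(ind.father_id)
        if b == 1:
            transmitters.add(ind.mother_id)
    sides = set()
    for pid in transmitters:
        if pid is None:
            return None  # unrecorded parent may have transmitted
        sides.add(_trace_entry_side(ped, genotypes, chrom, pid, _depth + 1))
    if len(sides) == 1:
        return sides.pop()
    return None


def infer_inheritance_side(
    ped: Pedigree, genotypes: Mapping[str, object], chrom: str
) -> str:
    """Which founder lineage a variant's affected carriers inherited it from.

    Every genotyped affected carrier's allele is traced upward to its
    founder entry point (see :func:`_trace_entry_side`).  The side is
    reported only when every affected carrier's entry point is unambiguous
    and all of them agree; any carrier whose allele could have entered
    through either lineage (or through an unlabeled founder) makes the
    result ``undetermined``.

    Raises ``ValueError`` when the family has no genotyped affected carrier.
    """
    carriers = [
        ind.individual_id
        for ind in ped
        if ind.affected and _code_of(genotypes, ind.individual_id) in CARRIER_CODES
    ]
    if not carriers:
        raise ValueError(
            f"family {ped.family_id!r}: no affected carrier for side inference"
        )
    sides = {_trace_entry_side(ped, genotypes, chrom, c) for c in carriers}
    if len(sides) == 1 and None not in sides:
        return sides.pop()
    return "undetermined"
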