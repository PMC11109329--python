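"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or naive
loops, independent of the library's vectorised / recursive code paths.
"""

from __future__ import annotations

from itertools import product

from famseg._gt import (
    CARRIER_CODES,
    HEMI_ALT,
    HEMI_REF,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
)

_X = ("X",)


def _is_x(chrom):
    return str(chrom).removeprefix("chr").upper() == "X"


def _alleles(code, n=2):
    return {
        HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1),
        HEMI_REF: (0,), HEMI_ALT: (1,),
    }[code]


def _transmissible(code):
    return {HOM_REF: {0}, HET: {0, 1}, HOM_ALT: {1},
            HEMI_REF: {0}, HEMI_ALT: {1}}[code]


def _assignment_consistent(ped, genos, chrom):
    """Full-assignment Mendelian check (every member has a genotype)."""
    x = _is_x(chrom)
    for ind in ped:
        code = genos[ind.individual_id]
        f, m = ind.father_id, ind.mother_id
        if f is None and m is None:
            continue
        tf = _transmissible(genos[f]) if f is not None else {0, 1}
        tm = _transmissible(genos[m]) if m is not None else {0, 1}
        if x and ind.sex == "male":
            if code == HET:
                return False
            allele = 1 if code in (HOM_ALT, HEMI_ALT) else 0
            if allele not in tm:
                return False
            continue
        child = _alleles(code)
        if len(child) == 1:
            if child[0] not in tf or child[0] not in tm:
                return False
            continue
        a, b = child
        if not ((a in tf and b in tm) or (b in tf and a in tm)):
            return False
    return True


def _entry_sides(ped, genos, chrom, iid, memo):
    """Founder sides the carrier's allele copies can originate from, for one
    fully specified assignment; '?' marks an unknowable origin."""
    if iid in memo:
        return memo[iid]
    ind = ped[iid]
    x = _is_x(chrom)
    if ind.is_founder:
        out = {
            {"tumor_side": "tumor_side", "married_in": "non_tumor_side"}.get(
                ind.side_label, "?"
            )
        }
        memo[iid] = out
        return out
    f, m = ind.father_id, ind.mother_id
    if x and ind.sex == "male":
        out = _entry_sides(ped, genos, chrom, m, memo) if m is not None else {"?"}
        memo[iid] = out
        return out
    tf = _transmissible(genos[f]) if f is not None else {0, 1}
    tm = _transmissible(genos[m]) if m is not None else {0, 1}
    code = genos[iid]
    if code == HET:
        pairs = [(1, 0), (0, 1)]
    else:  # hom_alt carrier
        pairs = [(1, 1)]
    out = set()
    for a, b in pairs:
        if a not in tf or b not in tm:
            continue
        if a == 1:
            out |= _entry_sides(ped, genos, chrom, f, memo) if f is not None else {"?"}
        if b == 1:
            out |= _entry_sides(ped, genos, chrom, m, memo) if m is not None else {"?"}
    memo[iid] = out
    return out


def oracle_inheritance_side(ped, genotypes, chrom):
    """Enumerate genotype assignments to ungenotyped members; report a side
    iff every consistent assignment places the affected carriers' allele
    entry points on that one founder side."""
    x = _is_x(chrom)
    observed = {
        i.individual_id: genotypes.get(i.individual_id, MISSING) for i in ped
    }
    unknown = [iid for iid, c in observed.items() if c == MISSING]
    affected_carriers = [
        i.individual_id for i in ped
        if i.affected and observed[i.individual_id] in CARRIER_CODES
    ]
    assert affected_carriers, "oracle precondition: an affected carrier exists"

    def options(iid):
        ind = ped[iid]
        if x and ind.sex == "male":
            return (HEMI_REF, HEMI_ALT)
        return (HOM_REF, HET, HOM_ALT)

    all_sides = set()
    any_consistent = False
    for combo in product(*(options(u) for u in unknown)):
        genos = dict(observed)
        genos.update(zip(unknown, combo))
        if not _assignment_consistent(ped, genos, chrom):
            continue
        any_consistent = True
        memo: dict = {}
        for iid in affected_carriers:
            all_sides |= _entry_sides(ped, genos, chrom, iid, memo)
    if not any_consistent:
        return "undetermined"
    if all_sides == {"tumor_side"}:
        return "tumor_side"
    if all_sides == {"non_tumor_side"}:
        return "non_tumor_side"
    return "undetermined"


# ---------------------------------------------------------------------------
# naive criteria-AND prioritization
# ---------------------------------------------------------------------------

def _naive_damaging(ann_row, rule="majority"):
    from famseg.variants import PRED_COLS

    calls = [str(ann_row[c]) for c in PRED_COLS]
    avail = [c for c in calls if c != "unavailable"]
    if not avail:
        cls = str(ann_row.get("clinvar_class") or "").lower()
        stars = ann_row.get("clinvar_stars")
        return cls == "pathogenic" and stars is not None and stars >= 2
    n = sum(c == "damaging" for c in avail)
    if rule == "majority":
        return 2 * n > len(avail)
    raise NotImplementedError(rule)


def oracle_prioritize(cohort, criteria, side_fn=None):
    """Naive per-(variant, criterion) evaluation followed by intersection.

    ``side_fn`` defaults to the enumeration oracle; returns (candidate gene
    set, candidate variant set).
    """
    if side_fn is None:
        side_fn = oracle_inheritance_side

    qualifying = {}
    for key in cohort.variants.index:
        ann = cohort.annotations.loc[key] if key in cohort.annotations.index else None
        af = float(ann["af_fin"]) if ann is not None else 0.0
        rare = af < criteria.af_fin_max
        damaging = _naive_damaging(ann, criteria.damaging_rule) if ann is not None else False
        relevant = (
            bool(ann["brain_expressed"]) or bool(ann["glioma_relevant"])
            if (criteria.require_gene_relevance and ann is not None)
            else not criteria.require_gene_relevance
        )
        supporting = set()
        for fam, ped in cohort.pedigrees.items():
            n_aff = n_car = 0
            for ind in ped:
                code = cohort.genotype_code(key, ind.individual_id)
                if code == MISSING or not ind.affected:
                    continue
                n_aff += 1
                n_car += code in CARRIER_CODES
            if n_car >= 1 and (not criteria.require_shared or n_car == n_aff):
                supporting.add(fam)
        side_ok = True
        if criteria.require_tumor_side and rare and damaging and relevant and supporting:
            sides = {
                fam: side_fn(
                    cohort.pedigrees[fam], cohort.genotypes_for(key),
                    cohort.variants.loc[key, "chrom"],
                )
                for fam in supporting
            }
            if criteria.tumor_side_mode == "every_determinable":
                side_ok = all(s != "non_tumor_side" for s in sides.values())
            else:
                side_ok = any(s == "tumor_side" for s in sides.values())
        if rare and damaging and relevant and supporting and side_ok:
            qualifying[key] = supporting

    gene_fams: dict[str, set] = {}
    for key, fams in qualifying.items():
        gene = cohort.variants.loc[key, "gene"] or key
        gene_fams.setdefault(gene, set()).update(fams)
    genes = {g for g, f in gene_fams.items() if len(f) >= criteria.min_families}
    variants = set()
    for key, fams in qualifying.items():
        gene = cohort.variants.loc[key, "gene"] or key
        if len(fams) >= criteria.min_families or (
            criteria.gene_level_aggregation and gene in genes
        ):
            variants.add(key)
    return genes, variants
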