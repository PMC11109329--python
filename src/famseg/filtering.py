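"""Discovery-stage variant filtering, within-family sharing, panel assembly
and targeted-genotyping QC.

The discovery cascade mirrors a family-based exome design: merge the call
sets of two variant callers, keep rare protein-altering variants, keep those
shared by the affected members of at least one discovery family, then carry
the surviving candidates (plus literature variants and gene regions) onto a
targeted genotyping panel that is quality-controlled before segregation
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._gt import CARRIER_CODES, MISSING
from .variants import CohortModel

log = logging.getLogger(__name__)

#: consequence classes treated as protein-altering by default
DEFAULT_PROTEIN_ALTERING = frozenset(
    {"missense", "frameshift", "stopgain", "splice"}
)


class FamilyUninformative(ValueError):
    """Family has no genotyped affected member for the requested variant."""


@dataclass
class FilterConfig:
    discovery_af_max: float = 0.01            # Finnish-population AF ceiling
    protein_altering_set: frozenset = DEFAULT_PROTEIN_ALTERING
    caller_merge_mode: str = "union"
    qc_min_call_rate: float = 0.9
    qc_min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.discovery_af_max <= 1.0:
            raise ValueError("discovery_af_max must be in [0, 1]")
        if not 0.0 <= self.qc_min_call_rate <= 1.0:
            raise ValueError("qc_min_call_rate must be in [0, 1]")
        if self.caller_merge_mode not in ("union", "intersection"):
            raise ValueError("caller_merge_mode must be union or intersection")
        self.protein_altering_set = frozenset(self.protein_altering_set)


@dataclass
class PanelSpec:
    """Targeted panel: exome candidates + literature variants + gene regions."""
    wes_candidates: set[str] = field(default_factory=set)
    literature_variants: set[str] = field(default_factory=set)
    regions: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based inclusive

    @property
    def all_variants(self) -> set[str]:
        return self.wes_candidates | self.literature_variants


def merge_callsets(a: Iterable[str], b: Iterable[str], mode: str = "union") -> set[str]:
    """Merge two caller outputs by variant key."""
    a, b = set(a), set(b)
    if mode == "union":
        return a | b
    if mode == "intersection":
        return a & b
    raise ValueError(f"unknown merge mode {mode!r}")


def filter_discovery(cohort: CohortModel, cfg: FilterConfig) -> set[str]:
    """Rare + protein-altering filter over the cohort's variants.

    A variant is retained when its Finnish-population allele frequency is
    strictly below ``discovery_af_max`` (absent frequency counts as 0, i.e.
    not previously observed) and its consequence class is protein-altering.
    """
    ann = cohort.annotations
    af = ann["af_fin"].reindex(cohort.variants.index).fillna(0.0) if len(ann) else pd.Series(
        0.0, index=cohort.variants.index
    )
    rare = af < cfg.discovery_af_max
    altering = cohort.variants["consequence"].isin(cfg.protein_altering_set)
    return set(cohort.variants.index[rare & altering])


def shared_in_family(cohort: CohortModel, variant: str, family_id: str) -> bool:
    """True iff every genotyped affected member of the family carries the variant.

    Affected members with missing genotypes drop from the denominator.
    Raises :class:`FamilyUninformative` when no affected member is genotyped.
    """
    counts = cohort.family_counts(variant, family_id)
    if counts["n_affected_genotyped"] == 0:
        raise FamilyUninformative(
            f"family {family_id!r} has no genotyped affected member for {variant}"
        )
    return counts["n_affected_carriers"] == counts["n_affected_genotyped"] >= 1


def build_panel(
    cohort: CohortModel,
    cfg: FilterConfig,
    literature: Iterable[str] = (),
    regions: Iterable[tuple[str, int, int]] = (),
    wes_families: Optional[Iterable[str]] = None,
) -> PanelSpec:
    """Assemble the targeted panel from the filtered discovery variants.

    A filtered variant enters the panel when it is shared by the affected
    members of at least one discovery (``wes_families``) family; literature
    variants and regions are carried through unchanged with their provenance.
    """
    families = list(wes_families) if wes_families is not None else list(cohort.pedigrees)
    filtered = filter_discovery(cohort, cfg)
    kept: set[str] = set()
    for v in sorted(filtered):
        for fam in families:
            try:
                if shared_in_family(cohort, v, fam):
                    kept.add(v)
                    break
            except FamilyUninformative:
                continue
    log.info("panel: %d/%d filtered variants shared in >=1 discovery family",
             len(kept), len(filtered))
    return PanelSpec(
        wes_candidates=kept,
        literature_variants=set(literature),
        regions=list(regions),
    )


def qc_targeted(cohort: CohortModel, cfg: FilterConfig,
                variants: Optional[Iterable[str]] = None) -> tuple[set[str], pd.DataFrame]:
    """Genotype-level QC over panel variants.

    Drops variants whose call rate falls below ``qc_min_call_rate`` or whose
    median read depth (when depths are available) falls below
    ``qc_min_depth``; the report lists each dropped variant with the reason.
    """
    keys = list(variants) if variants is not None else list(cohort.variants.index)
    idx = [cohort.variant_index(k) for k in keys]
    G = cohort.G[idx]
    genotyped = G != MISSING
    n_samples = G.shape[1]
    call_rate = genotyped.sum(axis=1) / max(n_samples, 1)

    rows = []
    kept: set[str] = set()
    for j, key in enumerate(keys):
        reasons = []
        if call_rate[j] < cfg.qc_min_call_rate:
            reasons.append(f"call rate {call_rate[j]:.3f} < {cfg.qc_min_call_rate}")
        med_depth = np.nan
        if cohort.D is not None:
            d = cohort.D[idx[j]]
            d = d[(d >= 0) & genotyped[j]]
            if d.size:
                med_depth = float(np.median(d))
                if med_depth < cfg.qc_min_depth:
                    reasons.append(f"median depth {med_depth:.0f} < {cfg.qc_min_depth}")
        if reasons:
            rows.append({"variant": key, "call_rate": call_rate[j],
                         "median_depth": med_depth, "reason": "; ".join(reasons)})
        else:
            kept.add(key)
    report = pd.DataFrame(rows, columns=["variant", "call_rate", "median_depth", "reason"])
    log.info("QC: kept %d/%d variants", len(kept), len(keys))
    return kept, report
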