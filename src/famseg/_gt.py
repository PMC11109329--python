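"""Shared genotype code alphabet.

Genotypes are stored in the cohort matrix as small integers so that carrier
and sharing computations can be vectorised; the string alphabet
(hom_ref/het/hom_alt/hemi_ref/hemi_alt/missing) is the public face.
Hemizygous codes are only valid on chrX (non-PAR males) and chrY.
"""

from __future__ import annotations

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2
HEMI_REF = 3
HEMI_ALT = 4

CODE_TO_NAME = {
    MISSING: "missing",
    HOM_REF: "hom_ref",
    HET: "het",
    HOM_ALT: "hom_alt",
    HEMI_REF: "hemi_ref",
    HEMI_ALT: "hemi_alt",
}
NAME_TO_CODE = {v: k for k, v in CODE_TO_NAME.items()}

CARRIER_CODES = frozenset({HET, HOM_ALT, HEMI_ALT})
REF_CODES = frozenset({HOM_REF, HEMI_REF})

#: alleles a genotype can transmit (alt allele coded 1)
TRANSMISSIBLE = {
    HOM_REF: (0,),
    HET: (0, 1),
    HOM_ALT: (1,),
    HEMI_REF: (0,),
    HEMI_ALT: (1,),
}

#: alt-allele dosage of a genotype
DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2, HEMI_REF: 0, HEMI_ALT: 1}


def as_code(genotype) -> int:
    """Coerce an int code or a string genotype name to an int code."""
    if isinstance(genotype, str):
        return NAME_TO_CODE[genotype]
    return int(genotype)


def is_x(chrom: str) -> bool:
    return str(chrom).removeprefix("chr").upper() == "X"


def is_y(chrom: str) -> bool:
    return str(chrom).removeprefix("chr").upper() == "Y"
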