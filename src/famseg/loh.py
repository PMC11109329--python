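"""Tumor/normal loss-of-heterozygosity screen at candidate loci.

At each germline-heterozygous site, the tumor vs normal ref/alt read counts
form a 2x2 table tested with a two-sided Fisher exact test; allelic
imbalance is summarised as the shift in tumor alt-allele fraction, and
significance across the screened loci is controlled with
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LOHInput:
    variant: str
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ("tumor_ref", "tumor_alt", "normal_ref", "normal_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.normal_ref == 0 or self.normal_alt == 0:
            raise ValueError(
                f"{self.variant}: normal sample must be heterozygous "
                "(both alleles observed)"
            )
        if self.tumor_ref + self.tumor_alt == 0:
            raise ValueError(f"{self.variant}: zero tumor depth")


def loh_test(x: LOHInput, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Fisher exact LOH test at one locus.

    Returns (two-sided p, tumor-minus-normal alt-fraction shift, flag at
    ``alpha``).  For a single locus the flag is the raw comparison; use
    :func:`loh_screen` for the Benjamini-Hochberg-adjusted flags across a
    panel of loci.
    """
    table = [[x.tumor_ref, x.tumor_alt], [x.normal_ref, x.normal_alt]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    shift = x.tumor_alt / (x.tumor_ref + x.tumor_alt) - x.normal_alt / (
        x.normal_ref + x.normal_alt
    )
    return p, float(shift), p < alpha


def loh_screen(inputs: Sequence[LOHInput], alpha: float = 0.05) -> pd.DataFrame:
    """LOH screen over many loci with Benjamini-Hochberg control at ``alpha``."""
    rows = []
    for x in inputs:
        p, shift, _ = loh_test(x, alpha)
        rows.append(
            {
                "variant": x.variant,
                "sample_id": x.sample_id,
                "p_value": p,
                "af_shift": shift,
            }
        )
    df = pd.DataFrame(rows, columns=["variant", "sample_id", "p_value", "af_shift"])
    if len(df):
        df["p_adjusted"] = stats.false_discovery_control(df["p_value"], method="bh")
        df["flagged"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = []
        df["flagged"] = []
    return df


def read_loh_inputs(path) -> list[LOHInput]:
    """Read an LOH read-count TSV: variant, sample_id, tumor_ref, tumor_alt,
    normal_ref, normal_alt."""
    df = pd.read_csv(path, sep="\t")
    return [
        LOHInput(
            variant=str(r.variant),
            sample_id=str(getattr(r, "sample_id", "")),
            tumor_ref=int(r.tumor_ref),
            tumor_alt=int(r.tumor_alt),
            normal_ref=int(r.normal_ref),
            normal_alt=int(r.normal_alt),
        )
        for r in df.itertuples(index=False)
    ]
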