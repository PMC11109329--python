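"""Family-design detection-power estimation.

For a variant present in a fraction ``p`` of families, sequencing ``n``
families detects it under the simple rule (any sequenced family carries it)
with probability 1 - (1-p)^n.  The Monte-Carlo estimator supports a
stricter detection rule in which a carrier family only counts when all of
its sampled affected members inherited the allele (gene-drop transmission
from a heterozygous founder, optionally enriched by penetrance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PowerDesign:
    n_families_sequenced: int
    p_carrier_family: float
    detection_rule: str = "any_family_carries"  # or shared_by_affected_in_a_family
    n_affected_sampled: int = 2
    #: prior probability that an offspring of the carrier founder inherits
    #: the allele (0.5 for children; lower for deeper relatives)
    offspring_carrier_prob: float = 0.5
    #: penetrance for carriers / sporadic rate for non-carriers; the default
    #: (equal rates) makes affection uninformative about carriage, i.e. the
    #: variant is an arbitrary tracked allele rather than the causal one
    penetrance: float = 1.0
    sporadic_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_families_sequenced < 1:
            raise ValueError("need at least one sequenced family")
        if not 0.0 <= self.p_carrier_family <= 1.0:
            raise ValueError("p_carrier_family must be in [0, 1]")
        if self.detection_rule not in ("any_family_carries", "shared_by_affected_in_a_family"):
            raise ValueError(f"unknown detection rule {self.detection_rule!r}")
        if self.n_affected_sampled < 1:
            raise ValueError("need at least one sampled affected per family")

    def carrier_prob_per_affected(self) -> float:
        """P(a sampled affected carries | carrier family), by Bayes over the
        offspring prior and the penetrance/sporadic rates."""
        q = self.offspring_carrier_prob
        f1, f0 = self.penetrance, self.sporadic_rate
        denom = q * f1 + (1.0 - q) * f0
        if denom == 0.0:
            return 0.0
        return q * f1 / denom


def power_closed_form(p: float, n: int) -> float:
    """Probability that >= 1 of n sequenced families carries the variant."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - p) ** n


def power_mc(design: PowerDesign, n_sim: int, seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo detection power with a normal-approximation 95% CI.

    Under ``any_family_carries`` a simulation detects when any sequenced
    family carries the variant; under ``shared_by_affected_in_a_family`` a
    carrier family additionally requires all of its sampled affected members
    to have inherited the allele.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    n = design.n_families_sequenced
    carries = rng.random((n_sim, n)) < design.p_carrier_family
    if design.detection_rule == "any_family_carries":
        detected = carries.any(axis=1)
    else:
        q = design.carrier_prob_per_affected()
        all_shared = (
            rng.random((n_sim, n, design.n_affected_sampled)) < q
        ).all(axis=2)
        detected = (carries & all_shared).any(axis=1)
    est = float(detected.mean())
    se = float(np.sqrt(est * (1.0 - est) / n_sim))
    return est, (max(0.0, est - 1.96 * se), min(1.0, est + 1.96 * se))
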