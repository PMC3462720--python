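"""Stage-profile classification into degrading, stable and activating transcripts.

A gene's four-stage EST distribution is classified by where its transcript
mass sits relative to the maternal-to-zygotic transition: degrading when at
least 95% of transcripts fall in the maternal stages (oocyte through
blastula), activating when at least 95% fall in blastula plus gastrula, and
stable when the gene is present in all four stages with every stage holding
between 10% and 40% of its transcripts.  Relaxed rules additionally admit
degrading genes with above 70% of transcripts in oocyte plus 1-2 cell,
activating genes with above 70% in gastrula alone, and widen the stable band
from 25 +/- 15% to 25 +/- 20%.  Profiles satisfying both directional (95%)
criteria at once — possible only when blastula dominates — are flagged
ambiguous rather than resolved by precedence; a directional class does take
precedence over a coincidental fit of the widened stable band, mirroring
how the relaxed criteria were built around oocyte/1-2 cell and gastrula
proportions specifically to avoid multi-category assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from estmzt.core import ValidationError, require

__all__ = [
    "ClassRules",
    "ClassifiedGene",
    "STRICT_RULES",
    "RELAXED_RULES",
    "stage_proportions",
    "classify",
    "class_census",
]

CLASSES = ("degrading", "stable", "activating", "ambiguous", "unclassified")


@dataclass(frozen=True)
class ClassRules:
    maternal_min: float = 0.95
    zygotic_min: float = 0.95
    stable_lo: float = 0.10
    stable_hi: float = 0.40
    relaxed: bool = False
    relaxed_early_min: float = 0.70
    relaxed_gastrula_min: float = 0.70
    relaxed_stable_lo: float = 0.05
    relaxed_stable_hi: float = 0.45

    def __post_init__(self) -> None:
        require(0.0 <= self.stable_lo < self.stable_hi <= 1.0, "need 0 <= lo < hi <= 1")
        require(0.5 < self.maternal_min <= 1.0, "maternal_min must be in (0.5, 1]")
        require(0.5 < self.zygotic_min <= 1.0, "zygotic_min must be in (0.5, 1]")

    @property
    def version(self) -> str:
        return "relaxed" if self.relaxed else "strict"


STRICT_RULES = ClassRules()
RELAXED_RULES = ClassRules(relaxed=True)


@dataclass
class ClassifiedGene:
    gene_id: str
    transcript_class: str
    proportions: tuple[float, float, float, float]
    rule_version: str
    qualifying: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        require(self.transcript_class in CLASSES, f"unknown class {self.transcript_class}")
        require(abs(sum(self.proportions) - 1.0) <= 1e-9, "proportions must sum to 1")


def stage_proportions(counts: Sequence[int]) -> tuple[float, float, float, float]:
    """Counts normalized to per-stage fractions (sum to 1)."""
    arr = np.asarray(counts, dtype=float)
    require(arr.shape == (4,), "expected 4 stage counts")
    require((arr >= 0).all(), "counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValidationError("stage_proportions: total count is zero")
    p = arr / total
    return (float(p[0]), float(p[1]), float(p[2]), float(p[3]))


def classify(
    counts: Sequence[int], rules: ClassRules = STRICT_RULES, gene_id: str = ""
) -> ClassifiedGene:
    """Classify one gene's four-stage count profile.

    Boundary conventions: the 95% maternal/zygotic minima are inclusive
    (>=), as are the 10%/40% stable bounds; the relaxed 70% additions are
    strict (>), following their "above 70%" phrasing.  Stable additionally
    requires a nonzero count in every stage (presence in all four
    libraries).
    """
    o, c, b, g = (int(x) for x in counts)
    p = stage_proportions((o, c, b, g))
    po, pc, pb, pg = p

    qualifying: list[str] = []
    degrading = (po + pc + pb) >= rules.maternal_min
    activating = (pb + pg) >= rules.zygotic_min
    lo, hi = rules.stable_lo, rules.stable_hi
    if rules.relaxed:
        degrading = degrading or (po + pc) > rules.relaxed_early_min
        activating = activating or pg > rules.relaxed_gastrula_min
        lo, hi = rules.relaxed_stable_lo, rules.relaxed_stable_hi
    stable = (
        o > 0 and c > 0 and b > 0 and g > 0
        and all(lo <= x <= hi for x in p)
    )
    if degrading:
        qualifying.append("degrading")
    if stable:
        qualifying.append("stable")
    if activating:
        qualifying.append("activating")

    # A directional class takes precedence over a coincidental stable-band
    # fit (possible only under the widened relaxed band); ambiguity is
    # reserved for profiles satisfying both directional criteria at once.
    effective = [q for q in qualifying if q != "stable"] or qualifying
    if len(effective) == 0:
        cls = "unclassified"
    elif len(effective) == 1:
        cls = effective[0]
    else:
        cls = "ambiguous"
    return ClassifiedGene(
        gene_id=gene_id,
        transcript_class=cls,
        proportions=p,
        rule_version=rules.version,
        qualifying=tuple(qualifying),
    )


def class_census(classified: Iterable[ClassifiedGene]) -> dict[str, int]:
    """Tally genes per class; values sum to the input length."""
    census = {cls: 0 for cls in CLASSES}
    for cg in classified:
        census[cg.transcript_class] += 1
    return census
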