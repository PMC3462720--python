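"""Polyadenylation-signal hexamer scanning over 3'UTR sequences.

The canonical signal AATAAA plus eleven single-substitution variants are
searched as exact substrings on the sense strand of each UTR isoform.
Summaries report, per transcript class, the proportion of UTR records
containing each motif and the prevalence of multiple distinct motifs —
presence of a motif type is binary, occurrence counts are recorded but not
used in the class summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from estmzt.core import require
from estmzt.utr import UtrRecord

__all__ = [
    "DEFAULT_CATALOGUE",
    "MotifProfile",
    "scan_motifs",
    "motif_summary_by_class",
    "profile_utr_records",
]

#: Canonical polyadenylation hexamer followed by 11 putative alternatives.
DEFAULT_CATALOGUE: tuple[str, ...] = (
    "AATAAA",
    "ATTAAA",
    "AGTAAA",
    "TATAAA",
    "CATAAA",
    "GATAAA",
    "AATATA",
    "AATACA",
    "AATAGA",
    "ACTAAA",
    "AAGAAA",
    "AATGAA",
)


def validate_catalogue(catalogue: Sequence[str]) -> tuple[str, ...]:
    cat = tuple(catalogue)
    require(len(cat) == len(set(cat)), "catalogue entries must be unique")
    for motif in cat:
        require(len(motif) == 6, f"motif {motif!r} is not a hexamer")
        require(set(motif) <= set("ACGT"), f"motif {motif!r} has invalid bases")
    return cat


@dataclass
class MotifProfile:
    utr_id: str
    presence: dict[str, bool]
    occurrence_counts: dict[str, int] = field(default_factory=dict)
    transcript_class: str = "unclassified"

    @property
    def n_distinct_motifs(self) -> int:
        return sum(self.presence.values())

    @property
    def multi_motif(self) -> bool:
        return self.n_distinct_motifs >= 2


def _count_overlapping(sequence: str, motif: str) -> int:
    count = 0
    start = sequence.find(motif)
    while start != -1:
        count += 1
        start = sequence.find(motif, start + 1)
    return count


def scan_motifs(
    sequence: str,
    catalogue: Sequence[str] = DEFAULT_CATALOGUE,
    utr_id: str = "",
    window: int | None = None,
) -> MotifProfile:
    """Exact-substring scan of one sense-strand UTR sequence.

    Overlapping occurrences count; presence per motif is binary.  An
    optional ``window`` restricts the scan to the last ``window`` nt
    (positional analysis of the canonical signal); default scans the whole
    UTR.  Sequences shorter than 6 nt yield an all-absent profile with a
    warning.
    """
    cat = validate_catalogue(catalogue)
    seq = sequence.upper()
    require(set(seq) <= set("ACGTN"), "sequence alphabet must be A/C/G/T/N")
    if window is not None:
        seq = seq[-window:]
    if len(seq) < 6:
        if sequence:
            warnings.warn(f"UTR {utr_id or '<anonymous>'} shorter than 6 nt; no motif scan")
        return MotifProfile(utr_id=utr_id, presence={m: False for m in cat},
                            occurrence_counts={m: 0 for m in cat})
    counts = {m: _count_overlapping(seq, m) for m in cat}
    return MotifProfile(
        utr_id=utr_id,
        presence={m: c > 0 for m, c in counts.items()},
        occurrence_counts=counts,
    )


def profile_utr_records(
    records: Iterable[UtrRecord],
    catalogue: Sequence[str] = DEFAULT_CATALOGUE,
    window: int | None = None,
) -> list[MotifProfile]:
    profiles = []
    for rec in records:
        profile = scan_motifs(
            rec.sequence, catalogue, utr_id=f"{rec.gene_id}|{rec.isoform_index}", window=window
        )
        profile.transcript_class = rec.transcript_class
        profiles.append(profile)
    return profiles


def motif_summary_by_class(
    profiles: Iterable[MotifProfile],
    catalogue: Sequence[str] = DEFAULT_CATALOGUE,
) -> pd.DataFrame:
    """Per-class, per-motif presence proportions plus multi-motif prevalence.

    Denominators are UTR records (isoforms included) in each class; empty
    classes are simply absent from the table.
    """
    cat = validate_catalogue(catalogue)
    by_class: dict[str, list[MotifProfile]] = {}
    for p in profiles:
        by_class.setdefault(p.transcript_class, []).append(p)
    rows = []
    for cls in sorted(by_class):
        members = by_class[cls]
        n = len(members)
        row: dict = {"class": cls, "n": n}
        for motif in cat:
            row[motif] = sum(p.presence[motif] for p in members) / n
        row["any_motif"] = sum(p.n_distinct_motifs >= 1 for p in members) / n
        row["multi_motif"] = sum(p.multi_motif for p in members) / n
        rows.append(row)
    return pd.DataFrame(rows)
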