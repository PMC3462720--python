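"""Published per-stage EST counts for Atlantic cod egg/embryo libraries.

Worked-example inputs: stage-resolved EST counts (oocyte, 1-2 cell,
blastula, gastrula) for three published gene sets from staged cod cDNA
libraries — the 20 most abundant transcripts overall (five mitochondrial),
the 17 transcripts present in the gastrula library only, and the 20 most
abundant transcripts found in maternal libraries only.  Each row is
(gene name, printed total, oocyte, cell_1_2, blastula, gastrula); repeated
"Unknown" entries are suffixed to keep identifiers unique.
"""

from __future__ import annotations

from estmzt.core import StageCountMatrix

__all__ = [
    "TOP20_ALL",
    "TOP20_MITO_GENES",
    "GASTRULA_ONLY_17",
    "MATERNAL_ONLY_20",
    "as_matrix",
]

# The 20 most abundant transcripts across all four libraries.
TOP20_ALL: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("Cytochrome c oxidase subunit II", 3418, 910, 1293, 881, 334),
    ("Cytochrome B", 563, 137, 114, 263, 49),
    ("Cytochrome c oxidase subunit I", 353, 90, 110, 119, 34),
    ("ATP synthase F0 subunit 8", 176, 36, 45, 84, 11),
    ("ATP synthase F0 subunit 6", 144, 32, 45, 50, 17),
    ("H2A Histone family, member V", 463, 94, 208, 82, 79),
    ("Tetraspanin 3", 185, 3, 20, 159, 3),
    ("Small nuclear ribonucleoprotein polypeptide E", 133, 25, 34, 7, 67),
    ("Ribosomal protein S20", 128, 2, 1, 2, 123),
    ("Ribosomal protein S12", 111, 7, 1, 1, 102),
    ("Ribosomal protein S23", 106, 0, 0, 0, 106),
    ("Ribosomal protein L34", 103, 4, 4, 16, 79),
    ("CDKN2A interacting protein N-terminal like", 103, 27, 28, 19, 29),
    ("COX17 cytochrome c oxidase assembly homolog", 101, 60, 28, 13, 0),
    ("Unknown-1", 97, 46, 48, 2, 1),
    ("Small nuclear ribonucleoprotein D3 polypeptide 18kDa", 95, 16, 36, 32, 11),
    ("Small nuclear ribonucleoprotein polypeptide F", 84, 10, 8, 63, 3),
    ("Mago-nashi homolog B", 78, 10, 25, 39, 4),
    ("Unknown-2", 78, 0, 0, 0, 78),
    ("Unknown-3", 74, 2, 0, 3, 69),
)

#: Mitochondrial entries of TOP20_ALL (the first five rows).
TOP20_MITO_GENES: tuple[str, ...] = tuple(name for name, *_ in TOP20_ALL[:5])

# The 17 transcripts present in the gastrula library only.
GASTRULA_ONLY_17: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("Ribosomal protein S23", 106, 0, 0, 0, 106),
    ("Unknown-1", 78, 0, 0, 0, 78),
    ("Ribosomal protein L27a", 58, 0, 0, 0, 58),
    ("Ribosomal protein L28", 54, 0, 0, 0, 54),
    ("Unknown-2", 50, 0, 0, 0, 50),
    ("Ribosomal protein L18a", 48, 0, 0, 0, 48),
    ("Ribosomal protein L24", 48, 0, 0, 0, 48),
    ("Ribosomal protein S27", 48, 0, 0, 0, 48),
    ("Ribosomal protein S19", 46, 0, 0, 0, 46),
    ("Unknown-3", 41, 0, 0, 0, 41),
    ("Unknown-4", 40, 0, 0, 0, 40),
    ("Ribosomal protein L31", 36, 0, 0, 0, 36),
    ("Ribosomal protein S7", 30, 0, 0, 0, 30),
    ("Ribosomal protein, large, P2", 26, 0, 0, 0, 26),
    ("Ribosomal protein, large, P1", 14, 0, 0, 0, 14),
    ("Ubiquitin A-52 residue ribosomal protein fusion product 1", 12, 0, 0, 0, 12),
    ("Small nucleolar RNA, C/D box 68", 9, 0, 0, 0, 9),
)

# The 20 most abundant transcripts found in maternal libraries only.
MATERNAL_ONLY_20: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("COX17 Cytochrome c oxidase assembly homolog", 101, 60, 28, 13, 0),
    ("Stathmin 1", 61, 14, 25, 22, 0),
    ("Adenylosuccinate synthase like 1", 49, 10, 36, 3, 0),
    ("S100 calcium binding protein A1", 41, 9, 26, 6, 0),
    ("THAP domain containing 4", 34, 10, 16, 8, 0),
    ("Unknown-1", 25, 7, 0, 18, 0),
    ("Uncharacterized protein C14orf119", 24, 0, 1, 23, 0),
    ("Unknown-2", 20, 6, 9, 5, 0),
    ("Claudin 4", 20, 9, 6, 5, 0),
    ("Unknown-3", 20, 8, 4, 8, 0),
    ("LSM12 homolog", 19, 3, 15, 1, 0),
    ("UPF0139 membrane protein C19orf56", 17, 2, 11, 4, 0),
    ("Topoisomerase (DNA) I", 17, 10, 5, 2, 0),
    ("Unknown-4", 17, 7, 4, 6, 0),
    ("Unknown-5", 17, 14, 1, 2, 0),
    ("Cyclin A1", 15, 2, 6, 7, 0),
    ("Protein NIMA-interacting 4 (parvulin)", 15, 5, 2, 8, 0),
    ("Cyclin A2", 15, 3, 1, 11, 0),
    ("H1 histone family, member O, oocyte-specific", 14, 5, 3, 6, 0),
    ("Unknown-6", 12, 4, 7, 1, 0),
)


def as_matrix(
    rows: tuple[tuple[str, int, int, int, int, int], ...],
    mito_genes: tuple[str, ...] = (),
) -> StageCountMatrix:
    """Build a StageCountMatrix from a bundled reference table."""
    counts = {name: (o, c, b, g) for name, _total, o, c, b, g in rows}
    mito = {name: name in mito_genes for name in counts}
    return StageCountMatrix.from_records(counts, mito=mito)


def printed_totals(
    rows: tuple[tuple[str, int, int, int, int, int], ...],
) -> dict[str, int]:
    return {name: total for name, total, *_ in rows}
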