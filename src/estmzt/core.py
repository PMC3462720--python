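"""Shared constants and the stage count matrix container."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Developmental stages in library order: unfertilized egg, first cleavage,
#: pre-MZT blastula, post-MZT gastrula.
STAGES: tuple[str, str, str, str] = ("oocyte", "cell_1_2", "blastula", "gastrula")

#: The first three stages, dominated by maternally deposited transcripts.
MATERNAL_STAGES: tuple[str, str, str] = ("oocyte", "cell_1_2", "blastula")

Stage = str


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass
class StageCountMatrix:
    """Genes x 4 developmental stages integer EST counts.

    ``counts`` is indexed by gene_id with the four stage columns in fixed
    order; ``mito`` and ``pseudogene`` are boolean flags aligned to the same
    index.
    """

    counts: pd.DataFrame
    mito: pd.Series = field(default=None)  # type: ignore[assignment]
    pseudogene: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(STAGES):
            raise ValidationError(
                f"count matrix columns must be {STAGES}, got {list(self.counts.columns)}"
            )
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.mito is None:
            self.mito = pd.Series(False, index=self.counts.index)
        if self.pseudogene is None:
            self.pseudogene = pd.Series(False, index=self.counts.index)
        self.mito = self.mito.reindex(self.counts.index, fill_value=False).astype(bool)
        self.pseudogene = self.pseudogene.reindex(self.counts.index, fill_value=False).astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        """Per-gene total EST count across the four stages."""
        return self.counts.sum(axis=1)

    def stage_total(self, stage: Stage) -> int:
        return int(self.counts[stage].sum())

    @classmethod
    def from_records(
        cls,
        rows: Mapping[str, Iterable[int]],
        mito: Mapping[str, bool] | None = None,
        pseudogene: Mapping[str, bool] | None = None,
    ) -> "StageCountMatrix":
        df = pd.DataFrame.from_dict(
            {g: list(v) for g, v in rows.items()}, orient="index", columns=list(STAGES)
        ).astype(np.int64)
        return cls(
            counts=df,
            mito=pd.Series(mito) if mito else None,
            pseudogene=pd.Series(pseudogene) if pseudogene else None,
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out["is_mito"] = self.mito.astype(int)
        out["is_pseudogene"] = self.pseudogene.astype(int)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StageCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
        mito = df["is_mito"].astype(bool) if "is_mito" in df else None
        pseudo = df["is_pseudogene"].astype(bool) if "is_pseudogene" in df else None
        return cls(counts=df[list(STAGES)].astype(np.int64), mito=mito, pseudogene=pseudo)
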