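"""Per-genome protein inventories (id, amino-acid length, COG category)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CATALOG_COLUMNS = ("protein_id", "length", "cog")

#: Pseudo-category used for proteins without a COG assignment, so that
#: functional summaries conserve counts.
UNANNOTATED = "-"


@dataclass
class ProteinCatalog:
    """Protein inventory of one genome.

    ``table`` has columns ``protein_id`` (unique), ``length`` (amino acids,
    positive) and ``cog`` (single-letter category or ``-``).  ``sequences``
    optionally maps protein id to amino-acid sequence.
    """

    genome: str
    table: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CATALOG_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog table missing columns: {sorted(missing)}")
        if self.table["protein_id"].duplicated().any():
            raise ValueError(f"duplicate protein ids in catalog {self.genome!r}")
        if (self.table["length"] <= 0).any():
            bad = self.table.loc[self.table["length"] <= 0, "protein_id"].tolist()
            raise ValueError(f"non-positive protein lengths for: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def protein_ids(self) -> pd.Index:
        return pd.Index(self.table["protein_id"])

    def lengths(self) -> pd.Series:
        return self.table.set_index("protein_id")["length"]

    def cogs(self) -> pd.Series:
        return self.table.set_index("protein_id")["cog"]

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, genome: str | None = None) -> "ProteinCatalog":
        table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "cog": str})
        name = genome if genome is not None else Path(path).stem
        return cls(genome=name, table=table)

    def to_fasta(self, path: str | Path) -> None:
        """Write sequences as FASTA (requires ``sequences`` to be populated)."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequences[pid]), id=pid, description=self.genome)
            for pid in self.table["protein_id"]
            if pid in self.sequences
        ]
        SeqIO.write(records, str(path), "fasta")
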