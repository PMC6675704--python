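"""Overlapping-peptide tiling of protein antigens.

Serological peptide microarrays print a panel of short peptides that tile an
antigen with a fixed length and a fixed start-to-start offset, so that every
residue is covered and adjacent peptides share an overlap (for a 20-mer panel
at offset 10, a 10-residue overlap).  This module decomposes an antigen into
such a panel and, conversely, reassembles an antigen sequence from an
overlapping panel, which is how panel coordinates are validated.

Coordinates are 1-based and inclusive throughout, matching how peptide panels
are conventionally tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "PeptideTile",
    "tile_protein",
    "assemble_from_tiles",
    "read_fasta",
    "write_tiles_tsv",
    "read_tiles_tsv",
    "write_tiles_fasta",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence (uppercase, standard 20-letter alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """One peptide of a tiling panel, with 1-based inclusive coordinates."""

    index: int
    start: int
    end: int
    sequence: str
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"tile {self.name!r}: invalid span {self.start}-{self.end}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"tile {self.name!r}: span {self.start}-{self.end} does not match "
                f"sequence length {len(self.sequence)}"
            )


def tile_protein(
    protein: ProteinRecord, tile_length: int = 20, offset: int = 10
) -> list[PeptideTile]:
    """Tile a protein into overlapping peptides of ``tile_length`` every ``offset``.

    Tile *i* starts at position ``1 + (i-1)*offset``; the number of tiles is
    ``ceil((L - tile_length)/offset) + 1``.  The final tile is truncated so
    that it ends exactly at the last residue — it is never extended past the
    sequence and its start is never shifted back, so a terminal tile may be
    shorter than ``tile_length``.

    Raises ``ValueError`` if the protein is shorter than ``tile_length`` or
    the parameters do not satisfy ``tile_length >= offset >= 1``.
    """
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    if tile_length < offset:
        raise ValueError(
            f"tile_length ({tile_length}) must be >= offset ({offset}); "
            "larger offsets would leave residues uncovered"
        )
    L = len(protein)
    if L < tile_length:
        raise ValueError(
            f"protein {protein.id!r} has {L} residues, shorter than the "
            f"tile length {tile_length}; cannot tile"
        )
    n_tiles = math.ceil((L - tile_length) / offset) + 1
    tiles = []
    for i in range(1, n_tiles + 1):
        start = 1 + (i - 1) * offset
        end = min(start + tile_length - 1, L)
        tiles.append(
            PeptideTile(
                index=i,
                start=start,
                end=end,
                sequence=protein.sequence[start - 1 : end],
                name=f"{protein.id}-{i:02d}",
            )
        )
    return tiles


def assemble_from_tiles(
    tiles: Sequence[PeptideTile], protein_id: str | None = None
) -> ProteinRecord:
    """Reconstruct an antigen sequence from an ordered overlapping panel.

    Consecutive tiles must overlap by at least one residue and all tiles must
    agree wherever they overlap; a gap or a residue conflict raises
    ``ValueError`` naming the offending position.
    """
    if not tiles:
        raise ValueError("cannot assemble from an empty panel")
    length = max(t.end for t in tiles)
    residues: list[str | None] = [None] * length
    covered_end = 0
    for t in tiles:
        if covered_end and t.start > covered_end:
            raise ValueError(
                f"gap between assembled positions {covered_end} and {t.start} "
                f"(tile {t.name!r} does not overlap its predecessor)"
            )
        for pos, aa in zip(range(t.start, t.end + 1), t.sequence):
            prev = residues[pos - 1]
            if prev is not None and prev != aa:
                raise ValueError(
                    f"conflicting residues at position {pos}: "
                    f"{prev!r} vs {aa!r} (tile {t.name!r})"
                )
            residues[pos - 1] = aa
        covered_end = max(covered_end, t.end)
    if tiles[0].start != 1 or any(r is None for r in residues):
        raise ValueError("panel does not cover every position from 1")
    if protein_id is None:
        # common "antigen-NN" naming: strip the ordinal suffix if shared
        prefixes = {t.name.rsplit("-", 1)[0] for t in tiles}
        protein_id = prefixes.pop() if len(prefixes) == 1 else "assembled"
    return ProteinRecord(id=protein_id, sequence="".join(residues))  # type: ignore[arg-type]


def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinRecord:
    """Read one protein from a (possibly multi-record) FASTA file.

    With ``record_id=None`` the file must contain exactly one record.
    """
    records = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records present; select one of "
                f"{sorted(records)} by id"
            )
        record = next(iter(records.values()))
    else:
        try:
            record = records[record_id]
        except KeyError:
            raise ValueError(f"{path}: record {record_id!r} not found") from None
    return ProteinRecord(id=record.id, sequence=str(record.seq).upper())


def write_tiles_tsv(tiles: Iterable[PeptideTile], path: str | Path) -> None:
    """Write a panel as a TSV with columns name, start, end, sequence."""
    frame = pd.DataFrame(
        [(t.name, t.start, t.end, t.sequence) for t in tiles],
        columns=["name", "start", "end", "sequence"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_tiles_tsv(path: str | Path) -> list[PeptideTile]:
    frame = pd.read_csv(path, sep="\t")
    required = {"name", "start", "end", "sequence"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PeptideTile(
            index=i + 1,
            start=int(row.start),
            end=int(row.end),
            sequence=str(row.sequence),
            name=str(row.name_),
        )
        for i, row in enumerate(
            frame.rename(columns={"name": "name_"}).itertuples(index=False)
        )
    ]


def write_tiles_fasta(tiles: Iterable[PeptideTile], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.name, description=f"{t.start}-{t.end}")
        for t in tiles
    ]
    SeqIO.write(records, str(path), "fasta")
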