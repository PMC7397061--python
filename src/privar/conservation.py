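"""Cross-species conservation of a protein residue.

Given a protein multiple alignment and a residue index in one reference
sequence, map the residue to its alignment column and score the column
by binary identity: the fraction of non-gap rows matching the reference
residue.  ``strictly_conserved`` means every non-gap row agrees — the
kind of evidence usually shown for a candidate causal missense variant.

Scoring is deliberately identity-only (no substitution-matrix
similarity, no phylogenetic weighting): the claim being tested is strict
conservation, and the fraction stays directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

GAP = "-"


class ConservationError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Aligned amino-acid sequences keyed by species/sequence id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ConservationError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ConservationError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MultipleAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls({rec.id: str(rec.seq).upper() for rec in aln})

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class ConservationResult:
    """Identity score of one alignment column against a reference residue."""

    column: int  # 1-based alignment column
    reference_residue: str
    n_sequences: int  # non-gap rows at the column
    fraction_identical: float

    @property
    def strictly_conserved(self) -> bool:
        return self.fraction_identical == 1.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tresidue\tn_species\tfraction_identical\tstrictly_conserved\n")
            fh.write(
                f"{self.column}\t{self.reference_residue}\t{self.n_sequences}\t"
                f"{self.fraction_identical:.6g}\t{self.strictly_conserved}\n"
            )


def map_residue_to_column(
    msa: MultipleAlignment, seq_id: str, residue_index: int
) -> int:
    """1-based alignment column of the residue_index-th non-gap character."""
    try:
        row = msa.sequences[seq_id]
    except KeyError:
        raise ConservationError(f"sequence {seq_id!r} not in alignment") from None
    if residue_index < 1:
        raise ConservationError(f"residue_index must be >= 1, got {residue_index}")
    seen = 0
    for col, char in enumerate(row, start=1):
        if char != GAP:
            seen += 1
            if seen == residue_index:
                return col
    raise ConservationError(
        f"residue_index {residue_index} beyond ungapped length {seen} of {seq_id!r}"
    )


def column_conservation(
    msa: MultipleAlignment, ref_seq_id: str, residue_index: int
) -> ConservationResult:
    """Score the column holding a reference residue by identity fraction.

    Gap rows are excluded from the denominator; the reference sequence's
    own row is included.
    """
    col = map_residue_to_column(msa, ref_seq_id, residue_index)
    ref_char = msa.sequences[ref_seq_id][col - 1]
    chars = [row[col - 1] for row in msa.sequences.values() if row[col - 1] != GAP]
    if not chars:
        raise ConservationError(f"alignment column {col} is all gaps")
    frac = sum(1 for c in chars if c == ref_char) / len(chars)
    return ConservationResult(
        column=col,
        reference_residue=ref_char,
        n_sequences=len(chars),
        fraction_identical=frac,
    )
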