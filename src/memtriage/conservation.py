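"""Per-position evolutionary conservation from a multiple sequence alignment.

The conservation (EC) score of a reference position is the fraction of
aligned sequences whose residue at that column is identical to the
reference residue.  Positions where the reference row has a gap carry no
reference residue and are skipped.  Gaps in non-reference rows count as
mismatches; the denominator is the total number of rows (the reference
included by default, so every scored position has EC > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from Bio import AlignIO

from .profiles import ResidueProfile

GAP_CHARS = frozenset("-.")


@dataclass
class Alignment:
    """Gapped, equal-length sequences with a designated reference row."""

    sequences: List[Tuple[str, str]]  # (id, gapped sequence)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if self.reference_id not in {sid for sid, _ in self.sequences}:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def reference_seq(self) -> str:
        for sid, seq in self.sequences:
            if sid == self.reference_id:
                return seq
        raise AssertionError("unreachable")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)


def read_alignment(path, reference_id: str | None = None, fmt: str | None = None) -> Alignment:
    """Load an aligned FASTA or Clustal file.

    If ``reference_id`` is None the first row is taken as the reference.
    Format is sniffed from the first line unless ``fmt`` is given
    (``"fasta"`` or ``"clustal"``).
    """
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    msa = AlignIO.read(path, fmt)
    sequences = [(rec.id, str(rec.seq).upper()) for rec in msa]
    if reference_id is None:
        reference_id = sequences[0][0]
    return Alignment(sequences=sequences, reference_id=reference_id)


def ec_score(alignment: Alignment, include_reference: bool = True) -> ResidueProfile:
    """Identity fraction per ungapped reference position.

    ``include_reference=False`` drops the reference row from both the
    numerator and the denominator (scores then live in [0, 1]).
    """
    ref = alignment.reference_seq
    rows = [seq for sid, seq in alignment.sequences
            if include_reference or sid != alignment.reference_id]
    n_total = len(rows)
    if n_total == 0:
        raise ValueError("no rows to score against")

    scores = {}
    ref_pos = 0
    for col, ref_aa in enumerate(ref):
        if ref_aa in GAP_CHARS:
            continue
        ref_pos += 1
        n_identity = sum(1 for seq in rows
                         if seq[col] not in GAP_CHARS and seq[col].upper() == ref_aa.upper())
        scores[ref_pos] = n_identity / n_total
    return ResidueProfile(values=scores, units="fraction")


def conserved_mask(profile: ResidueProfile, threshold: float = 0.9) -> ResidueProfile:
    """Boolean profile: strictly greater than ``threshold``."""
    return ResidueProfile(
        values={r: float(v > threshold) for r, v in profile.values.items()},
        units="bool",
    )
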