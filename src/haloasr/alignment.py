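"""Protein alignments (20-state alphabet + gap) and the column filters of the pipeline.

Columns are filtered two ways: gappy columns (more than a fraction of gaps,
default 20%) are dropped after family alignment, and fast-evolving columns
are stripped in 10%-of-sites steps ranked by posterior mean rate to reduce
systematic error near the root of the species tree.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # PAML dat-file state order, fixed everywhere
GAP = "-"
UNKNOWN = "X"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Fixed-length rows over the amino-acid alphabet plus gap.

    ``names`` keeps input order; lookup by name is O(1).
    """

    names: list[str]
    rows: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise AlignmentError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("rows have unequal lengths")
        allowed = set(AMINO_ACIDS + GAP + UNKNOWN)
        for name, row in zip(self.names, self.rows):
            bad = set(row) - allowed
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in {name!r}")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        """Number of columns."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __getitem__(self, name: str) -> str:
        return self.rows[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(list(self.names), ["".join(r[j] for j in cols) for r in self.rows])

    # -- FASTA / PHYLIP ----------------------------------------------------
    @classmethod
    def from_fasta(cls, handle) -> "Alignment":
        if isinstance(handle, str):
            with open(handle) as fh:
                return cls.from_fasta(fh)
        names, rows = [], []
        for rec in SeqIO.parse(handle, "fasta"):
            names.append(rec.id)  # name up to first whitespace
            rows.append(str(rec.seq).upper())
        if not names:
            raise AlignmentError("empty FASTA")
        return cls(names, rows)

    def to_fasta(self, handle=None) -> Optional[str]:
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(self.names, self.rows)
        ]
        if handle is None:
            buf = io.StringIO()
            SeqIO.write(records, buf, "fasta")
            return buf.getvalue()
        if isinstance(handle, str):
            with open(handle, "w") as fh:
                SeqIO.write(records, fh, "fasta")
            return None
        SeqIO.write(records, handle, "fasta")
        return None

    def to_phylip(self) -> str:
        """Relaxed PHYLIP (name, two spaces, full row)."""
        out = [f" {self.n_rows} {len(self)}"]
        for name, row in zip(self.names, self.rows):
            out.append(f"{name}  {row}")
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# column filters


def filter_gappy_columns(
    alignment: Alignment, max_gap_fraction: float = 0.2
) -> tuple[Alignment, list[int]]:
    """Drop columns with strictly more than ``max_gap_fraction`` gaps.

    Returns the filtered alignment and the surviving original column indices.
    A column with exactly the threshold fraction of gaps is kept.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise AlignmentError("max_gap_fraction outside [0, 1]")
    n = alignment.n_rows
    keep = [
        j
        for j in range(len(alignment))
        if alignment.column(j).count(GAP) / n <= max_gap_fraction
    ]
    return alignment.take_columns(keep), keep


def remove_fast_sites(
    alignment: Alignment, rates: Sequence[float], fraction: float
) -> tuple[Alignment, list[int]]:
    """Remove the ``floor(fraction * L)`` columns with the highest posterior mean rate.

    Ties are broken by removing the lower column index first; surviving columns
    keep their original order. Returns (alignment, surviving original indices).
    """
    if not 0 <= fraction <= 1:
        raise AlignmentError("fraction outside [0, 1]")
    L = len(alignment)
    if len(rates) != L:
        raise AlignmentError("rates length does not match alignment length")
    n_remove = math.floor(fraction * L)
    # sort by (-rate, index): highest rate first, lower index first among ties
    order = sorted(range(L), key=lambda j: (-rates[j], j))
    removed = set(order[:n_remove])
    keep = [j for j in range(L) if j not in removed]
    return alignment.take_columns(keep), keep


def concatenate_alignments(
    families: Iterable[Alignment], taxon_set: Sequence[str]
) -> tuple[Alignment, list[tuple[int, int]]]:
    """Concatenate gene-family alignments over a shared taxon set.

    Taxa absent from a family get a gap block of that family's length.
    Returns the concatenation and the (start, end) half-open block boundaries.
    """
    taxon_set = list(taxon_set)
    parts: dict[str, list[str]] = {t: [] for t in taxon_set}
    blocks: list[tuple[int, int]] = []
    pos = 0
    for fam in families:
        unknown = set(fam.names) - set(taxon_set)
        if unknown:
            raise AlignmentError(f"family taxa {sorted(unknown)} not in taxon set")
        L = len(fam)
        for t in taxon_set:
            parts[t].append(fam[t] if t in fam else GAP * L)
        blocks.append((pos, pos + L))
        pos += L
    return Alignment(taxon_set, ["".join(parts[t]) for t in taxon_set]), blocks
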