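"""Evolution-based arm: alignment statistics, conservation, redundancy
reduction and back-to-consensus mutation calling.

The back-to-consensus strategy proposes mutating a wild-type residue to the
residue most frequent at that position across homologues, whenever the two
differ and the majority residue clears a frequency cutoff (0.5 here,
inclusive).  Conservation is scored per column from Shannon entropy of the
amino-acid frequency vector; a greedy identity-threshold clustering provides
CD-HIT-style redundancy reduction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ColumnProfile:
    """Residue tally of one alignment column (1-based ``column``)."""

    column: int
    counts: dict[str, int]
    gap_count: int
    depth: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.gap_count != self.depth:
            raise ValueError("column profile counts do not sum to depth")


@dataclass(frozen=True)
class ConsensusCall:
    """A back-to-consensus mutation proposal in query (precursor) numbering.

    ``frequency`` is the fraction of *all* alignment rows (gaps included in
    the denominator) carrying the consensus residue.
    """

    position: int
    wt_residue: str
    consensus_residue: str
    frequency: float

    @property
    def mutation(self) -> str:
        return f"{self.wt_residue}{self.position}{self.consensus_residue}"


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores in [0, 1]; 1 = invariant column.

    ``unreliable`` flags columns with more than 50% gaps, where the
    frequency vector rests on few observations.
    """

    scores: np.ndarray
    unreliable: np.ndarray
    rule: str = "1 - H/ln(20), gaps excluded from frequencies"


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with a designated query row."""

    ids: list[str]
    rows: list[str]
    query_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
        if self.query_id not in self.ids:
            raise ValueError(f"query {self.query_id!r} not in alignment")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.ids.index(self.query_id)]

    def query_positions(self) -> dict[int, int]:
        """Map 1-based alignment column -> 1-based ungapped query position.

        Columns where the query is gapped are absent from the map.
        """
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.query_row, start=1):
            if ch != GAP:
                pos += 1
                mapping[col] = pos
        return mapping


def read_alignment(path: str | Path, query_id: str) -> Alignment:
    """Read an aligned FASTA file, preserving record order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Alignment(ids=ids, rows=rows, query_id=query_id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def column_profile(aln: Alignment, column: int) -> ColumnProfile:
    """Exact residue counts of one 1-based alignment column."""
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} out of range 1..{aln.length}")
    chars = [row[column - 1] for row in aln.rows]
    gap_count = sum(c == GAP for c in chars)
    counts = dict(Counter(c for c in chars if c != GAP))
    return ColumnProfile(
        column=column, counts=counts, gap_count=gap_count, depth=aln.depth
    )


def conservation_profile(aln: Alignment) -> ConservationProfile:
    """Entropy-based conservation: score = 1 - H/ln(20) per column.

    H is the Shannon entropy of the residue frequency vector with gaps
    excluded.  An all-gap column scores 0 and is flagged unreliable, as is
    any column with more than 50% gaps.
    """
    hmax = math.log(len(AMINO_ACIDS))
    scores = np.zeros(aln.length)
    unreliable = np.zeros(aln.length, dtype=bool)
    for col in range(1, aln.length + 1):
        prof = column_profile(aln, col)
        n = sum(prof.counts.values())
        if prof.gap_count > aln.depth / 2:
            unreliable[col - 1] = True
        if n == 0:
            scores[col - 1] = 0.0
            continue
        freqs = np.array(list(prof.counts.values()), dtype=float) / n
        h = float(-(freqs * np.log(freqs)).sum())
        scores[col - 1] = 1.0 - h / hmax
    return ConservationProfile(scores=scores, unreliable=unreliable)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where both rows are non-gap."""
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def reduce_redundancy(aln: Alignment, identity_threshold: float = 0.9) -> Alignment:
    """Greedy identity clustering; keeps one representative per cluster.

    Sequences are visited in descending ungapped-length order (ties keep the
    original order).  A sequence joins the first existing cluster whose
    representative shares identity >= threshold, otherwise it founds a new
    cluster.  The query row is always retained.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(
        range(aln.depth),
        key=lambda i: (-len(aln.rows[i].replace(GAP, "")), i),
    )
    reps: list[int] = []
    for i in order:
        for r in reps:
            if pairwise_identity(aln.rows[i], aln.rows[r]) >= identity_threshold:
                break
        else:
            reps.append(i)
    keep = set(reps)
    keep.add(aln.ids.index(aln.query_id))
    kept = sorted(keep)
    return Alignment(
        ids=[aln.ids[i] for i in kept],
        rows=[aln.rows[i] for i in kept],
        query_id=aln.query_id,
    )


def back_to_consensus(aln: Alignment, cutoff: float = 0.5) -> list[ConsensusCall]:
    """Call consensus mutations against the query row.

    For each column where the query is non-gap, the most frequent non-gap
    residue is the consensus if its frequency over *all* rows is >= cutoff
    (inclusive).  A call is emitted when the consensus differs from the
    query residue.  Frequency ties (possible only at exactly cutoff = 0.5)
    break to the alphabetically earlier one-letter code.  Positions are
    reported in ungapped query (precursor) numbering.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    query = aln.query_row
    pos_map = aln.query_positions()
    calls: list[ConsensusCall] = []
    for col, qpos in pos_map.items():
        wt = query[col - 1]
        prof = column_profile(aln, col)
        if not prof.counts:
            continue
        # top count; alphabetical tie-break
        best = min(prof.counts, key=lambda r: (-prof.counts[r], r))
        freq = prof.counts[best] / aln.depth
        if freq >= cutoff and best != wt:
            calls.append(
                ConsensusCall(
                    position=qpos, wt_residue=wt, consensus_residue=best,
                    frequency=freq,
                )
            )
    return sorted(calls, key=lambda c: c.position)


def calls_to_table(calls: Iterable[ConsensusCall]):
    """Consensus calls as a pandas DataFrame (position, wt, consensus, frequency)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "position": c.position,
                "wt": c.wt_residue,
                "consensus": c.consensus_residue,
                "frequency": round(c.frequency, 2),
            }
            for c in calls
        ]
    )
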