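"""Energy-based arm and merged candidate selection.

Mutations predicted by external ΔΔG calculators (Rosetta, FoldX) are read
from tables; the energy arm admits mutations with ΔΔG_Rosetta <= -1.0
kcal/mol, the evolution (consensus) arm is gated by ΔΔG_FoldX <= 0.5
kcal/mol, and both arms honour exclusion masks for conserved, functionally
relevant and ion-pairing positions.  Coordinates are precursor numbering
(signal peptide included); a stored offset maps to the mature protein.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

from .alignment import AMINO_ACIDS, ConsensusCall

logger = logging.getLogger(__name__)

STABILIZING_DDG = -1.0   # kcal/mol, inclusive
DESTABILIZING_DDG = 1.0  # kcal/mol, exclusive
CONSENSUS_FOLDX_MAX = 0.5  # kcal/mol

#: residues 1-28 of the precursor are the cleaved signal peptide
SIGNAL_PEPTIDE_LENGTH = 28

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A point mutation in 1-based precursor coordinates."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self}: wild-type and mutant residues equal")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-canonical residue {aa!r}")
        if self.position < 1:
            raise ValueError("position must be 1-based positive")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(position=int(m.group(2)), wt_aa=m.group(1), mut_aa=m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class DdgRecord:
    """Predicted folding free-energy changes for one mutation (kcal/mol)."""

    mutation: MutationSpec
    ddg_rosetta: float | None = None
    ddg_foldx: float | None = None

    def __post_init__(self) -> None:
        if self.ddg_rosetta is None and self.ddg_foldx is None:
            raise ValueError(f"{self.mutation}: no ΔΔG value present")


@dataclass
class ExclusionMask:
    """Positions excluded from the design, by provenance."""

    conserved_positions: set[int] = field(default_factory=set)
    functional_positions: set[int] = field(default_factory=set)
    ion_pair_positions: set[int] = field(default_factory=set)

    def reason_for(self, position: int) -> str | None:
        if position in self.conserved_positions:
            return "conserved position"
        if position in self.functional_positions:
            return "functionally relevant position"
        if position in self.ion_pair_positions:
            return "ion interaction"
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExclusionMask":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            conserved_positions=set(raw.get("conserved_positions", [])),
            functional_positions=set(raw.get("functional_positions", [])),
            ion_pair_positions=set(raw.get("ion_pair_positions", [])),
        )


Source = Literal["energy", "consensus", "both"]


@dataclass(frozen=True)
class Candidate:
    mutation: MutationSpec
    source: Source
    ddg_rosetta: float | None = None
    ddg_foldx: float | None = None
    consensus_frequency: float | None = None


@dataclass
class CandidateSet:
    candidates: list[Candidate] = field(default_factory=list)
    rejected: list[tuple[MutationSpec, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def positions(self) -> set[int]:
        return {c.mutation.position for c in self.candidates}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mutation": str(c.mutation),
                    "position": c.mutation.position,
                    "wt": c.mutation.wt_aa,
                    "mut": c.mutation.mut_aa,
                    "source": c.source,
                    "ddg_rosetta": c.ddg_rosetta,
                    "ddg_foldx": c.ddg_foldx,
                    "consensus_frequency": c.consensus_frequency,
                }
                for c in self.candidates
            ]
        )


def classify_ddg(
    ddg: float,
    stab_threshold: float = STABILIZING_DDG,
    destab_threshold: float = DESTABILIZING_DDG,
) -> str:
    """Partition a ΔΔG value into stabilizing / neutral / destabilizing.

    Stabilizing is inclusive (ddg <= stab_threshold), destabilizing strict
    (ddg > destab_threshold); everything between is neutral.
    """
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValueError("non-finite ΔΔG")
    if ddg <= stab_threshold:
        return "stabilizing"
    if ddg > destab_threshold:
        return "destabilizing"
    return "neutral"


def energy_candidates(
    records: Sequence[DdgRecord],
    mask: ExclusionMask | None = None,
    stab_threshold: float = STABILIZING_DDG,
) -> CandidateSet:
    """Energy arm: mutations with ΔΔG_Rosetta <= threshold at unmasked positions.

    Records at masked positions or without a Rosetta value are dropped with a
    logged reason, never raised.  Output sorted ascending by ΔΔG_Rosetta
    (most stabilizing first).
    """
    mask = mask or ExclusionMask()
    out = CandidateSet()
    for rec in records:
        pos = rec.mutation.position
        reason = mask.reason_for(pos)
        if reason is not None:
            logger.info("energy arm: %s dropped (%s)", rec.mutation, reason)
            out.rejected.append((rec.mutation, reason))
            continue
        if rec.ddg_rosetta is None:
            reason = "missing ΔΔG_Rosetta (fail closed)"
            logger.info("energy arm: %s dropped (%s)", rec.mutation, reason)
            out.rejected.append((rec.mutation, reason))
            continue
        if rec.ddg_rosetta <= stab_threshold:
            out.candidates.append(
                Candidate(
                    mutation=rec.mutation, source="energy",
                    ddg_rosetta=rec.ddg_rosetta, ddg_foldx=rec.ddg_foldx,
                )
            )
        else:
            out.rejected.append(
                (rec.mutation, f"ΔΔG_Rosetta {rec.ddg_rosetta} above threshold")
            )
    out.candidates.sort(key=lambda c: (c.ddg_rosetta, str(c.mutation)))
    return out


def consensus_candidates(
    calls: Sequence[ConsensusCall],
    records: Sequence[DdgRecord],
    mask: ExclusionMask | None = None,
    foldx_max: float = CONSENSUS_FOLDX_MAX,
) -> CandidateSet:
    """Evolution arm: consensus calls gated by ΔΔG_FoldX <= foldx_max and masks.

    A call with no matching ΔΔG record, or a missing FoldX value, fails
    closed with a logged reason.
    """
    mask = mask or ExclusionMask()
    by_mut = {
        (r.mutation.position, r.mutation.mut_aa): r for r in records
    }
    out = CandidateSet()
    for call in calls:
        mut = MutationSpec(
            position=call.position, wt_aa=call.wt_residue,
            mut_aa=call.consensus_residue,
        )
        reason = mask.reason_for(call.position)
        if reason is not None:
            logger.info("consensus arm: %s dropped (%s)", mut, reason)
            out.rejected.append((mut, reason))
            continue
        rec = by_mut.get((call.position, call.consensus_residue))
        if rec is None or rec.ddg_foldx is None:
            reason = "missing ΔΔG_FoldX (fail closed)"
            logger.info("consensus arm: %s dropped (%s)", mut, reason)
            out.rejected.append((mut, reason))
            continue
        if rec.ddg_foldx <= foldx_max:
            out.candidates.append(
                Candidate(
                    mutation=mut, source="consensus",
                    ddg_rosetta=rec.ddg_rosetta, ddg_foldx=rec.ddg_foldx,
                    consensus_frequency=call.frequency,
                )
            )
        else:
            out.rejected.append(
                (mut, f"ΔΔG_FoldX {rec.ddg_foldx} exceeds {foldx_max}")
            )
    out.candidates.sort(key=lambda c: c.mutation.position)
    return out


def merge_candidates(energy: CandidateSet, consensus: CandidateSet) -> CandidateSet:
    """Union keyed by (position, mutant residue); overlaps become source='both'.

    Every ΔΔG value and consensus frequency from either arm is retained.
    """
    merged: dict[tuple[int, str], Candidate] = {}
    for c in energy.candidates + consensus.candidates:
        key = (c.mutation.position, c.mutation.mut_aa)
        if key not in merged:
            merged[key] = c
            continue
        prev = merged[key]
        merged[key] = Candidate(
            mutation=prev.mutation,
            source="both" if prev.source != c.source else prev.source,
            ddg_rosetta=prev.ddg_rosetta if prev.ddg_rosetta is not None else c.ddg_rosetta,
            ddg_foldx=prev.ddg_foldx if prev.ddg_foldx is not None else c.ddg_foldx,
            consensus_frequency=(
                prev.consensus_frequency
                if prev.consensus_frequency is not None
                else c.consensus_frequency
            ),
        )
    out = CandidateSet(rejected=energy.rejected + consensus.rejected)
    out.candidates = sorted(
        merged.values(), key=lambda c: (c.mutation.position, c.mutation.mut_aa)
    )
    return out


def apply_mutations(
    sequence: str,
    numbering_offset: int,
    mutations: Iterable[MutationSpec],
) -> str:
    """Apply point mutations to a sequence; order of application is irrelevant.

    ``numbering_offset`` converts precursor numbering to sequence index:
    sequence index (1-based) = position - numbering_offset.  Use 0 for a
    precursor sequence and SIGNAL_PEPTIDE_LENGTH (28) for the mature protein.
    """
    chars = list(sequence)
    for mut in mutations:
        idx = mut.position - numbering_offset
        if not 1 <= idx <= len(sequence):
            raise IndexError(
                f"{mut}: position maps to index {idx}, outside 1..{len(sequence)}"
            )
        found = chars[idx - 1]
        if found != mut.wt_aa:
            raise ValueError(
                f"{mut}: expected {mut.wt_aa} at position {mut.position}, "
                f"found {found}"
            )
        chars[idx - 1] = mut.mut_aa
    return "".join(chars)


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """Read a ΔΔG CSV with columns position, wt, mut, ddg_rosetta, ddg_foldx."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            DdgRecord(
                mutation=MutationSpec(
                    position=int(row["position"]), wt_aa=str(row["wt"]),
                    mut_aa=str(row["mut"]),
                ),
                ddg_rosetta=None if pd.isna(row.get("ddg_rosetta")) else float(row["ddg_rosetta"]),
                ddg_foldx=None if pd.isna(row.get("ddg_foldx")) else float(row["ddg_foldx"]),
            )
        )
    return records
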