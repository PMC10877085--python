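"""Seeded synthetic-data generators for every input class the pipeline
consumes: alignments with exact planted column compositions, two-state melt
curves with planted Tm, 4PL dose-response data with planted ED50, toy
structures with planted ion pairs, and rigidly perturbed conformer
ensembles with recorded ground-truth RMSDs.

All generators are pure functions of (parameters, seed).  Planted
quantities are realized exactly in noiseless mode, which is what makes
them usable as recovery oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .alignment import AMINO_ACIDS, GAP, Alignment
from .bioactivity import DoseResponse, four_pl
from .geometry import (
    AtomRecord,
    ConformerEnsemble,
    StructureModel,
)
from .thermal import MeltCurve, two_state_ratio


@dataclass(frozen=True)
class ColumnSpec:
    """Exact residue composition planted at one alignment column.

    ``position`` is the 1-based precursor coordinate; with an ungapped
    query row it coincides with the alignment column.
    """

    position: int
    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        for res, count in self.composition.items():
            if res != GAP and res not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {res!r}")
            if count < 0:
                raise ValueError("negative count")

    @property
    def depth(self) -> int:
        return sum(self.composition.values())


#: channel baselines: (folded intercept, folded drift, unfolded intercept,
#: unfolded drift) in arbitrary fluorescence units.  Chosen so the 350/330
#: ratio increases through the transition AND is itself an exact two-state
#: logistic with its inflection at Tm: the 330 channel is a flat reference
#: and the 350 channel uses equal folded/unfolded drifts, so dividing by
#: f330 and differentiating leave the midpoint untouched.
DEFAULT_BASELINES: dict[int, tuple[float, float, float, float]] = {
    330: (1.00, 0.0, 1.00, 0.0),
    350: (0.70, -0.0004, 1.00, -0.0004),
}


@dataclass(frozen=True)
class MeltCurveParams:
    tm: float                      # °C
    slope: float = 1.0             # °C transition width
    baselines: Mapping[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    noise_sd: float = 0.0          # fluorescence units
    temp_start: float = 20.0       # °C
    temp_stop: float = 90.0        # °C
    temp_step: float = 0.5         # °C

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.temp_start < self.tm < self.temp_stop:
            raise ValueError("tm must lie strictly inside the temperature range")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.temp_start, self.temp_stop + 1e-9, self.temp_step)

    def amplitude(self, channel: int) -> float:
        bf, df, bu, du = self.baselines[channel]
        return abs((bu + du * self.tm) - (bf + df * self.tm))


@dataclass(frozen=True)
class DoseResponseParams:
    ed50: float                    # ng/ml
    hill: float = 1.0
    top: float = 1000.0            # fluorescence units
    bottom: float = 100.0
    doses: tuple[float, ...] = tuple(np.geomspace(0.1, 1000.0, 8))
    replicates: int = 3
    noise_sd: float = 0.0          # fluorescence units

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")


def gen_alignment(
    specs: Sequence[ColumnSpec],
    depth: int,
    seed: int,
    length: int | None = None,
    background: Mapping[str, float] | None = None,
    query_seq: str | None = None,
    query_id: str = "query",
) -> Alignment:
    """Alignment with exact planted column compositions.

    Residues are placed deterministically per column (the query row, if
    given, takes its own residue first), then rows other than the query are
    shuffled under the seed, so realized counts equal the spec exactly.
    Unspecified columns are drawn i.i.d. from ``background`` (uniform over
    the 20 amino acids by default); the query row keeps ``query_seq``
    everywhere.
    """
    if query_seq is not None:
        length = len(query_seq)
    if length is None:
        raise ValueError("need length or query_seq")
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate column positions in specs")
    for s in specs:
        if not 1 <= s.position <= length:
            raise ValueError(f"column {s.position} outside 1..{length}")
        if s.depth != depth:
            raise ValueError(
                f"column {s.position}: composition sums to {s.depth}, "
                f"expected depth {depth}"
            )
    rng = np.random.default_rng(seed)
    bg_res = list(background or {aa: 1.0 for aa in AMINO_ACIDS})
    bg_p = np.array([(background or {aa: 1.0 for aa in AMINO_ACIDS})[r] for r in bg_res])
    bg_p = bg_p / bg_p.sum()
    spec_by_col = {s.position: s for s in specs}

    n_free = depth - (1 if query_seq is not None else 0)
    matrix = np.empty((depth, length), dtype="<U1")
    for col in range(1, length + 1):
        if col in spec_by_col:
            comp = dict(spec_by_col[col].composition)
            if query_seq is not None:
                q = query_seq[col - 1]
                if comp.get(q, 0) < 1:
                    raise ValueError(
                        f"column {col}: query residue {q!r} absent from "
                        "planted composition"
                    )
                comp[q] -= 1
            stack = [r for r in sorted(comp) for _ in range(comp[r])]
        else:
            stack = list(rng.choice(bg_res, size=n_free, p=bg_p))
        if query_seq is not None:
            column = [query_seq[col - 1]] + stack
        else:
            column = stack
        matrix[:, col - 1] = column
    # one row permutation for the whole matrix keeps rows coherent and
    # column compositions exact; the query row stays first
    if query_seq is not None:
        perm = np.concatenate([[0], 1 + rng.permutation(depth - 1)])
    else:
        perm = rng.permutation(depth)
    matrix = matrix[perm]
    rows = ["".join(matrix[i]) for i in range(depth)]
    if query_seq is not None:
        ids = [query_id] + [f"seq_{i:04d}" for i in range(1, depth)]
        qid = query_id
    else:
        ids = [f"seq_{i:04d}" for i in range(1, depth + 1)]
        qid = ids[0]
    return Alignment(ids=ids, rows=rows, query_id=qid)


def gen_melt_curve(params: MeltCurveParams, seed: int) -> MeltCurve:
    """Two-state melt curve at 330 and 350 nm with planted Tm.

    Per channel, F(T) = base_f(T) + (base_u(T) - base_f(T)) /
    (1 + exp((tm - T)/slope)); Gaussian noise of sd ``noise_sd`` is added
    independently per point and channel.
    """
    rng = np.random.default_rng(seed)
    T = params.grid
    channels = {}
    for ch in (330, 350):
        bf, df, bu, du = params.baselines[ch]
        signal = two_state_ratio(T, bf, df, bu, du, params.tm, params.slope)
        if params.noise_sd > 0:
            signal = signal + rng.normal(0.0, params.noise_sd, size=T.shape)
        channels[ch] = signal
    return MeltCurve(temperatures=T, f330=channels[330], f350=channels[350])


def gen_dose_response(params: DoseResponseParams, seed: int) -> DoseResponse:
    """Replicate 4PL dose-response data with planted ED50."""
    rng = np.random.default_rng(seed)
    doses = np.asarray(params.doses, dtype=float)
    mean = four_pl(doses, params.bottom, params.top, params.ed50, params.hill)
    responses = np.tile(mean[:, None], (1, params.replicates))
    if params.noise_sd > 0:
        responses = responses + rng.normal(
            0.0, params.noise_sd, size=responses.shape
        )
    return DoseResponse(
        doses=doses,
        responses=responses,
        metadata={"planted_ed50": params.ed50, "planted_hill": params.hill},
    )


def gen_toy_structure(
    n_residues: int,
    planted_pairs: Sequence[tuple[int, int, float]],
    seed: int = 0,
) -> StructureModel:
    """Cα trace with charged side-chain pseudo-atoms planted at exact
    ion-pair distances.

    Residues sit 10 Å apart on a line; each planted (acidic, basic,
    distance) triple makes the acidic residue an Asp (OD1/OD2) and the
    basic one a Lys whose NZ is placed so the minimum charged-atom
    distance equals the requested value.  The layout guarantees that no
    unplanted acidic/basic pair comes under 7 Å.  The geometry is a
    detection fixture, not a physical model.
    """
    planted_res: dict[int, str] = {}
    for a, b, d in planted_pairs:
        if not (1 <= a <= n_residues and 1 <= b <= n_residues) or a == b:
            raise ValueError(f"invalid pair indices ({a}, {b})")
        if d <= 0:
            raise ValueError(f"planted distance {d} is not realizable")
        if a in planted_res or b in planted_res:
            raise ValueError("each residue may appear in at most one pair")
        planted_res[a] = "ASP"
        planted_res[b] = "LYS"

    def ca_pos(i: int) -> tuple[float, float, float]:
        # widely spaced, non-collinear trace: 10 Å stride plus a zig-zag
        return (10.0 * (i - 1), 2.0 * (i % 2), 1.5 * (i % 3))

    atoms: list[AtomRecord] = []
    for i in range(1, n_residues + 1):
        name = planted_res.get(i, "ALA")
        atoms.append(AtomRecord(i, name, "CA", *ca_pos(i)))
    for a, b, d in planted_pairs:
        xa, ya, za = ca_pos(a)
        # carboxylate oxygens near the acidic Cα; the basic amine sits on
        # the same x lane at exactly d from OD1 (and farther from OD2)
        atoms.append(AtomRecord(a, "ASP", "OD1", xa, ya + 3.0, za))
        atoms.append(AtomRecord(a, "ASP", "OD2", xa, ya + 3.0, za + 1.4))
        atoms.append(AtomRecord(b, "LYS", "NZ", xa, ya + 3.0 + d, za))
    model = StructureModel(atoms=atoms)
    _validate_planted(model, planted_pairs)
    return model


def _validate_planted(
    model: StructureModel, planted_pairs: Sequence[tuple[int, int, float]]
) -> None:
    from .geometry import detect_ion_pairs

    planted = {(a, b): d for a, b, d in planted_pairs}
    found = {
        (p.acidic_index, p.basic_index): p.min_distance
        for p in detect_ion_pairs(model, cutoff=7.0)
    }
    for key, d in found.items():
        if key not in planted:
            raise ValueError(
                f"layout infeasible: unplanted pair {key} at {d:.2f} Å"
            )
    for key, d in planted.items():
        if d <= 7.0 and abs(found.get(key, np.inf) - d) > 0.01:
            raise ValueError(f"planted pair {key} not realized at {d} Å")


def perturb_ensemble(
    model: StructureModel,
    n_conformers: int,
    noise_sd: float,
    seed: int,
) -> ConformerEnsemble:
    """Rigidly rotated/translated copies of a model with isotropic Gaussian
    coordinate noise.

    The per-conformer ground-truth RMSD after optimal superposition is
    recorded in ``metadata['planted_rmsd']``, computed directly with
    scipy's Rotation.align_vectors on the noisy vs. original coordinates
    (the rigid motion itself cannot change it).
    """
    rng = np.random.default_rng(seed)
    X = model.coords()
    conformers = []
    planted = []
    for _ in range(n_conformers):
        E = (
            rng.normal(0.0, noise_sd, size=X.shape)
            if noise_sd > 0
            else np.zeros_like(X)
        )
        noisy = X + E
        R = Rotation.random(random_state=rng)
        t = rng.normal(0.0, 5.0, size=3)
        moved = R.apply(noisy) + t
        atoms = [
            AtomRecord(a.res_index, a.res_name, a.atom_name, *xyz)
            for a, xyz in zip(model.atoms, moved)
        ]
        conformers.append(StructureModel(atoms=atoms, chain_id=model.chain_id))
        if noise_sd == 0:
            planted.append(0.0)  # rigid motion alone is removed exactly
        else:
            a0 = noisy - noisy.mean(axis=0)
            b0 = X - X.mean(axis=0)
            _, rssd = Rotation.align_vectors(a0, b0)
            planted.append(float(rssd / np.sqrt(X.shape[0])))
    return ConformerEnsemble(
        conformers=conformers,
        metadata={"planted_rmsd": planted, "noise_sd": noise_sd, "seed": seed},
    )
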