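"""Structural geometry: Kabsch superposition / Cα RMSD against conformer
ensembles, salt-bridge (ion-pair) detection between charged side-chain
atoms, and distance-based polar-contact comparison.

PDB reading and writing go through gemmi; only ATOM records of a single
chain are used, alternate locations resolve to the highest-occupancy copy,
and MODEL blocks yield a conformer ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

#: charged side-chain atoms considered for salt bridges
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}

ION_PAIR_CUTOFF = 6.0  # Å, between charged side-chain atoms
POLAR_CONTACT_CUTOFF = 3.5  # Å, N/O donor-acceptor distance


@dataclass(frozen=True)
class AtomRecord:
    res_index: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """A single-chain structure as a flat list of atom records."""

    atoms: list[AtomRecord]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        keys = [(a.res_index, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue, atom) keys")
        coords = self.coords()
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    def coords(
        self,
        atom_names: Sequence[str] | None = None,
        positions: Iterable[int] | None = None,
    ) -> np.ndarray:
        sel = self.select(atom_names, positions)
        return np.array([[a.x, a.y, a.z] for a in sel]).reshape(-1, 3)

    def select(
        self,
        atom_names: Sequence[str] | None = None,
        positions: Iterable[int] | None = None,
    ) -> list[AtomRecord]:
        pos = set(positions) if positions is not None else None
        return [
            a
            for a in self.atoms
            if (atom_names is None or a.atom_name in atom_names)
            and (pos is None or a.res_index in pos)
        ]

    def atom_map(self) -> dict[tuple[int, str], AtomRecord]:
        return {(a.res_index, a.atom_name): a for a in self.atoms}

    def residue_names(self) -> dict[int, str]:
        return {a.res_index: a.res_name for a in self.atoms}


@dataclass
class ConformerEnsemble:
    """Conformers sharing residue numbering, e.g. the models of an NMR entry."""

    conformers: list[StructureModel]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("negative RMSD")


@dataclass(frozen=True)
class IonPair:
    acidic_index: int
    basic_index: int
    min_distance: float


@dataclass(frozen=True)
class PolarContact:
    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    distance: float

    @property
    def key(self) -> tuple[int, str, int, str]:
        return (self.res_i, self.atom_i, self.res_j, self.atom_j)


@dataclass(frozen=True)
class EnsembleRmsd:
    conformer: int
    rmsd: float
    n_atoms: int


# ---------------------------------------------------------------------------
# PDB input / output


def _model_from_gemmi(model: gemmi.Model, chain: str | None) -> StructureModel:
    chains = {ch.name: ch for ch in model}
    if not chains:
        raise ValueError("no ATOM records in file")
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found (have {sorted(chains)})")
    best: dict[tuple[int, str], tuple[float, AtomRecord]] = {}
    for res in chains[chain]:
        for atom in res:
            key = (res.seqid.num, atom.name)
            rec = AtomRecord(
                res_index=res.seqid.num, res_name=res.name, atom_name=atom.name,
                x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
            )
            # altloc resolution: keep the highest-occupancy copy
            if key not in best or atom.occ > best[key][0]:
                best[key] = (atom.occ, rec)
    if not best:
        raise ValueError(f"no ATOM records in chain {chain!r}")
    atoms = [rec for _, (_, rec) in sorted(best.items(), key=lambda kv: kv[0])]
    return StructureModel(atoms=atoms, chain_id=chain)


def read_structure(
    path: str | Path, chain: str | None = None
) -> StructureModel | ConformerEnsemble:
    """Read ATOM records of one chain; multi-MODEL files give an ensemble."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    models = [_model_from_gemmi(m, chain) for m in st]
    if len(models) == 1:
        return models[0]
    return ConformerEnsemble(conformers=models)


def _to_gemmi_model(model: StructureModel, name: str) -> gemmi.Model:
    gm = gemmi.Model(name)
    ch = gemmi.Chain(model.chain_id)
    by_res: dict[int, list[AtomRecord]] = {}
    for a in model.atoms:
        by_res.setdefault(a.res_index, []).append(a)
    for idx in sorted(by_res):
        res = gemmi.Residue()
        res.name = by_res[idx][0].res_name
        res.seqid = gemmi.SeqId(idx, " ")
        res.het_flag = "A"
        for a in by_res[idx]:
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.pos = gemmi.Position(a.x, a.y, a.z)
            atom.occ = 1.0
            element = a.atom_name[0] if a.atom_name[0] in "CNOSH" else "C"
            atom.element = gemmi.Element(element)
            res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    return gm


def write_structure(
    obj: StructureModel | ConformerEnsemble, path: str | Path
) -> None:
    """Write a minimal PDB file; ensembles become MODEL blocks."""
    st = gemmi.Structure()
    models = obj.conformers if isinstance(obj, ConformerEnsemble) else [obj]
    for i, m in enumerate(models, start=1):
        st.add_model(_to_gemmi_model(m, str(i)))
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition


def superpose_kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired coordinate sets.

    Returns the proper rotation R (reflection corrected) and translation t
    minimizing ||(mobile @ R.T + t) - target||, with the minimized RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) with equal n")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    t = qc - R @ pc
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def rmsd_to_ensemble(
    model: StructureModel,
    ensemble: ConformerEnsemble,
    atom_names: Sequence[str] = ("CA",),
    positions: Iterable[int] | None = None,
) -> list[EnsembleRmsd]:
    """Superpose each conformer onto the model over a common atom selection."""
    pos = set(positions) if positions is not None else None
    keys = [
        (a.res_index, a.atom_name)
        for a in model.select(atom_names, pos)
    ]
    common = [
        k
        for k in keys
        if all(k in c.atom_map() for c in ensemble.conformers)
    ]
    if not common:
        raise ValueError("empty common atom selection")
    target = np.array([model.atom_map()[k].xyz for k in common])
    out = []
    for i, conf in enumerate(ensemble.conformers, start=1):
        amap = conf.atom_map()
        mob = np.array([amap[k].xyz for k in common])
        res = superpose_kabsch(mob, target)
        out.append(EnsembleRmsd(conformer=i, rmsd=res.rmsd, n_atoms=res.n_atoms))
    return out


# ---------------------------------------------------------------------------
# Interaction detection


def _charged_atoms(
    model: StructureModel, table: dict[str, tuple[str, ...]]
) -> tuple[list[int], np.ndarray]:
    """Residue indices and coordinates of charged side-chain atoms."""
    res_idx: list[int] = []
    coords: list[np.ndarray] = []
    amap = model.atom_map()
    for idx, name in model.residue_names().items():
        if name not in table:
            continue
        found = [amap[(idx, an)] for an in table[name] if (idx, an) in amap]
        if not found:
            warnings.warn(
                f"residue {name}{idx} lacks charged side-chain atoms; skipped"
            )
            continue
        for a in found:
            res_idx.append(idx)
            coords.append(a.xyz)
    return res_idx, np.array(coords).reshape(-1, 3)


def detect_ion_pairs(
    model: StructureModel,
    cutoff: float = ION_PAIR_CUTOFF,
    include_his: bool = True,
) -> list[IonPair]:
    """Salt bridges: acidic/basic residue pairs with minimum charged-atom
    distance <= cutoff.  Each unordered pair is reported once, sorted by
    residue indices."""
    basic_table = dict(BASIC_ATOMS)
    if not include_his:
        basic_table.pop("HIS")
    ai, ac = _charged_atoms(model, ACIDIC_ATOMS)
    bi, bc = _charged_atoms(model, basic_table)
    if not ai or not bi:
        return []
    dmat = cdist(ac, bc)
    best: dict[tuple[int, int], float] = {}
    for r, arow in enumerate(ai):
        for c, brow in enumerate(bi):
            key = (arow, brow)
            d = dmat[r, c]
            if key not in best or d < best[key]:
                best[key] = d
    return sorted(
        (
            IonPair(acidic_index=a, basic_index=b, min_distance=float(d))
            for (a, b), d in best.items()
            if d <= cutoff
        ),
        key=lambda p: (p.acidic_index, p.basic_index),
    )


def detect_polar_contacts(
    model: StructureModel, donor_acceptor_cutoff: float = POLAR_CONTACT_CUTOFF
) -> list[PolarContact]:
    """Distance-only polar contacts between N/O atoms of different residues.

    A deliberately simple proxy for hydrogen bonding: no angle terms, no
    donor/acceptor chemistry, one unordered contact per atom pair.
    """
    polar = [a for a in model.atoms if a.atom_name[:1] in ("N", "O")]
    if not polar:
        return []
    coords = np.array([a.xyz for a in polar])
    dmat = cdist(coords, coords)
    out: list[PolarContact] = []
    for i in range(len(polar)):
        for j in range(i + 1, len(polar)):
            a, b = polar[i], polar[j]
            if a.res_index == b.res_index:
                continue
            if dmat[i, j] <= donor_acceptor_cutoff:
                first, second = sorted(
                    [(a.res_index, a.atom_name), (b.res_index, b.atom_name)]
                )
                out.append(
                    PolarContact(
                        res_i=first[0], atom_i=first[1],
                        res_j=second[0], atom_j=second[1],
                        distance=float(dmat[i, j]),
                    )
                )
    return sorted(out, key=lambda c: c.key)


def diff_contacts(
    a: list[PolarContact], b: list[PolarContact]
) -> tuple[list[PolarContact], list[PolarContact]]:
    """Contacts present in exactly one structure: (gained in b, lost from a)."""
    akeys = {c.key for c in a}
    bkeys = {c.key for c in b}
    gained = [c for c in b if c.key not in akeys]
    lost = [c for c in a if c.key not in bkeys]
    return gained, lost
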