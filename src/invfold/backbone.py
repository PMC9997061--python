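"""Backbone structure I/O and virtual-Cb geometry.

Reads protein backbones (N, Ca, C, O per residue) from PDB/mmCIF via gemmi,
places an idealised beta carbon from the backbone triad so featurisation is
independent of the (unknown) sequence, and writes design outputs as FASTA.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

from .errors import DegenerateGeometryError, EmptyStructureError, FormatError

__all__ = [
    "ATOM_NAMES",
    "BackboneStructure",
    "place_virtual_cb",
    "compute_virtual_cb",
    "read_backbone",
    "write_pdb",
    "write_designs",
]

ATOM_NAMES = ("N", "CA", "C", "O")

# Ideal-tetrahedral expansion of Cb in the (b x c, b, c) frame with
# b = Ca - N, c = C - Ca.  Standard ideal-geometry placement.
_CB_W1 = -0.58273431
_CB_W2 = 0.56802827
_CB_W3 = -0.54067466

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclasses.dataclass
class BackboneStructure:
    """Per-residue backbone coordinates for one or more chains.

    coords holds N/Ca/C/O positions in Å, shape (n_residues, 4, 3) in the
    order of :data:`ATOM_NAMES`; `cb` the virtual beta carbon.  Residues are
    indexed 0-based and contiguously across chains; author numbering is kept
    only for I/O (`residue_numbers`).  Residues missing any of N/Ca/C are
    flagged invalid via `residue_mask` and excluded from the neighbor graph;
    a missing O keeps the residue but zeroes its O-distance features.
    """

    chain_ids: list[str]
    residue_numbers: list[list[str]]
    coords: np.ndarray
    cb: np.ndarray
    atom_mask: np.ndarray
    residue_mask: np.ndarray
    chain_index: np.ndarray
    chain_pos: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    def chain_lengths(self) -> list[int]:
        return [int((self.chain_index == c).sum()) for c in range(self.n_chains)]

    def position_of(self, key: str) -> int:
        """Resolve a 'A12' style chain+author-number key to a 0-based index."""
        chain, num = key[0], key[1:].strip()
        if chain not in self.chain_ids:
            raise KeyError(f"no chain {chain!r} in structure")
        ci = self.chain_ids.index(chain)
        for offset, rn in enumerate(self.residue_numbers[ci]):
            if rn == num:
                return int(np.nonzero(self.chain_index == ci)[0][offset])
        raise KeyError(f"no residue {num!r} in chain {chain!r}")

    def chain_sequence_slices(self) -> list[slice]:
        """Contiguous residue index ranges, one per chain."""
        out = []
        for c in range(self.n_chains):
            idx = np.nonzero(self.chain_index == c)[0]
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            chain_ids=list(self.chain_ids),
            residue_numbers=[list(r) for r in self.residue_numbers],
            coords=self.coords.copy(),
            cb=self.cb.copy(),
            atom_mask=self.atom_mask.copy(),
            residue_mask=self.residue_mask.copy(),
            chain_index=self.chain_index.copy(),
            chain_pos=self.chain_pos.copy(),
        )


def place_virtual_cb(n, ca, c):
    """Ideal beta-carbon position from the backbone N, Ca, C triad.

    Accepts single coordinates or arrays with a trailing axis of length 3.
    Equivariant under rigid motion of the inputs.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (np.isfinite(n).all() and np.isfinite(ca).all() and np.isfinite(c).all()):
        raise DegenerateGeometryError("non-finite backbone coordinates")
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    norm_a = np.linalg.norm(a, axis=-1)
    scale = np.maximum(np.linalg.norm(b, axis=-1) * np.linalg.norm(cvec, axis=-1), 1e-12)
    if np.any(norm_a / scale < 1e-6):
        raise DegenerateGeometryError("collinear N-Ca-C triad")
    return ca + _CB_W1 * a + _CB_W2 * b + _CB_W3 * cvec


def compute_virtual_cb(coords: np.ndarray, residue_mask: np.ndarray) -> np.ndarray:
    """Virtual Cb for every valid residue; invalid residues get their Ca (or 0)."""
    cb = coords[:, 1, :].copy()
    valid = np.nonzero(residue_mask)[0]
    if valid.size:
        cb[valid] = place_virtual_cb(coords[valid, 0], coords[valid, 1], coords[valid, 2])
    return cb


def _pick_altloc(atoms) -> gemmi.Atom | None:
    """Highest occupancy wins; ties go to the first atom in file order."""
    if not atoms:
        return None
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_backbone(path, dialect: str = "pdb") -> BackboneStructure:
    """Read polymer backbone residues from a PDB or mmCIF file.

    Waters, heteroatoms and non-protein polymers are skipped; alternate
    locations are resolved to the highest-occupancy conformer.
    """
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chain_ids: list[str] = []
    residue_numbers: list[list[str]] = []
    coords_list, amask_list, chain_idx_list, chain_pos_list = [], [], [], []
    for chain in model:
        numbers: list[str] = []
        pos_in_chain = 0
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid() or res.is_water():
                continue
            xyz = np.zeros((4, 3))
            mask = np.zeros(4, dtype=bool)
            for ai, name in enumerate(ATOM_NAMES):
                atom = _pick_altloc([a for a in res if a.name == name])
                if atom is not None:
                    xyz[ai] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    mask[ai] = True
            coords_list.append(xyz)
            amask_list.append(mask)
            chain_idx_list.append(len(chain_ids))
            chain_pos_list.append(pos_in_chain)
            numbers.append(f"{res.seqid.num}{res.seqid.icode}".strip())
            pos_in_chain += 1
        if numbers:
            if chain.name in chain_ids:
                raise FormatError(f"duplicate chain label {chain.name!r}")
            chain_ids.append(chain.name)
            residue_numbers.append(numbers)

    if not coords_list:
        raise EmptyStructureError(f"{path}: no protein residues")
    coords = np.asarray(coords_list)
    atom_mask = np.asarray(amask_list)
    residue_mask = atom_mask[:, :3].all(axis=1)
    cb = compute_virtual_cb(coords, residue_mask)
    return BackboneStructure(
        chain_ids=chain_ids,
        residue_numbers=residue_numbers,
        coords=coords,
        cb=cb,
        atom_mask=atom_mask,
        residue_mask=residue_mask,
        chain_index=np.asarray(chain_idx_list, dtype=np.int64),
        chain_pos=np.asarray(chain_pos_list, dtype=np.int64),
    )


def write_pdb(structure: BackboneStructure, path, sequence: str | None = None) -> None:
    """Write backbone atoms as a PDB file (used for synthetic fixtures).

    `sequence` optionally assigns one-letter residue names; default is GLY.
    """
    st = gemmi.Structure()
    st.name = "invfold"
    model = gemmi.Model(1)
    for ci, chain_id in enumerate(structure.chain_ids):
        chain = gemmi.Chain(chain_id)
        res_indices = np.nonzero(structure.chain_index == ci)[0]
        for local, ri in enumerate(res_indices):
            res = gemmi.Residue()
            letter = sequence[ri] if sequence is not None else "G"
            res.name = _THREE_LETTER.get(letter.upper(), "UNK")
            res.seqid = gemmi.SeqId(structure.residue_numbers[ci][local])
            for ai, name in enumerate(ATOM_NAMES):
                if not structure.atom_mask[ri, ai]:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                x, y, z = structure.coords[ri, ai]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_designs(designs, path) -> None:
    """Write sampled designs as FASTA, one record per sample.

    Headers carry the sample index, temperature, average log probability and
    (when a reference sequence was given) recovery; multi-chain sequences are
    joined with '/'.
    """
    samples = designs.samples
    if not samples:
        raise ValueError("no designs to write")
    lines = []
    for i, s in enumerate(samples):
        parts = [f">design_{i}", f"T={designs.temperature:g}",
                 f"avg_log_prob={s.avg_log_prob:.4f}"]
        if s.recovery is not None:
            parts.append(f"recovery={s.recovery:.4f}")
        parts.append(f"seed={designs.seed}")
        lines.append(" ".join(parts))
        lines.append("/".join(s.chain_sequences))
    Path(path).write_text("\n".join(lines) + "\n")
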