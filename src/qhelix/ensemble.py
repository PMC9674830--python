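"""Multi-conformer peptide ensembles backed by biotite atom arrays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


@dataclass
class Ensemble:
    """Conformer pool sharing one topology (PDB naming, 1-based residues)."""

    stack: struc.AtomArrayStack

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.stack.coord)):
            raise ValueError("ensemble contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    @property
    def res_ids(self) -> np.ndarray:
        return self.stack.res_id

    @property
    def atom_names(self) -> np.ndarray:
        return self.stack.atom_name

    @property
    def res_names(self) -> np.ndarray:
        return self.stack.res_name

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.stack.res_id)

    def res_name_of(self, res_id: int) -> str:
        mask = self.stack.res_id == res_id
        if not mask.any():
            raise KeyError(f"no residue {res_id}")
        return str(self.stack.res_name[mask][0])

    def frame(self, i: int) -> struc.AtomArray:
        return self.stack[i]

    def frames(self) -> list[struc.AtomArray]:
        return [self.stack[i] for i in range(self.n_frames)]

    def atom_index(self, res_id: int, atom_name: str) -> int:
        mask = (self.stack.res_id == res_id) & (self.stack.atom_name == atom_name)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"atom {atom_name} of residue {res_id} not in topology")
        return int(idx[0])

    def coord(self, frame: int, res_id: int, atom_name: str) -> np.ndarray:
        return self.stack.coord[frame, self.atom_index(res_id, atom_name)]

    def subset(self, frame_indices) -> "Ensemble":
        return Ensemble(self.stack[np.asarray(frame_indices, dtype=int)])

    def to_pdb(self, path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path) -> "Ensemble":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        return cls(stack)

    @classmethod
    def from_frames(cls, frames: list[struc.AtomArray]) -> "Ensemble":
        return cls(struc.stack(frames))
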