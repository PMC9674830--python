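"""Ideal-geometry peptide construction and side-chain dihedral manipulation.

Backbones are grown atom by atom with the natural-extension reference frame
(NeRF) using idealized bond lengths and angles; side chains are grafted from
the chemical-component-dictionary ideal residues bundled with biotite and
then rotated about their chi bonds to realize requested rotamers exactly.
Only dihedrals and coarse geometry are consumed downstream, so idealized
internal coordinates (no rotamer-library refinement) are sufficient.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from .ensemble import Ensemble

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# idealized backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: IUPAC chi dihedral atom quadruples per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_BACKBONE_TEMPLATE_EXCLUDE = {"N", "CA", "C", "O", "OXT", "H", "H2", "H3", "HXT"}


def place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg):
    """NeRF: position d with |cd|, angle(b,c,d) and dihedral(a,b,c,d) given."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.deg2rad(bond_angle_deg)
    phi = np.deg2rad(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@lru_cache(maxsize=32)
def _template(res_name: str) -> struc.AtomArray:
    return struc_info.residue(res_name)


@lru_cache(maxsize=32)
def residue_bond_graph(res_name: str) -> dict[str, frozenset]:
    """Adjacency (by atom name) of the CCD ideal residue."""
    tmpl = _template(res_name)
    adj: dict[str, set] = {name: set() for name in tmpl.atom_name}
    for i, j, _ in tmpl.bonds.as_array():
        adj[tmpl.atom_name[i]].add(tmpl.atom_name[j])
        adj[tmpl.atom_name[j]].add(tmpl.atom_name[i])
    return {k: frozenset(v) for k, v in adj.items()}


def attached_heavy_atom(res_name: str, h_name: str) -> str | None:
    """Name of the heavy atom a hydrogen is bonded to in the ideal residue."""
    graph = residue_bond_graph(res_name)
    for nb in graph.get(h_name, ()):
        if not nb.startswith("H"):
            return nb
    return None


def _kabsch(mobile: np.ndarray, fixed: np.ndarray):
    """Rotation + translation mapping mobile points onto fixed points."""
    mc, fc = mobile.mean(axis=0), fixed.mean(axis=0)
    H = (mobile - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, fc - R @ mc


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    ang = np.rad2deg(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def wrap_deg(angle):
    """Wrap angle(s) to (-180, 180]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


def n_chi(res_name: str) -> int:
    return len(CHI_ATOMS.get(res_name, []))


def get_chi(frame: struc.AtomArray, res_id: int, chi_index: int) -> float:
    """Chi dihedral (1-based index) of a residue, degrees."""
    res_mask = frame.res_id == res_id
    res_name = str(frame.res_name[res_mask][0])
    quads = CHI_ATOMS.get(res_name, [])
    if chi_index < 1 or chi_index > len(quads):
        raise ValueError(f"residue {res_id} ({res_name}) has no chi{chi_index}")
    coords = []
    for name in quads[chi_index - 1]:
        idx = np.flatnonzero(res_mask & (frame.atom_name == name))
        if idx.size == 0:
            raise ValueError(f"residue {res_id} missing atom {name} for chi{chi_index}")
        coords.append(frame.coord[idx[0]])
    return dihedral_deg(*coords)


def set_chi(frame: struc.AtomArray, res_id: int, chi_index: int, target_deg: float) -> None:
    """Rotate the side-chain subtree about the chi bond to the target, in place."""
    res_mask = frame.res_id == res_id
    res_name = str(frame.res_name[res_mask][0])
    quads = CHI_ATOMS.get(res_name, [])
    if chi_index < 1 or chi_index > len(quads):
        raise ValueError(f"residue {res_id} ({res_name}) has no chi{chi_index}")
    a_name, b_name, c_name, _ = quads[chi_index - 1]
    current = get_chi(frame, res_id, chi_index)
    delta = np.deg2rad(target_deg - current)
    # atoms distal to the b-c bond, found on the template bond graph
    graph = residue_bond_graph(res_name)
    distal: set[str] = set()
    frontier = [c_name]
    while frontier:
        node = frontier.pop()
        for nb in graph[node]:
            if nb == b_name or nb in distal or nb == c_name:
                continue
            distal.add(nb)
            frontier.append(nb)
    idx_b = np.flatnonzero(res_mask & (frame.atom_name == b_name))[0]
    idx_c = np.flatnonzero(res_mask & (frame.atom_name == c_name))[0]
    axis = frame.coord[idx_c] - frame.coord[idx_b]
    axis /= np.linalg.norm(axis)
    move = res_mask & np.isin(frame.atom_name, list(distal))
    rel = frame.coord[move] - frame.coord[idx_c]
    cos, sin = np.cos(delta), np.sin(delta)
    rotated = (
        rel * cos
        + np.cross(axis, rel) * sin
        + np.outer(rel @ axis, axis) * (1.0 - cos)
    )
    frame.coord[move] = rotated + frame.coord[idx_c]


def build_ideal_helix(
    sequence: str,
    phi: float = -60.0,
    psi: float = -40.0,
    rotamers: dict[int, dict[int, float]] | None = None,
) -> Ensemble:
    """Build a single-frame peptide with the given backbone dihedrals.

    ``rotamers`` maps 1-based residue numbers to ``{chi_index: degrees}``;
    requested chi angles are realized exactly (subtree rotation).  The
    defaults (-60, -40) are the canonical alpha-helical backbone.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("phi/psi must be finite")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {aa!r} at position {pos}")
    rotamers = rotamers or {}
    for res_id, chis in rotamers.items():
        if not 1 <= res_id <= len(sequence):
            raise ValueError(f"rotamer requested for absent residue {res_id}")
        res_name = ONE_TO_THREE[sequence[res_id - 1]]
        for ci in chis:
            if ci < 1 or ci > n_chi(res_name):
                raise ValueError(
                    f"residue {res_id} ({res_name}) has no chi{ci} dihedral"
                )

    n = len(sequence)
    # backbone trace
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    theta = np.deg2rad(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])]
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi))
    O = []
    for i in range(n):
        # carbonyl O trans to the next amide N (psi + 180 about N-CA-C)
        O.append(place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0))

    atoms: list[struc.Atom] = []

    def add(res_id, res_name, name, element, coord):
        atoms.append(
            struc.Atom(
                coord,
                chain_id="A",
                res_id=res_id,
                res_name=res_name,
                atom_name=name,
                element=element,
                hetero=False,
            )
        )

    for i in range(n):
        res_id = i + 1
        res_name = ONE_TO_THREE[sequence[i]]
        add(res_id, res_name, "N", "N", N[i])
        add(res_id, res_name, "CA", "C", CA[i])
        add(res_id, res_name, "C", "C", C[i])
        add(res_id, res_name, "O", "O", O[i])
        if res_name != "PRO":
            if i == 0:
                h = place_atom(C[0], CA[0], N[0], BOND_N_H, 118.2, 180.0)
            else:
                u1 = C[i - 1] - N[i]
                u1 /= np.linalg.norm(u1)
                u2 = CA[i] - N[i]
                u2 /= np.linalg.norm(u2)
                bis = u1 + u2
                h = N[i] - BOND_N_H * bis / np.linalg.norm(bis)
            add(res_id, res_name, "H", "H", h)
        # graft side chain (and HA) from the ideal residue template
        tmpl = _template(res_name)
        keep = ~np.isin(tmpl.atom_name, list(_BACKBONE_TEMPLATE_EXCLUDE))
        if keep.any():
            ref_names = ["N", "CA", "C"]
            mob = np.array(
                [tmpl.coord[tmpl.atom_name == nm][0] for nm in ref_names]
            )
            fix = np.array([N[i], CA[i], C[i]])
            R, t = _kabsch(mob, fix)
            for name, element, coord in zip(
                tmpl.atom_name[keep], tmpl.element[keep], tmpl.coord[keep]
            ):
                add(res_id, res_name, str(name), str(element), R @ coord + t)

    frame = struc.array(atoms)
    for res_id, chis in rotamers.items():
        for ci in sorted(chis):
            set_chi(frame, res_id, ci, chis[ci])
    return Ensemble.from_frames([frame])
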