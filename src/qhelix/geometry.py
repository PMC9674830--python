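"""Geometry on conformer ensembles: H-bonds, rotamers, solvent accessibility.

Hydrogen bonds follow the distance/angle rule used throughout the package:
donor H to acceptor O closer than 2.4 A and a donor-H-acceptor angle (at the
hydrogen) larger than 120 degrees.  A Gln_{i+4} -> X_i contact is flagged
*bifurcated* when both the main-chain amide H and a side-chain carboxamide
H of residue i+4 bond the same carbonyl O of residue i.

SASA is computed with the Shrake-Rupley method on a deterministic Fibonacci
sphere lattice, with Bondi van der Waals radii (amide hydrogens 1.10 A so
that the solvent exposure of carboxamide protons is meaningful).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import biotite.structure as struc

from .builder import CHI_ATOMS, attached_heavy_atom, get_chi, wrap_deg
from .ensemble import Ensemble

#: Bondi van der Waals radii by element (A)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
AMIDE_H_RADIUS = 1.10


@dataclass(frozen=True)
class HBondCriteria:
    max_dist_H_acceptor: float = 2.4  # A
    min_angle_donor_H_acceptor: float = 120.0  # degrees, measured at H

    def __post_init__(self) -> None:
        if self.max_dist_H_acceptor <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_angle_donor_H_acceptor <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


class HBond(NamedTuple):
    donor_index: int     # heavy donor atom index
    h_index: int
    acceptor_index: int
    distance: float      # H..acceptor, A
    angle: float         # donor-H-acceptor, degrees
    bifurcated: bool


def _is_amide_h(res_name: str, atom_name: str) -> bool:
    if atom_name == "H":
        return True
    heavy = attached_heavy_atom(res_name, atom_name)
    return heavy is not None and heavy.startswith("N")


def default_donors(frame: struc.AtomArray) -> list[tuple[int, int]]:
    """(heavy, H) donor pairs: every N-H in the frame (main and side chain)."""
    pairs = []
    for i in np.flatnonzero(frame.element == "H"):
        res_mask = frame.res_id == frame.res_id[i]
        res_name = str(frame.res_name[i])
        heavy_name = (
            "N" if frame.atom_name[i] == "H"
            else attached_heavy_atom(res_name, str(frame.atom_name[i]))
        )
        if heavy_name is None or not heavy_name.startswith("N"):
            continue
        j = np.flatnonzero(res_mask & (frame.atom_name == heavy_name))
        if j.size:
            pairs.append((int(j[0]), int(i)))
    return pairs


def default_acceptors(frame: struc.AtomArray) -> list[int]:
    """Carbonyl-type oxygens: main-chain O plus side-chain carboxamide O."""
    mask = (frame.element == "O") & np.isin(frame.atom_name, ["O", "OE1", "OD1"])
    return [int(i) for i in np.flatnonzero(mask)]


def detect_hbonds(
    frame: struc.AtomArray,
    criteria: HBondCriteria = HBondCriteria(),
    donors: list[tuple[int, int]] | None = None,
    acceptors: list[int] | None = None,
) -> list[HBond]:
    """Exhaustive H-bond detection over donor/acceptor lists.

    Donors are (heavy, H) index pairs; a donor heavy atom without a resolved
    hydrogen must be excluded by the caller (automatic selection only emits
    complete pairs).
    """
    donors = default_donors(frame) if donors is None else donors
    acceptors = default_acceptors(frame) if acceptors is None else acceptors
    for heavy, h in donors:
        if frame.element[h] != "H":
            raise ValueError(f"donor pair ({heavy}, {h}): atom {h} is not a hydrogen")
    raw: list[tuple[int, int, int, float, float]] = []
    for heavy, h in donors:
        hpos = frame.coord[h]
        dpos = frame.coord[heavy]
        for acc in acceptors:
            if acc == heavy:
                continue
            apos = frame.coord[acc]
            dist = float(np.linalg.norm(apos - hpos))
            if dist >= criteria.max_dist_H_acceptor:
                continue
            u = dpos - hpos
            v = apos - hpos
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            angle = float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle > criteria.min_angle_donor_H_acceptor:
                raw.append((heavy, h, acc, dist, angle))
    # bifurcation: main-chain N-H(i+4) and side-chain Ne2-H(i+4) on the same O(i)
    bonded_types: dict[tuple[int, int], set[str]] = {}
    for heavy, h, acc, _, _ in raw:
        key = (int(frame.res_id[heavy]), acc)
        kind = "main" if frame.atom_name[h] == "H" else "side"
        bonded_types.setdefault(key, set()).add(kind)
    out = []
    for heavy, h, acc, dist, angle in raw:
        key = (int(frame.res_id[heavy]), acc)
        bif = (
            bonded_types[key] == {"main", "side"}
            and int(frame.res_id[heavy]) - int(frame.res_id[acc]) == 4
        )
        out.append(HBond(heavy, h, acc, dist, angle, bif))
    return out


def chi_angles(frame: struc.AtomArray, res_id: int) -> tuple[float, ...]:
    """All defined chi dihedrals of a residue, degrees in (-180, 180]."""
    res_name = str(frame.res_name[frame.res_id == res_id][0])
    quads = CHI_ATOMS.get(res_name, [])
    if not quads:
        raise ValueError(f"residue {res_id} ({res_name}) has no chi dihedrals")
    return tuple(get_chi(frame, res_id, k + 1) for k in range(len(quads)))


ROTAMER_CENTERS = {"m": -60.0, "p": 60.0, "t": 180.0}


@dataclass(frozen=True)
class RotamerLabel:
    chi1_class: str
    chi2_class: str

    @property
    def label(self) -> str:
        return self.chi1_class + self.chi2_class


def classify_chi(chi: float) -> str:
    """Nearest rotamer class with half-open windows [center-60, center+60)."""
    if not np.isfinite(chi):
        raise ValueError("chi must be finite")
    w = float(wrap_deg(chi))
    if -120.0 <= w < 0.0:
        return "m"
    if 0.0 <= w < 120.0:
        return "p"
    return "t"


def classify_rotamer(chi1: float, chi2: float) -> RotamerLabel:
    return RotamerLabel(classify_chi(chi1), classify_chi(chi2))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = 2.0 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(frame: struc.AtomArray) -> np.ndarray:
    radii = np.empty(frame.array_length())
    for i in range(frame.array_length()):
        el = str(frame.element[i])
        if el not in VDW_RADII:
            raise ValueError(f"no van der Waals radius for element {el!r}")
        if el == "H" and _is_amide_h(str(frame.res_name[i]), str(frame.atom_name[i])):
            radii[i] = AMIDE_H_RADIUS
        else:
            radii[i] = VDW_RADII[el]
    return radii


def sasa(
    frame: struc.AtomArray,
    atom_selection: np.ndarray | list[int] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface area (A^2)."""
    radii = atom_radii(frame)
    coords = frame.coord
    sel = (
        np.arange(frame.array_length())
        if atom_selection is None
        else np.asarray(atom_selection, dtype=int)
    )
    sphere = fibonacci_sphere(n_points)
    out = np.empty(sel.size)
    for k, i in enumerate(sel):
        r_i = radii[i] + probe_radius
        pts = coords[i] + r_i * sphere
        d_other = np.linalg.norm(coords - coords[i], axis=1)
        neighbor = (d_other < radii + probe_radius + r_i) & (
            np.arange(coords.shape[0]) != i
        )
        if not neighbor.any():
            out[k] = 4.0 * np.pi * r_i**2
            continue
        nb_coord = coords[neighbor]
        nb_r = radii[neighbor] + probe_radius
        d2 = ((pts[:, None, :] - nb_coord[None, :, :]) ** 2).sum(axis=2)
        exposed = (d2 >= nb_r**2).all(axis=1)
        out[k] = 4.0 * np.pi * r_i**2 * exposed.mean()
    return out


def trajectory_summary(
    ensemble: Ensemble,
    donor_residue: int,
    acceptor_residue: int,
    criteria: HBondCriteria = HBondCriteria(),
    n_points: int = 960,
) -> tuple[float, float]:
    """Side-chain-to-main-chain H-bond frequency and mean donor He21 SASA.

    Counts a frame when any carboxamide H of the donor Gln bonds the
    main-chain O of the acceptor residue; SASA is averaged over all frames.
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    he21 = ensemble.atom_index(donor_residue, "HE21")
    he22 = ensemble.atom_index(donor_residue, "HE22")
    ne2 = ensemble.atom_index(donor_residue, "NE2")
    acc_o = ensemble.atom_index(acceptor_residue, "O")
    n_bonded = 0
    sasa_sum = 0.0
    for i in range(ensemble.n_frames):
        frame = ensemble.frame(i)
        bonds = detect_hbonds(
            frame,
            criteria,
            donors=[(ne2, he21), (ne2, he22)],
            acceptors=[acc_o],
        )
        if bonds:
            n_bonded += 1
        sasa_sum += float(sasa(frame, [he21], n_points=n_points)[0])
    return n_bonded / ensemble.n_frames, sasa_sum / ensemble.n_frames
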