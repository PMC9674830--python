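"""Synthetic inputs with known ground truth for every pipeline stage.

All generators are pure functions of their arguments and a seed (identical
calls give bitwise-identical outputs), zero-noise outputs satisfy the
generating equation exactly, and every planted truth is returned in a
machine-readable record next to the data.  Noise is everywhere additive
Gaussian with SD expressed as a fraction of the maximum clean signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .builder import build_ideal_helix, n_chi, set_chi, ONE_TO_THREE
from .comand import Strip, StripBackcalcParams, StripContext
from .ensemble import Ensemble
from .geometry import ROTAMER_CENTERS
from .motifs import (
    DEFAULT_ACCEPTORS,
    STANDARD_AA,
    compile_motif,
    scan_sequences,
)
from .nmr import DecaySeries, TitrationSeries, binding_isotherm

__all__ = [
    "SyntheticSpec",
    "build_ideal_helix",
    "plant_rotamer_ensemble",
    "simulate_titration",
    "simulate_decay",
    "generate_motif_sequences",
    "synth_strips",
    "default_assignments",
    "PlantedEnsemble",
    "StripSet",
]

ROTAMER_JITTER_SD = 10.0  # deg; keeps rotamer classes separable


@dataclass(frozen=True)
class SyntheticSpec:
    """Bookkeeping record for a synthetic dataset and its planted truth."""

    seed: int
    noise_sd: float = 0.0  # fraction of the maximum clean signal
    n_frames: int = 1
    planted_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


# ------------------------------------------------------------- ensembles

@dataclass
class PlantedEnsemble:
    ensemble: Ensemble
    labels: pd.DataFrame     # columns: frame, res_id, label, chi1, chi2
    mixture: dict[str, float]
    seed: int
    jitter_sd: float

    def label_fractions(self, res_id: int | None = None) -> dict[str, float]:
        df = self.labels if res_id is None else self.labels[self.labels.res_id == res_id]
        return (df["label"].value_counts() / len(df)).to_dict()


def plant_rotamer_ensemble(
    sequence: str,
    mixture: dict[str, float],
    n_frames: int,
    seed: int,
    residues: list[int] | None = None,
    phi: float = -57.0,
    psi: float = -47.0,
    jitter_sd: float = ROTAMER_JITTER_SD,
    chi3_center: float = 75.0,
) -> PlantedEnsemble:
    """Helical ensemble with side-chain rotamers drawn i.i.d. from a mixture.

    Rotamer labels ("mt", "tp", ...) give the chi1/chi2 class centers; each
    frame jitters the angles with a wrapped Gaussian of SD ``jitter_sd`` so
    the classes remain cleanly separable.  Gln chi3 jitters around
    ``chi3_center``.  Applies to ``residues`` (default: every residue with
    both chi1 and chi2).
    """
    if not mixture:
        raise ValueError("mixture must not be empty")
    weights = np.array(list(mixture.values()), dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for lbl in mixture:
        if len(lbl) != 2 or any(c not in ROTAMER_CENTERS for c in lbl):
            raise ValueError(f"bad rotamer label {lbl!r}")

    base = build_ideal_helix(sequence, phi, psi).frame(0)
    if residues is None:
        residues = [
            i + 1
            for i, aa in enumerate(sequence)
            if n_chi(ONE_TO_THREE[aa]) >= 2
        ]
    labels_list = list(mixture.keys())
    rng = np.random.default_rng(seed)
    frames = []
    rows = []
    for f in range(n_frames):
        frame = base.copy()
        for res_id in residues:
            lbl = labels_list[int(rng.choice(len(labels_list), p=weights))]
            chi1 = ROTAMER_CENTERS[lbl[0]] + jitter_sd * rng.standard_normal()
            chi2 = ROTAMER_CENTERS[lbl[1]] + jitter_sd * rng.standard_normal()
            set_chi(frame, res_id, 1, chi1)
            set_chi(frame, res_id, 2, chi2)
            if n_chi(ONE_TO_THREE[sequence[res_id - 1]]) >= 3:
                set_chi(
                    frame, res_id, 3, chi3_center + jitter_sd * rng.standard_normal()
                )
            rows.append((f, res_id, lbl, chi1, chi2))
        frames.append(frame)
    labels = pd.DataFrame(rows, columns=["frame", "res_id", "label", "chi1", "chi2"])
    return PlantedEnsemble(
        Ensemble.from_frames(frames), labels, dict(mixture), seed, jitter_sd
    )


# ------------------------------------------------------------ observables

def simulate_decay(
    i0: float,
    time_constant_s: float,
    delays_s,
    noise_sd: float = 0.0,
    seed: int = 0,
    owner: str = "",
) -> DecaySeries:
    """Exponential decay I(t) = I0 exp(-t/T) plus fractional Gaussian noise."""
    if time_constant_s <= 0:
        raise ValueError("time constant must be positive")
    t = np.asarray(delays_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be non-negative")
    clean = i0 * np.exp(-t / time_constant_s)
    noise = noise_sd * np.abs(clean).max() * np.random.default_rng(seed).standard_normal(
        t.size
    ) if noise_sd > 0 else 0.0
    return DecaySeries(t, clean + noise, owner)


def simulate_titration(
    kd_uM: float,
    ddmax_per_peak: dict[Any, float],
    protein_uM: float,
    peptide_uM_series,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """1:1 single-site titration CSPs with known K_D.

    Each peak's averaged CSP follows the exact binding isotherm scaled by
    its ddmax; the 1H and 15N components are split 0.8/3.0 so that the
    combined CSP sqrt(ddH^2 + (ddN/5)^2) equals ddmax times the bound
    fraction exactly.  ``noise_sd = 0`` reproduces the isotherm exactly.
    """
    if kd_uM <= 0 or protein_uM <= 0:
        raise ValueError("K_D and protein concentration must be positive")
    lig = np.asarray(peptide_uM_series, dtype=float)
    if np.any(lig < 0):
        raise ValueError("peptide concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for pid, ddmax in ddmax_per_peak.items():
        frac = binding_isotherm(protein_uM, lig, kd_uM)
        dd_1h = 0.8 * ddmax * frac
        dd_15n = 3.0 * ddmax * frac
        if noise_sd > 0:
            dd_1h = dd_1h + noise_sd * np.abs(dd_1h).max() * rng.standard_normal(lig.size)
            dd_15n = dd_15n + noise_sd * np.abs(dd_15n).max() * rng.standard_normal(
                lig.size
            )
        for l_um, h, n in zip(lig, dd_1h, dd_15n):
            rows.append((pid, l_um, h, n))
    data = pd.DataFrame(rows, columns=["peak_id", "peptide_uM", "dd_1h", "dd_15n"])
    return TitrationSeries(protein_uM, data)


# ----------------------------------------------------------------- motifs

def generate_motif_sequences(
    n_pairs: int,
    n_positives: int,
    n_decoys: int,
    length: int,
    seed: int = 0,
    acceptor_set: str = DEFAULT_ACCEPTORS,
) -> tuple[dict[str, str], dict[str, dict]]:
    """Random sequences with planted motif matches plus verified decoys.

    Positives carry at least one planted match (a random realization of the
    pattern at a random position); decoys are redrawn until an explicit
    scan finds no match, so truth labels are correct by construction.
    Returns ``(records, truth)`` with truth giving the planted position.
    """
    motif = compile_motif(n_pairs, acceptor_set)
    if length < motif.length:
        raise ValueError(f"length {length} shorter than motif length {motif.length}")
    rng = np.random.default_rng(seed)
    aas = np.array(list(STANDARD_AA))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(aas, size=n))

    def realization() -> str:
        out = []
        for tok in motif.tokens:
            if tok == "X":
                out.append(str(rng.choice(aas)))
            elif tok == "Q":
                out.append("Q")
            else:
                out.append(str(rng.choice(list(acceptor_set))))
        return "".join(out)

    records: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for i in range(n_positives):
        start = int(rng.integers(0, length - motif.length + 1))
        seq = random_seq(length)
        seq = seq[:start] + realization() + seq[start + motif.length:]
        rid = f"pos{i:03d}"
        records[rid] = seq
        truth[rid] = {"positive": True, "planted_at": start + 1}
    for i in range(n_decoys):
        rid = f"dec{i:03d}"
        while True:
            seq = random_seq(length)
            if not scan_sequences({rid: seq}, motif).per_record[rid]:
                break
        records[rid] = seq
        truth[rid] = {"positive": False, "planted_at": None}
    return records, truth


# ----------------------------------------------------------------- strips

#: Typical 13C shifts (ppm) for strip rendering, by (residue, carbon);
#: the generic fallback keys on the carbon name alone.
CARBON_SHIFTS = {
    ("ALA", "CA"): 52.5, ("ALA", "CB"): 19.1,
    ("LEU", "CA"): 55.1, ("LEU", "CB"): 42.4, ("LEU", "CG"): 26.9,
    ("LEU", "CD1"): 24.9, ("LEU", "CD2"): 23.3,
    ("GLN", "CA"): 55.7, ("GLN", "CB"): 29.4, ("GLN", "CG"): 33.7,
    ("GLY", "CA"): 45.1,
}
GENERIC_SHIFTS = {
    "CA": 55.0, "CB": 32.0, "CG": 27.0, "CG1": 25.0, "CG2": 20.0,
    "CD": 29.0, "CD1": 24.0, "CD2": 23.0, "CE": 17.0, "CE1": 131.0,
    "CZ": 129.0, "CH2": 123.0,
}


def default_assignments(ensemble: Ensemble) -> dict[tuple[int, str], float]:
    """Assign a typical carbon shift to every carbon-bound proton."""
    from .builder import attached_heavy_atom
    from .comand import carbon_bound_protons

    stack = ensemble.stack
    out = {}
    for i in carbon_bound_protons(ensemble):
        res_name = str(stack.res_name[i])
        carbon = attached_heavy_atom(res_name, str(stack.atom_name[i]))
        ppm = CARBON_SHIFTS.get((res_name, carbon), GENERIC_SHIFTS.get(carbon))
        if ppm is None:
            raise ValueError(f"no shift available for {res_name} {carbon}")
        # stereo pairs get slightly split shifts so strips stay informative
        out[(int(stack.res_id[i]), str(stack.atom_name[i]))] = ppm
    return out


@dataclass
class StripSet:
    strips: list[Strip]
    assignments: dict[tuple[int, str], float]
    params: StripBackcalcParams
    source: Ensemble         # ground-truth generating ensemble
    noise_sd: float
    seed: int


def synth_strips(
    ensemble: Ensemble,
    assignments: dict[tuple[int, str], float] | None = None,
    params: StripBackcalcParams = StripBackcalcParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
    owners: list[tuple[int, str]] | None = None,
) -> StripSet:
    """Back-calculate strips from a known ensemble and add fractional noise.

    Default owners are the He21 side-chain protons of all Gln residues.
    With ``noise_sd = 0`` the strips equal the clean back-calculation.
    """
    if assignments is None:
        assignments = default_assignments(ensemble)
    if owners is None:
        owners = [
            (int(rid), "HE21")
            for rid in ensemble.residue_ids
            if ensemble.res_name_of(int(rid)) == "GLN"
        ]
    if not owners:
        raise ValueError("no strip owners")
    rng = np.random.default_rng(seed)
    strips = []
    for owner in owners:
        ctx = StripContext(ensemble, owner, assignments, params)
        clean = ctx.pool_profiles(ensemble).mean(axis=0)
        noisy = (
            clean + noise_sd * clean.max() * rng.standard_normal(clean.size)
            if noise_sd > 0
            else clean
        )
        strips.append(Strip(owner, ctx.grid, noisy))
    return StripSet(strips, assignments, params, ensemble, noise_sd, seed)
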