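"""Helix-coil transition model with side-chain-to-main-chain H-bond terms.

A Zimm-Bragg-like two-state (helix/coil) model per residue: each helical
residue contributes a propagation weight ``exp(-dG_i/RT)``, each helical
segment pays a nucleation penalty once, and every declared ``i+4 -> i``
side-chain-to-main-chain hydrogen bond multiplies the configuration weight
by ``exp(-dG_side/RT)`` -- but only in configurations where the whole
window ``i .. i+4`` is helical, since the bond requires the intervening
helical turn to be formed.

Per-residue helical probabilities come from a transfer matrix with a
4-residue memory (16 states), which is exact for the span-5 window terms.
``enumerate_profile`` is the brute-force Boltzmann sum over all 2^N
configurations, used as an independent oracle for small N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

R_KCAL = 1.987204258e-3  # gas constant, kcal mol^-1 K^-1

#: Intrinsic helix propensities (kcal/mol, cost relative to Ala) from the
#: Pace & Scholtz consensus scale.
PACE_SCHOLTZ = {
    "A": 0.0, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26, "Q": 0.39,
    "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50, "Y": 0.53, "F": 0.54,
    "H": 0.61, "V": 0.61, "N": 0.65, "T": 0.66, "C": 0.68, "D": 0.69,
    "G": 1.00, "P": 3.16,
}

MAX_SEQUENCE_LENGTH = 10_000
MAX_ENUM_LENGTH = 15


@dataclass(frozen=True)
class Interaction:
    """One Gln_{i+4} -> X_i side-chain-to-main-chain H-bond term."""

    acceptor: int  # 1-based position of the acceptor residue i
    donor: int     # 1-based position of the donor residue i+4
    dG_side: float  # kcal/mol, negative stabilizes


@dataclass
class HelixCoilModel:
    sequence: str
    intrinsic_dG: np.ndarray  # kcal/mol per residue, helix propagation cost
    nucleation_penalty: float = 2.0  # kcal/mol, paid once per helical segment
    interactions: list[Interaction] = field(default_factory=list)
    temperature: float = 278.0  # K, the NMR condition

    def __post_init__(self) -> None:
        self.intrinsic_dG = np.asarray(self.intrinsic_dG, dtype=float)
        n = len(self.sequence)
        if self.intrinsic_dG.shape != (n,):
            raise ValueError(
                f"intrinsic_dG length {self.intrinsic_dG.size} != sequence length {n}"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for ia in self.interactions:
            if ia.donor - ia.acceptor != 4:
                raise ValueError(f"interaction {ia} is not i,i+4")
            if not (1 <= ia.acceptor and ia.donor <= n):
                raise ValueError(f"interaction {ia} outside sequence of length {n}")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @classmethod
    def from_scale(
        cls,
        sequence: str,
        scale: dict[str, float] | None = None,
        offset: float = 0.0,
        **kwargs,
    ) -> "HelixCoilModel":
        """Build a model with intrinsic dG taken from a published scale."""
        scale = PACE_SCHOLTZ if scale is None else scale
        try:
            dg = np.array([scale[aa] + offset for aa in sequence])
        except KeyError as err:
            raise ValueError(f"residue {err} not in the propensity scale") from err
        return cls(sequence, dg, **kwargs)

    def with_interaction_energy(self, dG_side: float) -> "HelixCoilModel":
        """Copy of the model with every interaction set to one shared energy."""
        return HelixCoilModel(
            self.sequence,
            self.intrinsic_dG.copy(),
            self.nucleation_penalty,
            [Interaction(ia.acceptor, ia.donor, dG_side) for ia in self.interactions],
            self.temperature,
        )


@dataclass
class HelicityProfile:
    sequence: str
    p_hel: np.ndarray  # per-residue helical probability in [0, 1]

    def __post_init__(self) -> None:
        self.p_hel = np.asarray(self.p_hel, dtype=float)
        if self.p_hel.shape != (len(self.sequence),):
            raise ValueError("p_hel length must match sequence")
        if np.any(self.p_hel < -1e-12) or np.any(self.p_hel > 1 + 1e-12):
            raise ValueError("p_hel must lie in [0, 1]")

    @property
    def mean_helicity(self) -> float:
        return float(self.p_hel.mean())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "residue_index": np.arange(1, len(self.sequence) + 1),
                "residue": list(self.sequence),
                "p_hel": self.p_hel,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HelicityProfile":
        df = pd.read_csv(path)
        return cls("".join(df["residue"]), df["p_hel"].to_numpy())


def _window_factors(model: HelixCoilModel) -> dict[int, float]:
    """Boltzmann factor applied when residue `donor` closes an all-helical window."""
    out: dict[int, float] = {}
    for ia in model.interactions:
        out[ia.donor] = out.get(ia.donor, 1.0) * float(np.exp(-ia.dG_side / model.rt))
    return out


def predict_profile(model: HelixCoilModel) -> HelicityProfile:
    """Per-residue helical probability via a 16-state transfer matrix.

    The state after residue i encodes (s_{i-3} .. s_i); bit 0 is the most
    recent residue. An i,i+4 interaction term fires on the h-transition at
    the donor when the four preceding residues are all helical (state 0b1111),
    i.e. exactly when the window i..i+4 is fully helical.
    """
    n = len(model.sequence)
    if n == 0:
        raise ValueError("empty sequence")
    if n > MAX_SEQUENCE_LENGTH:
        raise ValueError(f"sequence longer than cap {MAX_SEQUENCE_LENGTH}")
    rt = model.rt
    w_prop = np.exp(-model.intrinsic_dG / rt)
    w_nuc = float(np.exp(-model.nucleation_penalty / rt))
    factors = _window_factors(model)

    states = np.arange(16)
    nxt0 = (states << 1) & 15
    nxt1 = nxt0 | 1

    # forward pass, normalized each step (scales cancel in the marginal ratio)
    fwd = np.zeros((n + 1, 16))
    fwd[0, 0] = 1.0
    for i in range(1, n + 1):
        w_h = np.full(16, w_prop[i - 1])
        w_h[(states & 1) == 0] *= w_nuc  # previous residue coil -> nucleation
        if i in factors:
            w_h[states == 15] *= factors[i]
        f = np.zeros(16)
        np.add.at(f, nxt0, fwd[i - 1])          # coil transition, weight 1
        np.add.at(f, nxt1, fwd[i - 1] * w_h)    # helix transition
        fwd[i] = f / f.sum()

    # backward pass
    bwd = np.zeros((n + 1, 16))
    bwd[n] = 1.0
    for i in range(n, 0, -1):
        w_h = np.full(16, w_prop[i - 1])
        w_h[(states & 1) == 0] *= w_nuc
        if i in factors:
            w_h[states == 15] *= factors[i]
        b = bwd[i][nxt0] + w_h * bwd[i][nxt1]
        bwd[i - 1] = b / b.sum()

    p = np.empty(n)
    for i in range(1, n + 1):
        joint = fwd[i] * bwd[i]
        p[i - 1] = joint[(states & 1) == 1].sum() / joint.sum()
    return HelicityProfile(model.sequence, p)


def enumerate_profile(model: HelixCoilModel) -> HelicityProfile:
    """Exact Boltzmann average over all 2^N configurations (oracle, N <= 15)."""
    n = len(model.sequence)
    if n > MAX_ENUM_LENGTH:
        raise ValueError(f"enumeration limited to N <= {MAX_ENUM_LENGTH}")
    rt = model.rt
    configs = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
    log_w = -(configs @ model.intrinsic_dG) / rt
    padded = np.concatenate([np.zeros((2**n, 1), bool), configs], axis=1)
    starts = (configs & ~padded[:, :-1]).sum(axis=1)
    log_w -= starts * model.nucleation_penalty / rt
    for ia in model.interactions:
        full = configs[:, ia.acceptor - 1 : ia.donor].all(axis=1)
        log_w -= full * ia.dG_side / rt
    w = np.exp(log_w - log_w.max())
    p = (w @ configs) / w.sum()
    return HelicityProfile(model.sequence, p)


def rmsd_hel(predicted: HelicityProfile, observed: HelicityProfile) -> float:
    """Root-mean-square deviation between two per-residue helicity profiles."""
    if len(predicted.sequence) != len(observed.sequence):
        raise ValueError("profiles have different lengths")
    return float(np.sqrt(np.mean((predicted.p_hel - observed.p_hel) ** 2)))


def fit_interaction_energy(
    observed: HelicityProfile,
    template: HelixCoilModel,
    bounds: tuple[float, float] = (-2.0, 0.0),
    xatol: float = 1e-4,
) -> tuple[float, float]:
    """Fit the shared interaction energy minimizing the profile RMSD.

    Every interaction declared in the template shares the single unknown
    dG_side; a bounded 1-D minimization (tolerance ``xatol`` kcal/mol)
    returns ``(dG_side, rmsd_at_minimum)``.
    """
    if not template.interactions:
        raise ValueError("template declares no interactions to fit")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")

    def objective(dg: float) -> float:
        return rmsd_hel(predict_profile(template.with_interaction_energy(dg)), observed)

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    return float(res.x), float(res.fun)
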