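"""(P3-7)_n scaffold design, Prosite-style motif scanning, acceptor ranking.

The sequence family scanned and designed here interleaves hydrophobic
H-bond acceptors (the class Omega = {L, F, Y, W, I, M}) with glutamine
donors four positions downstream, such that the donor of one i,i+4
side-chain-to-main-chain interaction and the acceptor of the next share a
peptide bond (the concatenated, cooperative arrangement).  The Prosite
pattern for ``n`` donor/acceptor pairs expands as::

    Omega-X-X-(Omega-Q-X)_{n-1}-Q-X-X-Q-X-X      (3n + 6 positions)

which for n = 4 reads
``[LFYWIM]-X-X-[LFYWIM]-Q-X-[LFYWIM]-Q-X-[LFYWIM]-Q-X-Q-X-X-Q-X-X``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_ACCEPTORS = "LFYWIM"


@dataclass(frozen=True)
class MotifSpec:
    n_pairs: int
    acceptor_set: str
    pattern: str  # Prosite syntax, positions joined by '-'

    @property
    def tokens(self) -> list[str]:
        return self.pattern.split("-")

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def regex(self) -> str:
        out = []
        for tok in self.tokens:
            if tok == "X":
                out.append(f"[{STANDARD_AA}]")
            else:
                out.append(tok)
        return "".join(out)


def compile_motif(n_pairs: int, acceptor_set: str = DEFAULT_ACCEPTORS) -> MotifSpec:
    """Expand the scaffold motif for ``n_pairs`` donor/acceptor pairs."""
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    omega = acceptor_set if len(acceptor_set) == 1 else f"[{acceptor_set}]"
    tokens = [omega, "X", "X"]
    for _ in range(n_pairs - 1):
        tokens += [omega, "Q", "X"]
    tokens += ["Q", "X", "X", "Q", "X", "X"]
    return MotifSpec(n_pairs, acceptor_set, "-".join(tokens))


@dataclass
class MatchReport:
    motif: MotifSpec
    per_record: dict[str, list[int]]  # record id -> 1-based match start positions
    skipped: list[str] = field(default_factory=list)

    @property
    def n_records_with_match(self) -> int:
        return sum(1 for pos in self.per_record.values() if pos)

    @property
    def total_matches(self) -> int:
        return sum(len(p) for p in self.per_record.values())

    def count(self, record_id: str) -> int:
        return len(self.per_record[record_id])

    def to_tsv(self, path) -> None:
        rows = [
            (rid, self.motif.n_pairs, len(pos), ";".join(map(str, pos)))
            for rid, pos in self.per_record.items()
        ]
        pd.DataFrame(
            rows, columns=["record_id", "n_pairs", "count", "positions"]
        ).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_pairs": self.motif.n_pairs,
            "pattern": self.motif.pattern,
            "records_scanned": len(self.per_record),
            "records_with_match": self.n_records_with_match,
            "total_matches": self.total_matches,
            "records_skipped": len(self.skipped),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def scan_sequences(
    records: dict[str, str],
    motif: MotifSpec,
    overlap_policy: str = "overlapping",
) -> MatchReport:
    """Scan sequences for the motif; positions are 1-based.

    ``overlap_policy='overlapping'`` counts every distinct start position
    (lookahead matching); ``'non-overlapping'`` advances past each match.
    Records with non-amino-acid characters are skipped with a warning.
    """
    if not records:
        raise ValueError("no records to scan")
    if overlap_policy not in ("overlapping", "non-overlapping"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    pattern = re.compile(
        f"(?=({motif.regex}))" if overlap_policy == "overlapping" else motif.regex
    )
    per_record: dict[str, list[int]] = {}
    skipped: list[str] = []
    valid = set(STANDARD_AA)
    for rid, seq in records.items():
        seq = seq.upper()
        if not set(seq) <= valid:
            warnings.warn(f"record {rid!r} contains non-amino-acid characters; skipped")
            skipped.append(rid)
            continue
        per_record[rid] = [m.start() + 1 for m in pattern.finditer(seq)]
    return MatchReport(motif, per_record, skipped)


@dataclass
class ScaffoldDesign:
    sequence: str
    n_units: int
    pairs: list[tuple[int, int]]        # Omega-anchored (acceptor, donor), 1-based
    tail_donors: list[tuple[int, int]]  # (acceptor slot, donor) for the tail Gln
    free_positions: list[int]           # guest-editable (X) positions
    ncap: str = ""

    @property
    def acceptor_positions(self) -> list[int]:
        return [a for a, _ in self.pairs]

    @property
    def donor_positions(self) -> list[int]:
        return [d for _, d in self.pairs] + [d for _, d in self.tail_donors]


def design_scaffold(
    n_units: int,
    ncap: str | None = None,
    guest: tuple[str, int] | None = None,
    acceptor: str = "L",
    filler: str = "A",
    control: bool = False,
) -> ScaffoldDesign:
    """Build a (P3-7)_n-style scaffold sequence with pair annotations.

    Vacant (X) positions default to Ala and may carry a guest motif;
    ``control=True`` replaces every acceptor by Ala, abolishing the
    helix-stabilizing interactions (the scaffold then fails the motif scan).
    Guest residues may only occupy free positions; a collision raises with
    the offending 1-based index.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    n_pairs = max(n_units, 2)  # a single unit already carries two donor/acceptor pairs
    spec = compile_motif(n_pairs)
    tokens = spec.tokens
    seq = []
    free: list[int] = []
    for i, tok in enumerate(tokens, start=1):
        if tok == "X":
            seq.append(filler)
            free.append(i)
        elif tok == "Q":
            seq.append("Q")
        else:  # acceptor class position
            seq.append(filler if control else acceptor)
    pairs = [(1, 5)] + [(4 + 3 * k, 8 + 3 * k) for k in range(n_pairs - 2)]
    n = len(tokens)
    tail = [(n - 9, n - 5), (n - 6, n - 2)]  # acceptor slots are free positions

    if guest is not None:
        gseq, anchor = guest
        if any(aa not in STANDARD_AA for aa in gseq.upper()):
            raise ValueError("guest contains non-standard residues")
        for j, aa in enumerate(gseq.upper()):
            pos = anchor + j
            if pos < 1 or pos > n:
                raise ValueError(f"guest position {pos} outside scaffold")
            if pos not in free:
                raise ValueError(f"guest collides with acceptor/donor position {pos}")
            seq[pos - 1] = aa

    cap = ncap or ""
    off = len(cap)
    return ScaffoldDesign(
        sequence=cap + "".join(seq),
        n_units=n_units,
        pairs=[(a + off, d + off) for a, d in pairs],
        tail_donors=[(a + off, d + off) for a, d in tail],
        free_positions=[p + off for p in free],
        ncap=cap,
    )


@dataclass
class AcceptorModel:
    """Standardized two-predictor OLS for observed helicity of L3XQ16 variants.

    Predictors: x1 = intrinsic helical propensity of the acceptor residue,
    x2 = mean SASA of the donor Gln He21 proton (A^2). All variables are
    z-scored on the training data, so the betas are directly comparable.
    """

    beta_helicity: float
    beta_sasa: float
    intercept: float
    r_squared: float
    se_beta: tuple[float, float]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    residues: list[str]

    @property
    def sasa_to_helicity_weight_ratio(self) -> float:
        return abs(self.beta_sasa) / abs(self.beta_helicity)


MAX_CONDITION_NUMBER = 1e6


def fit_acceptor_model(table: pd.DataFrame) -> AcceptorModel:
    """OLS on standardized (intrinsic helicity, He21 SASA) -> observed helicity.

    ``table`` needs columns ``residue``, ``intrinsic_helicity``, ``sasa``,
    ``observed_helicity`` with one row per acceptor residue type (>= 3 rows).
    """
    required = {"residue", "intrinsic_helicity", "sasa", "observed_helicity"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if len(table) < 3:
        raise ValueError("need at least 3 residues to fit")
    X = table[["intrinsic_helicity", "sasa"]].to_numpy(float)
    y = table["observed_helicity"].to_numpy(float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    y_mean, y_sd = y.mean(), y.std(ddof=0)
    if np.any(x_sd == 0) or y_sd == 0:
        raise ValueError("constant predictor or response")
    Z = (X - x_mean) / x_sd
    if np.linalg.cond(Z) > MAX_CONDITION_NUMBER:
        raise ValueError("predictors are collinear")
    zy = (y - y_mean) / y_sd
    design = np.column_stack([np.ones(len(Z)), Z])
    beta, _, _, _ = np.linalg.lstsq(design, zy, rcond=None)
    resid = zy - design @ beta
    dof = len(zy) - 3
    sigma2 = resid @ resid / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(design.T @ design)
    ss_tot = zy @ zy
    r2 = 1.0 - (resid @ resid) / ss_tot
    return AcceptorModel(
        beta_helicity=float(beta[1]),
        beta_sasa=float(beta[2]),
        intercept=float(beta[0]),
        r_squared=float(r2),
        se_beta=(float(np.sqrt(cov[1, 1])), float(np.sqrt(cov[2, 2]))),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=float(y_mean),
        y_sd=float(y_sd),
        residues=list(table["residue"]),
    )


def predict_mean_helicity(model: AcceptorModel, x1: float, x2: float) -> float:
    """De-standardized linear prediction, clipped to [0, 1] with a warning."""
    z1 = (x1 - model.x_mean[0]) / model.x_sd[0]
    z2 = (x2 - model.x_mean[1]) / model.x_sd[1]
    zy = model.intercept + model.beta_helicity * z1 + model.beta_sasa * z2
    y = model.y_mean + model.y_sd * zy
    if not 0.0 <= y <= 1.0:
        warnings.warn(f"predicted helicity {y:.3f} outside [0, 1]; clipped")
        y = float(np.clip(y, 0.0, 1.0))
    return float(y)


def read_fasta(path) -> dict[str, str]:
    import biotite.sequence.io.fasta as fasta

    return dict(fasta.FastaFile.read(str(path)).items())


def write_fasta(path, records: dict[str, str]) -> None:
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile()
    for rid, seq in records.items():
        ff[rid] = seq
    ff.write(str(path))
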