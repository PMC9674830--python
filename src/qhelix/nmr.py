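"""NMR observables: relaxation, spectral densities, CSP titrations, RDCs.

Implements the observable equations used throughout the package:

* exponential decay fits ``I_t = I_0 exp(-t/T)`` for T1/T2,
* R2/R1 ratios, heteronuclear 15N{1H} NOE and their error propagation,
* the rigid-rotor (isotropic tumbling) 15N dipolar + CSA rates and the
  rotational correlation time implied by R2/R1 plateaus,
* three-point reduced spectral density mapping J(0), J(wN), J(0.87 wH),
* combined 1H/15N chemical shift perturbations and global K_D fitting to
  the 1:1 single-site binding isotherm with Monte-Carlo concentration
  errors,
* RDC scaling and the Q-factor.

Physical constants (r_NH = 1.02 A, 15N CSA = -160 ppm, standard
gyromagnetic ratios) are module defaults and can be overridden; ratio-type
outputs are insensitive to r_NH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

GAMMA_H = 2.6752218744e8   # rad s^-1 T^-1
GAMMA_N = -2.7126e7        # rad s^-1 T^-1 (15N, negative)
MU0 = 4e-7 * np.pi
HBAR = 1.054571817e-34
R_NH_DEFAULT = 1.02        # A
CSA_N_DEFAULT = -160.0     # ppm
HIGH_FREQ_SCALE = 0.87     # effective proton frequency for reduced mapping


# ---------------------------------------------------------------- decays

@dataclass
class DecaySeries:
    delays: np.ndarray      # s
    intensities: np.ndarray
    owner: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size < 3:
            raise ValueError("need at least 3 delay points")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if np.unique(self.delays).size != self.delays.size:
            raise ValueError("delays must be distinct")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"delay_s": self.delays, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, owner: str = "") -> "DecaySeries":
        df = pd.read_csv(path)
        return cls(df["delay_s"].to_numpy(), df["intensity"].to_numpy(), owner)


@dataclass(frozen=True)
class DecayFit:
    time_constant: float  # s
    i0: float
    sd_time_constant: float
    sd_i0: float


def fit_decay(series: DecaySeries) -> DecayFit:
    """Nonlinear least squares for I(t) = I0 exp(-t/T); SDs from the covariance."""
    t, y = series.delays, series.intensities
    if y.max() <= 0:
        raise ValueError("intensities must be positive-dominated")
    # log-linear starting values on the positive points
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    p0 = (np.exp(intercept), -1.0 / slope if slope < 0 else t.max())

    def model(tt, i0, tau):
        return i0 * np.exp(-tt / tau)

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"decay fit did not converge: {err}") from err
    sds = np.sqrt(np.diag(pcov))
    return DecayFit(float(popt[1]), float(popt[0]), float(sds[1]), float(sds[0]))


def ratio_r2_r1(
    t1: float, t2: float, sd_t1: float = 0.0, sd_t2: float = 0.0
) -> tuple[float, float]:
    """R2/R1 = T1/T2 with first-order error propagation."""
    ratio = t1 / t2
    sd = abs(ratio) * np.hypot(sd_t1 / t1, sd_t2 / t2)
    return float(ratio), float(sd)


def het_noe(
    i_sat: float, i_ref: float, sd_sat: float = 0.0, sd_ref: float = 0.0
) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat/I_ref with two-spectrum error propagation."""
    noe = i_sat / i_ref
    sd = abs(noe) * np.hypot(sd_sat / i_sat, sd_ref / i_ref)
    return float(noe), float(sd)


# ------------------------------------------------- rigid rotor / mapping

def _interaction_constants(field: float, r_nh: float, csa_ppm: float):
    d = MU0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4.0 * np.pi * (r_nh * 1e-10) ** 3)
    w_h = abs(GAMMA_H) * field
    w_n = abs(GAMMA_N) * field
    c = w_n * csa_ppm * 1e-6 / np.sqrt(3.0)
    return d, c, w_h, w_n


def _j_iso(w: float, tau_c: float) -> float:
    return 0.4 * tau_c / (1.0 + (w * tau_c) ** 2)


def rigid_rates(
    tau_c_ns: float,
    field: float,
    r_nh: float = R_NH_DEFAULT,
    csa_ppm: float = CSA_N_DEFAULT,
) -> tuple[float, float, float]:
    """R1, R2 (s^-1) and NOE of a rigid isotropic rotor at the given field (T)."""
    if tau_c_ns <= 0 or field <= 0:
        raise ValueError("tau_c and field must be positive")
    tau = tau_c_ns * 1e-9
    d, c, w_h, w_n = _interaction_constants(field, r_nh, csa_ppm)
    j = lambda w: _j_iso(w, tau)
    r1 = d**2 / 4.0 * (j(w_h - w_n) + 3 * j(w_n) + 6 * j(w_h + w_n)) + c**2 * j(w_n)
    r2 = d**2 / 8.0 * (
        4 * j(0) + j(w_h - w_n) + 3 * j(w_n) + 6 * j(w_h) + 6 * j(w_h + w_n)
    ) + c**2 / 6.0 * (4 * j(0) + 3 * j(w_n))
    sigma = d**2 / 4.0 * (6 * j(w_h + w_n) - j(w_h - w_n))
    noe = 1.0 + (GAMMA_H / GAMMA_N) * sigma / r1
    return float(r1), float(r2), float(noe)


def rigid_ratio(
    tau_c_ns: float,
    field: float,
    r_nh: float = R_NH_DEFAULT,
    csa_ppm: float = CSA_N_DEFAULT,
) -> float:
    """Theoretical R2/R1 of a rigid body in isotropic motion."""
    r1, r2, _ = rigid_rates(tau_c_ns, field, r_nh, csa_ppm)
    return r2 / r1


def estimate_tauc(
    plateaus: list[tuple[float, float, float]],
    bounds: tuple[float, float] = (0.1, 50.0),
    r_nh: float = R_NH_DEFAULT,
    csa_ppm: float = CSA_N_DEFAULT,
) -> tuple[float, float]:
    """Correlation time from R2/R1 plateau(s) as (ratio, SD, field_T) tuples.

    Weighted least squares against the rigid-rotor ratio; the SD comes from
    the curvature of the chi-square profile at the minimum.
    """
    if not plateaus:
        raise ValueError("need at least one plateau")

    def chi2(tc: float) -> float:
        return sum(
            ((rigid_ratio(tc, f, r_nh, csa_ppm) - r) / (s if s > 0 else 1.0)) ** 2
            for r, s, f in plateaus
        )

    res = minimize_scalar(chi2, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    tc = float(res.x)
    h = 1e-3 * tc
    curv = (chi2(tc + h) - 2.0 * chi2(tc) + chi2(tc - h)) / h**2
    sd = float(np.sqrt(2.0 / curv)) if curv > 0 else np.inf
    return tc, sd


@dataclass
class RelaxationRecord:
    r1: float               # s^-1
    r2: float               # s^-1
    noe: float
    field: float            # T
    sd_r1: float = 0.0
    sd_r2: float = 0.0
    sd_noe: float = 0.0
    moiety: str = "NH"      # main-chain NH or side-chain Ne2

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0 or self.field <= 0:
            raise ValueError("R1, R2 and field must be positive")


@dataclass(frozen=True)
class SpectralDensities:
    j0: float               # s/rad
    j_wn: float
    j_wh_eff: float
    sd_j0: float = 0.0
    sd_j_wn: float = 0.0
    sd_j_wh_eff: float = 0.0


def _reduced_map(r1, r2, noe, d, c):
    sigma = (noe - 1.0) * r1 * GAMMA_N / GAMMA_H
    j_h = 4.0 * sigma / (5.0 * d**2)
    j_n = (r1 - 7.0 * d**2 / 4.0 * j_h) / (3.0 * d**2 / 4.0 + c**2)
    j_0 = (r2 - d**2 / 8.0 * (3.0 * j_n + 13.0 * j_h) - c**2 / 2.0 * j_n) / (
        d**2 / 2.0 + 2.0 * c**2 / 3.0
    )
    return j_0, j_n, j_h


def reduced_spectral_density(
    record: RelaxationRecord,
    r_nh: float = R_NH_DEFAULT,
    csa_ppm: float = CSA_N_DEFAULT,
    n_mc: int = 500,
    seed: int = 0,
) -> SpectralDensities:
    """Three-point reduced spectral density mapping of one 15N record.

    High-frequency terms are lumped at the effective frequency 0.87 wH.
    SDs (when the record carries SDs) are propagated by Monte Carlo.
    """
    d, c, _, _ = _interaction_constants(record.field, r_nh, csa_ppm)
    j0, jn, jh = _reduced_map(record.r1, record.r2, record.noe, d, c)
    sds = (0.0, 0.0, 0.0)
    if record.sd_r1 or record.sd_r2 or record.sd_noe:
        rng = np.random.default_rng(seed)
        draws = np.array(
            [
                _reduced_map(
                    record.r1 + record.sd_r1 * rng.standard_normal(),
                    record.r2 + record.sd_r2 * rng.standard_normal(),
                    record.noe + record.sd_noe * rng.standard_normal(),
                    d,
                    c,
                )
                for _ in range(n_mc)
            ]
        )
        sds = tuple(draws.std(axis=0))
    return SpectralDensities(j0, jn, jh, *map(float, sds))


# ----------------------------------------------------------- titrations

def csp(dd_1h: float, dd_15n: float) -> float:
    """Combined chemical shift perturbation sqrt(ddH^2 + (ddN/5)^2), ppm."""
    return float(np.sqrt(dd_1h**2 + (dd_15n / 5.0) ** 2))


def binding_isotherm(
    protein_uM: float | np.ndarray,
    peptide_uM: float | np.ndarray,
    kd_uM: float,
    ddmax: float = 1.0,
) -> np.ndarray:
    """Single-site 1:1 binding: dd = ddmax * [PL]/[P]_tot (exact quadratic)."""
    p = np.asarray(protein_uM, dtype=float)
    l = np.asarray(peptide_uM, dtype=float)
    s = p + l + kd_uM
    frac = (s - np.sqrt(s**2 - 4.0 * p * l)) / (2.0 * p)
    return ddmax * frac


@dataclass
class TitrationSeries:
    protein_uM: float
    data: pd.DataFrame  # columns: peak_id, peptide_uM, dd_1h, dd_15n

    def __post_init__(self) -> None:
        required = {"peak_id", "peptide_uM", "dd_1h", "dd_15n"}
        if not required <= set(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if self.protein_uM <= 0:
            raise ValueError("protein concentration must be positive")
        if self.data.groupby("peak_id")["peptide_uM"].count().min() < 4:
            raise ValueError("need >= 4 titration points per peak")

    @property
    def peak_ids(self) -> list:
        return sorted(self.data["peak_id"].unique())

    def csp_table(self) -> pd.DataFrame:
        df = self.data.copy()
        df["dd_av"] = np.sqrt(df["dd_1h"] ** 2 + (df["dd_15n"] / 5.0) ** 2)
        return df

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "protein_uM", self.protein_uM)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        df = pd.read_csv(path)
        return cls(float(df["protein_uM"].iloc[0]), df.drop(columns=["protein_uM"]))


@dataclass
class BindingFit:
    kd_uM: float
    kd_interval: tuple[float, float]  # Monte-Carlo 95% interval
    ddmax: dict                       # peak_id -> ddmax (ppm, averaged CSP)
    peaks_used: list
    unidentifiable: bool = False
    mc_kds: np.ndarray = field(default_factory=lambda: np.empty(0))


def _profile_fit_kd(peak_curves, protein_uM, kd_bounds):
    """1-D profile over K_D; per-peak ddmax solved linearly at each K_D."""

    def sse(log_kd: float) -> float:
        kd = 10.0**log_kd
        total = 0.0
        for lig, y in peak_curves:
            f = binding_isotherm(protein_uM, lig, kd)
            denom = f @ f
            amp = (f @ y) / denom if denom > 0 else 0.0
            r = y - amp * f
            total += r @ r
        return total

    res = minimize_scalar(
        sse,
        bounds=(np.log10(kd_bounds[0]), np.log10(kd_bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return 10.0 ** float(res.x), float(res.fun), sse


def fit_kd(
    titration: TitrationSeries,
    top_fraction: float = 0.10,
    mc_reps: int = 1000,
    conc_error: float = 0.20,
    seed: int | None = None,
    kd_bounds: tuple[float, float] = (1e-3, 1e6),
) -> BindingFit:
    """Global K_D from the top-CSP peaks of a titration.

    Peaks are ranked by averaged CSP at the final titration point and the
    top ``top_fraction`` (at least one) are fit globally: one shared K_D,
    one ddmax per peak.  The Monte-Carlo interval refits with protein and
    peptide concentrations perturbed uniformly within ``conc_error``.
    A fit pinned at the K_D search bounds, or with a flat profile, is
    flagged unidentifiable (interval unbounded above).
    """
    table = titration.csp_table()
    final_point = table.loc[table.groupby("peak_id")["peptide_uM"].idxmax()]
    ranked = final_point.sort_values("dd_av", ascending=False)
    n_top = max(1, int(np.ceil(top_fraction * len(ranked))))
    peaks = list(ranked["peak_id"].iloc[:n_top])

    curves = []
    for pid in peaks:
        sub = table[table["peak_id"] == pid].sort_values("peptide_uM")
        curves.append((sub["peptide_uM"].to_numpy(), sub["dd_av"].to_numpy()))

    kd, sse_min, sse_fn = _profile_fit_kd(curves, titration.protein_uM, kd_bounds)

    # identifiability: curvature of the SSE profile across one decade
    unident = False
    lo, hi = np.log10(kd_bounds)
    lk = np.log10(kd)
    if lk - lo < 1e-3 or hi - lk < 1e-3:
        unident = True
    else:
        probe = sse_fn(min(lk + 1.0, hi))
        scale = max(sse_min, 1e-12 * max(abs(probe), 1.0))
        if (probe - sse_min) / scale < 1e-3:
            unident = True

    ddmax = {}
    for pid, (lig, y) in zip(peaks, curves):
        f = binding_isotherm(titration.protein_uM, lig, kd)
        ddmax[pid] = float((f @ y) / (f @ f))

    rng = np.random.default_rng(seed)
    mc = np.empty(mc_reps)
    for r in range(mc_reps):
        fp = 1.0 + conc_error * rng.uniform(-1.0, 1.0)
        fl = 1.0 + conc_error * rng.uniform(-1.0, 1.0)
        pc = [(lig * fl, y) for lig, y in curves]
        mc[r], _, _ = _profile_fit_kd(pc, titration.protein_uM * fp, kd_bounds)
    interval = (float(np.percentile(mc, 2.5)), float(np.percentile(mc, 97.5)))
    if unident:
        interval = (interval[0], np.inf)
        warnings.warn("K_D unidentifiable: saturation not reached or fit at bounds")
    return BindingFit(kd, interval, ddmax, peaks, unident, mc)


# ------------------------------------------------------------------ RDCs

@dataclass
class RDCSet:
    observed: np.ndarray   # Hz
    predicted: np.ndarray  # Hz
    scale: float = np.nan
    q_factor: float = np.nan


def rdc_q(observed, predicted) -> tuple[float, float]:
    """Least-squares scale of predicted RDCs and the Q-factor.

    Q = rms(D_obs - s * D_pred) / rms(D_obs), with s minimizing the RMSD.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 5:
        raise ValueError("need >= 5 paired RDC values")
    s = float((obs @ pred) / (pred @ pred))
    q = float(np.sqrt(np.mean((obs - s * pred) ** 2) / np.mean(obs**2)))
    return s, q
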