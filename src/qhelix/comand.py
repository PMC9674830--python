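"""Diagonal-free NOESY strip decomposition (CoMAND-style, reduced scope).

A *strip* is the 1D 13C sub-spectrum of NOE contacts from one 15N-bound
proton.  Strips are back-calculated per conformer in the isolated-spin-pair
approximation: every 13C-bound proton within a distance cap of the strip
owner contributes intensity proportional to the ensemble average of r^-6,
rendered as a Lorentzian at the shift of its attached carbon.  The mixing
time and overall correlation time enter as a uniform intensity scale that
the R-factor scaling absorbs.

The R-factor between observed and calculated strips is
``sum|I_obs - s I_calc| / sum|I_obs|`` with s the least-absolute-deviation
optimal scale (a weighted median).  Per-strip ensembles are selected by the
stochastic greedy protocol (random starting conformer among the lowest-R
seed pool, conformers tested in random order, additions must improve R by
more than a threshold), repeated over many trials with a confidence trim;
the global optimizer alternates conformer addition with GMM-driven
side-chain resampling under a steric acceptance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc

from .builder import attached_heavy_atom, set_chi
from .ensemble import Ensemble
from .geometry import VDW_RADII
from .gmm import DihedralGMM, sample_sidechains

DISTANCE_CAP = 6.0   # A, NOE contributor cap
GRID_STEP = 0.005    # ppm
CLASH_TOLERANCE = 0.4  # A below the sum of vdW radii


@dataclass
class Strip:
    owner: tuple[int, str]       # (res_id, 15N-bound proton name)
    ppm_grid: np.ndarray         # strictly descending 13C ppm
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm_grid = np.asarray(self.ppm_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm_grid.size < 2 or np.any(np.diff(self.ppm_grid) >= 0):
            raise ValueError("ppm grid must be strictly descending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"ppm": self.ppm_grid, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, owner=(0, "?")) -> "Strip":
        df = pd.read_csv(path)
        return cls(owner, df["ppm"].to_numpy(), df["intensity"].to_numpy())


@dataclass(frozen=True)
class StripBackcalcParams:
    tau_c: float = 2.0                 # ns, overall correlation time
    halfwidth_hz: float = 14.0         # effective 13C signal halfwidth
    mixing_s: float = 0.4              # NOE mixing time
    spectrometer_13c_mhz: float = 201.2  # 13C frequency (800 MHz 1H)
    distance_cap: float = DISTANCE_CAP
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        for name in ("tau_c", "halfwidth_hz", "mixing_s", "spectrometer_13c_mhz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def fwhm_ppm(self) -> float:
        return self.halfwidth_hz / self.spectrometer_13c_mhz


@dataclass(frozen=True)
class SelectionConfig:
    improvement_threshold: float = 0.0005
    max_ensemble: int = 20
    seed_pool_size: int = 20
    n_trials: int = 100
    ci_trim: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.improvement_threshold <= 0:
            raise ValueError("improvement threshold must be positive")
        if self.max_ensemble < 1:
            raise ValueError("max_ensemble must be >= 1")


# --------------------------------------------------------- back-calculation

def carbon_bound_protons(ensemble: Ensemble) -> list[int]:
    """Topology indices of protons attached to carbon (13C-edited dimension)."""
    out = []
    stack = ensemble.stack
    for i in np.flatnonzero(stack.element == "H"):
        heavy = attached_heavy_atom(str(stack.res_name[i]), str(stack.atom_name[i]))
        if heavy is not None and heavy.startswith("C"):
            out.append(int(i))
    return out


def default_grid(
    assignments: dict, step: float = GRID_STEP, window: float = 0.35
) -> np.ndarray:
    """Descending ppm grid covering windows around every assigned shift.

    Regions far from any resonance carry no intensity, so the grid is the
    union of +-``window`` ppm intervals around the assigned carbon shifts.
    """
    shifts = np.unique(np.asarray(list(assignments.values()), dtype=float))
    pts: list[np.ndarray] = []
    lo = hi = None
    for s in shifts:
        if lo is None:
            lo, hi = s - window, s + window
        elif s - window <= hi:
            hi = s + window
        else:
            pts.append(np.arange(lo, hi + step / 2, step))
            lo, hi = s - window, s + window
    pts.append(np.arange(lo, hi + step / 2, step))
    return np.concatenate(pts)[::-1]


def _lorentz_matrix(ppms: np.ndarray, grid: np.ndarray, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return hw**2 / ((grid[None, :] - ppms[:, None]) ** 2 + hw**2)


class StripContext:
    """Precomputed contributor set and line shapes for one strip owner."""

    def __init__(
        self,
        ensemble: Ensemble,
        owner: tuple[int, str],
        assignments: dict[tuple[int, str], float],
        params: StripBackcalcParams,
        grid: np.ndarray | None = None,
    ):
        self.owner = owner
        self.owner_idx = ensemble.atom_index(*owner)
        stack = ensemble.stack
        cand = [i for i in carbon_bound_protons(ensemble) if i != self.owner_idx]
        dists = np.linalg.norm(
            stack.coord[:, cand, :] - stack.coord[:, [self.owner_idx], :], axis=2
        )
        within = dists.min(axis=0) <= params.distance_cap
        self.contrib_idx = np.array(cand, dtype=int)[within]
        missing = [
            (int(stack.res_id[i]), str(stack.atom_name[i]))
            for i in self.contrib_idx
            if (int(stack.res_id[i]), str(stack.atom_name[i])) not in assignments
        ]
        if missing:
            raise ValueError(f"unassigned contributing atoms: {missing}")
        ppms = np.array(
            [
                assignments[(int(stack.res_id[i]), str(stack.atom_name[i]))]
                for i in self.contrib_idx
            ]
        )
        self.grid = default_grid(assignments, params.grid_step) if grid is None else grid
        self.lorentz = _lorentz_matrix(ppms, self.grid, params.fwhm_ppm)
        self.scale = params.mixing_s * params.tau_c

    def amplitudes(self, coords: np.ndarray) -> np.ndarray:
        """Per-contributor r^-6 amplitudes for one frame's coordinates."""
        if self.contrib_idx.size == 0:
            return np.empty(0)
        r = np.linalg.norm(
            coords[self.contrib_idx] - coords[self.owner_idx], axis=1
        )
        return self.scale * r**-6

    def frame_profile(self, coords: np.ndarray) -> np.ndarray:
        if self.contrib_idx.size == 0:
            return np.zeros(self.grid.size)
        return self.amplitudes(coords) @ self.lorentz

    def pool_profiles(self, ensemble: Ensemble) -> np.ndarray:
        """(n_frames, n_grid) single-conformer back-calculations."""
        if self.contrib_idx.size == 0:
            return np.zeros((ensemble.n_frames, self.grid.size))
        coords = ensemble.stack.coord
        r = np.linalg.norm(
            coords[:, self.contrib_idx, :] - coords[:, [self.owner_idx], :], axis=2
        )
        return (self.scale * r**-6) @ self.lorentz


def back_calculate_strip(
    ensemble: Ensemble,
    owner: tuple[int, str],
    assignments: dict[tuple[int, str], float],
    params: StripBackcalcParams = StripBackcalcParams(),
    grid: np.ndarray | None = None,
) -> Strip:
    """Ensemble-averaged (<r^-6>) back-calculated strip for one owner proton."""
    ctx = StripContext(ensemble, owner, assignments, params, grid)
    profile = ctx.pool_profiles(ensemble).mean(axis=0)
    return Strip(owner, ctx.grid, profile)


# ----------------------------------------------------------------- R-factor

def _lad_scale(y: np.ndarray, c: np.ndarray) -> float:
    """Scale s minimizing sum|y - s c| (weighted median of y/c, weights |c|)."""
    w = np.abs(c)
    ok = w > 0
    if not ok.any():
        return 0.0
    ratios = y[ok] / c[ok]
    order = np.argsort(ratios)
    cw = np.cumsum(w[ok][order])
    k = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(ratios[order][min(k, ratios.size - 1)])


def r_factor(observed: Strip | np.ndarray, calculated: Strip | np.ndarray) -> float:
    """sum|I_obs - s I_calc| / sum|I_obs| at the optimal LAD scale s."""
    y = observed.intensity if isinstance(observed, Strip) else np.asarray(observed)
    c = calculated.intensity if isinstance(calculated, Strip) else np.asarray(calculated)
    if y.shape != c.shape:
        raise ValueError("strips must share one grid")
    denom = np.abs(y).sum()
    if denom == 0:
        raise ValueError("observed strip is all zero")
    s = _lad_scale(y, c)
    return float(np.abs(y - s * c).sum() / denom)


def _r_factor_rows(y: np.ndarray, calc: np.ndarray) -> np.ndarray:
    """Vectorized R-factor of one observed strip against many calculated rows."""
    denom = np.abs(y).sum()
    w = np.abs(calc)
    safe = np.where(w > 0, calc, 1.0)
    ratios = np.where(w > 0, y[None, :] / safe, np.inf)
    order = np.argsort(ratios, axis=1)
    w_sorted = np.take_along_axis(w, order, axis=1)
    cw = np.cumsum(w_sorted, axis=1)
    target = 0.5 * cw[:, -1:]
    k = (cw < target).sum(axis=1)
    k = np.minimum(k, ratios.shape[1] - 1)
    s = np.take_along_axis(
        np.take_along_axis(ratios, order, axis=1), k[:, None], axis=1
    )[:, 0]
    s = np.where(np.isfinite(s), s, 0.0)
    return np.abs(y[None, :] - s[:, None] * calc).sum(axis=1) / denom


# ------------------------------------------------------------ decomposition

@dataclass
class DecompositionResult:
    trials: list[list[int]]      # conformer indices per trial (with multiplicity)
    trial_r: np.ndarray
    retained: np.ndarray         # boolean mask over trials
    r_min: float

    @property
    def pooled(self) -> np.ndarray:
        """Conformers of all retained trials, concatenated with multiplicity."""
        kept = [t for t, keep in zip(self.trials, self.retained) if keep]
        return np.concatenate([np.asarray(t) for t in kept]) if kept else np.empty(0, int)


def _greedy_trial(
    profiles: np.ndarray,
    y: np.ndarray,
    seed_pool: np.ndarray,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> tuple[list[int], float]:
    start = int(rng.choice(seed_pool))
    members = [start]
    total = profiles[start].copy()
    current = _r_factor_rows(y, total[None, :] / 1.0)[0]
    while len(members) < config.max_ensemble:
        k = len(members)
        cand_r = _r_factor_rows(y, (total[None, :] + profiles) / (k + 1))
        order = rng.permutation(profiles.shape[0])
        added = False
        for idx in order:
            if current - cand_r[idx] > config.improvement_threshold:
                members.append(int(idx))
                total += profiles[idx]
                current = float(cand_r[idx])
                added = True
                break
        if not added:
            break
    return members, float(current)


def decompose_strip(
    observed: Strip,
    pool: Ensemble | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    assignments: dict | None = None,
    params: StripBackcalcParams = StripBackcalcParams(),
) -> DecompositionResult:
    """Stochastic per-strip ensemble selection over a conformer pool.

    ``pool`` is either an Ensemble (back-calculated here with the given
    assignments) or a precomputed (n_conformers, n_grid) profile matrix.
    Each trial grows an ensemble greedily from a random member of the
    lowest-R seed pool; trials with R significantly above average
    (mean + 1.645 SD, the upper 90% tail) are discarded.
    """
    if isinstance(pool, Ensemble):
        if assignments is None:
            raise ValueError("assignments required when pool is an Ensemble")
        ctx = StripContext(pool, observed.owner, assignments, params, observed.ppm_grid)
        profiles = ctx.pool_profiles(pool)
    else:
        profiles = np.asarray(pool, dtype=float)
    n_pool = profiles.shape[0]
    if n_pool < config.seed_pool_size:
        raise ValueError(
            f"pool of {n_pool} smaller than seed pool size {config.seed_pool_size}"
        )
    y = observed.intensity
    single_r = _r_factor_rows(y, profiles)
    seed_pool = np.argsort(single_r, kind="stable")[: config.seed_pool_size]

    trials, trial_r = [], np.empty(config.n_trials)
    for t in range(config.n_trials):
        rng = np.random.default_rng([config.seed, t])
        members, r = _greedy_trial(profiles, y, seed_pool, config, rng)
        trials.append(members)
        trial_r[t] = r
    cutoff = trial_r.mean() + 1.645 * trial_r.std(ddof=0)
    retained = trial_r <= cutoff
    return DecompositionResult(trials, trial_r, retained, float(trial_r.min()))


# -------------------------------------------------------------- witnesses

def sidechain_protons(ensemble: Ensemble, res_id: int) -> list[int]:
    stack = ensemble.stack
    mask = (stack.res_id == res_id) & (stack.element == "H") & (stack.atom_name != "H")
    return [int(i) for i in np.flatnonzero(mask)]


def witness_strips(
    res_id: int,
    pool: Ensemble,
    observed_strips: list[Strip],
    cap: float = DISTANCE_CAP,
) -> list[int]:
    """Indices of strips whose owner approaches any side-chain proton of res_id."""
    if pool.n_frames == 0:
        raise ValueError("empty pool")
    sc = sidechain_protons(pool, res_id)
    out = []
    for k, strip in enumerate(observed_strips):
        owner_idx = pool.atom_index(*strip.owner)
        if not sc:
            continue
        d = np.linalg.norm(
            pool.stack.coord[:, sc, :] - pool.stack.coord[:, [owner_idx], :], axis=2
        )
        if d.min() <= cap:
            out.append(k)
    return out


# ----------------------------------------------------------- greedy global

def _clash(frame: struc.AtomArray, res_id: int, tol: float = CLASH_TOLERANCE) -> bool:
    """Steric rule: a moved side chain may not come closer than
    (r_vdw_i + r_vdw_j - tol) to heavy atoms of other residues."""
    heavy = frame.element != "H"
    moved = (
        (frame.res_id == res_id)
        & heavy
        & ~np.isin(frame.atom_name, ["N", "CA", "C", "O", "CB"])
    )
    others = heavy & (frame.res_id != res_id)
    if not moved.any() or not others.any():
        return False
    radii = np.array([VDW_RADII[str(e)] for e in frame.element])
    d = np.linalg.norm(
        frame.coord[moved][:, None, :] - frame.coord[others][None, :, :], axis=2
    )
    limit = radii[moved][:, None] + radii[others][None, :] - tol
    return bool((d < limit).any())


@dataclass
class GlobalResult:
    members: list[struc.AtomArray]   # selected (possibly resampled) conformers
    member_sources: list[int]        # pool frame index of each member
    r_trace: list[float]             # global R after every accepted step
    repeat_r: np.ndarray             # final R of every repeat
    best_repeat: int

    @property
    def ensemble(self) -> Ensemble:
        return Ensemble.from_frames(self.members)


class _GlobalState:
    def __init__(self, contexts, strips, pool):
        self.contexts = contexts
        self.observed = [s.intensity for s in strips]
        self.pool = pool
        self.pool_profiles = [ctx.pool_profiles(pool) for ctx in contexts]

    def member_profiles(self, coords: np.ndarray) -> list[np.ndarray]:
        return [ctx.frame_profile(coords) for ctx in self.contexts]

    def global_r(self, sums: list[np.ndarray], n: int) -> float:
        return float(
            np.mean(
                [
                    _r_factor_rows(y, (s / n)[None, :])[0]
                    for y, s in zip(self.observed, sums)
                ]
            )
        )


def greedy_global(
    pool: Ensemble,
    observed_strips: list[Strip],
    gmm_models: dict[int, tuple[DihedralGMM, float]],
    assignments: dict[tuple[int, str], float],
    params: StripBackcalcParams = StripBackcalcParams(),
    config: SelectionConfig = SelectionConfig(),
    n_repeats: int = 20,
) -> GlobalResult:
    """Greedy global-R ensemble building with GMM side-chain resampling.

    Phase 1 repeatedly adds the pool conformer giving the greatest reduction
    in the global R-factor (mean R over all strips).  Phase 2 revisits every
    residue with a fitted GMM (given as ``{res_id: (model, chi3_center)}``)
    and every ensemble member, testing sampled side-chain conformations and
    accepting the best sterically acceptable one that lowers global R.  The
    two phases alternate until neither changes the ensemble; the whole
    protocol runs ``n_repeats`` times and the best repeat is returned.  The
    R trace is strictly decreasing at every accepted step by construction.
    """
    contexts = [
        StripContext(pool, s.owner, assignments, params, s.ppm_grid)
        for s in observed_strips
    ]
    state = _GlobalState(contexts, observed_strips, pool)

    best: tuple[float, dict] | None = None
    repeat_r = np.empty(n_repeats)
    for rep in range(n_repeats):
        rng = np.random.default_rng([config.seed, 7919, rep])
        members: list[struc.AtomArray] = []
        sources: list[int] = []
        profiles: list[list[np.ndarray]] = []  # per member, per strip
        sums = [np.zeros(ctx.grid.size) for ctx in state.contexts]
        trace: list[float] = []
        current = np.inf

        changed = True
        while changed:
            changed = False
            # phase 1: add the conformer with the greatest global-R reduction
            while len(members) < config.max_ensemble:
                n_new = len(members) + 1
                r_all = np.mean(
                    [
                        _r_factor_rows(y, (s[None, :] + pp) / n_new)
                        for y, s, pp in zip(
                            state.observed, sums, state.pool_profiles
                        )
                    ],
                    axis=0,
                )
                idx = int(np.argmin(r_all))
                if current - r_all[idx] <= config.improvement_threshold:
                    break
                frame = pool.frame(idx).copy()
                members.append(frame)
                sources.append(idx)
                mp = state.member_profiles(frame.coord)
                profiles.append(mp)
                sums = [s + p for s, p in zip(sums, mp)]
                current = float(r_all[idx])
                trace.append(current)
                changed = True
            # phase 2: side-chain resampling
            for res_id, (model, chi3_center) in sorted(gmm_models.items()):
                for m, frame in enumerate(members):
                    cands = sample_sidechains(
                        model,
                        chi3_centers=chi3_center,
                        seed=int(rng.integers(2**31)),
                    )
                    best_cand = None
                    for chi1, chi2, chi3 in cands:
                        trial = frame.copy()
                        set_chi(trial, res_id, 1, chi1)
                        set_chi(trial, res_id, 2, chi2)
                        try:
                            set_chi(trial, res_id, 3, chi3)
                        except ValueError:
                            pass  # residue without chi3
                        if _clash(trial, res_id):
                            continue
                        mp = state.member_profiles(trial.coord)
                        new_sums = [
                            s - old + new
                            for s, old, new in zip(sums, profiles[m], mp)
                        ]
                        r_new = state.global_r(new_sums, len(members))
                        if best_cand is None or r_new < best_cand[0]:
                            best_cand = (r_new, trial, mp, new_sums)
                    if best_cand is not None and current - best_cand[0] > 0:
                        current, members[m], profiles[m], sums = (
                            best_cand[0],
                            best_cand[1],
                            best_cand[2],
                            best_cand[3],
                        )
                        trace.append(current)
                        changed = True
        repeat_r[rep] = current
        if best is None or current < best[0]:
            best = (
                current,
                {"members": members, "sources": sources, "trace": trace, "rep": rep},
            )
    payload = best[1]
    return GlobalResult(
        payload["members"],
        payload["sources"],
        payload["trace"],
        repeat_r,
        payload["rep"],
    )


# ------------------------------------------------------------------- IO

def read_assignments(path) -> dict[tuple[int, str], float]:
    df = pd.read_csv(path)
    return {
        (int(r.res_id), str(r.atom_name)): float(r.ppm) for r in df.itertuples()
    }


def write_assignments(path, assignments: dict[tuple[int, str], float]) -> None:
    rows = [(rid, name, ppm) for (rid, name), ppm in assignments.items()]
    pd.DataFrame(rows, columns=["res_id", "atom_name", "ppm"]).to_csv(path, index=False)
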