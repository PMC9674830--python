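"""Gaussian mixture modelling of (chi1, chi2) dihedral pairs.

EM is modified for angular periodicity by re-centering every data point to
the image nearest the current cluster mean in each iteration (an
approximation to a fully wrapped-normal likelihood that is accurate for
cluster widths well below the 360-degree period; rotamer clusters have
SDs of order 10 degrees).  Model complexity is selected by fitting K = 1..9
with cluster seeds placed at rotamer-class centers in a fixed frequency
order and minimizing the Bayesian information criterion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .builder import wrap_deg
from .geometry import ROTAMER_CENTERS, classify_rotamer

#: Seed order for EM initialization: rotamer forms by decreasing typical
#: database frequency for helical Gln/Leu side chains (user-overridable).
ROTAMER_SEED_ORDER = ("mt", "tt", "mm", "tp", "pt", "tm", "mp", "pp", "pm")

COV_FLOOR = 1.0  # deg^2, eigenvalue floor preventing singular clusters
PRIOR_PRUNE = 1e-6
MIN_POINTS_PER_CLUSTER = 5


def rotamer_center(label: str) -> np.ndarray:
    return np.array([ROTAMER_CENTERS[label[0]], ROTAMER_CENTERS[label[1]]])


@dataclass
class DihedralGMM:
    means: np.ndarray       # (K, 2) degrees, wrapped to (-180, 180]
    covariances: np.ndarray  # (K, 2, 2) deg^2
    priors: np.ndarray      # (K,), sums to 1
    log_likelihood: float
    n_points: int
    ll_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.priors.size

    @property
    def bic(self) -> float:
        # free parameters per cluster: 2 means + 3 covariance, plus K-1 priors
        p = 6 * self.k - 1
        return p * np.log(self.n_points) - 2.0 * self.log_likelihood

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "means": self.means.tolist(),
                    "covariances": self.covariances.tolist(),
                    "priors": self.priors.tolist(),
                    "log_likelihood": self.log_likelihood,
                    "bic": self.bic,
                    "n_points": self.n_points,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DihedralGMM":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["means"]),
            np.array(d["covariances"]),
            np.array(d["priors"]),
            d["log_likelihood"],
            d["n_points"],
        )


def _floor_cov(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, COV_FLOOR)
    return vecs @ np.diag(vals) @ vecs.T


def fit_gmm(
    points: np.ndarray,
    k: int,
    init_means: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed_order: tuple[str, ...] = ROTAMER_SEED_ORDER,
) -> DihedralGMM:
    """Periodic EM fit of a K-component Gaussian mixture to (chi1, chi2) data."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    if n < MIN_POINTS_PER_CLUSTER * k:
        raise ValueError(f"need at least {MIN_POINTS_PER_CLUSTER * k} points for K={k}")
    pts = wrap_deg(pts)
    if init_means is None:
        init_means = np.array([rotamer_center(lbl) for lbl in seed_order[:k]])
    means = np.array(init_means, dtype=float)
    covs = np.array([np.diag([900.0, 900.0]) for _ in range(k)])
    priors = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    ll_trace: list[float] = []
    for _ in range(max_iter):
        # E-step on nearest-image displacements
        log_resp = np.empty((n, priors.size))
        disp = np.empty((n, priors.size, 2))
        for j in range(priors.size):
            d = wrap_deg(pts - means[j])
            disp[:, j] = d
            cov = covs[j]
            inv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            mahal = np.einsum("ni,ij,nj->n", d, inv, d)
            log_resp[:, j] = (
                np.log(priors[j]) - 0.5 * (mahal + logdet + 2.0 * np.log(2.0 * np.pi))
            )
        m = log_resp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_resp - m).sum(axis=1))
        ll = float(lse.sum())
        ll_trace.append(ll)
        resp = np.exp(log_resp - lse[:, None])

        # M-step
        nk = resp.sum(axis=0)
        keep = nk / n >= PRIOR_PRUNE
        if not keep.all():
            warnings.warn("degenerate cluster pruned during EM")
            means, covs = means[keep], covs[keep]
            resp = resp[:, keep]
            nk = nk[keep]
        priors = nk / n
        new_means = np.empty_like(means)
        new_covs = np.empty_like(covs)
        for j in range(priors.size):
            d = wrap_deg(pts - means[j])
            shift = (resp[:, j] @ d) / nk[j]
            new_means[j] = wrap_deg(means[j] + shift)
            dc = d - shift
            new_covs[j] = _floor_cov((resp[:, j][:, None] * dc).T @ dc / nk[j])
        means, covs = new_means, new_covs

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return DihedralGMM(means, covs, priors, ll_trace[-1], n, ll_trace)


def select_k(
    points: np.ndarray,
    k_max: int = 9,
    seed_order: tuple[str, ...] = ROTAMER_SEED_ORDER,
) -> DihedralGMM:
    """Fit K = 1..k_max and return the minimum-BIC model."""
    pts = np.asarray(points, dtype=float)
    best: DihedralGMM | None = None
    for k in range(1, k_max + 1):
        if pts.shape[0] < MIN_POINTS_PER_CLUSTER * k:
            break
        model = fit_gmm(pts, k, seed_order=seed_order)
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise ValueError("not enough points to fit any model")
    return best


def rotamer_fractions(model_or_angles) -> dict[str, float]:
    """Rotamer-label populations, from a fitted model or raw (chi1, chi2) rows.

    For a model, each cluster's prior mass is assigned to the label of its
    mean; for raw angles, points are hard-classified and counted.
    """
    out: dict[str, float] = {}
    if isinstance(model_or_angles, DihedralGMM):
        for mean, prior in zip(model_or_angles.means, model_or_angles.priors):
            lbl = classify_rotamer(mean[0], mean[1]).label
            out[lbl] = out.get(lbl, 0.0) + float(prior)
    else:
        pts = np.asarray(model_or_angles, dtype=float)
        for chi1, chi2 in pts:
            lbl = classify_rotamer(chi1, chi2).label
            out[lbl] = out.get(lbl, 0.0) + 1.0 / pts.shape[0]
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def sample_sidechains(
    model: DihedralGMM,
    chi3_centers: np.ndarray | float = 0.0,
    prob_cutoff: float = 0.05,
    chi3_trials: int = 5,
    chi3_sd: float = 8.0,
    max_combos: int = 30,
    seed: int | None = None,
) -> list[tuple[float, float, float]]:
    """Draw side-chain (chi1, chi2, chi3) candidates from the fitted mixture.

    Only clusters with prior >= ``prob_cutoff`` are sampled; at most
    ``max_combos`` chi1/chi2 pairs are drawn (cluster choice proportional to
    the renormalized priors) and each pair carries ``chi3_trials`` chi3
    values jittered with SD ``chi3_sd`` around the per-cluster chi3 center.
    """
    rng = np.random.default_rng(seed)
    keep = model.priors >= prob_cutoff
    if not keep.any():
        raise ValueError("no cluster passes the probability cutoff")
    idx = np.flatnonzero(keep)
    w = model.priors[keep] / model.priors[keep].sum()
    centers = np.broadcast_to(
        np.atleast_1d(np.asarray(chi3_centers, dtype=float)), (model.k,)
    )
    out: list[tuple[float, float, float]] = []
    for _ in range(max_combos):
        j = int(rng.choice(idx, p=w))
        pair = rng.multivariate_normal(model.means[j], model.covariances[j])
        chi1, chi2 = wrap_deg(pair)
        for _ in range(chi3_trials):
            chi3 = float(wrap_deg(centers[j] + chi3_sd * rng.standard_normal()))
            out.append((float(chi1), float(chi2), chi3))
    return out
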