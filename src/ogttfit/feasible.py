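"""Simulation-based exploration of the feasible box.

Parameter vectors are drawn uniformly from F0, simulated, filtered through
the clinical normality criteria, and the surviving 5-point profiles are
clustered into shape groups.  Each group contributes a representative
parameter vector theta*_j used both as local-regularization anchor and as
the seed of the staged initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .params import FREE_PARAM_NAMES, FeasibleBox, ParameterSet
from .records import OGTTRecord
from .solver import PROTOCOL_TIMES, SimulationError, SolverSettings, sample_at, simulate


@dataclass(frozen=True)
class NormalityCriteria:
    """Threshold-based clinical normality rules for an OGTT.

    Basal glycemia < 100 mg/dL, basal insulinemia < 15 uU/mL, glycemia never
    above 160 mg/dL, glycemia not persisting above 140 mg/dL at 2 h, and
    insulinemia not persisting above 60 uU/mL over the whole 120-min window.
    """

    basal_G_max: float = 100.0
    basal_I_max: float = 15.0
    G_peak_max: float = 160.0
    G_persist_max: float = 140.0
    I_persist_max: float = 60.0

    def __post_init__(self) -> None:
        vals = (self.basal_G_max, self.basal_I_max, self.G_peak_max,
                self.G_persist_max, self.I_persist_max)
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if self.G_persist_max >= self.G_peak_max:
            raise ValueError("persistence threshold must lie below the peak threshold")


def check_normality(G, I, times=None,
                    criteria: NormalityCriteria | None = None
                    ) -> tuple[bool, list[str]]:
    """Apply the five clinical normality rules; returns (pass, violations).

    With 5-point data, "persisting above 140 mg/dL over 2 h" is read as
    G(120) > 140, and "insulinemia persisting above 60 uU/mL for 120 min"
    as I exceeding 60 on the entire [0, 120] window -- the strictest
    readings consistent with sparse sampling.
    """
    c = criteria or NormalityCriteria()
    G = np.asarray(G, dtype=float)
    I = np.asarray(I, dtype=float)
    if times is None:
        times = PROTOCOL_TIMES[: G.size] if G.size == 5 else np.linspace(0, 120, G.size)
    times = np.asarray(times, dtype=float)
    window = times <= 120.0
    violations: list[str] = []
    if G[0] >= c.basal_G_max:
        violations.append("basal_glycemia")
    if I[0] >= c.basal_I_max:
        violations.append("basal_insulinemia")
    if G[window].max() > c.G_peak_max:
        violations.append("glycemia_peak")
    g120 = float(np.interp(120.0, times, G)) if times[-1] >= 120 else float(G[-1])
    if g120 > c.G_persist_max:
        violations.append("glycemia_persistence")
    if I[window].min() > c.I_persist_max:
        violations.append("insulinemia_persistence")
    return not violations, violations


@dataclass(frozen=True)
class ProfileGroup:
    """One cluster of normal simulated profiles with its representative."""

    group_id: int
    member_thetas: np.ndarray        # (m, 13)
    member_curves: np.ndarray        # (m, 10): 5 G then 5 I values
    representative: np.ndarray       # theta*_j, shape (13,)
    representative_curve: np.ndarray  # (10,)
    peak_summary: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return self.member_thetas.shape[0]


def sample_box(box: FeasibleBox, n: int, seed: int) -> np.ndarray:
    """``n`` uniform draws from F0; reproducible under a fixed seed."""
    rng = np.random.default_rng(seed)
    return box.sample(n, rng)


def _interior_peak_count(vals: np.ndarray) -> int:
    d = np.diff(vals)
    return int(np.sum((d[:-1] > 0) & (d[1:] < 0)))


def profile_features(curves: np.ndarray) -> np.ndarray:
    """Shape features for clustering 5+5-point profiles.

    Per curve (G and I separately): the 5 measurements min-max normalized
    and damped by a saturating relative-range weight ``w = min(range /
    (0.1*basal), 1)``, the interior peak count, and ``w`` itself.  The
    damping keeps near-flat profiles from being blown up to arbitrary
    shapes by the min-max normalization (their shape dimensions collapse
    toward zero together).  All features are invariant to per-curve
    rescaling of the measurement units.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    feats = np.empty((curves.shape[0], 14))
    for k, sl in enumerate((slice(0, 5), slice(5, 10))):
        block = curves[:, sl]
        lo = block.min(axis=1, keepdims=True)
        rng = block.max(axis=1, keepdims=True) - lo
        safe = np.where(rng == 0, 1.0, rng)
        basal = np.abs(block[:, 0])
        w = np.minimum(rng[:, 0] / np.where(basal == 0, 1.0, 0.1 * basal), 1.0)
        feats[:, 5 * k:5 * k + 5] = (block - lo) / safe * w[:, None]
        feats[:, 10 + k] = [_interior_peak_count(row) for row in block]
        feats[:, 12 + k] = w
    return feats


def simulate_profiles(thetas: np.ndarray, basals: np.ndarray,
                      settings: SolverSettings | None = None,
                      criteria: NormalityCriteria | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate sampled parameter vectors and keep the clinically normal ones.

    ``basals`` is (n, 2) with per-draw (G_b, I_b).  Returns (kept_thetas,
    kept_basals, kept_curves) where curves stack the protocol-time G and I.
    """
    settings = settings or SolverSettings(method="rk4")
    kept_t, kept_b, kept_c = [], [], []
    for theta, (gb, ib) in zip(thetas, basals):
        try:
            params = ParameterSet.from_free_vector(theta, gb, ib)
            traj = simulate(params, settings)
        except (SimulationError, ValueError):
            continue
        ok, _ = check_normality(traj.G, traj.I, traj.times, criteria)
        if not ok:
            continue
        G5, I5 = sample_at(traj, PROTOCOL_TIMES)
        kept_t.append(theta)
        kept_b.append((gb, ib))
        kept_c.append(np.concatenate([G5, I5]))
    if not kept_t:
        return (np.empty((0, len(FREE_PARAM_NAMES))), np.empty((0, 2)),
                np.empty((0, 10)))
    return np.array(kept_t), np.array(kept_b), np.array(kept_c)


def cluster_profiles(thetas: np.ndarray, curves: np.ndarray,
                     k: int | str = "auto", seed: int = 0
                     ) -> list[ProfileGroup]:
    """Partition normal profiles into shape groups (k-means on shape
    features); the representative is the member whose curve is closest to
    the group's mean curve.  Deterministic under a fixed seed."""
    n = curves.shape[0]
    if k == "auto":
        best_k, best_score = 2, -np.inf
        feats = profile_features(curves)
        for kk in range(2, min(8, n - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(feats)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(feats, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    if n < k:
        raise ValueError(
            f"only {n} normal profiles for {k} clusters: increase the "
            "exploration budget"
        )
    feats = profile_features(curves)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(feats)
    groups: list[ProfileGroup] = []
    for gid in range(k):
        mask = labels == gid
        member_curves = curves[mask]
        member_thetas = thetas[mask]
        mean_curve = member_curves.mean(axis=0)
        rep_idx = int(np.argmin(np.sum((member_curves - mean_curve) ** 2, axis=1)))
        groups.append(
            ProfileGroup(
                group_id=gid,
                member_thetas=member_thetas,
                member_curves=member_curves,
                representative=member_thetas[rep_idx],
                representative_curve=member_curves[rep_idx],
                peak_summary={
                    "mean_G_peaks": float(np.mean(
                        [_interior_peak_count(c[:5]) for c in member_curves])),
                    "mean_I_peaks": float(np.mean(
                        [_interior_peak_count(c[5:]) for c in member_curves])),
                },
            )
        )
    return groups


def assign_group(record: OGTTRecord, groups: list[ProfileGroup]) -> ProfileGroup:
    """Nearest group by the clustering shape metric (mean feature vector);
    ties break deterministically toward the lower group id."""
    if not groups:
        raise ValueError("no profile groups available")
    rec_feat = profile_features(
        np.concatenate([record.G_exp, record.I_exp])[None, :])[0]
    dists = []
    for g in groups:
        centroid = profile_features(g.member_curves).mean(axis=0)
        dists.append(float(np.sum((rec_feat - centroid) ** 2)))
    order = sorted(range(len(groups)), key=lambda i: (dists[i], groups[i].group_id))
    return groups[order[0]]


def explore_feasible_set(box: FeasibleBox, n: int, seed: int,
                         basal_G_range: tuple[float, float] = (78.0, 96.0),
                         basal_I_range: tuple[float, float] = (4.0, 12.0),
                         k: int | str = "auto",
                         settings: SolverSettings | None = None,
                         criteria: NormalityCriteria | None = None,
                         ) -> list[ProfileGroup]:
    """Full exploration stage: sample F0, simulate, filter, cluster."""
    rng = np.random.default_rng(seed)
    thetas = box.sample(n, rng)
    basals = np.column_stack([
        rng.uniform(*basal_G_range, size=n),
        rng.uniform(*basal_I_range, size=n),
    ])
    kept_t, _, kept_c = simulate_profiles(thetas, basals, settings, criteria)
    return cluster_profiles(kept_t, kept_c, k=k, seed=seed)


def groups_to_frame(groups: list[ProfileGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row = {"group_id": g.group_id, "member_count": g.n_members}
        row.update(dict(zip(FREE_PARAM_NAMES, g.representative)))
        rows.append(row)
    return pd.DataFrame(rows)
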