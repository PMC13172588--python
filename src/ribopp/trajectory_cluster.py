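"""Metabolite trajectory clustering and ordination.

Implements the cohort-level trajectory workflow: z-score normalization of
per-metabolite group-mean profiles, fuzzy c-means clustering (soft k-means
with fuzzifier m, in the style of time-course omics clustering), elbow-based
selection of the cluster number, membership-based assignment, selection of
monotone (progressively increasing/decreasing) clusters, and cross-cohort
intersection of their members. Principal coordinates analysis (classical
multidimensional scaling) and PERMANOVA provide the ordination and the
between-group significance test on sample-level profiles.

Fuzzy c-means minimizes

    J(U, C) = sum_i sum_j  u_ij^m  ||x_i - c_j||^2

subject to each membership row of U summing to one, by alternating the
closed-form updates u_ij ~ (1/d_ij^2)^(1/(m-1)) (row-normalized) and
c_j = sum_i u_ij^m x_i / sum_i u_ij^m. A point coinciding with a center
receives full membership in that cluster (the m -> limit convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetabolitePanel",
    "ClusterModel",
    "PermanovaResult",
    "zscore_profiles",
    "fuzzy_cmeans",
    "choose_k_elbow",
    "select_monotone_cluster",
    "intersect_cohorts",
    "pcoa_embed",
    "permanova",
]


@dataclass
class MetabolitePanel:
    """Metabolite x ordered-group abundance panel for one cohort.

    ``values``: DataFrame of group means, rows metabolites, columns the
    ordered group labels. ``replicate_values`` / ``replicate_groups``
    optionally hold sample-level data (samples x metabolites and the
    sample -> group labels) for PERMANOVA. ``true_shapes`` is populated by
    the synthetic generator only.
    """

    cohort: str
    groups: tuple[str, ...]
    values: pd.DataFrame
    replicate_values: pd.DataFrame | None = None
    replicate_groups: pd.Series | None = None
    true_shapes: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.groups) != len(set(self.groups)):
            raise ValueError("group labels must be distinct and ordered")
        if list(self.values.columns) != list(self.groups):
            raise ValueError("panel columns must equal the ordered group labels")
        if not self.values.index.is_unique:
            raise ValueError("duplicate metabolite names within a cohort")


def zscore_profiles(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores of group-mean profiles.

    Each row is centered and scaled to unit sample standard deviation
    (n-1 denominator). Constant rows become all-zero and are flagged in
    the returned boolean Series. A single-column input is an error.
    """
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least two groups")
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[flat, :] = 0.0
    return (
        pd.DataFrame(z, index=values.index, columns=values.columns),
        pd.Series(flat, index=values.index, name="constant"),
    )


# ---------------------------------------------------------------------------
# fuzzy c-means


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    k: int
    m: float
    centers: np.ndarray  # k x n_features
    memberships: pd.DataFrame  # items x k, rows sum to 1
    objective: float
    n_iter: int
    seed: int | None
    objective_history: list[float] = field(default_factory=list, repr=False)

    @property
    def assignment(self) -> pd.Series:
        """Hard assignment: argmax membership (lowest index wins ties)."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )


def _memberships_from_centers(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():  # coincident point: full membership split over exact hits
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    w = d2[~hit] ** (-1.0 / (m - 1.0))
    u[~hit] = w / w.sum(axis=1, keepdims=True)
    return u


def _objective(x: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u**m) * d2).sum())


def _fit_once(
    x: np.ndarray, k: int, m: float, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centers = x[rng.choice(x.shape[0], size=k, replace=False)].copy()
    history: list[float] = []
    prev = np.inf
    for it in range(1, max_iter + 1):
        u = _memberships_from_centers(x, centers, m)
        um = u**m
        denom = um.sum(axis=0)[:, None]
        # a cluster losing all mass keeps its previous center
        new_centers = np.where(denom > 0, (um.T @ x) / np.where(denom == 0, 1, denom), centers)
        centers = new_centers
        obj = _objective(x, centers, u, m)
        history.append(obj)
        if prev - obj < tol * max(1.0, abs(prev)):
            break
        prev = obj
    return centers, u, history[-1], it, history


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    m: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 300,
    n_starts: int = 10,
    seed: int | None = None,
) -> ClusterModel:
    """Fuzzy c-means on row profiles (Euclidean distance).

    Runs ``n_starts`` restarts from random distinct data points (child
    seeds derived deterministically from ``seed``) and keeps the best
    objective. ``m`` is the fuzzifier (> 1; m -> 1 approaches hard
    k-means, larger m softens memberships).
    """
    x = np.asarray(profiles, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if k > np.unique(x, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct profiles")

    best: tuple | None = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, start]))
        fit = _fit_once(x, k, m, tol, max_iter, rng)
        if best is None or fit[2] < best[2]:
            best = fit
    centers, u, obj, n_iter, history = best
    drops = np.diff(history)
    if (drops > 1e-8 * max(1.0, abs(history[0]))).any():
        warnings.warn("objective increased during fitting beyond tolerance", stacklevel=2)
    memberships = pd.DataFrame(
        u, index=profiles.index if isinstance(profiles, pd.DataFrame) else None,
        columns=[f"cluster_{j}" for j in range(k)],
    )
    return ClusterModel(
        k=k, m=m, centers=centers, memberships=memberships, objective=obj,
        n_iter=n_iter, seed=seed, objective_history=history,
    )


def choose_k_elbow(
    profiles: pd.DataFrame,
    k_range: range | tuple[int, ...] = range(2, 9),
    m: float = 2.0,
    seed: int | None = None,
    n_starts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Elbow selection of the cluster number.

    Fits fuzzy c-means (best of restarts) for each k and picks the k whose
    point (k, J(k)) lies farthest from the chord joining the first and
    last points of the curve, after normalizing both axes to [0, 1]
    (Kneedle-style). Returns ``(k, curve)`` with the full objective curve.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = np.asarray(profiles).shape[0]
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two values")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n_profiles - 1]")

    js = []
    for k in ks:
        model = fuzzy_cmeans(profiles, k, m=m, seed=seed, n_starts=n_starts)
        js.append(model.objective)
    curve = pd.DataFrame({"k": ks, "objective": js})

    if (np.diff(js) > 1e-6 * max(1.0, abs(js[0]))).any():
        warnings.warn("objective curve not monotone decreasing in k", stacklevel=2)

    if len(ks) == 2:
        warnings.warn("k_range of length 2: chord degenerate, returning k_min", stacklevel=2)
        return ks[0], curve

    kx = (np.array(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    span = js[0] - js[-1]
    jy = (np.array(js) - js[-1]) / (span if span != 0 else 1.0)
    # distance from (kx, jy) to the chord from (0, jy[0]) to (1, jy[-1])
    chord = jy[0] + (jy[-1] - jy[0]) * kx
    dist = np.abs(jy - chord)
    best = int(np.argmax(dist))
    return ks[best], curve


def select_monotone_cluster(
    model: ClusterModel,
    direction: str = "increasing",
    min_membership: float = 0.5,
) -> set[str]:
    """Members of clusters whose center is strictly monotone.

    Selects every cluster whose center vector is strictly increasing (or
    decreasing) along the ordered groups, then returns the items assigned
    there (argmax membership) whose membership is at least
    ``min_membership``. Warns and returns the empty set when no cluster is
    monotone in the requested direction.
    """
    if direction not in {"increasing", "decreasing"}:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    diffs = np.diff(model.centers, axis=1)
    mono = (diffs > 0).all(axis=1) if direction == "increasing" else (diffs < 0).all(axis=1)
    selected = np.flatnonzero(mono)
    if selected.size == 0:
        warnings.warn(f"no {direction} cluster found", stacklevel=2)
        return set()
    assign = model.assignment
    top = model.memberships.to_numpy().max(axis=1)
    members: set[str] = set()
    for j in selected:
        mask = (assign.to_numpy() == j) & (top >= min_membership)
        members |= set(assign.index[mask])
    return members


def intersect_cohorts(member_sets: list[set[str]] | dict[str, set[str]]) -> list[str]:
    """Metabolite names common to every cohort (case/whitespace normalized)."""
    sets = list(member_sets.values()) if isinstance(member_sets, dict) else list(member_sets)
    if len(sets) < 2:
        raise ValueError("need at least two cohorts to intersect")
    norm = [{str(s).strip().lower() for s in members} for members in sets]
    common = set.intersection(*norm)
    return sorted(common)


# ---------------------------------------------------------------------------
# ordination


def pcoa_embed(
    distance: np.ndarray, n_axes: int = 2, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates analysis (classical scaling).

    Double-centers the squared distance matrix to the Gram matrix
    B = -1/2 J D^2 J and eigendecomposes it. Axes are ordered by
    decreasing eigenvalue; axes with negative eigenvalues (non-Euclidean
    distances) are reported in the eigenvalue vector but never embedded.
    Returns ``(coordinates, eigenvalues)`` with coordinates of shape
    (n, n_axes).
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=tol):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0, atol=tol):
        raise ValueError("distance matrix diagonal must be zero")
    if (d < -tol).any():
        raise ValueError("distances must be non-negative")

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    coords = np.zeros((n, n_axes))
    for ax in range(min(n_axes, n)):
        if eigvals[ax] > tol:
            coords[:, ax] = eigvecs[:, ax] * np.sqrt(eigvals[ax])
    return coords, eigvals


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    """Permutational multivariate ANOVA summary."""

    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def permanova(
    distance: np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the total sum of squared distances into between- and
    within-group components; pseudo-F = (SS_b/(a-1)) / (SS_w/(N-a)) for a
    groups and N samples; R^2 = SS_b / SS_total. The p-value is
    (1 + #{permuted F >= observed F}) / (n_permutations + 1) under random
    relabeling.
    """
    d = np.asarray(distance, dtype=float)
    y = np.asarray(labels)
    if d.shape[0] != d.shape[1] or d.shape[0] != y.size:
        raise ValueError("distance matrix and labels are inconsistent")
    groups, counts = np.unique(y, return_counts=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")

    d2 = d**2
    n, a = y.size, groups.size
    ss_total, ss_within = _permanova_ss(d2, y)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        sst, ssw = _permanova_ss(d2, perm)
        ssb = sst - ssw
        f_perm = (ssb / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(
        f_statistic=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
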