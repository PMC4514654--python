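"""Assessment machinery for network predictions.

Confusion counts and rates, ROC / precision-recall curves and areas,
permutation-null p-values with the combined challenge score, error / bias
convergence curves, and empirical phase-transition experiments for the
sparse solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solvers import SolverOptions, smomp_solve, stomp_solve, tls_solve

__all__ = [
    "ConfusionSummary",
    "CurveSet",
    "DreamScoreReport",
    "confusion",
    "roc_pr",
    "average_curves",
    "dream_pvalue",
    "dream_score",
    "error_bias_curves",
    "phase_experiment",
    "offdiagonal_scores",
]


@dataclass
class ConfusionSummary:
    """Edge-presence confusion counts and the derived rates.

    FS counts predicted-nonzero, truly-nonzero cells whose estimated sign
    disagrees with the truth; it is reported but plays no role in the
    presence-only rates.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    FS: int
    P: int
    N: int
    tpr: float
    fpr: float
    fnr: float
    tnr: float
    ppv: float


@dataclass
class CurveSet:
    """ROC and precision-recall curves with their areas."""

    roc_points: np.ndarray  # (fpr, tpr) rows, threshold descending
    pr_points: np.ndarray   # (recall, precision) rows
    auroc: float
    aupr: float


@dataclass
class DreamScoreReport:
    """Permutation p-values and the combined log-significance score."""

    p_auroc: list[float]
    p_aupr: list[float]
    score: float
    n_permutations: int


def offdiagonal_scores(
    truth: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten matched off-diagonal (label, score) pairs of two n x n matrices."""
    truth = np.asarray(truth)
    scores = np.asarray(scores)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores shapes differ")
    mask = ~np.eye(truth.shape[0], dtype=bool)
    return (truth[mask] != 0).astype(int), np.abs(scores[mask]).astype(float)


def confusion(
    truth: np.ndarray, estimate: np.ndarray, zero_tol: float = 1e-8
) -> ConfusionSummary:
    """Confusion counts over off-diagonal cells of two adjacency matrices.

    A cell counts as a predicted (or true) edge when its magnitude exceeds
    ``zero_tol``; the diagonal is excluded everywhere.
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs estimate {estimate.shape}"
        )
    mask = ~np.eye(truth.shape[0], dtype=bool)
    t = truth[mask]
    e = estimate[mask]
    t_nz = np.abs(t) > zero_tol
    e_nz = np.abs(e) > zero_tol

    TP = int(np.sum(t_nz & e_nz))
    FP = int(np.sum(~t_nz & e_nz))
    TN = int(np.sum(~t_nz & ~e_nz))
    FN = int(np.sum(t_nz & ~e_nz))
    FS = int(np.sum(t_nz & e_nz & (np.sign(t) != np.sign(e))))
    P = int(np.sum(t_nz))
    N = int(np.sum(~t_nz))
    return ConfusionSummary(
        TP=TP, FP=FP, TN=TN, FN=FN, FS=FS, P=P, N=N,
        tpr=TP / P if P else float("nan"),
        fpr=FP / N if N else float("nan"),
        fnr=FN / P if P else float("nan"),
        tnr=TN / N if N else float("nan"),
        ppv=TP / (TP + FP) if TP + FP else float("nan"),
    )


def roc_pr(scores: np.ndarray, labels: np.ndarray) -> CurveSet:
    """ROC and PR curves by scanning all distinct score thresholds.

    Tied scores are grouped at a single threshold.  AUROC is the
    trapezoidal area over (fpr, tpr) — equal to the tie-corrected
    Mann-Whitney statistic — and AUPR uses the step-wise
    achievable-precision integration (no linear precision interpolation),
    the standard choice for heavily class-imbalanced edge prediction.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    P = int(labels.sum())
    N = int(labels.size - P)
    if P == 0 or N == 0:
        raise ValueError("need at least one positive and one negative label")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # group ties: indices where a threshold block ends
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(l)[distinct]
    fp = distinct + 1 - tp

    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    recall = tpr
    precision = np.r_[1.0, tp / (tp + fp)]

    auroc = float(np.trapezoid(tpr, fpr))
    aupr = float(np.sum(np.diff(recall) * precision[1:]))
    return CurveSet(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        auroc=auroc, aupr=aupr,
    )


def average_curves(
    curves: list[np.ndarray], grid_size: int = 201
) -> np.ndarray:
    """Vertically average (x, y) curves on a uniform x grid in [0, 1].

    Each curve is interpolated at the grid points (step-wise linear) and
    the y values averaged; identical replicates average to themselves.
    """
    if not curves:
        raise ValueError("no curves supplied")
    grid = np.linspace(0.0, 1.0, grid_size)
    ys = []
    for c in curves:
        c = np.asarray(c, dtype=float)
        order = np.argsort(c[:, 0], kind="stable")
        ys.append(np.interp(grid, c[order, 0], c[order, 1]))
    return np.column_stack([grid, np.mean(ys, axis=0)])


def dream_pvalue(
    observed: float,
    labels: np.ndarray,
    metric: str = "auroc",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value of a curve-area metric under random link ordering.

    Estimates the upper-tail probability that a uniformly random ordering
    of the potential links reaches the observed metric against the same
    gold standard, with add-one smoothing so the p-value is never zero.
    """
    labels = np.asarray(labels).ravel().astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("gold standard needs both positives and negatives")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("auroc", "aupr"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = rng or np.random.default_rng()

    count = 0
    n = labels.size
    for _ in range(n_perm):
        random_scores = rng.permutation(n).astype(float)
        cs = roc_pr(random_scores, labels)
        value = cs.auroc if metric == "auroc" else cs.aupr
        if value >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def dream_score(p_auroc: list[float], p_aupr: list[float]) -> float:
    """Combined significance score -1/2 log10 of the geometric-mean p-values."""
    p_auroc = np.asarray(p_auroc, dtype=float)
    p_aupr = np.asarray(p_aupr, dtype=float)
    for p in (p_auroc, p_aupr):
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
    g_roc = np.prod(p_auroc) ** (1.0 / p_auroc.size)
    g_pr = np.prod(p_aupr) ** (1.0 / p_aupr.size)
    return float(-0.5 * np.log10(g_roc * g_pr))


def error_bias_curves(
    estimates: list[list[np.ndarray]], truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared error and squared bias per data length.

    ``estimates[h]`` holds the M replicate coefficient estimates at the
    h-th data length; returns ``(mse, bias_sq)`` arrays, one value per
    length: ``mse = mean_h ||xhat_h - x||^2`` and ``bias_sq =
    ||mean_h xhat_h - x||^2``.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    mse = np.empty(len(estimates))
    bias_sq = np.empty(len(estimates))
    for idx, reps in enumerate(estimates):
        X = np.vstack([np.asarray(r, dtype=float).ravel() for r in reps])
        if X.shape[1] != truth.size:
            raise ValueError(
                f"estimate length {X.shape[1]} does not match truth "
                f"{truth.size} at data length index {idx}"
            )
        diff = X - truth
        mse[idx] = float(np.mean(np.sum(diff**2, axis=1)))
        mean_err = X.mean(axis=0) - truth
        bias_sq[idx] = float(np.sum(mean_err**2))
    return mse, bias_sq


_PHASE_SOLVERS = {"smomp": smomp_solve, "stomp": stomp_solve}


def phase_experiment(
    n: int,
    delta_grid: np.ndarray,
    rho_grid: np.ndarray,
    trials: int = 50,
    solver: str = "smomp",
    success_tol: float = 1e-3,
    seed: int = 0,
    opts: SolverOptions | None = None,
) -> np.ndarray:
    """Empirical recovery-success frequencies over an undersampling grid.

    For every combination of undersampling ratio ``delta = m/n`` and
    sparsity ratio ``rho = k/m``: draw a Gaussian measurement matrix with
    normalized columns and a k-sparse vector with unit-scale nonzeros,
    and count the fraction of trials in which the solver attains relative
    l2 error below ``success_tol``.  Cells whose rounded ``k`` leaves
    ``k < 1`` or ``k >= m`` are skipped and flagged NaN.
    """
    if solver not in _PHASE_SOLVERS:
        raise ValueError(f"solver must be one of {sorted(_PHASE_SOLVERS)}")
    delta_grid = np.asarray(delta_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any((delta_grid <= 0) | (delta_grid > 1)) or np.any(
        (rho_grid <= 0) | (rho_grid > 1)
    ):
        raise ValueError("grids must lie in (0, 1]")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    solve = _PHASE_SOLVERS[solver]
    opts = opts or SolverOptions()

    freq = np.full((delta_grid.size, rho_grid.size), np.nan)
    for a, delta in enumerate(delta_grid):
        m = int(round(delta * n))
        for b_idx, rho in enumerate(rho_grid):
            k = int(round(rho * m))
            if k < 1 or k >= m:
                continue  # flagged NaN
            # per-cell stream: cell results do not depend on grid layout
            rng = np.random.default_rng([seed, a, b_idx])
            successes = 0
            for _ in range(trials):
                Phi = rng.normal(size=(m, n))
                Phi /= np.linalg.norm(Phi, axis=0)
                x = np.zeros(n)
                idx = rng.choice(n, size=k, replace=False)
                signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
                x[idx] = signs * rng.uniform(1.0, 2.0, size=k)
                sol = solve(Phi, Phi @ x, opts)
                err = np.linalg.norm(sol.coefficients - x) / np.linalg.norm(x)
                successes += err < success_tol
            freq[a, b_idx] = successes / trials
    return freq
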