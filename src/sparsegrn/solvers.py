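"""Stagewise sparse solvers for underdetermined linear systems y = Phi x.

Implements SmOMP (stagewise modified orthogonal matching pursuit), which
augments plain StOMP with (i) an iterative outlier-deletion estimate of the
null matched-filter variance and (ii) a true-positive-rate-based refinement
of each stage's candidate set, plus StOMP itself as the reference stagewise
solver and classical SVD-based total least squares as a dense baseline.

The matched-filter coefficients Phi^T r at a given stage are modelled as a
two-component Gaussian mixture: a zero-mean "null" component at coordinates
outside the true support and a "nonnull" component N(mu, sigma2^2) at true
support coordinates.  Hard thresholding at t * sigma_null classifies the
coordinates; SmOMP then keeps only the floor(k_s * beta_s) largest projected
amplitudes, where beta_s = Pr(|N(mu_s, sigma_{s,2}^2)| > t_s sigma_{s,1}) is
the estimated per-stage true positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import norm

__all__ = [
    "SolverOptions",
    "StageTrace",
    "SparseSolution",
    "DegenerateInputError",
    "matched_filter",
    "estimate_null_sigma",
    "fac_threshold",
    "estimate_nonnull_params",
    "tpr_beta",
    "refine_support",
    "smomp_solve",
    "stomp_solve",
    "tls_solve",
]

#: floor applied to the nonnull ML scale so the TPR integral stays defined
SIGMA2_FLOOR = 1e-12

#: lower clip for beta so a stage never reports an exactly-zero keep rate
BETA_FLOOR = 1e-16


class DegenerateInputError(ValueError):
    """Raised when an estimator receives input it cannot fit (e.g. empty)."""


@dataclass(frozen=True)
class SolverOptions:
    """Tuning knobs shared by the stagewise solvers.

    Parameters
    ----------
    max_stages : int
        Maximum number of stages S.
    residual_tol : float
        Relative residual stopping tolerance: iteration stops once
        ``||r_s|| <= residual_tol * ||y||``.
    variance_tol : float
        Relative-change convergence tolerance of the outlier-deletion
        null-variance loop.
    alpha0 : float or None
        False-alarm-control parameter.  When given, the stage threshold
        multiplier is the ``1 - alpha0/2`` standard-normal quantile; when
        None it is derived from the false-alarm formula with ``k_hint``.
    k_hint : int
        Sparsity guess used by the false-alarm formula when ``alpha0`` is
        not supplied.
    threshold_lo, threshold_hi : float
        Clamp interval for the threshold multiplier t_s.
    min_keep : int
        Minimum number of candidates retained per stage when the
        TPR-refined count floors to zero.
    """

    max_stages: int = 10
    residual_tol: float = 1e-6
    variance_tol: float = 1e-3
    alpha0: float | None = None
    k_hint: int = 0
    threshold_lo: float = 2.0
    threshold_hi: float = 3.0
    min_keep: int = 1

    def __post_init__(self) -> None:
        if self.max_stages < 1:
            raise ValueError("max_stages must be >= 1")
        if self.residual_tol <= 0 or self.variance_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.alpha0 is not None and not 0 < self.alpha0 < 1:
            raise ValueError(f"alpha0 must lie in (0, 1), got {self.alpha0}")
        if self.threshold_lo > self.threshold_hi:
            raise ValueError("threshold_lo must be <= threshold_hi")
        if self.min_keep < 1:
            raise ValueError("min_keep must be >= 1")

    @classmethod
    def from_mapping(cls, config: dict) -> "SolverOptions":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(config) - known - {"ls_backend"}
        if unknown:
            raise ValueError(f"unknown solver option(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in config.items() if k in known})


@dataclass
class StageTrace:
    """Per-stage diagnostics of a stagewise solve."""

    stage_index: int
    null_sigma: float
    nonnull_mean: float
    nonnull_sigma: float
    threshold: float
    candidate_set_size: int
    tpr_beta: float
    kept_set: np.ndarray
    residual_norm: float


@dataclass
class SparseSolution:
    """Result of a stagewise sparse solve."""

    coefficients: np.ndarray
    support: np.ndarray
    trace: list[StageTrace] = field(default_factory=list)
    converged_reason: str = "max_stages"

    def to_dict(self) -> dict:
        """JSON-serialisable summary (support, coefficients, trace scalars)."""
        return {
            "support": self.support.tolist(),
            "coefficients": self.coefficients.tolist(),
            "converged_reason": self.converged_reason,
            "trace": [
                {
                    "stage_index": t.stage_index,
                    "null_sigma": t.null_sigma,
                    "nonnull_mean": t.nonnull_mean,
                    "nonnull_sigma": t.nonnull_sigma,
                    "threshold": t.threshold,
                    "candidate_set_size": t.candidate_set_size,
                    "tpr_beta": t.tpr_beta,
                    "kept_set_size": int(len(t.kept_set)),
                    "residual_norm": t.residual_norm,
                }
                for t in self.trace
            ],
        }


# ---------------------------------------------------------------------------
# stage primitives
# ---------------------------------------------------------------------------

def matched_filter(Phi: np.ndarray, residual: np.ndarray) -> np.ndarray:
    """Residual correlations c = Phi^T r (Phi columns unit l2 norm)."""
    Phi = np.asarray(Phi, dtype=float)
    residual = np.asarray(residual, dtype=float)
    if Phi.shape[0] != residual.shape[0]:
        raise ValueError(
            f"Phi has {Phi.shape[0]} rows but residual has length "
            f"{residual.shape[0]}"
        )
    return Phi.T @ residual


def _truncation_factor(t: float) -> float:
    # E[X^2 | |X| <= t sigma] / sigma^2 for X ~ N(0, sigma^2)
    mass = 2.0 * norm.cdf(t) - 1.0
    if mass <= 0:
        return 1.0
    return 1.0 - 2.0 * t * norm.pdf(t) / mass


def estimate_null_sigma(
    coeffs: np.ndarray, t: float, variance_tol: float = 1e-3,
    max_iter: int = 100, truncation_correction: bool = True,
) -> tuple[float, int]:
    """Outlier-deletion estimate of the null matched-filter scale.

    Starting from the zero-mean ML standard deviation of all coefficients,
    repeatedly delete coefficients exceeding ``t * sigma`` and re-estimate
    sigma from the retained sample.  Stops when the relative change of
    sigma between iterations falls below ``variance_tol`` or no coefficient
    is deleted.

    With ``truncation_correction`` (the default) the ML second moment is
    corrected for the known truncation at the deletion threshold, making
    the estimator consistent for the null scale of a contaminated Gaussian
    sample.  The stagewise solvers deliberately disable the correction:
    the raw truncated-ML value tracks the shrinking per-stage residual,
    which is what keeps candidate coordinates flowing at later stages.

    Returns ``(sigma, iterations)``.  A retained sample that is identically
    zero yields ``sigma = 0.0`` (flagged degenerate by callers); deleting
    every coefficient raises :class:`DegenerateInputError`.
    """
    c = np.asarray(coeffs, dtype=float).ravel()
    if c.size == 0:
        raise DegenerateInputError("no coefficients supplied")
    if t <= 0 or variance_tol <= 0:
        raise ValueError("t and variance_tol must be > 0")

    correction = _truncation_factor(t) if truncation_correction else 1.0
    kept = c
    sigma_prev: float | None = None
    truncated = False
    iterations = 0
    while iterations < max_iter:
        iterations += 1
        m2 = float(np.mean(kept**2))
        if truncated and correction > 0:
            sigma = float(np.sqrt(m2 / correction))
        else:
            sigma = float(np.sqrt(m2))
        if sigma == 0.0:
            return 0.0, iterations
        if sigma_prev is not None and abs(sigma - sigma_prev) / sigma_prev < variance_tol:
            return sigma, iterations
        new_kept = kept[np.abs(kept) <= t * sigma]
        if new_kept.size == 0:
            raise DegenerateInputError(
                "outlier deletion removed every coefficient"
            )
        if new_kept.size == kept.size:
            return sigma, iterations
        sigma_prev = sigma
        kept = new_kept
        truncated = True
    return sigma, iterations


def fac_threshold(
    m: int,
    n: int,
    k_hint: int = 0,
    S: int = 10,
    alpha0_override: float | None = None,
    threshold_lo: float = 2.0,
    threshold_hi: float = 3.0,
) -> float:
    """False-alarm-control threshold multiplier t_s.

    Uses ``alpha0 = (m - k) / (S (n - k))`` unless overridden, takes the
    ``1 - alpha0/2`` standard-normal quantile, and clamps the result into
    ``[threshold_lo, threshold_hi]``.
    """
    if alpha0_override is not None:
        alpha0 = alpha0_override
    else:
        if not 0 <= k_hint < n or k_hint >= m:
            raise ValueError(
                f"k_hint must satisfy 0 <= k_hint < min(m, n), got {k_hint}"
            )
        alpha0 = (m - k_hint) / (S * (n - k_hint))
    if not 0 < alpha0 < 1:
        raise ValueError(f"alpha0 must lie in (0, 1), got {alpha0}")
    t = float(norm.ppf(1.0 - alpha0 / 2.0))
    return float(np.clip(t, threshold_lo, threshold_hi))


def estimate_nonnull_params(
    coeffs_above_threshold: np.ndarray,
) -> tuple[float, float]:
    """Gaussian ML fit (mean, ML sd) on |coefficients| above the threshold.

    The nonnull mixture component is a single-mean Gaussian, which cannot
    represent signed nonzeros directly; since the TPR integral is stated on
    the folded variable |N(mu, sigma^2)|, the fit is performed on absolute
    values.  The returned scale is floored at a small positive constant.
    """
    c = np.abs(np.asarray(coeffs_above_threshold, dtype=float).ravel())
    if c.size == 0:
        raise DegenerateInputError("no above-threshold coefficients supplied")
    mu = float(np.mean(c))
    sigma2 = float(np.std(c))  # ML (ddof=0)
    return mu, max(sigma2, SIGMA2_FLOOR)


def tpr_beta(mu_s: float, sigma2_s: float, t_s: float, sigma1_s: float) -> float:
    """Stage true-positive rate beta_s = Pr(|N(mu, sigma2^2)| > t sigma1)."""
    if sigma2_s <= 0 or sigma1_s <= 0:
        raise ValueError("sigma2_s and sigma1_s must be > 0")
    thr = t_s * sigma1_s
    beta = norm.sf((thr - mu_s) / sigma2_s) + norm.sf((thr + mu_s) / sigma2_s)
    return float(np.clip(beta, BETA_FLOOR, 1.0))


def refine_support(
    xtilde: np.ndarray,
    candidate_set: np.ndarray,
    beta: float,
    min_keep: int = 1,
) -> np.ndarray:
    """Keep the floor(|candidates| * beta) largest-amplitude candidates.

    ``xtilde`` holds the projected coefficients aligned with
    ``candidate_set``.  Never returns fewer than ``min_keep`` indices (so a
    stage with a nonempty candidate set cannot stall); ties in amplitude
    break toward the lower index.
    """
    candidate_set = np.asarray(candidate_set)
    xtilde = np.asarray(xtilde, dtype=float)
    if candidate_set.size == 0:
        raise ValueError("candidate_set must be nonempty")
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    n_keep = int(np.floor(candidate_set.size * beta))
    n_keep = max(n_keep, min(min_keep, candidate_set.size))
    # stable sort on (-|x|, index): ties break toward the lower index
    order = np.lexsort((candidate_set, -np.abs(xtilde)))
    return np.sort(candidate_set[order[:n_keep]])


# ---------------------------------------------------------------------------
# stagewise solvers
# ---------------------------------------------------------------------------

def _normalize_columns(Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scales = np.linalg.norm(Phi, axis=0)
    if np.any(scales == 0):
        bad = int(np.flatnonzero(scales == 0)[0])
        raise ValueError(f"column {bad} of Phi has zero norm")
    return Phi / scales, scales


def _lstsq(Phi_sub: np.ndarray, y: np.ndarray) -> np.ndarray:
    # dense QR/SVD path; rank deficiency handled by the pseudo-inverse
    sol, *_ = linalg.lstsq(Phi_sub, y, lapack_driver="gelsd")
    return sol


def _stagewise_solve(
    Phi: np.ndarray, y: np.ndarray, opts: SolverOptions, refine: bool,
    iterative_sigma: bool = True,
) -> SparseSolution:
    """Shared stagewise loop; ``refine=True`` gives SmOMP, False gives StOMP."""
    Phi = np.asarray(Phi, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = Phi.shape
    if y.shape[0] != m:
        raise ValueError(f"y has length {y.shape[0]}, expected {m}")

    Phi_n, scales = _normalize_columns(Phi)
    try:
        t_s = fac_threshold(
            m, n, k_hint=opts.k_hint, S=opts.max_stages,
            alpha0_override=opts.alpha0,
            threshold_lo=opts.threshold_lo, threshold_hi=opts.threshold_hi,
        )
    except ValueError:
        if opts.alpha0 is not None:
            raise
        # the false-alarm formula only makes sense for underdetermined
        # systems; elsewhere its raw quantile is <= 0 and would be clamped
        # to the range floor anyway
        t_s = opts.threshold_lo

    y_norm = float(np.linalg.norm(y))
    stop_resid = opts.residual_tol * y_norm

    support = np.array([], dtype=int)
    x = np.zeros(n)
    r = y.copy()
    trace: list[StageTrace] = []
    reason = "max_stages"

    for s in range(1, opts.max_stages + 1):
        c = matched_filter(Phi_n, r)
        free = np.setdiff1d(np.arange(n), support, assume_unique=False)
        c_free = c[free]
        if c_free.size == 0 or not np.any(c_free):
            reason = "empty_candidate"
            break

        if iterative_sigma:
            try:
                sigma1, _ = estimate_null_sigma(
                    c_free, t_s, opts.variance_tol,
                    truncation_correction=False,
                )
            except DegenerateInputError:
                sigma1 = 0.0
        else:
            # single-pass zero-mean ML scale of all free coefficients
            sigma1 = float(np.sqrt(np.mean(c_free**2)))
        if sigma1 <= 0.0:
            # exact-stage degeneracy (e.g. noise-free residual orthogonal to
            # all null columns): fall back to a machine-epsilon-scale floor
            # so remaining true coordinates are still selected
            sigma1 = float(np.max(np.abs(c_free))) * 1e-12 + np.finfo(float).tiny

        threshold = t_s * sigma1
        candidates = free[np.abs(c_free) > threshold]
        if candidates.size == 0:
            reason = "empty_candidate"
            break
        # keep the support determined: never let it outgrow m rows
        room = m - support.size
        if room <= 0:
            reason = "empty_candidate"
            break
        if candidates.size > room:
            order = np.argsort(-np.abs(c[candidates]), kind="stable")
            candidates = np.sort(candidates[order[:room]])

        mu_s, sigma2 = estimate_nonnull_params(c[candidates])
        beta = tpr_beta(mu_s, sigma2, t_s, sigma1)

        enlarged = np.union1d(support, candidates)
        xt = _lstsq(Phi_n[:, enlarged], y)
        if refine:
            pos = np.searchsorted(enlarged, candidates)
            kept = refine_support(xt[pos], candidates, beta, opts.min_keep)
        else:
            kept = candidates

        support = np.union1d(support, kept)
        x = np.zeros(n)
        x[support] = _lstsq(Phi_n[:, support], y)
        r = y - Phi_n @ x
        r_norm = float(np.linalg.norm(r))

        trace.append(StageTrace(
            stage_index=s, null_sigma=sigma1, nonnull_mean=mu_s,
            nonnull_sigma=sigma2, threshold=threshold,
            candidate_set_size=int(candidates.size), tpr_beta=beta,
            kept_set=kept, residual_norm=r_norm,
        ))

        if r_norm <= stop_resid:
            reason = "residual_tol"
            break
    else:
        reason = "max_stages"

    # express coefficients on the caller's original column scaling
    coefficients = x / scales
    return SparseSolution(
        coefficients=coefficients, support=support, trace=trace,
        converged_reason=reason,
    )


def smomp_solve(
    Phi: np.ndarray, y: np.ndarray, opts: SolverOptions | None = None
) -> SparseSolution:
    """Solve y = Phi x for sparse x with SmOMP.

    Each stage applies the matched filter, estimates the null scale by
    iterative outlier deletion, hard-thresholds at ``t_s * sigma_{s,1}``,
    fits the nonnull component and its true-positive rate ``beta_s``,
    projects onto the enlarged support, and keeps only the
    ``floor(k_s * beta_s)`` largest projected amplitudes before the final
    least-squares update of the stage.
    """
    return _stagewise_solve(Phi, y, opts or SolverOptions(), refine=True)


def stomp_solve(
    Phi: np.ndarray, y: np.ndarray, opts: SolverOptions | None = None
) -> SparseSolution:
    """Plain StOMP: single-pass null-scale estimate, no TPR refinement."""
    return _stagewise_solve(Phi, y, opts or SolverOptions(), refine=False,
                            iterative_sigma=False)


# ---------------------------------------------------------------------------
# total least squares baseline
# ---------------------------------------------------------------------------

def tls_solve(Phi: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Classical total least squares via the smallest singular pair.

    Returns the dense coefficient vector x such that ``[x; -1]`` spans the
    right singular direction of the augmented matrix ``[Phi b]`` associated
    with its smallest singular value.
    """
    Phi = np.asarray(Phi, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if Phi.shape[0] != b.shape[0]:
        raise ValueError("Phi and b row counts differ")
    augmented = np.column_stack([Phi, b])
    # thin SVD keeps all right singular vectors only when m > p; the
    # underdetermined case needs the full V to reach the null space
    full = augmented.shape[0] < augmented.shape[1]
    _, _, Vt = linalg.svd(augmented, full_matrices=full)
    v = Vt[-1]
    if abs(v[-1]) < 1e-12 * np.linalg.norm(v):
        raise linalg.LinAlgError(
            "non-generic TLS problem: smallest singular vector has a "
            "vanishing observation component"
        )
    return -v[:-1] / v[-1]
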