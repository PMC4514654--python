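"""Per-gene regression construction and network assembly.

Turns steady-state perturbation data into one sparse regression problem per
gene and assembles the per-gene solutions into a signed adjacency estimate.

The linearized steady-state model says that the relative change
``phi_j = dx_j / x_j`` of every gene across an experiment satisfies
``sum_{j != i} u_ij phi_j ~= phi_i`` for each target gene ``i``, where
``u_ij`` is the log-gain of gene ``j`` on gene ``i`` (positive activation,
negative inhibition, zero no direct regulation).  Stacking the m
experiments gives ``Phi alpha_i = b`` with ``Phi`` the relative changes of
the other genes and ``b`` those of gene ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solvers import (
    SolverOptions,
    SparseSolution,
    smomp_solve,
    stomp_solve,
    tls_solve,
)

__all__ = [
    "PerturbationDataset",
    "RegressionProblem",
    "NetworkEstimate",
    "relative_changes",
    "build_gene_problem",
    "infer_network",
    "solve_linear_model",
]


@dataclass
class PerturbationDataset:
    """Wild-type plus perturbed steady-state expression levels.

    ``perturbed`` has one row per perturbation experiment; the labels say
    what was perturbed (for knockout designs, the name of the deleted gene).
    """

    wildtype: np.ndarray
    perturbed: np.ndarray
    gene_names: list[str]
    perturbation_labels: list[str]

    def __post_init__(self) -> None:
        self.wildtype = np.asarray(self.wildtype, dtype=float).ravel()
        self.perturbed = np.atleast_2d(np.asarray(self.perturbed, dtype=float))
        n = self.wildtype.shape[0]
        if self.perturbed.shape[1] != n:
            raise ValueError(
                f"perturbed has {self.perturbed.shape[1]} columns, "
                f"expected {n}"
            )
        if len(self.gene_names) != n:
            raise ValueError("gene_names length does not match wildtype")
        if len(self.perturbation_labels) != self.perturbed.shape[0]:
            raise ValueError("perturbation_labels length does not match rows")

    @property
    def n_genes(self) -> int:
        return self.wildtype.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.perturbed.shape[0]


@dataclass
class RegressionProblem:
    """The (Phi, b) pair for one target gene."""

    target_index: int
    Phi: np.ndarray
    b: np.ndarray
    column_scales: np.ndarray
    column_gene_map: np.ndarray  # Phi column j refers to gene column_gene_map[j]


@dataclass
class NetworkEstimate:
    """Signed n x n adjacency estimate with zero diagonal.

    ``adjacency[i, j]`` is the estimated direct effect of gene ``j`` on
    gene ``i``; ``ranking_scores`` are nonnegative per-edge confidences
    (absolute coefficients on the original column scale).
    """

    adjacency: np.ndarray
    ranking_scores: np.ndarray
    solver_name: str
    gene_names: list[str] | None = None
    per_gene_traces: dict[int, SparseSolution] = field(default_factory=dict)


def relative_changes(dataset: PerturbationDataset) -> np.ndarray:
    """Relative steady-state changes phi[l, j] = (x_perturbed - x_wt) / x_wt."""
    bad = np.flatnonzero(dataset.wildtype <= 0)
    if bad.size:
        raise ValueError(
            f"wild-type level of gene {dataset.gene_names[bad[0]]!r} is "
            f"{dataset.wildtype[bad[0]]}; relative changes require strictly "
            "positive wild-type levels"
        )
    return (dataset.perturbed - dataset.wildtype) / dataset.wildtype


def build_gene_problem(
    phi: np.ndarray,
    target: int,
    normalize: bool = True,
    center: bool = False,
    row_mask: np.ndarray | None = None,
) -> RegressionProblem:
    """Build the per-gene regression ``Phi alpha = b`` for one target gene.

    ``Phi`` is the relative-change matrix with the target column removed;
    ``b`` is the target column.  With ``normalize`` each Phi column is
    divided by its l2 norm (scales recorded, so coefficients can be mapped
    back to the original scale).  With ``center`` the rows of Phi and b are
    demeaned across experiments first, removing any common-mode response so
    the matched-filter null of the stagewise solvers is zero-mean.
    ``row_mask`` optionally restricts which experiments are used.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    m, n = phi.shape
    if n < 2:
        raise ValueError("need at least 2 genes")
    if not 0 <= target < n:
        raise ValueError(f"target {target} out of range for {n} genes")

    keep_cols = np.delete(np.arange(n), target)
    rows = np.arange(m) if row_mask is None else np.flatnonzero(row_mask)
    if rows.size == 0:
        raise ValueError(f"no experiments left for target gene {target}")
    Phi = phi[np.ix_(rows, keep_cols)]
    b = phi[rows, target]

    if center:
        Phi = Phi - Phi.mean(axis=0)
        b = b - b.mean()

    scales = np.ones(n - 1)
    if normalize:
        scales = np.linalg.norm(Phi, axis=0)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            raise ValueError(
                f"gene column {keep_cols[zero[0]]} never responds in any "
                "experiment (zero norm under normalization)"
            )
        Phi = Phi / scales

    return RegressionProblem(
        target_index=target, Phi=Phi, b=b, column_scales=scales,
        column_gene_map=keep_cols,
    )


_SOLVERS = ("smomp", "stomp", "tls")


def _solve_problem(
    problem: RegressionProblem, solver: str, opts: SolverOptions
) -> tuple[np.ndarray, SparseSolution | None]:
    """Solve one gene problem; returns original-scale coefficients."""
    if solver == "tls":
        coeffs = tls_solve(problem.Phi, problem.b)
        sol = None
    else:
        fn = smomp_solve if solver == "smomp" else stomp_solve
        sol = fn(problem.Phi, problem.b, opts)
        coeffs = sol.coefficients
    return coeffs / problem.column_scales, sol


def infer_network(
    data: PerturbationDataset | np.ndarray,
    solver: str = "smomp",
    opts: SolverOptions | None = None,
    normalize: bool = True,
    center: bool = True,
    exclude_target_knockout: bool = True,
    keep_traces: bool = False,
) -> NetworkEstimate:
    """Infer the full regulatory network, one sparse regression per gene.

    ``data`` is either a :class:`PerturbationDataset` or a precomputed
    relative-change matrix (experiments x genes).  Row ``i`` of the
    returned adjacency holds gene ``i``'s regression coefficients, so
    entry ``(i, j)`` is the estimated direct effect of gene ``j`` on gene
    ``i``.  With ``exclude_target_knockout`` (knockout designs only),
    experiments in which the target gene itself was deleted are dropped
    from that gene's problem — its forced change is an intervention, not a
    regulatory response.
    """
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; choose from {_SOLVERS}")
    opts = opts or SolverOptions()

    gene_names: list[str] | None = None
    labels: list[str] | None = None
    if isinstance(data, PerturbationDataset):
        phi = relative_changes(data)
        gene_names = data.gene_names
        labels = data.perturbation_labels
    else:
        phi = np.atleast_2d(np.asarray(data, dtype=float))
    m, n = phi.shape

    adjacency = np.zeros((n, n))
    traces: dict[int, SparseSolution] = {}
    for i in range(n):
        row_mask = None
        if exclude_target_knockout and gene_names is not None and labels is not None:
            row_mask = np.array(
                [lab != gene_names[i] for lab in labels], dtype=bool
            )
            if not row_mask.any():
                row_mask = None
        rows = np.arange(m) if row_mask is None else np.flatnonzero(row_mask)
        if not np.any(phi[rows, i]):
            continue  # gene never responds: empty adjacency row
        try:
            problem = build_gene_problem(
                phi, i, normalize=normalize, center=center, row_mask=row_mask
            )
            coeffs, sol = _solve_problem(problem, solver, opts)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise type(exc)(
                f"inference failed for gene {i}"
                + (f" ({gene_names[i]})" if gene_names else "")
                + f": {exc}"
            ) from exc
        adjacency[i, problem.column_gene_map] = coeffs
        if keep_traces and sol is not None:
            traces[i] = sol

    return NetworkEstimate(
        adjacency=adjacency, ranking_scores=np.abs(adjacency),
        solver_name=solver, gene_names=gene_names, per_gene_traces=traces,
    )


def solve_linear_model(
    A: np.ndarray,
    B: np.ndarray,
    solver: str = "smomp",
    opts: SolverOptions | None = None,
    normalize: bool = True,
    center: bool = True,
) -> np.ndarray:
    """Estimate the causal matrix X of a linear network model A X = B.

    Column ``i`` of the returned matrix is the estimated adjacency vector
    of gene ``i`` (self entry zero), obtained by solving ``A_{-i} x =
    B[:, i]`` with the chosen solver under the same preprocessing as
    :func:`infer_network`.  This is the estimation protocol of the
    artificial linear benchmark.
    """
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; choose from {_SOLVERS}")
    opts = opts or SolverOptions()
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[1]
    if B.shape != (A.shape[0], n):
        raise ValueError("A and B shapes are inconsistent")

    Xhat = np.zeros((n, n))
    for i in range(n):
        cols = np.delete(np.arange(n), i)
        Phi = A[:, cols]
        b = B[:, i]
        if center:
            Phi = Phi - Phi.mean(axis=0)
            b = b - b.mean()
        scales = np.ones(cols.size)
        if normalize:
            scales = np.linalg.norm(Phi, axis=0)
            if np.any(scales == 0):
                raise ValueError(f"zero-norm column while solving gene {i}")
            Phi = Phi / scales
        problem = RegressionProblem(
            target_index=i, Phi=Phi, b=b, column_scales=scales,
            column_gene_map=cols,
        )
        coeffs, _ = _solve_problem(problem, solver, opts)
        Xhat[cols, i] = coeffs
    return Xhat
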