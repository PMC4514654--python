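"""Synthetic linear-network benchmark generation.

Builds artificial gene regulatory network instances of the form
``A0 @ X0 = B0`` in which ``A0`` is a random measurement matrix, ``X0`` a
sparse signed causal adjacency matrix whose per-column in-degree follows a
truncated power law, and the observed matrices ``A = A0 + noise`` and
``B = A0 @ X0 + noise`` carry i.i.d. Gaussian measurement error.  Every
downstream stage (solvers, network assembly, evaluation) is testable
against the known ground truth ``X0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PowerLawPrior",
    "ArtificialInstance",
    "sample_power_law_degree",
    "generate_artificial_instance",
    "save_instance",
    "load_instance",
]


@dataclass(frozen=True)
class PowerLawPrior:
    """Truncated power-law distribution over node degrees ``k``.

    The probability mass is ``mu * k_min**-gamma`` for ``1 <= k <= k_min``
    and ``mu * k**-gamma`` for ``k_min <= k <= n_max``, with ``mu`` the
    normalising constant over the support ``{1, ..., n_max}``.

    Parameters
    ----------
    k_min : int
        Degree below which the mass is flat (``>= 1``).
    gamma : float
        Power-law exponent (``> 0``).
    n_max : int
        Largest attainable degree, normally the number of genes.
    """

    k_min: int = 1
    gamma: float = 2.5
    n_max: int = 100

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.n_max < self.k_min:
            raise ValueError(
                f"n_max ({self.n_max}) must be >= k_min ({self.k_min})"
            )

    def pmf(self) -> np.ndarray:
        """Probability masses over degrees ``1..n_max`` (index 0 -> k=1)."""
        k = np.arange(1, self.n_max + 1, dtype=float)
        mass = np.where(k <= self.k_min, float(self.k_min) ** -self.gamma,
                        k ** -self.gamma)
        return mass / mass.sum()

    def mean(self) -> float:
        """Analytic mean degree of the normalized distribution."""
        k = np.arange(1, self.n_max + 1, dtype=float)
        return float(k @ self.pmf())


def sample_power_law_degree(
    prior: PowerLawPrior, rng: np.random.Generator, size: int | None = None
) -> int | np.ndarray:
    """Draw node degrees from the truncated power-law prior.

    Returns a scalar int when ``size`` is None, else an int array.
    """
    draws = rng.choice(np.arange(1, prior.n_max + 1), size=size, p=prior.pmf())
    if size is None:
        return int(draws)
    return draws.astype(int)


@dataclass
class ArtificialInstance:
    """One synthetic linear-network benchmark instance.

    ``X0[j, i]`` is the signed direct effect of gene ``j`` on gene ``i``
    (column ``i`` is the adjacency vector of gene ``i``); the diagonal is
    identically zero because self-regulation is excluded from the model.
    """

    A0: np.ndarray
    X0: np.ndarray
    A: np.ndarray
    B: np.ndarray
    sigma: float
    rho_a: float
    seed: int
    prior: PowerLawPrior = field(default_factory=PowerLawPrior)

    @property
    def n(self) -> int:
        return self.X0.shape[0]

    @property
    def m(self) -> int:
        return self.A0.shape[0]


def generate_artificial_instance(
    n: int,
    m: int,
    sigma: float,
    prior: PowerLawPrior | None = None,
    rho_a: float = 1e-5,
    entry_low: float = 1.0,
    entry_high: float = 10.0,
    two_interval: bool = False,
    seed: int = 0,
) -> ArtificialInstance:
    """Generate an artificial linear-network instance.

    ``A0`` entries are uniform on ``[entry_low, entry_high]`` (or, with
    ``two_interval=True``, on ``[-entry_high, -entry_low] U [entry_low,
    entry_high]``).  Each column of ``X0`` is built in three steps: a
    power-law degree draw ``k``, ``k`` uniformly random non-self row
    locations, and magnitudes uniform on ``[-2, -rho_a] U [rho_a, 2]``.
    Noise ``N(0, sigma^2)`` is added independently to ``A`` and ``B``.

    A fixed sub-stream order (degrees, locations, magnitudes, noise) makes
    identical seeds produce bit-identical instances.
    """
    if n < 2:
        raise ValueError(f"need at least 2 genes, got n={n}")
    if m < 1:
        raise ValueError(f"need at least 1 experiment, got m={m}")
    if sigma < 0:
        raise ValueError(f"noise sd must be >= 0, got {sigma}")
    if not 0 < rho_a < 2:
        raise ValueError(f"rho_a must lie in (0, 2), got {rho_a}")
    if prior is None:
        prior = PowerLawPrior(k_min=1, gamma=2.5, n_max=n)

    root = np.random.default_rng(seed)
    rng_deg, rng_loc, rng_mag, rng_noise, rng_meas = root.spawn(5)

    # degrees first, then locations, then magnitudes, then noise: tests can
    # pin each stage by re-spawning the same sub-streams.
    degrees = np.minimum(
        sample_power_law_degree(prior, rng_deg, size=n), n - 1
    )

    X0 = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        rows = rng_loc.choice(others, size=degrees[i], replace=False)
        mags = rng_mag.uniform(rho_a, 2.0, size=degrees[i])
        signs = np.where(rng_mag.random(degrees[i]) < 0.5, -1.0, 1.0)
        X0[rows, i] = signs * mags

    if two_interval:
        mags = rng_meas.uniform(entry_low, entry_high, size=(m, n))
        signs = np.where(rng_meas.random((m, n)) < 0.5, -1.0, 1.0)
        A0 = signs * mags
    else:
        A0 = rng_meas.uniform(entry_low, entry_high, size=(m, n))

    A = A0 + rng_noise.normal(0.0, sigma, size=(m, n)) if sigma > 0 else A0.copy()
    B0 = A0 @ X0
    B = B0 + rng_noise.normal(0.0, sigma, size=(m, n)) if sigma > 0 else B0

    return ArtificialInstance(
        A0=A0, X0=X0, A=A, B=B, sigma=sigma, rho_a=rho_a, seed=seed,
        prior=prior,
    )


def save_instance(inst: ArtificialInstance, directory: str | Path) -> None:
    """Write an instance as tab-separated text matrices plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("A0", "X0", "A", "B"):
        np.savetxt(directory / f"{name}.tsv", getattr(inst, name),
                   delimiter="\t")
    sidecar = {
        "n": inst.n,
        "m": inst.m,
        "sigma": inst.sigma,
        "rho_a": inst.rho_a,
        "seed": inst.seed,
        "prior": {"k_min": inst.prior.k_min, "gamma": inst.prior.gamma,
                  "n_max": inst.prior.n_max},
    }
    (directory / "instance.json").write_text(json.dumps(sidecar, indent=2))


def load_instance(directory: str | Path) -> ArtificialInstance:
    """Read back an instance written by :func:`save_instance`."""
    directory = Path(directory)
    meta = json.loads((directory / "instance.json").read_text())
    mats = {
        name: np.loadtxt(directory / f"{name}.tsv", delimiter="\t", ndmin=2)
        for name in ("A0", "X0", "A", "B")
    }
    return ArtificialInstance(
        A0=mats["A0"], X0=mats["X0"], A=mats["A"], B=mats["B"],
        sigma=meta["sigma"], rho_a=meta["rho_a"], seed=meta["seed"],
        prior=PowerLawPrior(**meta["prior"]),
    )
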