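"""Simulation parameters for clustered-population generation.

The data-generating process is a linear mixed model for a continuous outcome
of patient ``j`` at clinic ``i``::

    Y_ij = b_0i + (beta1 + b_1i) X_1ij + (beta2 + b_2i) X_2ij
           + gamma * f(N_i) + quad1 * X_1ij^2 + quad2 * X_2ij^2 + eps_ij

with clinic sizes ``N_i ~ ceil(exp(Normal(mu_N, sigma_N^2)))``, clinic-level
random effects ``(b_0i, b_1i, b_2i) ~ N(0, T)`` sharing a common correlation
``rho``, a standardized log-volume effect ``f(N_i)``, and residuals
``eps_ij ~ N(0, sigma_eps^2)`` calibrated so that the residual share of the
total outcome variance equals ``alpha``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationParams"]

#: sentinel: tau2_sq defaults to the convention "0 if beta2 == 0 else tau1_sq"
_AUTO = None


@dataclass(frozen=True)
class SimulationParams:
    """Every scalar governing the data-generating process and the experiment.

    Defaults are the base combination of the simulation study: 500 clinics
    with median size 65, tau0^2 = 1, tau1^2 = 0.25, rho = 0.3, beta1 = 1,
    beta2 = gamma = 0, alpha = 0.2, update interval theta = 500 with an 80%
    outcome-incorporation probability, and a stratified 6/6/3/3/2 training
    sample across size quintiles (smallest to largest).
    """

    n_clinics: int = 500
    mu_N: float = math.log(65.0)
    sigma_N: float = math.log(2.0)
    tau0_sq: float = 1.0
    tau1_sq: float = 0.25
    tau2_sq: float | None = _AUTO
    rho: float = 0.3
    beta0: float = 0.0  # overall intercept, fixed at 0 in the stated world
    beta1: float = 1.0
    beta2: float = 0.0
    gamma: float = 0.0
    alpha: float = 0.2
    quad1: float = 0.0
    quad2: float = 0.0
    theta: int = 500
    p_incorporate: float = 0.8
    training_quintile_counts: tuple[int, ...] = (6, 6, 3, 3, 2)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau2_sq is _AUTO:
            resolved = 0.0 if self.beta2 == 0.0 else float(self.tau1_sq)
            object.__setattr__(self, "tau2_sq", resolved)
        object.__setattr__(
            self, "training_quintile_counts", tuple(int(c) for c in self.training_quintile_counts)
        )
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.n_clinics < 1:
            raise ValueError("n_clinics must be a positive integer")
        if self.sigma_N < 0:
            raise ValueError("sigma_N must be non-negative")
        for name in ("tau0_sq", "tau1_sq", "tau2_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if not 0.0 <= self.p_incorporate <= 1.0:
            raise ValueError("p_incorporate must lie in [0, 1]")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if len(self.training_quintile_counts) != 5:
            raise ValueError("training_quintile_counts must have one entry per quintile")
        if any(c < 0 for c in self.training_quintile_counts):
            raise ValueError("training_quintile_counts must be non-negative")
        # reject (rho, tau) combinations whose implied covariance is not PSD
        self.re_cov()

    # ------------------------------------------------------------------
    def re_cov(self) -> np.ndarray:
        """Random-effects covariance matrix T for (b0, b1, b2).

        Zero-variance components are dropped before the positive
        semidefiniteness check and re-inserted as exact zero rows/columns,
        since the full matrix is singular whenever any tau is zero.
        """
        tau = np.sqrt([self.tau0_sq, self.tau1_sq, self.tau2_sq])
        T = np.outer(tau, tau) * self.rho
        np.fill_diagonal(T, tau**2)
        active = tau > 0
        if active.any():
            sub = T[np.ix_(active, active)]
            eigmin = np.linalg.eigvalsh(sub).min()
            if eigmin < -1e-10:
                raise ValueError(
                    f"random-effects covariance is not positive semidefinite "
                    f"(min eigenvalue {eigmin:.3g}); adjust rho or the tau values"
                )
        T[~active, :] = 0.0
        T[:, ~active] = 0.0
        return T

    # ------------------------------------------------------------------
    def evolve(self, **changes) -> "SimulationParams":
        """Return a copy with ``changes`` applied.

        If ``beta2`` or ``tau1_sq`` changes and ``tau2_sq`` is not given
        explicitly, ``tau2_sq`` is re-resolved by the default convention.
        """
        if "tau2_sq" not in changes and ("beta2" in changes or "tau1_sq" in changes):
            changes["tau2_sq"] = _AUTO
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["training_quintile_counts"] = list(self.training_quintile_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SimulationParams":
        return cls.from_dict(json.loads(s))
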