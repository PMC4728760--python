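"""Clustered-population generator.

Generates a population of clinics with log-normally distributed sizes, a
shared-correlation multivariate-normal draw of clinic-level random effects,
standard-normal patient covariates, a standardized log-volume effect, and a
residual variance calibrated analytically so that the residual share of the
total outcome variance equals ``alpha``.

Populations are plain pandas DataFrames (one row per clinic, one per patient)
wrapped in a :class:`Population` container that also carries the parameters
and the calibrated residual variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SimulationParams

__all__ = [
    "Population",
    "draw_clinic_sizes",
    "assign_quintiles",
    "draw_random_effects",
    "compute_volume_effect",
    "compute_residual_variance",
    "generate_population",
]

CLINIC_COLUMNS = ["clinic_id", "size", "quintile", "b0", "b1", "b2", "volume_effect"]
PATIENT_COLUMNS = ["clinic_id", "patient_id", "x1", "x2", "y", "mu_true", "eps"]


def draw_clinic_sizes(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Draw clinic sizes ``N_i = ceil(exp(Normal(mu_N, sigma_N^2)))``.

    The log-normal shape yields a large number of smaller clinics and a small
    number of very large ones; the ceiling guarantees every size >= 1.
    """
    z = rng.normal(params.mu_N, params.sigma_N, size=params.n_clinics)
    return np.ceil(np.exp(z)).astype(np.int64)


def assign_quintiles(sizes: np.ndarray) -> np.ndarray:
    """Assign size-quintile labels 1 (smallest) .. 5 (largest) by rank.

    Ties are broken by position (clinic id order), so the partition is
    deterministic and each quintile receives an equal share (exactly equal
    when the number of clinics is divisible by 5).
    """
    sizes = np.asarray(sizes)
    n = sizes.size
    if n < 5:
        raise ValueError("need at least 5 clinics to form size quintiles")
    order = np.argsort(sizes, kind="stable")  # stable sort = ties broken by index
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * 5 // n + 1).astype(np.int64)


def draw_random_effects(
    params: SimulationParams, n_clinics: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-clinic random effects (b0, b1, b2) ~ i.i.d. N(0, T).

    Zero-variance components are returned as exact zeros; the multivariate
    draw is taken only over the active components (the full T is singular
    whenever any tau is zero).
    """
    T = params.re_cov()
    tau = np.sqrt(np.diag(T))
    active = tau > 0
    b = np.zeros((n_clinics, 3))
    if active.any():
        sub = T[np.ix_(active, active)]
        # eigendecomposition square root: tolerates rho = +/-1 (rank-deficient T)
        w, V = np.linalg.eigh(sub)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        z = rng.standard_normal((n_clinics, int(active.sum())))
        b[:, active] = z @ L.T
    return b


def compute_volume_effect(sizes: np.ndarray) -> np.ndarray:
    """Standardized log-size effect ``f(N_i) = Omega (ln N_i - mean(ln N_i))``.

    Omega is the reciprocal of the *empirical* standard deviation of
    ``ln N_i`` over the given clinics, so that ``sd(f) = 1`` and
    ``mean(f) = 0`` hold exactly in every population (the ceiling applied to
    the size draw distorts the theoretical scale, so the theoretical
    ``sigma_N`` is not used). If all sizes are identical the effect is
    degenerate: an all-zero vector is returned with a warning.
    """
    sizes = np.asarray(sizes)
    logs = np.log(sizes.astype(float))
    centered = logs - logs.mean()
    sd = logs.std(ddof=1) if logs.size > 1 else 0.0
    if sd == 0.0 or np.all(sizes == sizes.flat[0]):
        warnings.warn(
            "all clinic sizes are identical; volume effect is identically zero",
            stacklevel=2,
        )
        return np.zeros_like(logs)
    return centered / sd


def compute_residual_variance(params: SimulationParams) -> float:
    """Analytic residual variance ``sigma_eps^2 = alpha/(1-alpha) * V``.

    ``V`` is the variance of the linear predictor, computed in closed form
    under independence of the covariates, the random effects, and the volume
    effect (all cross-covariances vanish because the covariates have mean 0)::

        V = tau0^2 + (beta1^2 + tau1^2) Var(X1) + (beta2^2 + tau2^2) Var(X2)
            + gamma^2 Var(f) + 2 quad1^2 + 2 quad2^2

    with Var(X1) = Var(X2) = Var(f) = 1 and Var(c X^2) = 2 c^2 for standard
    normal X. The quadratic terms also shift the mean of the outcome by
    quad1 + quad2; that shift is part of the true conditional mean and is
    deliberately not removed.
    """
    V = (
        params.tau0_sq
        + (params.beta1**2 + params.tau1_sq)
        + (params.beta2**2 + params.tau2_sq)
        + params.gamma**2
        + 2.0 * params.quad1**2
        + 2.0 * params.quad2**2
    )
    return params.alpha / (1.0 - params.alpha) * V


@dataclass
class Population:
    """A simulated clustered population.

    Attributes
    ----------
    params : SimulationParams
        The generating parameters.
    clinics : pandas.DataFrame
        One row per clinic: clinic_id, size, quintile, b0, b1, b2,
        volume_effect.
    patients : pandas.DataFrame
        One row per patient: clinic_id, patient_id, x1, x2, y, mu_true, eps,
        where ``y = mu_true + eps`` exactly and ``mu_true`` is the true
        conditional mean (the generating model minus the residual).
    sigma_eps_sq : float
        The analytically calibrated residual variance.
    """

    params: SimulationParams
    clinics: pd.DataFrame
    patients: pd.DataFrame
    sigma_eps_sq: float

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patients_of(self, clinic_ids) -> pd.DataFrame:
        return self.patients[self.patients["clinic_id"].isin(np.asarray(clinic_ids))]

    # -- serialization -------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        """Write clinics.csv, patients.csv and a params.json sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clinics.to_csv(out / "clinics.csv", index=False)
        self.patients.to_csv(out / "patients.csv", index=False)
        sidecar = {
            "params": self.params.to_dict(),
            "sigma_eps_sq": self.sigma_eps_sq,
        }
        (out / "params.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "Population":
        src = Path(in_dir)
        sidecar = json.loads((src / "params.json").read_text())
        return cls(
            params=SimulationParams.from_dict(sidecar["params"]),
            clinics=pd.read_csv(src / "clinics.csv"),
            patients=pd.read_csv(src / "patients.csv"),
            sigma_eps_sq=float(sidecar["sigma_eps_sq"]),
        )


def generate_population(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Population:
    """Generate a complete population: clinics, random effects, patients.

    Draws are taken from four named substreams (sizes, random effects,
    covariates, residuals) spawned in a fixed order from ``rng``/``seed``, so
    that changing one sweep parameter never perturbs unrelated draws. The
    same parameters and seed always yield a bit-identical population.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    rng_sizes, rng_re, rng_cov, rng_eps = rng.spawn(4)

    sizes = draw_clinic_sizes(params, rng_sizes)
    quintiles = assign_quintiles(sizes)
    b = draw_random_effects(params, params.n_clinics, rng_re)
    f = compute_volume_effect(sizes)
    sigma_eps_sq = compute_residual_variance(params)

    clinics = pd.DataFrame(
        {
            "clinic_id": np.arange(params.n_clinics, dtype=np.int64),
            "size": sizes,
            "quintile": quintiles,
            "b0": b[:, 0],
            "b1": b[:, 1],
            "b2": b[:, 2],
            "volume_effect": f,
        }
    )

    n_total = int(sizes.sum())
    clinic_idx = np.repeat(np.arange(params.n_clinics), sizes)
    patient_id = np.concatenate([np.arange(1, s + 1) for s in sizes])
    x1 = rng_cov.standard_normal(n_total)
    x2 = rng_cov.standard_normal(n_total)
    eps = rng_eps.normal(0.0, np.sqrt(sigma_eps_sq), size=n_total)

    mu_true = (
        params.beta0
        + b[clinic_idx, 0]
        + (params.beta1 + b[clinic_idx, 1]) * x1
        + (params.beta2 + b[clinic_idx, 2]) * x2
        + params.gamma * f[clinic_idx]
        + params.quad1 * x1**2
        + params.quad2 * x2**2
    )

    patients = pd.DataFrame(
        {
            "clinic_id": clinic_idx.astype(np.int64),
            "patient_id": patient_id.astype(np.int64),
            "x1": x1,
            "x2": x2,
            "y": mu_true + eps,
            "mu_true": mu_true,
            "eps": eps,
        }
    )
    patients["quintile"] = quintiles[clinic_idx]

    return Population(
        params=params, clinics=clinics, patients=patients, sigma_eps_sq=sigma_eps_sq
    )
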