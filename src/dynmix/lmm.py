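"""Linear mixed-effects models for clustered prediction.

Implements the three model families used throughout the package -- a
fixed-effects-only linear model, a random-intercept model, and a
random-intercept-and-slope model (each optionally with clinic-size quintile
as a categorical fixed effect) -- estimated by restricted maximum likelihood
with a weak Wishart-style penalty that keeps the random-effects covariance
positive definite, mirroring non-informative-prior Bayesian LMM estimation.

The fitter profiles the fixed effects and the residual variance out of the
restricted likelihood and evaluates the profiled deviance from per-cluster
sufficient statistics (cross-products), so a fit costs O(n) once plus a few
hundred O(m) objective evaluations regardless of the number of rows. Cluster
random effects are recovered as empirical-Bayes conditional modes (BLUPs at
the estimated variance components).

Usage follows the statsmodels convention: build a :class:`ClusteredLMM` from
a DataFrame and a :class:`ModelSpec`, call :meth:`ClusteredLMM.fit`, and use
the returned :class:`LMMResults` for prediction and reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ModelSpec",
    "ClusteredLMM",
    "LMMResults",
    "intercept_only",
    "linear",
    "random_intercept",
    "random_intercept_slope",
    "standard_specs",
]

_FIXED_TERMS = ("intercept", "x1", "quintile")
_RANDOM_TERMS = ("intercept", "x1")
_QUINTILE_LEVELS = (2, 3, 4, 5)  # treatment coding, quintile 1 is the reference
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed and random terms a model has (identity link only).

    ``fixed`` is a subset of {intercept, x1, quintile}; ``quintile`` enters
    as a 5-level categorical with quintile 1 as the reference level.
    ``random`` is a subset of {intercept, x1}.
    """

    name: str
    fixed: tuple[str, ...] = ("intercept", "x1")
    random: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.fixed:
            if t not in _FIXED_TERMS:
                raise ValueError(f"unsupported fixed term {t!r}")
        for t in self.random:
            if t not in _RANDOM_TERMS:
                raise ValueError(f"unsupported random term {t!r}")
        if "x1" in self.random and "intercept" not in self.random:
            raise ValueError("a random slope requires a random intercept")

    @property
    def is_mixed(self) -> bool:
        return len(self.random) > 0

    def with_quintile(self) -> "ModelSpec":
        if "quintile" in self.fixed:
            return self
        return ModelSpec(self.name + "_q", self.fixed + ("quintile",), self.random)


def intercept_only() -> ModelSpec:
    """The null model: a single overall mean (the RI baseline)."""
    return ModelSpec("intercept_only", ("intercept",), ())


def linear(quintile: bool = False) -> ModelSpec:
    spec = ModelSpec("linear", ("intercept", "x1"), ())
    return spec.with_quintile() if quintile else spec


def random_intercept(quintile: bool = False) -> ModelSpec:
    spec = ModelSpec("random_intercept", ("intercept", "x1"), ("intercept",))
    return spec.with_quintile() if quintile else spec


def random_intercept_slope(quintile: bool = False) -> ModelSpec:
    spec = ModelSpec("random_slope", ("intercept", "x1"), ("intercept", "x1"))
    return spec.with_quintile() if quintile else spec


def standard_specs(quintile: bool = False) -> tuple[ModelSpec, ModelSpec, ModelSpec]:
    """The three model families compared throughout the simulation study."""
    return (linear(quintile), random_intercept(quintile), random_intercept_slope(quintile))


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------

def design_matrices(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (X, Z, fixed-effect names) for ``spec`` from patient rows.

    Quintile dummies are always emitted for levels 2..5; levels absent from
    the data yield all-zero columns, which the fitter drops (their
    coefficients are reported as exact zeros, so predictions for unseen
    levels fall back to the reference-level contribution).
    """
    n = len(data)
    cols, names = [], []
    if "intercept" in spec.fixed:
        cols.append(np.ones(n))
        names.append("intercept")
    if "x1" in spec.fixed:
        cols.append(np.asarray(data["x1"], dtype=float))
        names.append("x1")
    if "quintile" in spec.fixed:
        quint = np.asarray(data["quintile"])
        for lev in _QUINTILE_LEVELS:
            cols.append((quint == lev).astype(float))
            names.append(f"quintile_{lev}")
    X = np.column_stack(cols)

    zcols = []
    if "intercept" in spec.random:
        zcols.append(np.ones(n))
    if "x1" in spec.random:
        zcols.append(np.asarray(data["x1"], dtype=float))
    Z = np.column_stack(zcols) if zcols else np.empty((n, 0))
    return X, Z, names


# ----------------------------------------------------------------------
# sufficient statistics and the profiled (penalized) REML deviance
# ----------------------------------------------------------------------

@dataclass
class _GroupStats:
    """Per-cluster cross-products; everything the REML objective needs."""

    A: np.ndarray        # (p+1, p+1): total [X, y]'[X, y]
    B: np.ndarray        # (m, q, p+1): per-group Z'[X, y]
    C: np.ndarray        # (m, q, q): per-group Z'Z
    n: int
    p: int
    q: int
    m: int
    labels: np.ndarray   # (m,) original group labels, sorted


def group_stats(X: np.ndarray, Z: np.ndarray, y: np.ndarray, groups: np.ndarray) -> _GroupStats:
    n, p = X.shape
    q = Z.shape[1]
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    m = labels.size
    F = np.concatenate([X, y[:, None]], axis=1)
    A = F.T @ F
    if q:
        B = np.zeros((m, q, p + 1))
        np.add.at(B, codes, Z[:, :, None] * F[:, None, :])
        C = np.zeros((m, q, q))
        np.add.at(C, codes, Z[:, :, None] * Z[:, None, :])
    else:
        B = np.zeros((m, 0, p + 1))
        C = np.zeros((m, 0, 0))
    return _GroupStats(A=A, B=B, C=C, n=n, p=p, q=q, m=m, labels=labels)


def _lambda_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular relative Cholesky factor with log-scale diagonal."""
    theta = np.clip(np.asarray(theta, dtype=float), -40.0, 40.0)
    if q == 1:
        return np.array([[math.exp(theta[0])]])
    L = np.zeros((2, 2))
    L[0, 0] = math.exp(theta[0])
    L[1, 0] = theta[1]
    L[1, 1] = math.exp(theta[2])
    return L


def _batched_inv_logdet(M: np.ndarray, q: int) -> tuple[np.ndarray, float]:
    """Inverse and total log-determinant of the stacked (m, q, q) matrices.

    M = I + L'CL is symmetric positive definite by construction, so the
    determinants are positive and the closed forms are safe.
    """
    if q == 1:
        det = M[:, 0, 0]
        inv = (1.0 / det)[:, None, None]
        return inv, float(np.log(det).sum())
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    inv /= det[:, None, None]
    return inv, float(np.log(det).sum())


def _profiled_deviance(
    L: np.ndarray,
    stats: _GroupStats,
    penalty_coef: float,
    fixed_scale: float | None = None,
):
    """Penalized profiled REML deviance at relative Cholesky factor ``L``.

    Returns (objective, beta, sigma2, aux) where aux holds the pieces needed
    to compute BLUPs and the fixed-effects covariance at this point.
    """
    p, q, n = stats.p, stats.q, stats.n
    if q:
        Bt = np.einsum("ba,mbk->mak", L, stats.B)           # L' B_i
        M = np.einsum("ba,mbc,cd->mad", L, stats.C, L)      # L' C_i L
        M[:, np.arange(q), np.arange(q)] += 1.0
        Minv, logdet_M = _batched_inv_logdet(M, q)
        U = np.einsum("mab,mbk->mak", Minv, Bt)
        S = stats.A - np.einsum("mak,maj->kj", Bt, U)
    else:
        Minv = None
        logdet_M = 0.0
        S = stats.A

    S_xx = S[:p, :p]
    S_xy = S[:p, p]
    S_yy = S[p, p]
    sign, logdet_Sxx = np.linalg.slogdet(S_xx)
    if sign <= 0:
        return np.inf, None, None, None
    beta = np.linalg.solve(S_xx, S_xy)
    rss = max(float(S_yy - S_xy @ beta), 1e-300)

    if fixed_scale is None:
        sigma2 = rss / (n - p)
    else:
        sigma2 = float(fixed_scale)
    if sigma2 <= 0:
        sigma2 = 1e-300
    dev = (
        logdet_M
        + logdet_Sxx
        + (n - p) * (_LOG_2PI + math.log(sigma2))
        + rss / sigma2
    )
    if penalty_coef and q:
        # -(nu - q - 1) * log|G|, G = sigma2 * L L'; bounds G away from singularity
        diag = np.diag(L)
        if np.any(diag <= 0):
            return np.inf, None, None, None
        log_det_G = q * math.log(sigma2) + 2.0 * float(np.log(diag).sum())
        dev -= penalty_coef * log_det_G
    aux = {"Minv": Minv, "S_xx": S_xx}
    return dev, beta, sigma2, aux


def _blups(L: np.ndarray, stats: _GroupStats, beta: np.ndarray, Minv: np.ndarray) -> np.ndarray:
    """Empirical-Bayes conditional modes b_i at the given variance point."""
    p = stats.p
    u = stats.B[:, :, p] - np.einsum("mqk,k->mq", stats.B[:, :, :p], beta)
    t = np.einsum("ba,mb->ma", L, u)                  # L' u
    v = np.einsum("mab,mb->ma", Minv, t)
    w = u - np.einsum("mab,bc,mc->ma", stats.C, L, v)  # u - C L Minv L' u
    Psi = L @ L.T
    return np.einsum("ab,mb->ma", Psi, w)


# ----------------------------------------------------------------------
# core fitting routine (array interface, used directly by the dynamic engine)
# ----------------------------------------------------------------------

@dataclass
class CoreFit:
    beta: np.ndarray            # (p,) aligned to the full design columns
    cov_beta: np.ndarray        # (p, p)
    sigma2: float
    cov_re: np.ndarray          # (q, q) estimated G
    group_labels: np.ndarray    # (m,)
    bhat: np.ndarray            # (m, q)
    converged: bool
    fallback_used: bool
    deviance: float
    n: int
    p: int
    q: int
    message: str = ""


def default_wishart_df(q: int) -> float:
    """Default prior degrees of freedom q + 2.5 (penalty coefficient 1.5)."""
    return q + 2.5


def fit_core(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    *,
    wishart_df: float | None = None,
    cov_re: np.ndarray | None = None,
    scale: float | None = None,
) -> CoreFit:
    """Fit the LMM (or OLS when Z has no columns) on raw arrays.

    All-zero design columns (absent categorical levels) are dropped for the
    fit and their coefficients restored as exact zeros. When ``cov_re`` and
    ``scale`` are both given, the variance components are held fixed and only
    the GLS fixed effects and BLUPs are computed (used by tests against the
    closed-form shrinkage estimator, and to force tau = 0 exactly).
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p_full = X.shape
    q = Z.shape[1]
    if n == 0:
        raise ValueError("empty training set")
    keep = X.any(axis=0)
    Xk = X[:, keep]
    p = Xk.shape[1]
    if q and np.unique(groups).size < 2:
        raise ValueError("mixed specifications require at least 2 clusters")

    stats = group_stats(Xk, Z, y, groups)

    def expand(beta_k: np.ndarray, cov_k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = np.zeros(p_full)
        beta[keep] = beta_k
        cov = np.zeros((p_full, p_full))
        cov[np.ix_(keep, keep)] = cov_k
        return beta, cov

    # --- fixed-effects-only: plain (RE)ML least squares -----------------
    if q == 0:
        dev, beta_k, sigma2, aux = _profiled_deviance(np.empty((0, 0)), stats, 0.0, scale)
        cov_k = sigma2 * np.linalg.inv(aux["S_xx"])
        beta, cov_beta = expand(beta_k, cov_k)
        return CoreFit(
            beta=beta, cov_beta=cov_beta, sigma2=sigma2,
            cov_re=np.zeros((0, 0)), group_labels=stats.labels,
            bhat=np.zeros((stats.m, 0)), converged=True, fallback_used=False,
            deviance=dev, n=n, p=p_full, q=0,
        )

    # --- variance components held fixed ---------------------------------
    if cov_re is not None:
        if scale is None:
            raise ValueError("cov_re requires scale (the residual variance)")
        Psi = np.asarray(cov_re, dtype=float) / float(scale)
        w, V = np.linalg.eigh(Psi)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        dev, beta_k, sigma2, aux = _profiled_deviance(L, stats, 0.0, scale)
        bhat = _blups(L, stats, beta_k, aux["Minv"])
        cov_k = sigma2 * np.linalg.inv(aux["S_xx"])
        beta, cov_beta = expand(beta_k, cov_k)
        return CoreFit(
            beta=beta, cov_beta=cov_beta, sigma2=sigma2,
            cov_re=np.asarray(cov_re, dtype=float), group_labels=stats.labels,
            bhat=bhat, converged=True, fallback_used=False,
            deviance=dev, n=n, p=p_full, q=q,
        )

    # --- penalized REML over the relative Cholesky factor ---------------
    nu = default_wishart_df(q) if wishart_df is None else float(wishart_df)
    penalty_coef = nu - q - 1.0

    def objective(theta: np.ndarray) -> float:
        L = _lambda_from_theta(theta, q)
        dev = _profiled_deviance(L, stats, penalty_coef)[0]
        return dev if np.isfinite(dev) else 1e12

    n_par = 1 if q == 1 else 3
    starts = [np.zeros(n_par)]
    inflated = np.zeros(n_par)
    inflated[0] = math.log(5.0)
    if q == 2:
        inflated[2] = math.log(5.0)
    starts.append(inflated)

    best = None
    converged = False
    message = ""
    for k, x0 in enumerate(starts):
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            best = res if res.fun <= best.fun + 1e-9 else best
            if k == 0:
                break  # default start converged; no retry needed
        message = res.message

    fallback_used = False
    if best is None or not np.isfinite(best.fun):
        # total failure: fall back to the fixed-effects-only fit (Psi = 0)
        L = np.zeros((q, q))
        fallback_used = True
        converged = False
    else:
        L = _lambda_from_theta(best.x, q)

    dev, beta_k, sigma2, aux = _profiled_deviance(L, stats, penalty_coef)
    bhat = _blups(L, stats, beta_k, aux["Minv"])
    cov_k = sigma2 * np.linalg.inv(aux["S_xx"])
    beta, cov_beta = expand(beta_k, cov_k)
    return CoreFit(
        beta=beta, cov_beta=cov_beta, sigma2=sigma2,
        cov_re=sigma2 * (L @ L.T), group_labels=stats.labels,
        bhat=bhat, converged=converged, fallback_used=fallback_used,
        deviance=dev, n=n, p=p_full, q=q, message=str(message),
    )


# ----------------------------------------------------------------------
# statsmodels-style model / results objects
# ----------------------------------------------------------------------

class ClusteredLMM:
    """A clustered linear (mixed) model bound to patient-level data.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``y``, ``clinic_id``, and the covariates the spec uses
        (``x1``; ``quintile`` when the spec includes the quintile fixed
        effect).
    spec : ModelSpec
        Which fixed and random terms to include.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if len(data) == 0:
            raise ValueError("empty training set")
        self.data = data
        self.spec = spec
        self.X, self.Z, self.fe_names = design_matrices(data, spec)
        self.groups = np.asarray(data["clinic_id"])
        self.y = np.asarray(data["y"], dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "ClusteredLMM":
        return cls(data, spec)

    def fit(
        self,
        wishart_df: float | None = None,
        cov_re: np.ndarray | None = None,
        scale: float | None = None,
    ) -> "LMMResults":
        """Estimate the model by penalized REML (deterministic, seed-free).

        ``wishart_df`` controls the Wishart-style covariance penalty
        (default q + 2.5; q + 1 disables it). Passing ``cov_re`` and
        ``scale`` fixes the variance components instead of estimating them.
        """
        core = fit_core(
            self.X, self.Z, self.y, self.groups,
            wishart_df=wishart_df, cov_re=cov_re, scale=scale,
        )
        return LMMResults(self, core)


class LMMResults:
    """Estimates, uncertainties and cluster effects from a fitted model."""

    def __init__(self, model: ClusteredLMM, core: CoreFit):
        self.model = model
        self.spec = model.spec
        self._core = core
        self.fe_params = core.beta
        self.cov_params = core.cov_beta
        self.bse = np.sqrt(np.clip(np.diag(core.cov_beta), 0.0, None))
        self.scale = core.sigma2            # residual variance sigma^2
        self.cov_re = core.cov_re           # estimated G
        self.n_obs = core.n
        self.n_clusters = core.group_labels.size
        self.converged = core.converged
        self.fallback_used = core.fallback_used
        self.deviance = core.deviance

    @property
    def random_effects(self) -> dict:
        """Map clinic_id -> estimated random-effect vector (BLUP)."""
        return {
            label: self._core.bhat[i].copy()
            for i, label in enumerate(self._core.group_labels)
        }

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Point predictions x'beta + z'b_i; novel clinics use b_i = 0."""
        X, Z, _ = design_matrices(data, self.spec)
        pred = X @ self.fe_params
        if self._core.q:
            lab = self._core.group_labels
            lookup = {v: i for i, v in enumerate(lab)}
            idx = np.array([lookup.get(g, -1) for g in np.asarray(data["clinic_id"])])
            bh = np.vstack([self._core.bhat, np.zeros((1, self._core.q))])
            pred = pred + np.einsum("nq,nq->n", Z, bh[idx])
        return pred

    def summary(self) -> str:
        spec = self.spec
        lines = [
            f"Clustered LMM results: {spec.name}",
            "=" * 58,
            f"fixed terms:  {', '.join(spec.fixed)}",
            f"random terms: {', '.join(spec.random) if spec.random else '(none)'}",
            f"n obs: {self.n_obs}    n clusters: {self.n_clusters}    "
            f"converged: {self.converged}",
            "-" * 58,
            f"{'coef':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name, b, se in zip(self.model.fe_names, self.fe_params, self.bse):
            lines.append(f"{name:<14}{b:>12.4f}{se:>12.4f}")
        lines.append("-" * 58)
        lines.append(f"residual variance sigma^2: {self.scale:.4f}")
        if self._core.q:
            lines.append("random-effects covariance G:")
            for row in self.cov_re:
                lines.append("  " + "  ".join(f"{v:10.4f}" for v in row))
        return "\n".join(lines)

    def to_json(self) -> str:
        """Serialize coefficients, covariances and cluster effects."""
        payload = {
            "spec": {"name": self.spec.name, "fixed": list(self.spec.fixed),
                     "random": list(self.spec.random)},
            "fe_names": list(self.model.fe_names),
            "fe_params": self.fe_params.tolist(),
            "bse": self.bse.tolist(),
            "scale": self.scale,
            "cov_re": self.cov_re.tolist(),
            "random_effects": {str(k): v.tolist() for k, v in self.random_effects.items()},
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "fallback_used": self.fallback_used,
        }
        return json.dumps(payload, indent=2)


def true_model_predict(population, patients: pd.DataFrame) -> np.ndarray:
    """Predictions of the data-generating ('true') model: the stored
    conditional mean of each patient (the generating equation minus the
    residual). Raises if any patient is not part of the population."""
    merged = patients.merge(
        population.patients[["clinic_id", "patient_id", "mu_true"]],
        on=["clinic_id", "patient_id"],
        how="left",
        suffixes=("", "_pop"),
    )
    col = "mu_true_pop" if "mu_true_pop" in merged.columns else "mu_true"
    vals = merged[col].to_numpy()
    if np.isnan(vals).any():
        raise KeyError("patient(s) not found in the population")
    return vals
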