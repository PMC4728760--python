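"""Calibration metrics: MAE, relative improvement, learning curves.

Model accuracy is summarized as mean absolute error (MAE),

    phi = mean |prediction - outcome|,

and reported as the relative improvement (RI) over the intercept-only null,

    RI = (phi_0 - phi_model) / (phi_0 - phi_1),

where phi_0 is the MAE of the constant prediction (the training-sample mean
outcome, fit once and never updated) and phi_1 is the MAE of the true
data-generating model (the conditional mean, i.e. the generating equation
minus the residual). RI = 0 means null-equivalent, RI = 1 oracle-equivalent;
values above 1 indicate in-sample overfitting and negative values a model
worse than predicting the average. Because all three MAEs share the same
residuals, RI is relatively insensitive to the residual-variance scale.

Learning curves track RI as a function of the within-clinic prediction index
j (the j-th prediction made at a clinic), pooling absolute errors over
clinics within each replicate, converting to RI with that replicate's
baselines, and averaging across replicates with count weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamic import PredictionTrace

__all__ = [
    "MetricsResult",
    "LearningCurve",
    "mae",
    "relative_improvement",
    "baselines",
    "score_trace",
    "score_predictions",
    "learning_curve",
    "gains_threshold",
]


def mae(predictions, outcomes) -> float:
    """Mean absolute error over the sample being assessed."""
    predictions = np.asarray(predictions, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if predictions.size == 0:
        raise ValueError("cannot compute MAE of an empty event set")
    return float(np.mean(np.abs(predictions - outcomes)))


def relative_improvement(phi_model: float, phi0: float, phi1: float) -> float:
    """RI = (phi0 - phi_model) / (phi0 - phi1); requires phi0 > phi1."""
    if not phi0 > phi1:
        raise ValueError(
            f"degenerate baselines: phi0 ({phi0}) must exceed phi1 ({phi1})"
        )
    return (phi0 - phi_model) / (phi0 - phi1)


def baselines(ybar_train: float, y, mu_true) -> tuple[float, float]:
    """(phi0, phi1) over a scope: MAE of the constant training-sample mean
    prediction, and MAE of the true conditional mean (= mean |residual|).

    ``ybar_train`` is estimated once in the original training sample and is
    deliberately not updated during dynamic runs, so RI stays comparable
    across models and update schedules.
    """
    phi0 = mae(np.full(len(np.asarray(y)), ybar_train), y)
    phi1 = mae(mu_true, y)
    return phi0, phi1


@dataclass
class MetricsResult:
    """MAE/RI summary for one model over one scope (set of events)."""

    model: str
    scope: str
    mae: float
    mae_null: float        # phi_0
    mae_true: float        # phi_1
    ri: float
    ri_by_quintile: dict[int, float] = field(default_factory=dict)
    n: int = 0

    def to_row(self) -> dict:
        row = {
            "model": self.model, "scope": self.scope, "n": self.n,
            "mae": self.mae, "mae_null": self.mae_null, "mae_true": self.mae_true,
            "ri": self.ri,
        }
        for quint, ri in self.ri_by_quintile.items():
            row[f"ri_q{quint}"] = ri
        return row


def score_predictions(
    predictions,
    y,
    mu_true,
    ybar_train: float,
    model: str = "",
    scope: str = "",
    quintile=None,
) -> MetricsResult:
    """Score a set of predictions against the shared baselines.

    Per-quintile RI restricts the model MAE *and* both baseline MAEs to each
    quintile's events (the baseline predictors themselves stay global), so
    overall RI is the gain-mass-weighted aggregate of per-quintile RIs.
    """
    predictions = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    mu_true = np.asarray(mu_true, dtype=float)
    phi0, phi1 = baselines(ybar_train, y, mu_true)
    phi = mae(predictions, y)
    ri = relative_improvement(phi, phi0, phi1)
    by_quint: dict[int, float] = {}
    if quintile is not None:
        quintile = np.asarray(quintile)
        for quint in np.unique(quintile):
            mask = quintile == quint
            q_phi0, q_phi1 = baselines(ybar_train, y[mask], mu_true[mask])
            by_quint[int(quint)] = relative_improvement(
                mae(predictions[mask], y[mask]), q_phi0, q_phi1
            )
    return MetricsResult(
        model=model, scope=scope, mae=phi, mae_null=phi0, mae_true=phi1,
        ri=ri, ri_by_quintile=by_quint, n=len(y),
    )


def score_trace(trace: PredictionTrace, ybar_train: float, scope: str = "testing") -> MetricsResult:
    ev = trace.events
    return score_predictions(
        ev["prediction"], ev["y"], ev["mu_true"], ybar_train,
        model=trace.model, scope=scope, quintile=ev["quintile"],
    )


# ----------------------------------------------------------------------
# learning curves
# ----------------------------------------------------------------------

@dataclass
class LearningCurve:
    """RI as a function of the within-clinic prediction index j.

    ``index`` holds the supported j values (1-based, truncated where the
    pooled count falls below ``support_frac`` of the j = 1 count); ``ri``
    the pooled RI at each; ``counts`` the number of contributing
    predictions. ``plateau`` is the mean RI over the trailing
    ``plateau_frac`` share of supported indices.
    """

    index: np.ndarray
    ri: np.ndarray
    counts: np.ndarray
    plateau: float
    support_frac: float
    plateau_frac: float
    pooling: str = "pooled |error| per replicate; count-weighted RI across replicates"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"within_clinic_index": self.index, "ri": self.ri, "count": self.counts}
        )


def learning_curve(
    traces: list[PredictionTrace],
    replicate_baselines: list[tuple[float, float]],
    support_frac: float = 0.05,
    plateau_frac: float = 0.2,
) -> LearningCurve:
    """Pool traces from one or more replicates into a single RI-vs-j curve.

    Within each replicate, absolute errors are pooled over clinics at each
    index j and converted to RI with that replicate's (phi0, phi1); across
    replicates the per-index RIs are averaged with count weights. Indices
    whose pooled count falls below ``support_frac`` of the j = 1 count are
    truncated (small-count tails are noise-dominated).
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if len(traces) != len(replicate_baselines):
        raise ValueError("one (phi0, phi1) pair per trace is required")

    per_rep = []
    for trace, (phi0, phi1) in zip(traces, replicate_baselines):
        if not phi0 > phi1:
            raise ValueError("degenerate baselines: phi0 must exceed phi1")
        ev = trace.events
        err = np.abs(ev["prediction"].to_numpy() - ev["y"].to_numpy())
        grouped = pd.DataFrame(
            {"j": ev["within_clinic_index"].to_numpy(), "err": err}
        ).groupby("j")["err"].agg(["sum", "count"])
        ri = (phi0 - grouped["sum"] / grouped["count"]) / (phi0 - phi1)
        per_rep.append(pd.DataFrame({"j": grouped.index, "ri": ri.to_numpy(),
                                     "count": grouped["count"].to_numpy()}))

    pooled = pd.concat(per_rep, ignore_index=True)
    pooled["w_ri"] = pooled["ri"] * pooled["count"]
    agg = pooled.groupby("j").agg(count=("count", "sum"), w_ri=("w_ri", "sum"))
    agg["ri"] = agg["w_ri"] / agg["count"]
    agg = agg.sort_index()

    counts = agg["count"].to_numpy()
    supported = counts >= support_frac * counts[0]
    # truncate at the first unsupported index (counts are non-increasing in
    # expectation; any later re-crossing would be noise)
    cutoff = int(np.argmin(supported)) if not supported.all() else len(supported)
    index = agg.index.to_numpy()[:cutoff]
    ri = agg["ri"].to_numpy()[:cutoff]
    counts = counts[:cutoff]
    if index.size == 0:
        raise ValueError("no supported indices in the learning curve")

    window = max(1, int(round(plateau_frac * index.size)))
    plateau = float(np.mean(ri[-window:]))
    return LearningCurve(
        index=index, ri=ri, counts=counts, plateau=plateau,
        support_frac=support_frac, plateau_frac=plateau_frac,
    )


def gains_threshold(curve: LearningCurve, fraction: float = 0.8) -> tuple[int, bool]:
    """Smallest index j at which ``fraction`` of the total learning-curve
    gains (plateau minus RI at j = 1) have been attained.

    Returns (j_star, degenerate): when the total gain is non-positive (a
    flat or falling curve), j_star = 1 with the degenerate flag set.
    """
    if curve.index.size < 2:
        raise ValueError("need at least 2 supported indices")
    total = curve.plateau - curve.ri[0]
    if total <= 0:
        return int(curve.index[0]), True
    target = curve.ri[0] + fraction * total
    hit = np.flatnonzero(curve.ri >= target)
    return int(curve.index[hit[0]]), False
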