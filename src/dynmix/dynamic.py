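"""Static and dynamic prediction experiments over a simulated population.

The engine selects a stratified training sample of clinics, fits every model
spec on it, then walks the testing sample (all patients of the remaining
clinics) in one global uniform-random permutation. Under dynamic updating,
after every ``theta`` predictions the outcomes of that block's patients are
added to the training data independently with probability ``p_incorporate``
and all models are refit on the accumulated data; the final partial block is
predicted but triggers no refit. Static models are the ``theta = None``
special case: one fit, never updated, novel clinics predicted at the
hypothetical mean cluster (b_i = 0).

All model specs share the same permutation and incorporation draws within a
run (a paired design), and a refit is bit-equivalent to a fresh static fit
on the accumulated training set (no warm starts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import CoreFit, ModelSpec, design_matrices, fit_core
from .simulate import Population

__all__ = [
    "PredictionTrace",
    "select_training_clinics",
    "run_static",
    "run_dynamic",
]

EVENT_COLUMNS = [
    "order_index", "clinic_id", "patient_id", "quintile", "within_clinic_index",
    "cycle_index", "prediction", "y", "mu_true", "incorporated",
]


@dataclass
class PredictionTrace:
    """Ordered log of every out-of-sample prediction for one model spec."""

    model: str
    events: pd.DataFrame    # EVENT_COLUMNS, one row per testing-sample patient
    refit_log: pd.DataFrame  # cycle, n_rows, n_clusters, refitted, converged, fallback_used

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out.insert(0, "model_name", self.model)
        out.to_csv(path, index=False)


def select_training_clinics(
    population: Population, rng: np.random.Generator, counts=None
) -> np.ndarray:
    """Simple random sample of clinics without replacement within each size
    quintile, with the configured per-quintile counts (smallest to largest,
    default 6, 6, 3, 3, 2)."""
    counts = population.params.training_quintile_counts if counts is None else tuple(counts)
    clinics = population.clinics
    chosen = []
    for quint, want in zip(range(1, 6), counts):
        ids = clinics.loc[clinics["quintile"] == quint, "clinic_id"].to_numpy()
        if len(ids) < want:
            raise ValueError(
                f"quintile {quint} has {len(ids)} clinics, fewer than the "
                f"requested {want}"
            )
        chosen.append(rng.choice(ids, size=want, replace=False))
    return np.sort(np.concatenate(chosen))


def _prepare(population: Population, specs):
    """Precompute full-population design matrices per spec (rows are shared
    between the training sample and the testing stream)."""
    pat = population.patients
    codes, labels = pd.factorize(pat["clinic_id"], sort=True)
    designs = {}
    for spec in specs:
        X, Z, names = design_matrices(pat, spec)
        designs[spec.name] = (spec, X, Z, names)
    y = pat["y"].to_numpy(dtype=float)
    return pat, codes.astype(np.int64), np.asarray(labels), designs, y


def run_dynamic(
    population: Population,
    training_ids: np.ndarray,
    specs,
    theta: int | None = None,
    p_incorporate: float | None = None,
    rng: np.random.Generator | None = None,
    wishart_df: float | None = None,
) -> dict[str, PredictionTrace]:
    """Run the prediction experiment; returns one trace per model spec.

    ``theta = None`` disables updating entirely (the static experiment).
    The permutation and the per-patient incorporation draws come from two
    dedicated substreams of ``rng``, so static and dynamic runs seeded
    identically walk the testing sample in the same order.
    """
    params = population.params
    if theta is not None and theta < 1:
        raise ValueError("theta must be >= 1")
    if p_incorporate is None:
        p_incorporate = params.p_incorporate
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rng_perm, rng_inc = rng.spawn(2)

    specs = list(specs)
    pat, codes, labels, designs, y_all = _prepare(population, specs)
    mu_all = pat["mu_true"].to_numpy(dtype=float)
    clinic_ids_all = pat["clinic_id"].to_numpy()
    quintile_all = pat["quintile"].to_numpy()
    n_clinics = labels.size

    training_ids = np.asarray(training_ids)
    is_train = np.isin(clinic_ids_all, training_ids)
    train_rows = np.flatnonzero(is_train)
    test_rows = np.flatnonzero(~is_train)
    n_test = test_rows.size
    if n_test == 0:
        raise ValueError("no testing-sample patients")

    order = test_rows[rng_perm.permutation(n_test)]
    incorporated = rng_inc.random(n_test) < p_incorporate

    # within-clinic prediction index along the permutation (1-based)
    perm_codes = codes[order]
    within = (
        pd.Series(perm_codes).groupby(perm_codes).cumcount().to_numpy(np.int64) + 1
    )

    if theta is None:
        cycle_index = np.zeros(n_test, dtype=np.int64)
    else:
        cycle_index = np.arange(n_test, dtype=np.int64) // theta

    def fit_on(rows: np.ndarray, spec_name: str) -> CoreFit:
        spec, X, Z, _ = designs[spec_name]
        return fit_core(
            X[rows], Z[rows], y_all[rows], codes[rows], wishart_df=wishart_df
        )

    def bhat_lookup(core: CoreFit) -> np.ndarray:
        table = np.zeros((n_clinics, max(core.q, 1)))
        if core.q:
            # group labels here are compact codes into `labels`
            table[core.group_labels.astype(np.int64), :] = core.bhat
        return table

    fits: dict[str, CoreFit] = {}
    tables: dict[str, np.ndarray] = {}
    logs: dict[str, list] = {s.name: [] for s in specs}
    for spec in specs:
        core = fit_on(train_rows, spec.name)
        fits[spec.name] = core
        tables[spec.name] = bhat_lookup(core)
        logs[spec.name].append(
            (0, core.n, core.group_labels.size, True, core.converged, core.fallback_used)
        )

    preds = {s.name: np.empty(n_test) for s in specs}
    acc_rows = [train_rows]
    n_acc_new = 0
    block = theta if theta is not None else n_test

    start = 0
    while start < n_test:
        stop = min(start + block, n_test)
        rows = order[start:stop]
        for spec in specs:
            _, X, Z, _ = designs[spec.name]
            core = fits[spec.name]
            pr = X[rows] @ core.beta
            if core.q:
                pr = pr + np.einsum("nq,nq->n", Z[rows], tables[spec.name][codes[rows]])
            preds[spec.name][start:stop] = pr
        # incorporate this block's outcomes, then refit at exact block
        # boundaries while predictions remain (final partial block: no refit)
        if theta is not None and stop - start == theta and stop < n_test:
            new = rows[incorporated[start:stop]]
            if new.size:
                acc_rows.append(new)
                n_acc_new += new.size
            acc = np.concatenate(acc_rows) if len(acc_rows) > 1 else acc_rows[0]
            cycle = stop // theta
            for spec in specs:
                if new.size == 0:
                    # nothing accumulated: the refit would reproduce the
                    # current fit exactly (fitting is deterministic); skip
                    core = fits[spec.name]
                    logs[spec.name].append(
                        (cycle, core.n, core.group_labels.size, False,
                         core.converged, core.fallback_used)
                    )
                    continue
                core = fit_on(acc, spec.name)
                if not core.converged and not core.fallback_used:
                    pass  # usable non-converged fit: keep, but it is logged
                if core.fallback_used:
                    # estimation collapsed: reuse the previous cycle's fit
                    prev = fits[spec.name]
                    logs[spec.name].append(
                        (cycle, core.n, core.group_labels.size, True, False, True)
                    )
                    core = prev
                else:
                    logs[spec.name].append(
                        (cycle, core.n, core.group_labels.size, True,
                         core.converged, core.fallback_used)
                    )
                fits[spec.name] = core
                tables[spec.name] = bhat_lookup(core)
        start = stop

    traces = {}
    for spec in specs:
        events = pd.DataFrame(
            {
                "order_index": np.arange(n_test, dtype=np.int64),
                "clinic_id": clinic_ids_all[order],
                "patient_id": pat["patient_id"].to_numpy()[order],
                "quintile": quintile_all[order],
                "within_clinic_index": within,
                "cycle_index": cycle_index,
                "prediction": preds[spec.name],
                "y": y_all[order],
                "mu_true": mu_all[order],
                "incorporated": incorporated if theta is not None else np.zeros(n_test, bool),
            }
        )
        refit_log = pd.DataFrame(
            logs[spec.name],
            columns=["cycle", "n_rows", "n_clusters", "refitted", "converged", "fallback_used"],
        )
        traces[spec.name] = PredictionTrace(spec.name, events, refit_log)
    return traces


def run_static(
    population: Population,
    training_ids: np.ndarray,
    specs,
    rng: np.random.Generator | None = None,
    wishart_df: float | None = None,
) -> dict[str, PredictionTrace]:
    """One fit on the training sample, applied unchanged to every
    testing-sample patient (every testing clinic is novel, so mixed-model
    predictions use b_i = 0). Output is independent of theta by
    construction."""
    return run_dynamic(
        population, training_ids, specs,
        theta=None, p_incorporate=0.0, rng=rng, wishart_df=wishart_df,
    )
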