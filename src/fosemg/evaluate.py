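"""Evaluation: RMSD, R-squared, cross-validation and method comparison.

Forces are compared on the normalized (max = 1) scale, so the root mean
square difference

    RMSD = sqrt( sum_i (yhat_i - y_i)^2 / T ) * 100 %

is a percentage of full scale, and

    R^2 = 1 - sum_i (yhat_i - y_i)^2 / sum_i (ybar - y_i)^2

measures stability relative to the constant-mean predictor. The
cross-validation protocol trains the force model on a single repetition
and tests on every other repetition of the same session, cycling the
training repetition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgumentError, signal_values
from .fos import (
    DEFAULT_MAX_FUNCTIONS,
    DEFAULT_RMSD_THRESHOLD,
    build_candidate_pool,
    fos_fit,
    fos_predict,
)
from .preprocess import normalize_to_max


@dataclass(frozen=True)
class Metrics:
    """RMSD (percent of full scale) and R-squared for one comparison."""

    rmsd: float
    r2: float
    n_samples: int


@dataclass
class TrialSet:
    """Repetitions of (H_BI, H_TR, force) at one force level.

    Force traces and activation signals are expected on the normalized
    (max = 1) per-trial scale.
    """

    repetitions: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    level: float = 0.4
    method_label: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.repetitions) < 2:
            raise InvalidArgumentError("cross-validation needs at least 2 repetitions")
        reps = []
        for h_bi, h_tr, force in self.repetitions:
            a, b, f = signal_values(h_bi), signal_values(h_tr), signal_values(force)
            if not (a.size == b.size == f.size):
                raise InvalidArgumentError("lengths within a repetition must match")
            reps.append((a, b, f))
        self.repetitions = reps


def rmsd(y, yhat) -> float:
    """Root mean square difference in percent of the normalized scale."""
    yv, yh = signal_values(y), signal_values(yhat)
    if yv.size != yh.size or yv.size == 0:
        raise InvalidArgumentError("inputs must be nonempty and of equal length")
    return float(np.sqrt(np.mean((yh - yv) ** 2)) * 100.0)


def r_squared(y, yhat) -> float:
    """Coefficient of determination relative to the mean predictor."""
    yv, yh = signal_values(y), signal_values(yhat)
    if yv.size != yh.size or yv.size == 0:
        raise InvalidArgumentError("inputs must be nonempty and of equal length")
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot <= 0:
        raise InvalidArgumentError("y is constant; R^2 undefined")
    return float(1.0 - np.sum((yh - yv) ** 2) / ss_tot)


def metrics(y, yhat) -> Metrics:
    return Metrics(rmsd(y, yhat), r_squared(y, yhat), signal_values(y).size)


def activation_force_correlation(h, y) -> float:
    """Pearson correlation between an activation signal and the force."""
    hv, yv = signal_values(h), signal_values(y)
    if hv.size != yv.size:
        raise InvalidArgumentError("inputs must have equal length")
    if np.ptp(hv) == 0 or np.ptp(yv) == 0:
        raise InvalidArgumentError("correlation undefined for constant input")
    return float(stats.pearsonr(hv, yv).statistic)


@dataclass
class CrossvalResult:
    """Per-fold records plus their aggregate."""

    records: pd.DataFrame  # train_rep, test_rep, rmsd, r2, error
    rmsd_mean: float
    rmsd_sd: float
    r2_mean: float
    r2_sd: float


def crossval(
    trials: TrialSet,
    max_functions: int = DEFAULT_MAX_FUNCTIONS,
    rmsd_reduction_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> CrossvalResult:
    """One-repetition-train / rest-test cross-validation.

    Each repetition in turn is the training set; the FOS model fitted on it
    is evaluated on every other repetition. A fitting failure on a fold is
    recorded in that fold's row rather than raised.
    """
    rows = []
    n = len(trials.repetitions)
    for train in range(n):
        h_bi, h_tr, force = trials.repetitions[train]
        try:
            pool = build_candidate_pool(h_bi, h_tr)
            model = fos_fit(force, pool, max_functions, rmsd_reduction_threshold)
        except Exception as exc:  # recorded per fold, not fatal
            for test in range(n):
                if test != train:
                    rows.append(
                        dict(train_rep=train, test_rep=test, rmsd=np.nan, r2=np.nan, error=str(exc))
                    )
            continue
        for test in range(n):
            if test == train:
                continue
            tb, tt, tf = trials.repetitions[test]
            yhat = fos_predict(model, tb, tt)
            rows.append(
                dict(train_rep=train, test_rep=test, rmsd=rmsd(tf, yhat), r2=r_squared(tf, yhat), error="")
            )
    records = pd.DataFrame(rows)
    ok = records[records["error"] == ""]
    return CrossvalResult(
        records=records,
        rmsd_mean=float(ok["rmsd"].mean()),
        rmsd_sd=float(ok["rmsd"].std(ddof=1)) if len(ok) > 1 else 0.0,
        r2_mean=float(ok["r2"].mean()),
        r2_sd=float(ok["r2"].std(ddof=1)) if len(ok) > 1 else 0.0,
    )


def compare_methods(results: dict[str, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Summarize per-fold records as mean +/- sd RMSD and R^2 per method.

    Accepts either a combined records table with a ``method`` column or a
    mapping from method name to its records. If a ``level`` column is
    present the summary is additionally split by force level.
    """
    if isinstance(results, dict):
        if len(results) < 2:
            raise InvalidArgumentError("need at least two methods to compare")
        frames = []
        for name, df in results.items():
            f = df.copy()
            f["method"] = name
            frames.append(f)
        records = pd.concat(frames, ignore_index=True)
    else:
        records = results
    if "error" in records.columns:
        records = records[records["error"].fillna("") == ""]
    keys = ["method"] + (["level"] if "level" in records.columns else [])
    summary = (
        records.groupby(keys, sort=False)
        .agg(
            rmsd_mean=("rmsd", "mean"),
            rmsd_sd=("rmsd", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            r2_mean=("r2", "mean"),
            r2_sd=("r2", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n_folds=("rmsd", "size"),
        )
        .reset_index()
    )
    return summary


def experiment_grid(
    n_subjects: int = 7,
    levels: tuple[float, ...] = (0.2, 0.4, 0.6),
    methods: tuple[str, ...] = ("avg", "pca", "ica", "nmf"),
    n_repetitions: int = 7,
) -> pd.DataFrame:
    """Full factorial design of training runs: subjects x levels x methods x repetitions."""
    from itertools import product

    rows = [
        dict(subject=s, level=l, method=m, repetition=r)
        for s, l, m, r in product(
            range(1, n_subjects + 1), levels, methods, range(1, n_repetitions + 1)
        )
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged heterogeneity benchmark
# ---------------------------------------------------------------------------


def heterogeneity_benchmark(
    n_seeds: int = 20,
    methods: tuple[str, ...] = ("avg", "pca", "ica", "nmf"),
    protocol=None,
    base_seed: int = 0,
    max_functions: int = DEFAULT_MAX_FUNCTIONS,
    rmsd_reduction_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic comparison of activation-extraction methods.

    Simulates ``n_seeds`` sessions with strongly heterogeneous activation
    (disjoint footprints of unequal width, unequal channel gains, staggered
    component recruitment), runs the 1-train / rest-test cross-validation
    for every method, and returns ``(records, summary)``: per-fold metrics
    and the per-method aggregate. Averaging all channel envelopes mixes the
    latent drives with footprint-dependent weights, while factorization
    recovers them individually, which is the effect the benchmark isolates.
    """
    from .factorize import extract_activation
    from .synth import _child_seeds, simulate_study

    all_records = []
    for i, seed in enumerate(_child_seeds(base_seed, n_seeds)):
        session = simulate_study(protocol=protocol, seed=seed)
        forces = [normalize_to_max(rep.force) for rep in session.repetitions]
        for method in methods:
            ex_seeds = _child_seeds(seed + 1, len(session.repetitions))
            reps = []
            for rep, f, s in zip(session.repetitions, forces, ex_seeds):
                h_bi = extract_activation(rep.agonist, method, seed=s)
                h_tr = extract_activation(rep.antagonist, method, seed=s)
                reps.append((h_bi.values, h_tr.values, f))
            trials = TrialSet(reps, level=session.protocol.target_level, method_label=method)
            cv = crossval(trials, max_functions, rmsd_reduction_threshold)
            rec = cv.records.copy()
            rec["method"] = method
            rec["seed_index"] = i
            rec["level"] = session.protocol.target_level
            all_records.append(rec)
    records = pd.concat(all_records, ignore_index=True)
    summary = compare_methods(records.drop(columns=["level"]))
    return records, summary
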