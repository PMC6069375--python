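"""Fast orthogonal search (FOS) for SEMG-driven force modelling.

FOS approximates a measured output y(t) as a weighted sum of basis functions
built from the muscle activation signals,

    y(t) = sum_m a_m p_m(t) + e(t).

Candidates p_m are drawn greedily from a fixed pool: at every step the
candidate whose Gram-Schmidt orthogonalization against the already selected
functions yields the largest mean-square-error reduction is added, until a
maximum model size is reached or no remaining candidate can reduce the
normalized RMSD by more than a threshold (in percentage points). Orthogonal
coefficients g_m come for free from the greedy search; coefficients a_m in
the original basis are recovered by the standard back-substitution

    a_m = sum_{i=m}^{M} g_i v_i,   v_m = 1,
    v_i = -sum_{r=m}^{i-1} alpha_ir v_r   (m < i <= M),

where alpha_ir is the projection coefficient of candidate p_i onto the
orthogonal function q_r. With a fixed selected set this is algebraically
identical to ordinary least squares on the selected columns; the greedy
search is what makes the model sparse and fast to build.

All inner products are time averages, mean(u * v), following the system-
identification convention; this only rescales g and alpha consistently and
leaves the fitted values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import InvalidArgumentError, signal_values

#: Relative tolerance below which an orthogonalized candidate is treated as
#: collinear with the current selection and skipped.
COLLINEARITY_RTOL = 1e-12

DEFAULT_MAX_FUNCTIONS = 7
DEFAULT_RMSD_THRESHOLD = 0.2  # percentage points of normalized RMSD


def sigm(x: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1 / (1 + exp(-x)).

    Monotone increasing and bounded in (0, 1). Activation signals are
    max-normalized upstream, so the argument lives in [0, 1].
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class BasisFunction:
    """One candidate basis function of the pool.

    ``evaluator`` maps a dict of named activation signals to the time series
    p_m(t); evaluation is pure and pointwise.
    """

    name: str
    inputs: frozenset[str]
    evaluator: Callable[[Mapping[str, np.ndarray]], np.ndarray]

    def __call__(self, signals: Mapping[str, np.ndarray]) -> np.ndarray:
        return np.asarray(self.evaluator(signals), dtype=float)


def _bf(name: str, inputs: Sequence[str], fn) -> BasisFunction:
    return BasisFunction(name, frozenset(inputs), fn)


#: Dual-grid candidate pool: a bias plus 13 functions of the agonist and
#: antagonist activation signals H_BI and H_TR, in four families
#: (fundamental, polynomial, square root, sigmoid).
_BIAS = _bf("bias", (), lambda s: np.ones_like(next(iter(s.values()))))

DUAL_POOL: tuple[BasisFunction, ...] = (
    _BIAS,
    # fundamental
    _bf("H_BI", ("H_BI",), lambda s: s["H_BI"]),
    _bf("H_TR", ("H_TR",), lambda s: s["H_TR"]),
    _bf("H_BI*H_TR", ("H_BI", "H_TR"), lambda s: s["H_BI"] * s["H_TR"]),
    # polynomial
    _bf("H_BI^2", ("H_BI",), lambda s: s["H_BI"] ** 2),
    _bf("H_TR^2", ("H_TR",), lambda s: s["H_TR"] ** 2),
    _bf("H_BI^3", ("H_BI",), lambda s: s["H_BI"] ** 3),
    _bf("H_TR^3", ("H_TR",), lambda s: s["H_TR"] ** 3),
    # square root
    _bf("sqrt(H_BI)", ("H_BI",), lambda s: np.sqrt(s["H_BI"])),
    _bf("sqrt(H_TR)", ("H_TR",), lambda s: np.sqrt(s["H_TR"])),
    _bf("sqrt(H_BI*H_TR)", ("H_BI", "H_TR"), lambda s: np.sqrt(s["H_BI"] * s["H_TR"])),
    # sigmoid
    _bf("sigm(H_BI)", ("H_BI",), lambda s: sigm(s["H_BI"])),
    _bf("sigm(H_TR)", ("H_TR",), lambda s: sigm(s["H_TR"])),
    _bf(
        "sigm(H_BI)*sigm(H_TR)",
        ("H_BI", "H_TR"),
        lambda s: sigm(s["H_BI"]) * sigm(s["H_TR"]),
    ),
)

#: Single-grid pool used when only one electrode grid is available.
SINGLE_POOL: tuple[BasisFunction, ...] = (
    _BIAS,
    _bf("H", ("H",), lambda s: s["H"]),
    _bf("H^2", ("H",), lambda s: s["H"] ** 2),
    _bf("H^3", ("H",), lambda s: s["H"] ** 3),
    _bf("sqrt(H)", ("H",), lambda s: np.sqrt(s["H"])),
    _bf("sigm(H)", ("H",), lambda s: sigm(s["H"])),
)

DUAL_POOL_NAMES = tuple(f.name for f in DUAL_POOL)
SINGLE_POOL_NAMES = tuple(f.name for f in SINGLE_POOL)
_FUNCTIONS_BY_NAME = {f.name: f for f in DUAL_POOL} | {f.name: f for f in SINGLE_POOL}


def basis_function(name: str) -> BasisFunction:
    """Look up a pool function by name."""
    try:
        return _FUNCTIONS_BY_NAME[name]
    except KeyError:
        raise InvalidArgumentError(f"unknown basis function {name!r}") from None


@dataclass
class CandidatePool:
    """An ordered candidate pool evaluated on concrete activation signals.

    ``columns`` holds each candidate evaluated on the signals the pool was
    built from (the training signals); ``signals`` keeps those inputs so
    fitted models can be re-evaluated elsewhere.
    """

    functions: tuple[BasisFunction, ...]
    signals: dict[str, np.ndarray]
    kind: str  # "dual" | "single"
    columns: np.ndarray = field(init=False)  # n_functions x T

    def __post_init__(self) -> None:
        names = [f.name for f in self.functions]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("pool function names must be unique")
        if names.count("bias") != 1:
            raise InvalidArgumentError("pool must contain exactly one bias function")
        self.columns = np.vstack([f(self.signals) for f in self.functions])
        if not np.all(np.isfinite(self.columns)):
            raise InvalidArgumentError("pool evaluation produced non-finite values")

    def __len__(self) -> int:
        return len(self.functions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.functions)


def _checked_signals(**named) -> dict[str, np.ndarray]:
    out = {}
    length = None
    for name, x in named.items():
        v = signal_values(x)
        if np.any(v < 0):
            raise InvalidArgumentError(f"{name} must be nonnegative")
        if length is not None and v.size != length:
            raise InvalidArgumentError("activation signals must have equal length")
        length = v.size
        out[name] = v
    return out


def build_candidate_pool(h_bi, h_tr) -> CandidatePool:
    """Bias + 13 candidates of (H_BI, H_TR): 14 functions total."""
    signals = _checked_signals(H_BI=h_bi, H_TR=h_tr)
    return CandidatePool(DUAL_POOL, signals, kind="dual")


def build_candidate_pool_single(h) -> CandidatePool:
    """Bias + {H, H^2, H^3, sqrt(H), sigm(H)}: 6 functions total."""
    signals = _checked_signals(H=h)
    return CandidatePool(SINGLE_POOL, signals, kind="single")


@dataclass
class FosModel:
    """A fitted FOS model.

    ``selected`` is the ordered list of chosen basis functions; ``g`` are the
    orthogonal-basis coefficients, ``a`` the original-basis coefficients and
    ``alpha`` the lower-triangular Gram-Schmidt projection coefficients.
    ``training_rmsd_path`` records the normalized RMSD (percent) after each
    added function.
    """

    selected: list[BasisFunction]
    g: np.ndarray
    a: np.ndarray
    alpha: np.ndarray
    training_rmsd_path: np.ndarray
    pool_kind: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.selected)

    @property
    def n_functions(self) -> int:
        return len(self.selected)


def mse_reduction(
    candidate: np.ndarray,
    selected_orthogonal: Sequence[np.ndarray],
    residual: np.ndarray,
) -> float:
    """MSE reduction a candidate would give, after orthogonalization.

    Returns g^2 * mean(q^2) where q is the candidate orthogonalized against
    the selected orthogonal columns and g = mean(q * residual) / mean(q^2);
    returns 0 when the orthogonalized power falls below the collinearity
    tolerance.
    """
    p = np.asarray(candidate, dtype=float)
    q = p.copy()
    for qr in selected_orthogonal:
        q = q - (np.mean(q * qr) / np.mean(qr * qr)) * qr
    p_power = np.mean(p * p)
    q_power = np.mean(q * q)
    if p_power <= 0 or q_power < COLLINEARITY_RTOL * p_power:
        return 0.0
    g = np.mean(q * residual) / q_power
    return float(g * g * q_power)


def fos_fit(
    y,
    pool: CandidatePool,
    max_functions: int = DEFAULT_MAX_FUNCTIONS,
    rmsd_reduction_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> FosModel:
    """Greedy FOS fit of y on the candidate pool.

    Parameters
    ----------
    y
        Measured output, on the normalized (max = 1) scale so the RMSD path
        and threshold are in percent of full scale.
    pool
        Candidate pool evaluated on the training activation signals.
    max_functions
        Upper bound M on the number of selected functions.
    rmsd_reduction_threshold
        Stop when the best remaining candidate would lower the normalized
        RMSD by less than this many percentage points.
    """
    yv = np.asarray(signal_values(y), dtype=float)
    if len(pool) == 0:
        raise InvalidArgumentError("candidate pool is empty")
    if yv.size != pool.columns.shape[1]:
        raise InvalidArgumentError("y length does not match pool columns")
    if not np.all(np.isfinite(yv)):
        raise InvalidArgumentError("y contains non-finite values")
    if max_functions < 1:
        raise InvalidArgumentError("max_functions must be at least 1")
    max_functions = min(max_functions, len(pool))

    T = yv.size
    cols = pool.columns
    p_power = np.mean(cols * cols, axis=1)

    selected: list[int] = []
    Q: list[np.ndarray] = []          # orthogonalized selected columns
    alpha_rows: list[np.ndarray] = [] # alpha[m][r] = proj of p_m on q_r
    g_list: list[float] = []
    rmsd_path: list[float] = []
    fitted = np.zeros(T)
    mse = float(np.mean(yv * yv))
    terminated = "max_functions"

    while len(selected) < max_functions:
        residual = yv - fitted
        best_j = -1
        best_red = -np.inf
        for j in range(len(pool)):
            if j in selected:
                continue
            # modified Gram-Schmidt; with Q orthogonal the recorded
            # coefficients equal projections of the original column
            q = cols[j].copy()
            coeffs = np.empty(len(Q))
            for r, qr in enumerate(Q):
                coeffs[r] = np.mean(q * qr) / np.mean(qr * qr)
                q = q - coeffs[r] * qr
            q_power = np.mean(q * q)
            if p_power[j] <= 0 or q_power < COLLINEARITY_RTOL * p_power[j]:
                continue
            g = np.mean(q * residual) / q_power
            red = g * g * q_power
            if red > best_red:
                best_red = red
                best_j = j
                best_q, best_coeffs, best_g = q, coeffs, g

        if best_j < 0:
            terminated = "all_collinear"
            break

        new_mse = max(mse - best_red, 0.0)
        rmsd_before = np.sqrt(mse) * 100.0
        rmsd_after = np.sqrt(new_mse) * 100.0
        if rmsd_before - rmsd_after < rmsd_reduction_threshold:
            terminated = "threshold"
            break

        selected.append(best_j)
        Q.append(best_q)
        alpha_rows.append(best_coeffs)
        g_list.append(best_g)
        fitted = fitted + best_g * best_q
        mse = float(np.mean((yv - fitted) ** 2))
        rmsd_path.append(np.sqrt(mse) * 100.0)

    if not selected:
        raise InvalidArgumentError(
            "no candidate passes the selection criteria (threshold too high "
            "or pool collinear with zero)"
        )

    M = len(selected)
    alpha = np.zeros((M, M))
    for i, row in enumerate(alpha_rows):
        alpha[i, : row.size] = row
    g = np.asarray(g_list)

    # back-substitution to original-basis coefficients
    a = np.empty(M)
    for m in range(M):
        v = np.zeros(M)
        v[m] = 1.0
        for i in range(m + 1, M):
            v[i] = -np.dot(alpha[i, m:i], v[m:i])
        a[m] = np.dot(g[m:], v[m:])

    return FosModel(
        selected=[pool.functions[j] for j in selected],
        g=g,
        a=a,
        alpha=alpha,
        training_rmsd_path=np.asarray(rmsd_path),
        pool_kind=pool.kind,
        diagnostics={
            "terminated": terminated,
            "selected_indices": list(selected),
            "final_training_mse": mse,
        },
    )


def _predict_signals(model: FosModel, h_bi, h_tr=None) -> dict[str, np.ndarray]:
    if model.pool_kind == "single":
        return _checked_signals(H=h_bi)
    if h_tr is None:
        raise InvalidArgumentError("dual-pool model needs both H_BI and H_TR")
    return _checked_signals(H_BI=h_bi, H_TR=h_tr)


def fos_predict(model: FosModel, h_bi, h_tr=None) -> np.ndarray:
    """Evaluate the fitted model on activation signals.

    For a single-grid model pass the lone activation signal as the first
    argument.
    """
    if model.n_functions == 0:
        raise RuntimeError("model has no selected functions")
    signals = _predict_signals(model, h_bi, h_tr)
    out = np.zeros(next(iter(signals.values())).size)
    for coeff, func in zip(model.a, model.selected):
        out += coeff * func(signals)
    return out
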