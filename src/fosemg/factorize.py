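"""Factorization of HD-SEMG into activation patterns and curves.

All three methods approximate the channels x samples matrix S by a product
W H of a spatial pattern matrix (channels x n) and temporal activation
curves (n x samples):

* PCA operates on the raw signals; patterns are the leading eigenvectors of
  the channel covariance and curves are the rectified, low-pass-filtered
  principal-component scores.
* ICA (FastICA, negentropy contrast) also operates on the raw signals after
  whitening to n components; curves are envelopes of the estimated sources
  and patterns are the mixing-matrix columns.
* NMF operates on the nonnegative envelope matrix and factorizes it under
  nonnegativity constraints with Lee-Seung multiplicative updates for the
  squared Euclidean objective.

The per-muscle activation signal fed to the force model is the unweighted
sum of a decomposition's curves, max-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

from .core import (
    ActivationSignal,
    ConvergenceError,
    EnvelopeMatrix,
    InvalidArgumentError,
    SignalMatrix,
)
from .preprocess import envelope, lowpass_envelope, normalize_to_max

#: Component counts matching upper-arm anatomy: the biceps brachii has two
#: heads, the triceps brachii three.
DEFAULT_N_COMPONENTS = {"agonist": 2, "antagonist": 3}

NMF_DEFAULT_MAX_ITER = 2000
NMF_DEFAULT_TOL = 1e-6


@dataclass
class Decomposition:
    """Paired activation patterns (W) and activation curves (H)."""

    patterns: np.ndarray  # channels x n
    curves: np.ndarray  # n x samples, nonnegative
    method: str  # "pca" | "ica" | "nmf"
    n_components: int
    muscle_label: str = "agonist"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.patterns.shape[1] != self.n_components:
            raise InvalidArgumentError("patterns must have n_components columns")
        if self.curves.shape[0] != self.n_components:
            raise InvalidArgumentError("curves must have n_components rows")
        if np.any(self.curves < -1e-12):
            raise InvalidArgumentError("activation curves must be nonnegative")
        self.curves = np.clip(self.curves, 0.0, None)
        if self.method == "nmf" and np.any(self.patterns < 0):
            raise InvalidArgumentError("NMF patterns must be nonnegative")


def _orient_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude weight is positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def decompose_pca(s: SignalMatrix, n_components: int) -> Decomposition:
    """PCA of the raw signal matrix.

    Patterns are the unit-norm eigenvectors of the channel covariance in
    decreasing eigenvalue order; curves are the rectified, low-pass
    filtered score time series. Channels are mean-centered before
    projection.
    """
    if not (1 <= n_components <= s.n_channels):
        raise InvalidArgumentError("n_components must be in [1, channels]")
    centered = s.data - s.data.mean(axis=1, keepdims=True)
    cov = (centered @ centered.T) / centered.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:n_components]
    patterns = _orient_sign(eigvecs[:, order])
    scores = patterns.T @ centered
    curves = np.clip(lowpass_envelope(np.abs(scores), s.sampling_rate), 0.0, None)
    return Decomposition(
        patterns, curves, "pca", n_components, s.muscle_label,
        diagnostics={"explained_variance": eigvals[order].tolist()},
    )


def decompose_ica(
    s: SignalMatrix,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> Decomposition:
    """FastICA of the raw signal matrix.

    The data are whitened to ``n_components`` dimensions; FastICA with the
    log-cosh negentropy contrast and symmetric decorrelation estimates the
    unmixing. Patterns are the mixing-matrix columns; curves are rectified,
    low-pass-filtered source envelopes. Raises :class:`ConvergenceError` if
    the fixed-point iteration does not converge within ``max_iter``.
    """
    if not (1 <= n_components <= s.n_channels):
        raise InvalidArgumentError("n_components must be in [1, channels]")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        whiten="unit-variance",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            sources = ica.fit_transform(s.data.T).T  # n x samples
        except ConvergenceWarning as w:
            raise ConvergenceError(f"FastICA did not converge: {w}", max_iter) from None
    patterns = ica.mixing_
    curves = np.clip(lowpass_envelope(np.abs(sources), s.sampling_rate), 0.0, None)
    return Decomposition(
        patterns, curves, "ica", n_components, s.muscle_label,
        diagnostics={"n_iter": int(ica.n_iter_)},
    )


def nmf_multiplicative(
    E: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = NMF_DEFAULT_MAX_ITER,
    tol: float = NMF_DEFAULT_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lee-Seung multiplicative updates for ``min ||E - W H||_F^2``.

    W and H are initialized from a seeded uniform distribution scaled to the
    data magnitude. Each sweep updates H then W; the Frobenius objective is
    non-increasing across sweeps and the iteration stops when the relative
    improvement drops below ``tol`` or after ``max_iter`` sweeps. Returns
    ``(W, H, errors)`` with one Frobenius error per sweep.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise InvalidArgumentError("NMF input must be nonnegative")
    m, t = E.shape
    if not (1 <= n_components <= min(m, t)):
        raise InvalidArgumentError("n_components must be in [1, min(channels, samples)]")
    rng = np.random.default_rng(int(seed))
    scale = np.sqrt(max(E.mean(), np.finfo(float).tiny) / n_components)
    W = rng.uniform(size=(m, n_components)) * scale
    H = rng.uniform(size=(n_components, t)) * scale
    eps = 1e-12
    errors = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ E) / (W.T @ W @ H + eps)
        W *= (E @ H.T) / (W @ (H @ H.T) + eps)
        err = float(np.linalg.norm(E - W @ H))
        errors.append(err)
        if prev is not None and prev - err <= tol * max(prev, eps):
            break
        prev = err
    return W, H, np.asarray(errors)


def decompose_nmf(
    e: EnvelopeMatrix,
    n_components: int,
    seed: int = 0,
    max_iter: int = NMF_DEFAULT_MAX_ITER,
    tol: float = NMF_DEFAULT_TOL,
    muscle_label: str = "agonist",
) -> Decomposition:
    """NMF of the envelope matrix by multiplicative updates.

    The scale indeterminacy between W and H is fixed by normalizing each
    pattern column to unit maximum and rescaling the matching curve, so
    curve amplitudes are comparable across components.
    """
    W, H, errors = nmf_multiplicative(e.data, n_components, seed, max_iter, tol)
    peaks = W.max(axis=0)
    peaks[peaks <= 0] = 1.0
    W = W / peaks
    H = H * peaks[:, None]
    return Decomposition(
        W, H, "nmf", n_components, muscle_label,
        diagnostics={
            "n_iter": int(errors.size),
            "reconstruction_errors": errors,
            "final_error": float(errors[-1]),
        },
    )


def activation_signal(d: Decomposition) -> ActivationSignal:
    """Per-muscle activation signal: max-normalized unweighted curve sum."""
    if d.curves.shape[0] < 1:
        raise InvalidArgumentError("decomposition has no curves")
    total = d.curves.sum(axis=0)
    if total.max() <= 0:
        raise InvalidArgumentError("all curves are zero; normalization undefined")
    return ActivationSignal(normalize_to_max(total), d.muscle_label, d.method)


def extract_activation(
    s: SignalMatrix,
    method: str,
    n_components: int | None = None,
    seed: int = 0,
) -> ActivationSignal:
    """End-to-end activation extraction for one grid by any method.

    ``method`` is one of ``avg`` (channel-envelope average), ``pca``,
    ``ica`` or ``nmf``. The component count defaults to 2 for the agonist
    and 3 for the antagonist.
    """
    from .preprocess import avg_envelope

    method = method.lower()
    if n_components is None:
        n_components = DEFAULT_N_COMPONENTS.get(s.muscle_label, 2)
    if method == "avg":
        sig = avg_envelope(s)
        return ActivationSignal(normalize_to_max(sig.values), s.muscle_label, "avg")
    if method == "pca":
        d = decompose_pca(s, n_components)
    elif method == "ica":
        d = decompose_ica(s, n_components, seed)
    elif method == "nmf":
        d = decompose_nmf(envelope(s), n_components, seed, muscle_label=s.muscle_label)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return activation_signal(d)
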