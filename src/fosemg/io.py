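"""CSV/JSON persistence and the end-to-end pipeline runner.

Signal matrices travel as plain CSV (rows = channels, columns = samples)
with an optional JSON sidecar (``<name>.meta.json``) carrying the sampling
rate, grid geometry and muscle label; fitted models are serialized to a
versioned JSON schema. Everything is human-inspectable text.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GridSpec, InvalidArgumentError, SignalMatrix
from .fos import FosModel, basis_function

logger = logging.getLogger("fosemg")

MODEL_SCHEMA = "fosemg-model/1"


class ParseError(ValueError):
    """A file could not be parsed; the message locates the offending cell."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_signal_csv(s: SignalMatrix, path) -> None:
    path = Path(path)
    np.savetxt(path, s.data, delimiter=",", fmt="%.12g")
    meta = {
        "sampling_rate": s.sampling_rate,
        "n_rows": s.grid.n_rows,
        "n_cols": s.grid.n_cols,
        "inter_electrode_distance_mm": s.grid.inter_electrode_distance_mm,
        "muscle_label": s.muscle_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_signal_csv(
    path,
    sampling_rate: float = 1000.0,
    grid: GridSpec | None = None,
    muscle_label: str = "agonist",
) -> SignalMatrix:
    """Read a channels x samples CSV, taking metadata from the sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.strip().split(",")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ParseError(f"{path}: row {i} has {len(cells)} cells, expected {width}")
            row = []
            for j, cell in enumerate(cells):
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}") from None
                if not np.isfinite(v):
                    raise ParseError(f"{path}: non-finite cell at row {i}, column {j}: {cell!r}")
                row.append(v)
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty file")
    data = np.asarray(rows)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sampling_rate = meta.get("sampling_rate", sampling_rate)
        grid = GridSpec(
            meta.get("n_rows", 4),
            meta.get("n_cols", 8),
            meta.get("inter_electrode_distance_mm", 10.0),
        )
        muscle_label = meta.get("muscle_label", muscle_label)
    if grid is None:
        if data.shape[0] == 32:
            grid = GridSpec()
        else:
            raise ParseError(f"{path}: {data.shape[0]} channels; supply a grid spec")
    return SignalMatrix(data, sampling_rate, grid, muscle_label)


def write_series_csv(values, path) -> None:
    np.savetxt(Path(path), np.asarray(values, dtype=float).ravel(), fmt="%.12g")


def read_series_csv(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    values = np.loadtxt(path, ndmin=1)
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: contains non-finite values")
    return values.ravel()


def write_model_json(model: FosModel, path) -> None:
    payload = {
        "schema": MODEL_SCHEMA,
        "pool_kind": model.pool_kind,
        "names": list(model.names),
        "a": model.a.tolist(),
        "g": model.g.tolist(),
        "alpha": model.alpha.tolist(),
        "training_rmsd_path": model.training_rmsd_path.tolist(),
        "diagnostics": {
            k: v for k, v in model.diagnostics.items() if isinstance(v, (int, float, str, list))
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path) -> FosModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: cannot parse model JSON: {exc}") from None
    schema = payload.get("schema")
    if schema != MODEL_SCHEMA:
        raise ParseError(f"{path}: unsupported model schema {schema!r}, expected {MODEL_SCHEMA!r}")
    return FosModel(
        selected=[basis_function(n) for n in payload["names"]],
        g=np.asarray(payload["g"], dtype=float),
        a=np.asarray(payload["a"], dtype=float),
        alpha=np.asarray(payload["alpha"], dtype=float),
        training_rmsd_path=np.asarray(payload["training_rmsd_path"], dtype=float),
        pool_kind=payload["pool_kind"],
        diagnostics=dict(payload.get("diagnostics", {})),
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly via JSON."""

    method: str = "nmf"
    sampling_rate: float = 1000.0
    envelope_cutoff: float = 5.0
    envelope_order: int = 50
    n_components_agonist: int = 2
    n_components_antagonist: int = 3
    max_functions: int = 7
    rmsd_reduction_threshold: float = 0.2
    target_level: float = 0.4
    n_repetitions: int = 7
    seed: int = 0
    out_dir: str = "fosemg_out"

    def __post_init__(self) -> None:
        if self.method not in ("avg", "pca", "ica", "nmf"):
            raise InvalidArgumentError(f"unknown method {self.method!r}")
        for name in (
            "sampling_rate", "envelope_cutoff", "envelope_order",
            "n_components_agonist", "n_components_antagonist",
            "max_functions", "rmsd_reduction_threshold",
            "target_level", "n_repetitions",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        params = asdict(self)
        params.pop("out_dir")
        blob = json.dumps(params, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig):
    """Simulate, decompose, fit and cross-validate end to end.

    Writes per-fold metrics, the per-method summary row, and the config
    (with its hash) under ``config.out_dir``; returns the CrossvalResult.
    Deterministic given the config.
    """
    from .core import ProtocolSpec
    from .evaluate import TrialSet, crossval
    from .factorize import extract_activation
    from .preprocess import normalize_to_max
    from .synth import _child_seeds, simulate_study

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: method=%s seed=%d hash=%s", config.method, config.seed, config.config_hash)

    protocol = ProtocolSpec(
        sampling_rate=config.sampling_rate,
        target_level=config.target_level,
        n_repetitions=config.n_repetitions,
    )
    session = simulate_study(protocol=protocol, seed=config.seed)
    ex_seeds = _child_seeds(config.seed + 1, len(session.repetitions))
    reps = []
    for rep, s in zip(session.repetitions, ex_seeds):
        h_bi = extract_activation(
            rep.agonist, config.method, config.n_components_agonist, seed=s
        )
        h_tr = extract_activation(
            rep.antagonist, config.method, config.n_components_antagonist, seed=s
        )
        reps.append((h_bi.values, h_tr.values, normalize_to_max(rep.force)))
    trials = TrialSet(reps, level=config.target_level, method_label=config.method)
    result = crossval(trials, config.max_functions, config.rmsd_reduction_threshold)

    records = result.records.copy()
    records.insert(0, "config_hash", config.config_hash)
    records.to_csv(out / "folds.csv", index=False, float_format="%.10g")
    summary = pd.DataFrame(
        [
            dict(
                config_hash=config.config_hash,
                method=config.method,
                level=config.target_level,
                rmsd_mean=result.rmsd_mean,
                rmsd_sd=result.rmsd_sd,
                r2_mean=result.r2_mean,
                r2_sd=result.r2_sd,
            )
        ]
    )
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    (out / "config.json").write_text(config.to_json())
    logger.info("pipeline done: RMSD %.3f +/- %.3f %%", result.rmsd_mean, result.rmsd_sd)
    return result
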