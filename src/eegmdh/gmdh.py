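"""Self-organizing GMDH polynomial network for multiclass EEG decoding.

The network is built layer by layer from two-input quadratic units
(Ivakhnenko polynomials)

    y = b0 + b1·x1 + b2·x2 + b3·x1² + b4·x2² + b5·x1·x2

Each hidden layer fits one candidate neuron per unordered pair of the previous
layer's outputs by ordinary least squares on an internal fit split, scores
every candidate with the classical GMDH regularity criterion (mean squared
error on an internal validation split), and retains the best ``width``
candidates of the layer schedule.  The default decremental schedule is
40-38-27-22-16-10-8-5; the final output is the best last-layer neuron,
selected rather than refitted, so the parameter accounting of the realized
architecture is exactly 6 coefficients per retained neuron.

Class labels enter as a numeric regression target.  The default ``ordinal``
encoding regresses directly on the 1..K class code and decodes by
round-and-clamp — the single-output reading of the architecture.  A
``one_vs_rest`` mode trains K parallel networks on 0/1 targets and decodes by
argmax, for users who reject the induced ordinal structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCHEDULE",
    "PolynomialNeuron",
    "FitConfig",
    "Standardizer",
    "GMDHNetwork",
    "GMDHModel",
    "neuron_forward",
    "fit_neuron",
    "score_neuron",
    "build_layer",
    "fit_gmdh",
    "predict",
    "decision_values",
    "save_model",
    "load_model",
    "validate_model",
]

#: The reference decremental layer schedule (8 hidden layers, 166 neurons).
DEFAULT_SCHEDULE: tuple[int, ...] = (40, 38, 27, 22, 16, 10, 8, 5)

MODEL_FORMAT_VERSION = 1


@dataclass
class PolynomialNeuron:
    """A two-input quadratic unit with six coefficients.

    ``input_a`` / ``input_b`` index the previous layer's outputs (or the
    standardized input features for layer 1), with input_a < input_b.
    ``criterion_score`` is the external-criterion value recorded at selection.
    """

    input_a: int
    input_b: int
    coefficients: np.ndarray
    criterion_score: float = float("nan")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (6,):
            raise ValueError("a polynomial neuron has exactly 6 coefficients")
        if self.input_a == self.input_b:
            raise ValueError("neuron inputs must be distinct")


def _design(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Design matrix [1, x1, x2, x1², x2², x1·x2] for the quadratic unit."""
    return np.column_stack([
        np.ones_like(x1), x1, x2, x1 * x1, x2 * x2, x1 * x2,
    ])


def neuron_forward(neuron: PolynomialNeuron, x1, x2):
    """Evaluate b0 + b1·x1 + b2·x2 + b3·x1² + b4·x2² + b5·x1·x2."""
    b = neuron.coefficients
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    out = b[0] + b[1] * x1 + b[2] * x2 + b[3] * x1 * x1 + b[4] * x2 * x2 + b[5] * x1 * x2
    return out if out.ndim else float(out)


def fit_neuron(x1, x2, target) -> np.ndarray:
    """Least-squares coefficients (b0..b5) for one candidate unit.

    Uses the minimum-norm solution, so rank-deficient designs (constant or
    duplicated inputs) are handled without error.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if not (x1.shape == x2.shape == target.shape) or x1.ndim != 1 or x1.size < 1:
        raise ValueError("x1, x2 and target must be equal-length 1-D columns")
    coeffs, *_ = np.linalg.lstsq(_design(x1, x2), target, rcond=None)
    return coeffs


def score_neuron(neuron: PolynomialNeuron, x1_val, x2_val, target_val) -> float:
    """External criterion: MSE of the neuron on held-out validation rows."""
    target_val = np.asarray(target_val, dtype=np.float64)
    if target_val.size == 0:
        raise ValueError("validation set must be non-empty")
    pred = neuron_forward(neuron, x1_val, x2_val)
    return float(np.mean((pred - target_val) ** 2))


def _candidate_pairs(n_cols: int, max_candidate_pairs: int | None,
                     rng: np.random.Generator) -> np.ndarray:
    pairs = np.array(list(combinations(range(n_cols), 2)), dtype=np.int64)
    if max_candidate_pairs is not None and len(pairs) > max_candidate_pairs:
        keep = rng.choice(len(pairs), size=max_candidate_pairs, replace=False)
        pairs = pairs[np.sort(keep)]  # keep lexicographic pair order
    return pairs


def _fit_candidates(X: np.ndarray, Xv: np.ndarray, y: np.ndarray, yv: np.ndarray,
                    pairs: np.ndarray, chunk: int = 2048
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Batched least squares + validation MSE for every candidate pair.

    Solves the 6×6 normal equations per pair in chunks; pairs whose normal
    equations are singular or blow up fall back to the minimum-norm
    per-pair solve of :func:`fit_neuron`.
    """
    n_pairs = len(pairs)
    coeffs = np.empty((n_pairs, 6))
    scores = np.empty(n_pairs)
    for start in range(0, n_pairs, chunk):
        sl = slice(start, min(start + chunk, n_pairs))
        a, b = pairs[sl, 0], pairs[sl, 1]
        x1, x2 = X[:, a].T, X[:, b].T            # (P, n)
        D = np.stack([np.ones_like(x1), x1, x2, x1 * x1, x2 * x2, x1 * x2], axis=2)
        A = np.einsum("pnd,pne->pde", D, D)
        rhs = np.einsum("pnd,n->pd", D, y)
        try:
            sol = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.full((len(a), 6), np.nan)
            for i in range(len(a)):
                try:
                    sol[i] = np.linalg.solve(A[i], rhs[i])
                except np.linalg.LinAlgError:
                    pass
        bad = ~np.isfinite(sol).all(axis=1)
        for i in np.flatnonzero(bad):
            sol[i] = fit_neuron(X[:, a[i]], X[:, b[i]], y)
        coeffs[sl] = sol
        v1, v2 = Xv[:, a].T, Xv[:, b].T
        pred = (sol[:, 0:1] + sol[:, 1:2] * v1 + sol[:, 2:3] * v2
                + sol[:, 3:4] * v1 * v1 + sol[:, 4:5] * v2 * v2 + sol[:, 5:6] * v1 * v2)
        scores[sl] = np.mean((pred - yv) ** 2, axis=1)
    return coeffs, scores


def build_layer(prev_outputs: np.ndarray, prev_outputs_val: np.ndarray,
                target: np.ndarray, target_val: np.ndarray, width: int,
                max_candidate_pairs: int | None = None,
                seed: int = 0) -> list[PolynomialNeuron]:
    """Fit and select one hidden layer.

    Fits one candidate per unordered column pair (a seeded subsample when the
    pair count exceeds ``max_candidate_pairs``), scores each on the validation
    rows, and returns the min(width, n_candidates) best by ascending
    criterion; ties break on (input_a, input_b) lexicographic order.
    """
    X = np.asarray(prev_outputs, dtype=np.float64)
    Xv = np.asarray(prev_outputs_val, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 input columns to form pairs")
    if width < 1:
        raise ValueError("layer width must be >= 1")
    y = np.asarray(target, dtype=np.float64)
    yv = np.asarray(target_val, dtype=np.float64)
    if yv.size == 0:
        raise ValueError("validation set must be non-empty")

    rng = np.random.default_rng(seed)
    pairs = _candidate_pairs(X.shape[1], max_candidate_pairs, rng)
    coeffs, scores = _fit_candidates(X, Xv, y, yv, pairs)

    order = np.lexsort((pairs[:, 1], pairs[:, 0], scores))
    keep = order[: min(width, len(pairs))]
    return [
        PolynomialNeuron(int(pairs[i, 0]), int(pairs[i, 1]), coeffs[i], float(scores[i]))
        for i in keep
    ]


@dataclass
class FitConfig:
    """Training-time knobs for :func:`fit_gmdh`."""

    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    internal_split_fraction: float = 0.25
    max_candidate_pairs: int | None = None
    seed: int = 0
    encoding_mode: str = "ordinal"

    def __post_init__(self) -> None:
        self.schedule = tuple(int(w) for w in self.schedule)
        if not 0 < self.internal_split_fraction < 1:
            raise ValueError("internal_split_fraction must be in (0, 1)")
        if self.encoding_mode not in ("ordinal", "one_vs_rest"):
            raise ValueError("encoding_mode must be 'ordinal' or 'one_vs_rest'")


@dataclass
class Standardizer:
    """Per-feature z-score state fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)  # constant features pass through
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class GMDHNetwork:
    """One single-output stack of selected layers."""

    layers: list[list[PolynomialNeuron]]
    output_selector: int

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = np.column_stack([
                neuron_forward(nrn, out[:, nrn.input_a], out[:, nrn.input_b])
                for nrn in layer
            ])
        return out[:, self.output_selector]


@dataclass
class GMDHModel:
    """A fitted model: network(s) + standardization and label-coding state."""

    networks: list[GMDHNetwork]
    standardizer: Standardizer
    n_classes: int
    encoding_mode: str
    schedule: tuple[int, ...]
    n_features: int
    version: int = MODEL_FORMAT_VERSION

    @property
    def layers(self) -> list[list[PolynomialNeuron]]:
        """Layers of the (single) network in ordinal mode."""
        return self.networks[0].layers

    @property
    def output_selector(self) -> int:
        return self.networks[0].output_selector

    def realized_widths(self) -> list[int]:
        """Retained neurons per layer, summed across parallel networks."""
        depth = max(len(net.layers) for net in self.networks)
        widths = [0] * depth
        for net in self.networks:
            for li, layer in enumerate(net.layers):
                widths[li] += len(layer)
        return widths


def _fit_network(Xf: np.ndarray, Xv: np.ndarray, y: np.ndarray, yv: np.ndarray,
                 config: FitConfig, seed: int) -> GMDHNetwork:
    layers: list[list[PolynomialNeuron]] = []
    out_f, out_v = Xf, Xv
    for li, width in enumerate(config.schedule):
        if out_f.shape[1] < 2:
            logger.warning("layer %d: only %d input column(s); stopping early",
                           li + 1, out_f.shape[1])
            break
        layer = build_layer(out_f, out_v, y, yv, width,
                            max_candidate_pairs=config.max_candidate_pairs,
                            seed=seed + li)
        if len(layer) < width:
            logger.info("layer %d: realized width %d below nominal %d",
                        li + 1, len(layer), width)
        layers.append(layer)
        out_f = np.column_stack([
            neuron_forward(nrn, out_f[:, nrn.input_a], out_f[:, nrn.input_b])
            for nrn in layer
        ])
        out_v = np.column_stack([
            neuron_forward(nrn, out_v[:, nrn.input_a], out_v[:, nrn.input_b])
            for nrn in layer
        ])
        logger.debug("layer %d: best criterion %.6g", li + 1, layer[0].criterion_score)
    if not layers:
        raise ValueError("could not build any layer (too few input columns)")
    # output = best last-layer neuron, selected not refitted; layers are
    # sorted by ascending criterion so the selector is index 0
    return GMDHNetwork(layers, output_selector=0)


def fit_gmdh(features: np.ndarray, labels: Sequence[int],
             config: FitConfig | None = None) -> GMDHModel:
    """Train the self-organizing network on (features, 1-based class codes).

    Training rows are standardized (z-score) and split by seeded shuffle into
    a fit part and an internal validation part; layers are grown per the
    schedule, each consuming only the previous layer's outputs.
    """
    config = config or FitConfig()
    X = np.asarray(features, dtype=np.float64)
    codes = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != codes.size:
        raise ValueError("features must be 2-D with one label per row")
    if X.shape[0] < 12:
        raise ValueError("need at least 12 training rows")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    if len(config.schedule) == 0:
        raise ValueError("layer schedule must be non-empty")
    classes = np.unique(codes)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    n_classes = int(codes.max())

    standardizer = Standardizer.fit(X)
    Xs = standardizer.transform(X)

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(config.internal_split_fraction * X.shape[0])))
    n_val = min(n_val, X.shape[0] - 6)  # keep enough rows for 6-coefficient fits
    val_idx, fit_idx = perm[:n_val], perm[n_val:]

    if config.encoding_mode == "ordinal":
        target = codes.astype(np.float64)
        networks = [_fit_network(Xs[fit_idx], Xs[val_idx], target[fit_idx],
                                 target[val_idx], config, seed=config.seed)]
    else:
        networks = []
        for k in range(1, n_classes + 1):
            target = (codes == k).astype(np.float64)
            networks.append(
                _fit_network(Xs[fit_idx], Xs[val_idx], target[fit_idx],
                             target[val_idx], config, seed=config.seed + 1000 * k)
            )
    model = GMDHModel(networks, standardizer, n_classes, config.encoding_mode,
                      config.schedule, n_features=X.shape[1])
    validate_model(model)
    return model


def decision_values(model: GMDHModel, features: np.ndarray) -> np.ndarray:
    """Raw network output(s): (n,) in ordinal mode, (n, K) in one-vs-rest."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got "
                         f"{X.shape[1] if X.ndim == 2 else 'non-2-D input'}")
    Xs = model.standardizer.transform(X)
    outs = [net.forward(Xs) for net in model.networks]
    return outs[0] if model.encoding_mode == "ordinal" else np.column_stack(outs)


def predict(model: GMDHModel, features: np.ndarray) -> np.ndarray:
    """Predicted 1-based class codes (deterministic)."""
    values = decision_values(model, features)
    if model.encoding_mode == "ordinal":
        return np.clip(np.rint(values), 1, model.n_classes).astype(np.int64)
    return np.argmax(values, axis=1).astype(np.int64) + 1


def validate_model(model: GMDHModel) -> None:
    """Structural checks: widths within schedule, indices valid, 6 coeffs."""
    for net in model.networks:
        prev_width = model.n_features
        for li, layer in enumerate(net.layers):
            if not 1 <= len(layer) <= model.schedule[li]:
                raise ValueError(f"layer {li + 1} width {len(layer)} violates "
                                 f"schedule cap {model.schedule[li]}")
            for nrn in layer:
                if not (0 <= nrn.input_a < nrn.input_b < prev_width):
                    raise ValueError(
                        f"layer {li + 1}: invalid input indices "
                        f"({nrn.input_a}, {nrn.input_b}) for width {prev_width}")
                if nrn.coefficients.shape != (6,):
                    raise ValueError("neuron does not have 6 coefficients")
            prev_width = len(layer)
        if not 0 <= net.output_selector < len(net.layers[-1]):
            raise ValueError("output selector outside the final layer")


def save_model(model: GMDHModel, path: str | Path) -> None:
    """Serialize the model as a versioned JSON document."""
    doc = {
        "version": model.version,
        "schedule": list(model.schedule),
        "encoding_mode": model.encoding_mode,
        "n_classes": model.n_classes,
        "n_features": model.n_features,
        "standardizer": {
            "mean": model.standardizer.mean.tolist(),
            "scale": model.standardizer.scale.tolist(),
        },
        "networks": [
            {
                "output_selector": net.output_selector,
                "layers": [
                    [
                        {"a": nrn.input_a, "b": nrn.input_b,
                         "coeffs": nrn.coefficients.tolist(),
                         "score": nrn.criterion_score}
                        for nrn in layer
                    ]
                    for layer in net.layers
                ],
            }
            for net in model.networks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> GMDHModel:
    """Load and structurally validate a saved model."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from None
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('version')!r}")
    networks = [
        GMDHNetwork(
            layers=[
                [PolynomialNeuron(n["a"], n["b"], np.array(n["coeffs"]), n["score"])
                 for n in layer]
                for layer in net["layers"]
            ],
            output_selector=net["output_selector"],
        )
        for net in doc["networks"]
    ]
    model = GMDHModel(
        networks=networks,
        standardizer=Standardizer(np.array(doc["standardizer"]["mean"]),
                                  np.array(doc["standardizer"]["scale"])),
        n_classes=doc["n_classes"],
        encoding_mode=doc["encoding_mode"],
        schedule=tuple(doc["schedule"]),
        n_features=doc["n_features"],
        version=doc["version"],
    )
    validate_model(model)
    return model
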