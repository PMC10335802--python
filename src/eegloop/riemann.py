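"""Covariance features and SPD-manifold classification.

Epoch covariances are treated as points on the manifold of symmetric
positive-definite (SPD) matrices under the affine-invariant Riemannian
metric (AIRM), with the log-Euclidean metric as an option.  Classification
is minimum distance to mean: one Fréchet (geometric) mean per class,
prediction by nearest mean.

SPD matrices are plain float64 ndarrays; :func:`validate_spd` enforces the
symmetry and positivity invariants at API boundaries.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .errors import (
    ConvergenceError,
    FormatError,
    InvalidArgumentError,
    NumericalError,
    VersionError,
)
from .preprocess import Epoch

MODEL_FORMAT_VERSION = "1"
METRICS = ("airm", "logeuclid")


# ---------------------------------------------------------------------------
# SPD primitives

def validate_spd(C: np.ndarray, sym_tol: float = 1e-10) -> np.ndarray:
    """Check symmetry and positive-definiteness; return C as float64."""
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidArgumentError(f"expected a square matrix, got shape {C.shape}")
    if np.linalg.norm(C - C.T) > sym_tol * max(1.0, np.linalg.norm(C)):
        raise InvalidArgumentError("matrix is not symmetric")
    if np.linalg.eigvalsh(C).min() <= 0:
        raise InvalidArgumentError("matrix is not positive definite")
    return C


def _eig_map(C: np.ndarray, fun) -> np.ndarray:
    w, v = eigh(C)
    return (v * fun(w)) @ v.T


def spd_sqrt(C):
    return _eig_map(C, np.sqrt)


def spd_inv_sqrt(C):
    return _eig_map(C, lambda w: 1.0 / np.sqrt(w))


def spd_log(C):
    return _eig_map(C, np.log)


def spd_exp(S):
    return _eig_map(S, np.exp)


# ---------------------------------------------------------------------------
# covariance estimation

@dataclass(frozen=True)
class CovSpec:
    """Empirical covariance with trace-normalized shrinkage toward identity:
    ``C = (1 - shrinkage) * C_emp + shrinkage * (trace(C_emp)/n) * I``."""

    estimator: str = "empirical"
    shrinkage: float = 0.05

    def __post_init__(self):
        if self.estimator != "empirical":
            raise InvalidArgumentError("only the empirical estimator is implemented")
        if not 0 <= self.shrinkage < 1:
            raise InvalidArgumentError("shrinkage must be in [0, 1)")


def epoch_covariance(epoch: Epoch, spec: CovSpec = CovSpec()) -> np.ndarray:
    """Shrunk empirical channel covariance of a (row-mean-centered) epoch."""
    X = epoch.data
    if X.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 samples per epoch")
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T / (X.shape[1] - 1)
    n = C.shape[0]
    if np.trace(C) <= 0:
        if spec.shrinkage == 0:
            raise NumericalError("zero-variance epoch gives a singular "
                                 "covariance with shrinkage=0")
        return spec.shrinkage * np.eye(n)
    if spec.shrinkage > 0:
        mu = np.trace(C) / n
        C = (1 - spec.shrinkage) * C + spec.shrinkage * mu * np.eye(n)
    return C


# ---------------------------------------------------------------------------
# metric

def airm_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance: Frobenius norm of log of the whitened ratio,
    i.e. ``sqrt(sum log^2 eigvals(A^-1 B))``."""
    A = validate_spd(A)
    B = validate_spd(B)
    if A.shape != B.shape:
        raise InvalidArgumentError("dimension mismatch")
    w = eigh(B, A, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def logeuclid_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Frobenius distance between matrix logarithms."""
    A = validate_spd(A)
    B = validate_spd(B)
    if A.shape != B.shape:
        raise InvalidArgumentError("dimension mismatch")
    return float(np.linalg.norm(spd_log(A) - spd_log(B)))


def distance(A, B, metric: str = "airm") -> float:
    if metric == "airm":
        return airm_distance(A, B)
    if metric == "logeuclid":
        return logeuclid_distance(A, B)
    raise InvalidArgumentError(f"metric must be one of {METRICS}")


def riemannian_mean(covs, tol: float = 1e-8, max_iter: int = 50,
                    metric: str = "airm") -> np.ndarray:
    """Fréchet mean of SPD matrices.

    AIRM: fixed-point iteration ``M <- M^1/2 exp(mean_i log(M^-1/2 C_i
    M^-1/2)) M^1/2`` starting from the arithmetic mean, stopping when the
    Frobenius norm of the tangent-space gradient is <= *tol*.
    Log-Euclidean: closed form ``exp(mean log C_i)``.
    """
    covs = [validate_spd(C) for C in covs]
    if not covs:
        raise InvalidArgumentError("need at least one matrix")
    if len({C.shape for C in covs}) != 1:
        raise InvalidArgumentError("matrices must share a dimension")
    if len(covs) == 1:
        return covs[0].copy()
    if metric == "logeuclid":
        return spd_exp(np.mean([spd_log(C) for C in covs], axis=0))
    if metric != "airm":
        raise InvalidArgumentError(f"metric must be one of {METRICS}")

    M = np.mean(covs, axis=0)
    grad_norm = np.inf
    for _ in range(max_iter):
        M_isqrt = spd_inv_sqrt(M)
        M_sqrt = spd_sqrt(M)
        S = np.zeros_like(M)
        for C in covs:
            W = M_isqrt @ C @ M_isqrt
            S += spd_log((W + W.T) / 2.0)
        S /= len(covs)
        grad_norm = float(np.linalg.norm(S))
        if grad_norm <= tol:
            return (M + M.T) / 2.0
        M = M_sqrt @ spd_exp(S) @ M_sqrt
        M = (M + M.T) / 2.0
    raise ConvergenceError(
        f"Riemannian mean did not converge in {max_iter} iterations",
        residual=grad_norm,
    )


# ---------------------------------------------------------------------------
# minimum-distance-to-mean classifier

@dataclass
class MDMModel:
    """One Fréchet mean per class; predicts by nearest mean."""

    class_ids: list
    means: list
    metric: str = "airm"
    cov_spec: CovSpec = field(default_factory=CovSpec)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.class_ids) != len(set(map(str, self.class_ids))):
            raise InvalidArgumentError("class ids must be unique")
        dims = {m.shape for m in self.means}
        if len(dims) != 1:
            raise InvalidArgumentError("class means must share a dimension")

    @property
    def n_channels(self) -> int:
        return self.means[0].shape[0]


def mdm_fit(epochs, spec: CovSpec = CovSpec(), metric: str = "airm",
            provenance: dict | None = None) -> MDMModel:
    """Fit class means from labeled epochs (>= 2 classes, >= 1 epoch each).

    Epoch order does not affect the result.
    """
    by_class: dict = {}
    for ep in epochs:
        if ep.label is None:
            raise InvalidArgumentError("all training epochs must carry a label")
        by_class.setdefault(ep.label, []).append(epoch_covariance(ep, spec))
    if len(by_class) < 2:
        raise InvalidArgumentError("training requires at least 2 classes")
    class_ids = sorted(by_class, key=str)
    means = [riemannian_mean(by_class[c], metric=metric) for c in class_ids]
    return MDMModel(class_ids, means, metric, spec, provenance or {})


def mdm_predict(model: MDMModel, epoch: Epoch):
    """Predict ``(class_id, scores)`` for one epoch.

    Scores are ``softmax(-distance)`` over classes (sum to 1); ties in the
    argmin are broken toward the first class id.
    """
    if epoch.n_channels != model.n_channels:
        raise InvalidArgumentError(
            f"epoch has {epoch.n_channels} channels, model expects {model.n_channels}"
        )
    C = epoch_covariance(epoch, model.cov_spec)
    dists = np.array([distance(C, m, model.metric) for m in model.means])
    predicted = model.class_ids[int(np.argmin(dists))]
    z = np.exp(-(dists - dists.min()))
    scores = z / z.sum()
    return predicted, dict(zip(model.class_ids, scores.tolist()))


def mdm_accuracy(model: MDMModel, epochs) -> float:
    """Fraction of labeled epochs predicted correctly."""
    hits = sum(1 for ep in epochs if mdm_predict(model, ep)[0] == ep.label)
    return hits / len(epochs)


# ---------------------------------------------------------------------------
# persistence

@dataclass
class ModelBundle:
    model: MDMModel
    created_at: str = ""
    digest: str = ""
    format_version: str = MODEL_FORMAT_VERSION

    def __post_init__(self):
        if not self.created_at:
            self.created_at = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if not self.digest:
            self.digest = model_digest(self.model)


def model_digest(model: MDMModel) -> str:
    """SHA-256 over the model parameters; changes iff the parameters change."""
    h = hashlib.sha256()
    h.update(json.dumps({
        "class_ids": [str(c) for c in model.class_ids],
        "metric": model.metric,
        "shrinkage": model.cov_spec.shrinkage,
    }, sort_keys=True).encode())
    for m in model.means:
        h.update(np.ascontiguousarray(m, dtype="<f8").tobytes())
    return h.hexdigest()


def save_model(bundle: ModelBundle, path) -> None:
    """Persist a bundle: ``.npz`` with the arrays and metadata plus a
    human-readable JSON sidecar at ``<path>.json``."""
    path = str(path)
    meta = {
        "format_version": bundle.format_version,
        "created_at": bundle.created_at,
        "digest": bundle.digest,
        "metric": bundle.model.metric,
        "shrinkage": bundle.model.cov_spec.shrinkage,
        "class_ids": list(bundle.model.class_ids),
        "n_channels": bundle.model.n_channels,
        "provenance": bundle.model.provenance,
    }
    with open(path, "wb") as fh:
        np.savez(fh,
                 means=np.stack(bundle.model.means),
                 meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                    dtype=np.uint8))
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_model(path) -> ModelBundle:
    """Load a bundle saved by :func:`save_model`.

    Raises :class:`FormatError` on corrupt/truncated files and
    :class:`VersionError` on a format-version mismatch; never returns a
    partially loaded model.
    """
    path = str(path)
    try:
        with np.load(path) as data:
            means = data["means"]
            meta = json.loads(bytes(data["meta"]).decode())
    except VersionError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise VersionError(
            f"model format {meta.get('format_version')!r} != {MODEL_FORMAT_VERSION!r}"
        )
    model = MDMModel(
        class_ids=meta["class_ids"],
        means=[means[i] for i in range(means.shape[0])],
        metric=meta["metric"],
        cov_spec=CovSpec(shrinkage=meta["shrinkage"]),
        provenance=meta.get("provenance", {}),
    )
    bundle = ModelBundle(model, created_at=meta["created_at"], digest=meta["digest"])
    if bundle.digest != model_digest(model):
        raise FormatError(f"model file {path} digest mismatch (corrupt?)")
    return bundle
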