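"""Unsupervised odd-one-out target detection for oddball sessions.

Epochs are grouped by stimulus class; each class gets a representative SPD
matrix (by default the covariance of the pointwise-averaged epoch, which
enhances the time-locked evoked response against non-time-locked
background).  The class whose representative is farthest from the others —
score = sum of pairwise manifold distances to the other classes — is the
candidate target; scores are normalized to per-class probabilities.

With only two classes the single pairwise distance makes both scores
equal, so the statistic is uninformative at K = 2 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .preprocess import Epoch
from .riemann import CovSpec, distance, epoch_covariance, riemannian_mean

REPRESENTATIVE_MODES = ("avg-then-cov", "cov-then-mean")

#: Epochs per class below which results are flagged low-confidence.
MIN_EPOCHS_PER_CLASS = 3


@dataclass
class ClassEnsemble:
    """All epochs recorded for one stimulus class."""

    class_id: object
    epochs: list

    def __post_init__(self):
        if not self.epochs:
            raise InvalidArgumentError("an ensemble needs at least one epoch")
        shapes = {ep.data.shape for ep in self.epochs}
        if len(shapes) != 1:
            raise InvalidArgumentError(f"epoch shapes differ within ensemble: {shapes}")


@dataclass
class OddOneOutResult:
    scores: dict
    probabilities: dict
    predicted_target: object
    n_epochs_used: dict = field(default_factory=dict)
    low_confidence: bool = False

    def __post_init__(self):
        probs = np.array(list(self.probabilities.values()))
        if probs.min() < -1e-12 or abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("probabilities must be nonnegative and sum to 1")


def class_representative(ensemble: ClassEnsemble, mode: str = "avg-then-cov",
                         spec: CovSpec = CovSpec()) -> np.ndarray:
    """Reduce an ensemble to one SPD matrix.

    ``avg-then-cov`` (default): covariance of the pointwise epoch average.
    ``cov-then-mean``: Riemannian mean of per-epoch covariances.
    Both agree on singleton ensembles.
    """
    if mode not in REPRESENTATIVE_MODES:
        raise InvalidArgumentError(f"mode must be one of {REPRESENTATIVE_MODES}")
    first = ensemble.epochs[0]
    if mode == "avg-then-cov":
        avg = np.mean([ep.data for ep in ensemble.epochs], axis=0)
        return epoch_covariance(
            Epoch(first.onset, avg, first.label, dict(first.meta)), spec
        )
    return riemannian_mean([epoch_covariance(ep, spec) for ep in ensemble.epochs])


def oddoneout_scores(reps: dict, metric: str = "airm",
                     n_epochs_used: dict | None = None,
                     low_confidence: bool = False) -> OddOneOutResult:
    """Score each class by its summed distance to the other representatives.

    ``score_k = sum_{j != k} d(C_k, C_j)``; probabilities are scores
    normalized to sum to 1 (uniform if every score is zero);
    ``predicted_target = argmax probability`` (ties toward the first class
    in *reps* order).
    """
    class_ids = list(reps)
    if len(class_ids) < 2:
        raise InvalidArgumentError("need at least 2 classes")
    dims = {np.asarray(reps[c]).shape for c in class_ids}
    if len(dims) != 1:
        raise InvalidArgumentError("representatives must share a dimension")
    k = len(class_ids)
    pairwise = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[i, j] = pairwise[j, i] = distance(
                reps[class_ids[i]], reps[class_ids[j]], metric
            )
    scores = pairwise.sum(axis=1)
    total = scores.sum()
    probs = scores / total if total > 0 else np.full(k, 1.0 / k)
    predicted = class_ids[int(np.argmax(probs))]
    return OddOneOutResult(
        scores=dict(zip(class_ids, scores.tolist())),
        probabilities=dict(zip(class_ids, probs.tolist())),
        predicted_target=predicted,
        n_epochs_used=dict(n_epochs_used or {c: 1 for c in class_ids}),
        low_confidence=low_confidence,
    )


class OddOneOutState:
    """Incremental odd-one-out scoring, equal to the batch computation.

    Re-scoring is pure in the accumulated ensembles: feeding the same
    epochs one by one or all at once yields identical probabilities.
    Classes with no epochs yet are held at the uniform prior weight
    ``1/K``; the remaining mass is split among the observed classes in
    proportion to their scores.
    """

    def __init__(self, class_ids, mode: str = "avg-then-cov",
                 spec: CovSpec = CovSpec(), metric: str = "airm",
                 min_epochs: int = MIN_EPOCHS_PER_CLASS):
        if len(class_ids) < 2:
            raise InvalidArgumentError("need at least 2 classes")
        self.class_ids = list(class_ids)
        self.mode = mode
        self.spec = spec
        self.metric = metric
        self.min_epochs = min_epochs
        self._epochs: dict = {c: [] for c in self.class_ids}

    def counts(self) -> dict:
        return {c: len(eps) for c, eps in self._epochs.items()}

    def update(self, epoch: Epoch, class_id) -> OddOneOutResult:
        if class_id not in self._epochs:
            raise InvalidArgumentError(f"unknown class id {class_id!r}")
        self._epochs[class_id].append(epoch)
        return self.result()

    def result(self) -> OddOneOutResult:
        counts = self.counts()
        low_conf = any(n < self.min_epochs for n in counts.values())
        present = [c for c in self.class_ids if counts[c] > 0]
        k = len(self.class_ids)
        if len(present) < 2:
            uniform = {c: 1.0 / k for c in self.class_ids}
            return OddOneOutResult(
                scores={c: 0.0 for c in self.class_ids},
                probabilities=uniform,
                predicted_target=self.class_ids[0],
                n_epochs_used=counts,
                low_confidence=True,
            )
        reps = {
            c: class_representative(ClassEnsemble(c, self._epochs[c]),
                                    self.mode, self.spec)
            for c in present
        }
        partial = oddoneout_scores(reps, self.metric)
        if len(present) == k:
            return OddOneOutResult(partial.scores, partial.probabilities,
                                   partial.predicted_target, counts, low_conf)
        # absent classes pinned to the uniform prior 1/K
        mass = 1.0 - (k - len(present)) / k
        probs = {c: 1.0 / k for c in self.class_ids}
        for c in present:
            probs[c] = partial.probabilities[c] * mass
        scores = {c: partial.scores.get(c, 0.0) for c in self.class_ids}
        predicted = max(self.class_ids, key=lambda c: (probs[c], -self.class_ids.index(c)))
        return OddOneOutResult(scores, probs, predicted, counts, True)


def running_update(state: OddOneOutState, new_epoch: Epoch, class_id):
    """Functional wrapper: ``(state, epoch, class) -> (state, result)``."""
    result = state.update(new_epoch, class_id)
    return state, result
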