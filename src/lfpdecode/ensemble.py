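"""Decision fusion and the two-stage rest → left/right decoder.

Each base classifier's score in [0, 1] is thresholded at 0.5 (score >= 0.5
votes 1); the three binary votes are fused by majority.  Decoding is a state
machine: stage 1 decides movement (1) vs rest (0); only on a movement
decision does stage 2 decide left (1) vs right (0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .baseclf import (FbannHyper, PnnHyper, RbfnnHyper, ZScore, fbann_train,
                      model_from_dict, pnn_train, rbfnn_train)
from .errors import ConfigurationError, ModelStateError

THRESHOLD = 0.5
N_BASE = 3  # FBANN, RBFNN, PNN

#: fixed class encodings per stage
STAGE1_ENCODING = {"movement": 1, "rest": 0}
STAGE2_ENCODING = {"left": 1, "right": 0}


def threshold_output(raw_score: float) -> int:
    """Binary vote from a base-classifier score: 1 iff score >= 0.5."""
    s = float(raw_score)
    if not math.isfinite(s) or not (0.0 <= s <= 1.0):
        raise ConfigurationError(f"threshold_output: score must be in [0, 1], got {raw_score}")
    return 1 if s >= THRESHOLD else 0


def majority_vote(votes, *, strict: bool = True) -> int:
    """Fused binary class = the one with the plurality of the T votes."""
    votes = list(votes)
    if strict and len(votes) != N_BASE:
        raise ConfigurationError(f"majority_vote expects {N_BASE} votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ConfigurationError(f"majority_vote: votes must be binary, got {votes}")
    return 1 if sum(votes) * 2 >= len(votes) + 1 else 0


@dataclass
class VoteDecision:
    """One fused decision with its provenance."""

    base_votes: tuple[int, ...]
    fused_class: int
    vote_count: int


def fuse(scores) -> VoteDecision:
    votes = tuple(threshold_output(s) for s in scores)
    fused = majority_vote(votes)
    return VoteDecision(base_votes=votes, fused_class=fused,
                        vote_count=sum(1 for v in votes if v == fused))


# ---------------------------------------------------------------------------
# trained stages and the two-stage model
# ---------------------------------------------------------------------------

BASE_NAMES = ("fbann", "rbfnn", "pnn")


@dataclass
class EnsembleStage:
    """Three trained base models plus the shared feature normalizer."""

    models: dict  # name -> trained model with .predict_score
    normalizer: ZScore

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Raw base scores, shape (N, 3), column order fbann/rbfnn/pnn."""
        Z = self.normalizer.transform(np.atleast_2d(X))
        return np.column_stack([self.models[n].predict_score(Z) for n in BASE_NAMES])

    def votes(self, X: np.ndarray) -> np.ndarray:
        S = self.scores(X)
        return np.array([[threshold_output(s) for s in row] for row in S], dtype=int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([majority_vote(row) for row in self.votes(X)], dtype=int)

    def ensemble_score(self, X: np.ndarray) -> np.ndarray:
        """Mean of the three thresholded votes, in {0, 1/3, 2/3, 1}."""
        return self.votes(X).mean(axis=1)

    def to_dict(self) -> dict:
        return {"models": {n: m.to_dict() for n, m in self.models.items()},
                "normalizer": self.normalizer.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleStage":
        return cls(models={n: model_from_dict(md) for n, md in d["models"].items()},
                   normalizer=ZScore.from_dict(d["normalizer"]))


@dataclass(frozen=True)
class StageHyper:
    fbann: FbannHyper = FbannHyper()
    rbfnn: RbfnnHyper = RbfnnHyper()
    pnn: PnnHyper = PnnHyper()


def fit_stage(X: np.ndarray, y: np.ndarray, hyper: StageHyper = StageHyper(),
              *, seed: int = 0, select_mask=None) -> EnsembleStage:
    """Train the three base classifiers on one binary problem (y in {0,1}).

    ``select_mask`` marks the original (non-augmented) samples and is
    forwarded to the PNN's sigma selection.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    norm = ZScore().fit(X)
    Z = norm.transform(X)
    import dataclasses as _dc

    fb = fbann_train(Z, y, _dc.replace(hyper.fbann, seed=seed))
    n_centers = min(hyper.rbfnn.n_centers, max(2, len(Z) - 1))
    rb = rbfnn_train(Z, y, _dc.replace(hyper.rbfnn, seed=seed, n_centers=n_centers))
    # PNN: fit on original samples, rebalance through equal Bayes priors
    classes = sorted(np.unique(y).tolist())
    priors = np.array([(y == c).mean() for c in classes])
    pn = pnn_train(Z, y, _dc.replace(hyper.pnn, seed=seed),
                   select_mask=select_mask, priors=priors)
    return EnsembleStage(models={"fbann": fb, "rbfnn": rb, "pnn": pn}, normalizer=norm)


@dataclass
class EnsembleModel:
    """Stage-1 (movement vs rest) and stage-2 (left vs right) ensembles."""

    stage1: EnsembleStage | None = None
    stage2: EnsembleStage | None = None

    def require_trained(self):
        if self.stage1 is None or self.stage2 is None:
            raise ModelStateError("EnsembleModel: both stages must be trained")

    def to_dict(self) -> dict:
        self.require_trained()
        return {"stage1": self.stage1.to_dict(), "stage2": self.stage2.to_dict(),
                "threshold": THRESHOLD}

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(stage1=EnsembleStage.from_dict(d["stage1"]),
                   stage2=EnsembleStage.from_dict(d["stage2"]))


@dataclass
class TrialDecision:
    decision: str  # 'rest' | 'left' | 'right'
    stage1: VoteDecision
    stage2: VoteDecision | None  # None iff stage 1 decided rest


def decode_trial(model: EnsembleModel, x: np.ndarray) -> TrialDecision:
    """Two-stage decoding of one 70-dim feature vector.

    Stage 2 is never invoked when stage 1 decides rest.
    """
    model.require_trained()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d1 = fuse(model.stage1.scores(x)[0])
    if d1.fused_class == STAGE1_ENCODING["rest"]:
        return TrialDecision(decision="rest", stage1=d1, stage2=None)
    d2 = fuse(model.stage2.scores(x)[0])
    decision = "left" if d2.fused_class == STAGE2_ENCODING["left"] else "right"
    return TrialDecision(decision=decision, stage1=d1, stage2=d2)


def decode_batch(model: EnsembleModel, X: np.ndarray) -> list[TrialDecision]:
    return [decode_trial(model, x) for x in np.atleast_2d(np.asarray(X, dtype=float))]


def decode_with_single_base(model: EnsembleModel, X: np.ndarray, base: str) -> list[str]:
    """Two-stage decisions using one base classifier alone (no fusion).

    Used to compare the fused ensemble against each base under the identical
    decoding protocol.
    """
    model.require_trained()
    if base not in BASE_NAMES:
        raise ConfigurationError(f"unknown base classifier {base!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    col = BASE_NAMES.index(base)
    v1 = model.stage1.votes(X)[:, col]
    v2 = model.stage2.votes(X)[:, col]
    out = []
    for a, b in zip(v1, v2):
        if a == STAGE1_ENCODING["rest"]:
            out.append("rest")
        else:
            out.append("left" if b == STAGE2_ENCODING["left"] else "right")
    return out
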