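"""End-to-end experiment: simulate → preprocess → features → CV-train → metrics.

The evaluation protocol mirrors the offline study design: stratified 10-fold
cross-validation over trials; inside each training fold the minority classes
are balanced with the neighbor-weighted bootstrap (test folds are never
augmented), the two binary ensemble stages are trained, and the held-out
trials are decoded through the two-stage state machine.  Fold confusion
tables are pooled by summation (micro) and also reported per fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as lfpio
from .bandfeat import (MOVEMENT_SPEC, REST_SPEC, FeatureVector, band_envelopes,
                       extract_features, segment_epoch)
from .baseclf import FbannHyper, PnnHyper, RbfnnHyper
from .ensemble import (BASE_NAMES, EnsembleModel, StageHyper, decode_batch,
                       decode_with_single_base, fit_stage)
from .errors import LfpDecodeError
from .metrics import MetricsReport, confusion_from_labels, kappa_with_se
from .preprocess import PreprocessParams, preprocess_channel
from .resampling import balance_with_bootstrap, kfold_split
from .synthlfp import LfpSession, SimConfig, simulate_session

log = logging.getLogger(__name__)

CLASSES_3 = ("rest", "left", "right")


@dataclass(frozen=True)
class ExperimentConfig:
    sim: SimConfig = SimConfig()
    preprocess: PreprocessParams = PreprocessParams()
    bootstrap_r: int = 5
    stage_hyper: StageHyper = StageHyper()
    k_folds: int = 10
    seed: int = 0
    outdir: str | None = None

    def validate(self):
        self.sim.validate()
        if self.k_folds < 2:
            raise LfpDecodeError(f"k_folds must be >= 2, got {self.k_folds}")


# ---------------------------------------------------------------------------
# feature pipeline
# ---------------------------------------------------------------------------


def session_features(session: LfpSession,
                     params: PreprocessParams = PreprocessParams()):
    """Preprocess a raw session and extract one feature vector per usable trial.

    Movement trials use the response-anchored -150..+350 ms windows; rest
    trials the pre-stimulus -750..-250 ms windows.  Trials flagged by the
    1-5 s inter-event rule (or whose epoch would leave the recording) are
    skipped and counted.
    """
    left = preprocess_channel(session.left, session.fs, params)
    right = preprocess_channel(session.right, session.fs, params)
    env = band_envelopes(left, right)
    onsets = [e.stimulus_time_s for e in session.events]
    features: list[FeatureVector] = []
    n_excluded = 0
    for i, ev in enumerate(session.events):
        spec = REST_SPEC if ev.label == "rest" else MOVEMENT_SPEC
        prev_t = onsets[i - 1] if i > 0 else None
        next_t = onsets[i + 1] if i + 1 < len(onsets) else None
        try:
            ep = segment_epoch(env, ev, spec, neighbor_onsets=(prev_t, next_t))
            if ep.excluded:
                n_excluded += 1
                continue
            features.append(extract_features(ep, spec, trial_id=i))
        except LfpDecodeError as e:
            n_excluded += 1
            log.warning("trial %d skipped: %s", i, e)
    if n_excluded:
        log.info("%d trial(s) excluded from feature extraction", n_excluded)
    return features, n_excluded


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_two_stage(X: np.ndarray, y: np.ndarray, *, hyper: StageHyper = StageHyper(),
                    bootstrap_r: int = 5, seed: int = 0) -> EnsembleModel:
    """Fit stage 1 (movement vs rest) and stage 2 (left vs right).

    Each stage's training set is class-balanced with the neighbor bootstrap
    before fitting.
    """
    y = np.asarray(y)
    y1 = (y != "rest").astype(float)  # movement = 1
    X1, y1b, prov1 = balance_with_bootstrap(X, y1, r=bootstrap_r, seed=seed)
    stage1 = fit_stage(X1, y1b, hyper, seed=seed, select_mask=prov1 == "original")

    mov = np.isin(y, ("left", "right"))
    y2 = (y[mov] == "left").astype(float)  # left = 1
    X2, y2b, prov2 = balance_with_bootstrap(X[mov], y2, r=bootstrap_r, seed=seed + 1)
    stage2 = fit_stage(X2, y2b, hyper, seed=seed + 1, select_mask=prov2 == "original")
    return EnsembleModel(stage1=stage1, stage2=stage2)


# ---------------------------------------------------------------------------
# the full experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    stage1_pooled: MetricsReport
    stage2_pooled: MetricsReport
    stage1_folds: list[MetricsReport]
    stage2_folds: list[MetricsReport]
    three_class_confusion: np.ndarray  # rows true, cols pred, order rest/left/right
    three_class_accuracy: float
    three_class_kappa: "object"
    base_three_class_accuracy: dict
    n_trials: int
    n_excluded: int
    stage2_invocations: int
    stage1_movement_decisions: int

    def to_dict(self) -> dict:
        return {
            "stage1_pooled": self.stage1_pooled.to_dict(),
            "stage2_pooled": self.stage2_pooled.to_dict(),
            "stage1_folds": [r.to_dict() for r in self.stage1_folds],
            "stage2_folds": [r.to_dict() for r in self.stage2_folds],
            "three_class_confusion": self.three_class_confusion.tolist(),
            "three_class_accuracy": self.three_class_accuracy,
            "three_class_kappa": {
                "kappa": self.three_class_kappa.kappa,
                "se": self.three_class_kappa.se,
                "ci95": list(self.three_class_kappa.ci95),
                "above_chance": self.three_class_kappa.above_chance,
            },
            "base_three_class_accuracy": self.base_three_class_accuracy,
            "n_trials": self.n_trials,
            "n_excluded": self.n_excluded,
            "stage2_invocations": self.stage2_invocations,
            "stage1_movement_decisions": self.stage1_movement_decisions,
        }


def _three_class_confusion(y_true, y_pred) -> np.ndarray:
    M = np.zeros((3, 3), dtype=int)
    idx = {c: i for i, c in enumerate(CLASSES_3)}
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the whole evaluation protocol; reproducible under fixed seed."""
    config.validate()
    session = simulate_session(config.sim)
    features, n_excluded = session_features(session, config.preprocess)
    X, y, ids = lfpio.features_to_arrays(features)
    log.info("experiment: %d usable trials (%d excluded), seed=%d",
             len(y), n_excluded, config.seed)

    folds = kfold_split(len(y), k=config.k_folds, labels=y, seed=config.seed)
    pooled1 = pooled2 = None
    folds1, folds2 = [], []
    y_true_all, y_pred_all = [], []
    base_pred_all = {b: [] for b in BASE_NAMES}
    stage2_invocations = 0
    stage1_movement = 0

    for f, (tr, te) in enumerate(folds):
        model = train_two_stage(X[tr], y[tr], hyper=config.stage_hyper,
                                bootstrap_r=config.bootstrap_r,
                                seed=config.seed * 1000 + f)
        decisions = decode_batch(model, X[te])
        pred = [d.decision for d in decisions]
        y_true_all.extend(y[te])
        y_pred_all.extend(pred)
        stage2_invocations += sum(d.stage2 is not None for d in decisions)
        stage1_movement += sum(d.stage1.fused_class == 1 for d in decisions)

        # stage-1 confusion: movement vs rest
        s1_true = np.where(y[te] == "rest", "rest", "movement")
        s1_pred = ["rest" if d.decision == "rest" else "movement" for d in decisions]
        ct_f1 = confusion_from_labels(s1_true, s1_pred, positive="movement")
        folds1.append(MetricsReport.from_confusion(ct_f1))
        pooled1 = ct_f1 if pooled1 is None else pooled1 + ct_f1

        # stage-2 confusion over all true-movement trials (classifier output,
        # independent of stage-1 errors)
        mov = np.isin(y[te], ("left", "right"))
        if mov.any():
            v2 = model.stage2.predict(X[te][mov])
            s2_pred = np.where(v2 == 1, "left", "right")
            ct_f2 = confusion_from_labels(y[te][mov], s2_pred, positive="left")
            folds2.append(MetricsReport.from_confusion(ct_f2))
            pooled2 = ct_f2 if pooled2 is None else pooled2 + ct_f2

        for b in BASE_NAMES:
            base_pred_all[b].extend(decode_with_single_base(model, X[te], b))

    M3 = _three_class_confusion(y_true_all, y_pred_all)
    acc3 = float(np.trace(M3) / M3.sum())
    kap3 = kappa_with_se(M3)
    base_acc = {
        b: float(np.mean([p == t for p, t in zip(base_pred_all[b], y_true_all)]))
        for b in BASE_NAMES
    }

    result = ExperimentResult(
        stage1_pooled=MetricsReport.from_confusion(pooled1),
        stage2_pooled=MetricsReport.from_confusion(pooled2),
        stage1_folds=folds1,
        stage2_folds=folds2,
        three_class_confusion=M3,
        three_class_accuracy=acc3,
        three_class_kappa=kap3,
        base_three_class_accuracy=base_acc,
        n_trials=len(y),
        n_excluded=n_excluded,
        stage2_invocations=stage2_invocations,
        stage1_movement_decisions=stage1_movement,
    )

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1)
        final = train_two_stage(X, y, hyper=config.stage_hyper,
                                bootstrap_r=config.bootstrap_r, seed=config.seed)
        lfpio.write_model(final, out / "model.json",
                          meta={"seed": config.seed, "k_folds": config.k_folds,
                                "n_trials": len(y)})
        lfpio.write_features(features, out / "features.csv")
        with open(out / "experiment_log.json", "w") as fh:
            json.dump({"seed": config.seed, "sim_seed": config.sim.seed,
                       "k_folds": config.k_folds, "bootstrap_r": config.bootstrap_r,
                       "n_trials": len(y), "n_excluded": n_excluded}, fh, indent=1)
    return result
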