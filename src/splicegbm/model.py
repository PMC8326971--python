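"""Gradient-boosted classifier: training, tuning, cross-validation, importance.

The backend is LightGBM behind a thin interface; training is deterministic
given (data, config, seed) and invariant to input row order because rows are
sorted by key before fitting. Probabilities refer to the pathogenic class;
the decision threshold is 0.5 with p >= 0.5 called splicing-affecting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd

from . import evaluation as _ev
from .dataset import LabeledDataset, SplitPlan, benchmark_split

log = logging.getLogger(__name__)

THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelConfig:
    """GBDT hyperparameters (LightGBM naming)."""

    num_leaves: int = 31
    learning_rate: float = 0.1
    n_estimators: int = 200
    min_child_samples: int = 20
    feature_fraction: float = 0.9
    bagging_fraction: float = 1.0
    bagging_freq: int = 0
    reg_alpha: float = 0.0
    reg_lambda: float = 0.0

    def lgbm_params(self, seed: int) -> dict:
        return {
            "objective": "binary",
            "num_leaves": self.num_leaves,
            "learning_rate": self.learning_rate,
            "n_estimators": self.n_estimators,
            "min_child_samples": self.min_child_samples,
            "colsample_bytree": self.feature_fraction,
            "subsample": self.bagging_fraction,
            "subsample_freq": self.bagging_freq,
            "reg_alpha": self.reg_alpha,
            "reg_lambda": self.reg_lambda,
            "random_state": seed,
            "n_jobs": 1,
            "deterministic": True,
            "force_row_wise": True,
            "verbose": -1,
        }


#: Randomized-search space for tune_hyperparameters (log-uniform where noted)
SEARCH_SPACE = {
    "num_leaves": (8, 64),                # int, uniform
    "learning_rate": (0.02, 0.3),         # log-uniform
    "min_child_samples": (5, 40),         # int, uniform
    "feature_fraction": (0.6, 1.0),
    "bagging_fraction": (0.6, 1.0),
    "n_estimators": (100, 400),           # int, uniform
    "reg_alpha": (1e-8, 1.0),             # log-uniform
    "reg_lambda": (1e-8, 1.0),            # log-uniform
}


class SchemaMismatchError(ValueError):
    pass


def _schema_hash(names: Sequence[str]) -> str:
    return hashlib.sha256(json.dumps(list(names)).encode()).hexdigest()[:16]


@dataclass
class TrainedClassifier:
    booster: lgb.LGBMClassifier
    feature_names: list[str]
    config: ModelConfig
    seed: int
    threshold: float = THRESHOLD
    schema_hash: str = ""

    def __post_init__(self):
        if not self.schema_hash:
            self.schema_hash = _schema_hash(self.feature_names)

    def _check_schema(self, names: Sequence[str]) -> None:
        if _schema_hash(names) != self.schema_hash:
            missing = sorted(set(self.feature_names) - set(names))
            extra = sorted(set(names) - set(self.feature_names))
            raise SchemaMismatchError(
                f"feature schema mismatch; missing={missing} extra={extra}"
            )

    def predict_proba(self, fv: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        """Pathogenic-class probability for one feature dict or a frame."""
        if isinstance(fv, Mapping):
            frame = pd.DataFrame([fv])
        else:
            frame = fv
        self._check_schema(list(frame.columns))
        frame = frame[self.feature_names]
        return self.booster.predict_proba(frame)[:, 1]

    def classify(self, p: float) -> str:
        return "splicing-affecting" if p >= self.threshold else "splicing-insensitive"

    def save(self, model_dir: str | Path) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.booster_.save_model(str(d / "ensemble.txt"))
        (d / "schema.json").write_text(
            json.dumps(
                {"feature_names": self.feature_names, "schema_hash": self.schema_hash}
            )
        )
        (d / "config.json").write_text(
            json.dumps({"config": asdict(self.config), "seed": self.seed,
                        "threshold": self.threshold})
        )
        (d / "training.log").write_text(
            f"rows={self.booster.n_features_in_} features "
            f"schema={self.schema_hash}\n"
        )

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedClassifier":
        d = Path(model_dir)
        schema = json.loads((d / "schema.json").read_text())
        meta = json.loads((d / "config.json").read_text())
        booster = lgb.Booster(model_file=str(d / "ensemble.txt"))
        clf = lgb.LGBMClassifier()
        clf._Booster = booster
        clf.fitted_ = True
        clf._n_classes = 2
        clf._n_features = booster.num_feature()
        obj = cls(
            booster=clf,
            feature_names=schema["feature_names"],
            config=ModelConfig(**meta["config"]),
            seed=meta["seed"],
            threshold=meta.get("threshold", THRESHOLD),
            schema_hash=schema["schema_hash"],
        )
        return obj


def fit(
    ds: LabeledDataset, config: ModelConfig | None = None, seed: int = 0
) -> TrainedClassifier:
    """Train on all rows of ``ds``; deterministic given (data, config, seed).

    Rows are sorted by key first, so predictions do not depend on input
    order. Raises on single-class data.
    """
    config = config or ModelConfig()
    df = ds.df.sort_values("key").reset_index(drop=True)
    y = df["label"].to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"need >=2 rows per class, got pathogenic={counts[1]} common={counts[0]}"
        )
    X = df[ds.feature_cols]
    clf = lgb.LGBMClassifier(**config.lgbm_params(seed))
    clf.fit(X, y)
    return TrainedClassifier(
        booster=clf, feature_names=list(ds.feature_cols), config=config, seed=seed
    )


@dataclass
class CVResult:
    fold_metrics: list[_ev.MetricsReport]
    fold_auroc: list[float]
    fold_aupr: list[float]
    roc_curves: list[list[tuple[float, float]]]
    pr_curves: list[list[tuple[float, float]]]

    @property
    def mean_metrics(self) -> dict[str, float | None]:
        keys = self.fold_metrics[0].as_dict().keys()
        return {
            k: _ev.mean_defined([m.as_dict()[k] for m in self.fold_metrics])
            for k in keys
        }

    @property
    def sd_metrics(self) -> dict[str, float | None]:
        out = {}
        for k in self.fold_metrics[0].as_dict():
            vals = [m.as_dict()[k] for m in self.fold_metrics if m.as_dict()[k] is not None]
            out[k] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        return out

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))


def cross_validate(
    ds: LabeledDataset, plan: SplitPlan, config: ModelConfig | None = None
) -> CVResult:
    """k-fold CV over the plan's train keys; per-fold metrics and curves."""
    config = config or ModelConfig()
    fold_metrics, fold_auroc, fold_aupr = [], [], []
    roc_curves, pr_curves = [], []
    for fold in range(1, plan.n_folds + 1):
        valid_keys = plan.fold_keys(fold)
        train_keys = [k for k in plan.train_keys if plan.folds[k] != fold]
        valid = ds.subset(valid_keys)
        if len(np.unique(valid.y())) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        clf = fit(ds.subset(train_keys), config, seed=plan.seed)
        p = clf.predict_proba(valid.X())
        y = valid.y()
        cm = _ev.confusion_from_predictions(y, p, THRESHOLD)
        fold_metrics.append(_ev.compute_metrics(cm))
        roc, auroc = _ev.roc_curve(y, p)
        pr, aupr = _ev.pr_curve(y, p)
        fold_auroc.append(auroc)
        fold_aupr.append(aupr)
        roc_curves.append(roc)
        pr_curves.append(pr)
    return CVResult(fold_metrics, fold_auroc, fold_aupr, roc_curves, pr_curves)


def _sample_config(rng: np.random.Generator) -> ModelConfig:
    lo, hi = SEARCH_SPACE["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    ra_lo, ra_hi = SEARCH_SPACE["reg_alpha"]
    rl_lo, rl_hi = SEARCH_SPACE["reg_lambda"]
    return ModelConfig(
        num_leaves=int(rng.integers(*SEARCH_SPACE["num_leaves"], endpoint=True)),
        learning_rate=lr,
        n_estimators=int(rng.integers(*SEARCH_SPACE["n_estimators"], endpoint=True)),
        min_child_samples=int(
            rng.integers(*SEARCH_SPACE["min_child_samples"], endpoint=True)
        ),
        feature_fraction=float(rng.uniform(*SEARCH_SPACE["feature_fraction"])),
        bagging_fraction=float(rng.uniform(*SEARCH_SPACE["bagging_fraction"])),
        bagging_freq=1,
        reg_alpha=float(np.exp(rng.uniform(np.log(ra_lo), np.log(ra_hi)))),
        reg_lambda=float(np.exp(rng.uniform(np.log(rl_lo), np.log(rl_hi)))),
    )


def tune_hyperparameters(
    train_ds: LabeledDataset, budget: int = 25, seed: int = 0
) -> ModelConfig:
    """Randomized search over SEARCH_SPACE maximizing mean CV AUROC.

    Deterministic given ``seed``; ``budget`` is the number of sampled
    configurations. ``budget=0`` returns the documented defaults with a
    warning.
    """
    if budget < 1:
        warnings.warn("tuning budget 0: returning default ModelConfig", stacklevel=2)
        return ModelConfig()
    rng = np.random.default_rng(seed)
    plan = benchmark_split(train_ds, (), seed=seed)
    best: tuple[float, ModelConfig] | None = None
    for trial in range(budget):
        cfg = _sample_config(rng)
        auroc = cross_validate(train_ds, plan, cfg).mean_auroc
        log.info("trial %d: auroc=%.4f %s", trial, auroc, cfg)
        if best is None or auroc > best[0]:
            best = (auroc, cfg)
    return best[1]


def feature_importance(
    clf: TrainedClassifier, top_n: int = 10, kind: str = "gain"
) -> list[tuple[str, float]]:
    """Top-``top_n`` features by total gain (default) or split count, descending.

    Ties break lexicographically on the feature name; ``top_n`` beyond the
    schema returns the full ranking.
    """
    if kind not in {"split", "gain"}:
        raise ValueError("kind must be 'split' or 'gain'")
    imp = clf.booster.booster_.feature_importance(importance_type=kind)
    pairs = sorted(
        zip(clf.feature_names, imp.astype(float)), key=lambda t: (-t[1], t[0])
    )
    return pairs[:top_n]


def predict_proba(clf: TrainedClassifier, fv: Mapping[str, float]) -> float:
    """Pathogenic-class probability of one feature vector."""
    return float(clf.predict_proba(fv)[0])
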