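"""Labelled datasets, MAF filtering, class balancing, circularity-free splits.

A dataset row is one (variant, transcript) pair keyed
``chrom:pos:ref:alt:transcript_id``. The genomic part of the key
(``chrom:pos:ref:alt``) is the atomic unit for splitting: all transcript rows
of one genomic SNV always land on the same side of a train/test split and in
the same CV fold, so the identical variant can never leak across a split.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import features as _feat
from .genomic_io import (
    AcceptorContext,
    Genome,
    TranscriptModel,
    VariantRecord,
    acceptor_windows,
    map_variant,
)

log = logging.getLogger(__name__)

LABEL_CODES = {"pathogenic": 1, "common": 0}
KEY_COLUMNS = ["key", "chrom", "pos", "ref", "alt", "transcript_id", "maf", "label"]


class CircularityError(RuntimeError):
    """Raised when a train/test split would share a variant key."""


def genomic_key(row_key: str) -> str:
    """chrom:pos:ref:alt part of a row key."""
    return ":".join(row_key.split(":")[:4])


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels, one row per (variant, transcript)."""

    df: pd.DataFrame
    feature_cols: list[str] = field(default_factory=_feat.feature_names)

    def __post_init__(self):
        if self.df["key"].duplicated().any():
            dupes = self.df.loc[self.df["key"].duplicated(), "key"].tolist()
            raise ValueError(f"duplicate dataset keys: {dupes[:5]}")
        if not set(self.df["label"].unique()) <= {0, 1}:
            raise ValueError("labels must be coded 0 (common) / 1 (pathogenic)")
        missing = [c for c in self.feature_cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> list[str]:
        return self.df["key"].tolist()

    def X(self, keys: Sequence[str] | None = None) -> pd.DataFrame:
        sub = self.df if keys is None else self.subset(keys).df
        return sub[self.feature_cols]

    def y(self, keys: Sequence[str] | None = None) -> np.ndarray:
        sub = self.df if keys is None else self.subset(keys).df
        return sub["label"].to_numpy()

    def subset(self, keys: Sequence[str]) -> "LabeledDataset":
        keyset = set(keys)
        sub = self.df[self.df["key"].isin(keyset)].reset_index(drop=True)
        return LabeledDataset(sub, self.feature_cols)

    def shuffled_labels(self, seed: int) -> "LabeledDataset":
        """Label-permuted copy (null-signal control)."""
        rng = np.random.default_rng(seed)
        df = self.df.copy()
        df["label"] = rng.permutation(df["label"].to_numpy())
        return LabeledDataset(df, self.feature_cols)

    def to_tsv(self, path: str | Path, provenance: Mapping | None = None) -> None:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "format": "splicegbm-dataset-v1",
            "feature_columns": self.feature_cols,
            "n_rows": len(self.df),
            "provenance": dict(provenance or {}),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        sidecar = path.with_suffix(path.suffix + ".json")
        cols = (
            json.loads(sidecar.read_text())["feature_columns"]
            if sidecar.exists()
            else _feat.feature_names()
        )
        return cls(df, cols)


def maf_filter(
    records: Iterable[VariantRecord], lo: float = 0.01, hi: float = 0.50
) -> list[VariantRecord]:
    """Keep pathogenic records and common records with lo <= MAF < hi.

    The interval is half-open: MAF equal to ``lo`` is kept, equal to ``hi``
    is dropped. ``hi=0.99`` reproduces the wider selection that also admits
    variants whose reference base is the minor allele.
    """
    out = []
    for r in records:
        if r.label == "pathogenic":
            out.append(r)
            continue
        if r.maf is None:
            warnings.warn(f"{r.key}: no MAF on a non-pathogenic record; dropped",
                          stacklevel=2)
            continue
        if lo <= r.maf < hi:
            out.append(r)
    return out


def balance_sample(
    pathogenic: Sequence[VariantRecord],
    common: Sequence[VariantRecord],
    seed: int,
) -> list[VariantRecord]:
    """All pathogenic records plus an equal-size uniform sample of commons.

    Sampling is without replacement and deterministic given ``seed``.
    """
    if len(common) < len(pathogenic):
        raise ValueError(
            f"only {len(common)} common records for {len(pathogenic)} pathogenic; "
            "downsample the pathogenic set instead"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(common), size=len(pathogenic), replace=False)
    return list(pathogenic) + [common[i] for i in sorted(idx)]


def build_dataset(
    records: Sequence[VariantRecord],
    models: Sequence[TranscriptModel],
    genome: Genome,
    config: _feat.FeatureConfig | None = None,
) -> LabeledDataset:
    """Featurize labelled variants into a LabeledDataset.

    One row per (variant, transcript) pair whose acceptor window covers the
    variant at Int-50..Int-3; unmapped or out-of-scope records are logged and
    dropped.
    """
    config = config or _feat.FeatureConfig()
    contexts: dict[str, list[AcceptorContext]] = {
        tm.transcript_id: acceptor_windows(tm, genome) for tm in models
    }
    ctx_by_tid = {
        tid: {c.intron_index: c for c in ctxs} for tid, ctxs in contexts.items()
    }
    rows = []
    for rec in records:
        if rec.label not in LABEL_CODES:
            log.info("%s: unlabeled record skipped", rec.key)
            continue
        hits = map_variant(rec, models, genome, contexts=contexts)
        if not hits:
            log.info("%s: no acceptor window covers this position", rec.key)
        for iv in hits:
            if not iv.in_model_scope:
                log.info("%s: Int-%d outside model scope", rec.key, iv.int_position)
                continue
            ctx = next(
                c
                for c in contexts[iv.transcript_id]
                if c.covers(rec.chrom, rec.pos)
            )
            fv = _feat.featurize(ctx, iv, config)
            row = {
                "key": iv.key,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref_base,
                "alt": rec.alt_base,
                "transcript_id": iv.transcript_id,
                "maf": np.nan if rec.maf is None else rec.maf,
                "label": LABEL_CODES[rec.label],
            }
            row.update(fv)
            rows.append(row)
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + _feat.feature_names())
    return LabeledDataset(df)


@dataclass(frozen=True)
class SplitPlan:
    """Train/test key sets plus a stratified CV fold id (1..n) per train key."""

    train_keys: tuple[str, ...]
    test_keys: tuple[str, ...]
    folds: Mapping[str, int]
    seed: int
    n_folds: int = 5

    def __post_init__(self):
        overlap = set(self.train_keys) & set(self.test_keys)
        if overlap:
            raise CircularityError(
                f"train/test overlap on {len(overlap)} keys, e.g. "
                f"{sorted(overlap)[:3]}"
            )
        if set(self.folds) != set(self.train_keys):
            raise ValueError("folds must partition exactly the train keys")
        ids = set(self.folds.values())
        if ids and not ids <= set(range(1, self.n_folds + 1)):
            raise ValueError(f"fold ids must lie in 1..{self.n_folds}")

    def fold_keys(self, fold: int) -> list[str]:
        return [k for k in self.train_keys if self.folds[k] == fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "splicegbm-splitplan-v1",
                    "seed": self.seed,
                    "n_folds": self.n_folds,
                    "train_keys": list(self.train_keys),
                    "test_keys": list(self.test_keys),
                    "folds": dict(self.folds),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["train_keys"]), tuple(d["test_keys"]), d["folds"],
            d["seed"], d["n_folds"],
        )


def benchmark_split(
    ds: LabeledDataset,
    held_out_keys: Sequence[str] = (),
    seed: int = 0,
    n_folds: int = 5,
) -> SplitPlan:
    """Hold out a benchmark test set and stratify the remainder into CV folds.

    ``held_out_keys`` may be row keys or genomic keys; holdout is atomic per
    genomic SNV (every transcript row of a held-out SNV goes to the test
    side). Folds are assigned per genomic SNV, stratified by label with
    per-class fold sizes differing by at most one. Any overlap between the
    resulting train and test sets raises :class:`CircularityError`.
    """
    all_keys = ds.keys
    held_genomic = {genomic_key(k) for k in held_out_keys}
    test = [k for k in all_keys if genomic_key(k) in held_genomic]
    missing = held_genomic - {genomic_key(k) for k in test}
    if missing:
        raise KeyError(f"held-out keys not in dataset: {sorted(missing)[:3]}")
    train = [k for k in all_keys if genomic_key(k) not in held_genomic]

    # stratify over unique genomic SNVs so duplicates stay in one fold
    gkeys: dict[str, int] = {}
    for k in train:
        gk = genomic_key(k)
        label = int(ds.df.loc[ds.df["key"] == k, "label"].iloc[0])
        gkeys.setdefault(gk, label)
    gk_list = sorted(gkeys)
    labels = np.array([gkeys[g] for g in gk_list])
    folds: dict[str, int] = {}
    if gk_list:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        gk_fold: dict[str, int] = {}
        for fold_id, (_, test_idx) in enumerate(
            skf.split(np.zeros(len(gk_list)), labels), start=1
        ):
            for i in test_idx:
                gk_fold[gk_list[i]] = fold_id
        folds = {k: gk_fold[genomic_key(k)] for k in train}
    return SplitPlan(tuple(train), tuple(test), folds, seed, n_folds)
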