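"""Metrics, split protocol and data-efficiency curves.

MAE (primary; sensitive to the magnitude of promoter strength) and R²
(secondary; overall fit) score the regression.  The experiment protocol is a
fixed 1/10 held-out test set plus repeated seeded 9:1 train/validation
resplits of the remainder, all at the *variant* level: augmented copies of a
variant always travel together, so no variant leaks across parts via a
different base promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import EVMPRecord
from .models import Prediction


def _as_arrays(y_true, y_pred=None) -> tuple[np.ndarray, np.ndarray]:
    if y_pred is None:  # a list of Prediction objects
        preds: Sequence[Prediction] = y_true
        if any(p.y is None for p in preds):
            raise ValueError("predictions must carry labels")
        return (np.array([p.y for p in preds]),
                np.array([p.y_hat for p in preds]))
    return np.asarray(y_true, dtype=float), np.asarray(y_pred, dtype=float)


def mae(y_true, y_pred=None) -> float:
    """Mean absolute error; accepts arrays or a list of Prediction."""
    y, y_hat = _as_arrays(y_true, y_pred)
    return float(np.mean(np.abs(y_hat - y)))


def r_squared(y_true, y_pred=None) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot, SS_tot about the
    evaluation set's own label mean.  Undefined for zero-variance labels."""
    y, y_hat = _as_arrays(y_true, y_pred)
    if len(y) < 2:
        raise ValueError("R^2 requires at least 2 points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance labels")
    return 1.0 - float(np.sum((y_hat - y) ** 2)) / ss_tot


@dataclass(frozen=True)
class SplitPlan:
    """Protocol: one fixed ``test_fraction`` hold-out, then ``repeats``
    seeded ``val_fraction`` train/validation resplits of the remainder."""

    test_fraction: float = 0.1
    val_fraction: float = 0.1
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.test_fraction, self.val_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class Split:
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]


def make_splits(
    items, plan: SplitPlan = SplitPlan(),
    variant_ids: Optional[Sequence[str]] = None,
) -> list[Split]:
    """Index splits for ``items`` (a count, a sequence of records, or any
    sized sequence).

    Grouping is by variant id: records sharing a variant id (augmented
    copies) land in the same part.  The test part is identical across all
    repeats; each repeat reshuffles the remainder into train/val.
    """
    if isinstance(items, int):
        n = items
    else:
        n = len(items)
        if variant_ids is None and n and isinstance(items[0], EVMPRecord):
            variant_ids = [r.variant_id for r in items]
    if variant_ids is None:
        variant_ids = [str(i) for i in range(n)]
    if len(variant_ids) != n:
        raise ValueError("variant_ids length mismatch")

    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for idx, vid in enumerate(variant_ids):
        if vid not in groups:
            groups[vid] = []
            order.append(vid)
        groups[vid].append(idx)

    rng = np.random.default_rng(plan.seed)
    shuffled = list(order)
    rng.shuffle(shuffled)
    n_groups = len(shuffled)
    n_test = int(round(plan.test_fraction * n_groups))
    test_groups = shuffled[:n_test]
    rest = shuffled[n_test:]
    test_idx = tuple(i for g in test_groups for i in groups[g])

    splits = []
    for rep in range(plan.repeats):
        rep_rng = np.random.default_rng(plan.seed + 1 + rep)
        rest_shuffled = list(rest)
        rep_rng.shuffle(rest_shuffled)
        n_val = int(round(plan.val_fraction * len(rest_shuffled)))
        val_groups = rest_shuffled[:n_val]
        train_groups = rest_shuffled[n_val:]
        splits.append(Split(
            train=tuple(i for g in train_groups for i in groups[g]),
            val=tuple(i for g in val_groups for i in groups[g]),
            test=test_idx,
        ))
    return splits


@dataclass
class MetricReport:
    """Per-repeat MAE/R² with mean ± s.d. summaries (Table-style format)."""

    mae_values: list[float] = field(default_factory=list)
    r2_values: list[float] = field(default_factory=list)

    def add(self, mae_value: float, r2_value: float) -> None:
        self.mae_values.append(float(mae_value))
        self.r2_values.append(float(r2_value))

    @property
    def mae_mean(self) -> float:
        return float(np.mean(self.mae_values))

    @property
    def mae_std(self) -> float:
        return float(np.std(self.mae_values))

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_values))

    @property
    def r2_std(self) -> float:
        return float(np.std(self.r2_values))

    def as_dict(self) -> dict:
        return {
            "mae": self.mae_values, "r2": self.r2_values,
            "mae_mean": self.mae_mean, "mae_std": self.mae_std,
            "r2_mean": self.r2_mean, "r2_std": self.r2_std,
        }

    def __str__(self) -> str:
        return (f"MAE {self.mae_mean:.4f} ± {self.mae_std:.4f}, "
                f"R² {self.r2_mean:.3f} ± {self.r2_std:.3f} "
                f"({len(self.mae_values)} repeats)")


def cross_validate(estimator, records: Sequence[EVMPRecord],
                   plan: SplitPlan = SplitPlan(),
                   part: str = "val") -> MetricReport:
    """Run the split protocol with a fresh clone of ``estimator`` per repeat
    and score the requested part ("val" or "test")."""
    from sklearn.base import clone

    records = list(records)
    y = np.array([r.strength for r in records], dtype=float)
    report = MetricReport()
    for rep, split in enumerate(make_splits(records, plan)):
        est = clone(estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=plan.seed + rep)
        train_recs = [records[i] for i in split.train]
        val_recs = [records[i] for i in split.val]
        est.fit(train_recs, y[list(split.train)],
                X_val=val_recs, y_val=y[list(split.val)])
        eval_idx = split.val if part == "val" else split.test
        eval_recs = [records[i] for i in eval_idx]
        y_hat = est.predict(eval_recs)
        report.add(mae(y[list(eval_idx)], y_hat),
                   r_squared(y[list(eval_idx)], y_hat))
    return report


def data_efficiency_curve(records: Sequence[EVMPRecord], fractions,
                          estimator, plan: SplitPlan = SplitPlan(repeats=1)):
    """Validation MAE/R² as a function of the training-set fraction.

    A fixed validation set (``val_fraction`` of the non-test remainder) is
    scored while the training pool is subsampled to each fraction of its
    full size (seeded).  Returns a pandas DataFrame with one row per
    fraction.
    """
    import pandas as pd
    from sklearn.base import clone

    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    records = list(records)
    y = np.array([r.strength for r in records], dtype=float)
    split = make_splits(records, plan)[0]
    val_recs = [records[i] for i in split.val]
    y_val = y[list(split.val)]
    rng = np.random.default_rng(plan.seed)
    pool = np.array(split.train)
    pool_order = rng.permutation(len(pool))
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * len(pool)))
        if n_sub < 1:
            raise ValueError(f"fraction {frac} leaves an empty training set")
        sub = pool[pool_order[:n_sub]]
        est = clone(estimator)
        train_recs = [records[i] for i in sub]
        est.fit(train_recs, y[sub], X_val=val_recs, y_val=y_val)
        y_hat = est.predict(val_recs)
        rows.append({"fraction": frac, "n_train": n_sub,
                     "val_mae": mae(y_val, y_hat),
                     "val_r2": r_squared(y_val, y_hat)})
    return pd.DataFrame(rows)
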