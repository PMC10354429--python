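"""Multi-base-promoter data augmentation.

Choosing a good base promoter is hard, so instead each synthetic variant S'
can be re-expressed against several base promoters P1..Pm, yielding m
records <Pi, M(Pi, S')> per variant.  Three dataset modes:

* ``fixed`` — every variant against one designated base (the library base
  by default);
* ``rand`` — one base drawn uniformly per variant (seeded);
* ``augmented`` — all m bases per variant (dataset expands m-fold).

Records carry their base id alongside the variant id so that train/test
splits can group all copies of a variant together and avoid leakage.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .align import AlignmentParams, EVMPRecord, make_record
from .seq import Promoter, PromoterLibrary

Mode = Literal["fixed", "rand", "augmented"]
_MODES = ("fixed", "rand", "augmented")


@dataclass
class AugmentationPlan:
    """Base-promoter panel plus the train/eval dataset modes.

    The designated base for ``fixed`` mode is ``panel[fixed_index]``; by
    convention the library base occupies panel position 0 (see
    :func:`default_plan`), so ``fixed`` is always a subset of ``augmented``.
    """

    panel: list[Promoter]
    mode_train: Mode = "fixed"
    mode_eval: Mode = "fixed"
    seed: int = 0
    fixed_index: int = 0

    def __post_init__(self) -> None:
        if self.mode_train not in _MODES or self.mode_eval not in _MODES:
            raise ValueError(f"modes must be one of {_MODES}")
        if not self.panel:
            raise ValueError("panel must contain at least one base promoter")
        ids = [p.id for p in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("panel ids must be unique")
        if not 0 <= self.fixed_index < len(self.panel):
            raise ValueError("fixed_index out of range")

    @property
    def m(self) -> int:
        return len(self.panel)


def default_plan(
    lib: PromoterLibrary,
    extra_bases: Sequence[Promoter] = (),
    mode_train: Mode = "fixed",
    mode_eval: Mode = "fixed",
    seed: int = 0,
) -> AugmentationPlan:
    """Plan whose panel is the library base (P1) followed by any extra
    bases (e.g. a generated panel)."""
    return AugmentationPlan(
        panel=[lib.base, *extra_bases],
        mode_train=mode_train,
        mode_eval=mode_eval,
        seed=seed,
    )


def build_records(
    lib: PromoterLibrary,
    plan: AugmentationPlan,
    k: int,
    role: Literal["train", "eval"] = "train",
    params: AlignmentParams = AlignmentParams(),
) -> list[EVMPRecord]:
    """Materialise the EVMP records for one dataset role.

    Record counts: ``fixed`` -> N, ``rand`` -> N (base drawn uniformly per
    variant, seeded per role), ``augmented`` -> m*N (variant-major order).
    Every record reconstructs to its original variant regardless of the base
    it was expressed against.
    """
    mode = plan.mode_train if role == "train" else plan.mode_eval
    if mode != "fixed" and len(plan.panel) < 2:
        raise ValueError(f"mode {mode!r} requires a panel of at least 2 promoters")
    L = lib.pad_length
    records: list[EVMPRecord] = []
    if mode == "fixed":
        base = plan.panel[plan.fixed_index]
        for variant in lib.variants:
            records.append(make_record(base, variant, k, L, params))
    elif mode == "rand":
        rng = np.random.default_rng(plan.seed + (0 if role == "train" else 1))
        choices = rng.integers(plan.m, size=len(lib.variants))
        for variant, idx in zip(lib.variants, choices):
            records.append(make_record(plan.panel[int(idx)], variant, k, L, params))
    else:  # augmented
        for variant in lib.variants:
            for base in plan.panel:
                records.append(make_record(base, variant, k, L, params))
    return records


def aggregate_predictions(
    per_record_predictions: Sequence[tuple[str, str, float]],
    strategy: Literal["mean", "per_record"] = "per_record",
):
    """Collapse per-record predictions to per-variant form.

    ``per_record_predictions`` are ``(variant_id, base_id, yhat)`` triples.
    ``mean`` averages yhat over base promoters per variant (insertion
    order preserved); ``per_record`` returns the triples unchanged.
    Duplicate (variant, base) pairs are rejected.
    """
    if not per_record_predictions:
        raise ValueError("no predictions to aggregate")
    seen: set[tuple[str, str]] = set()
    for variant_id, base_id, _ in per_record_predictions:
        key = (variant_id, base_id)
        if key in seen:
            raise ValueError(f"duplicate prediction for {key}")
        seen.add(key)
    if strategy == "per_record":
        return list(per_record_predictions)
    if strategy != "mean":
        raise ValueError(f"unknown strategy {strategy!r}")
    grouped: "OrderedDict[str, list[float]]" = OrderedDict()
    for variant_id, _, yhat in per_record_predictions:
        grouped.setdefault(variant_id, []).append(float(yhat))
    return OrderedDict((vid, float(np.mean(vals))) for vid, vals in grouped.items())
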