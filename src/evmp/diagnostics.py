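"""Over-smoothing diagnostics via the average embedding distance.

Over-smoothing is the collapse of distinct inputs onto near-identical
embeddings — fatal for mutant libraries whose sequences differ at only a
handful of positions.  It is quantified per layer by the average embedding
distance

    d_l = (1/N) * sum_i ||e_l(P_i) - e_l(P_0)||_2 / n_l ,

the mean L2 distance of each variant's layer-l embedding from the base
promoter's, normalised by the embedding dimension n_l.  Layer 0 is the raw
model input, so d_0 measures how dispersed the *representations* are before
any learning: the mutation-stream input of a paired-encoder model is far
more dispersed than near-identical full sequences, which is the mechanism
by which it escapes over-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import EVMPRecord, make_record
from .models import UnsupportedOperationError
from .representation import PEConfig, encode_vars_pe
from .seq import Promoter, PromoterLibrary, one_hot


@dataclass(frozen=True)
class EmbeddingTrace:
    """Embeddings of N variants plus the base-promoter reference at one
    layer; ``reference`` has shape (n_l,), ``embeddings`` (N, n_l)."""

    layer: str
    reference: np.ndarray
    embeddings: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        emb = np.atleast_2d(np.asarray(self.embeddings, dtype=float))
        if emb.shape[1] != ref.shape[-1]:
            raise ValueError(
                f"dimension mismatch: embeddings {emb.shape[1]} vs "
                f"reference {ref.shape[-1]}")
        object.__setattr__(self, "reference", ref.ravel())
        object.__setattr__(self, "embeddings", emb)

    @property
    def n_l(self) -> int:
        return self.reference.shape[0]


def avg_embedding_distance(trace: EmbeddingTrace) -> float:
    """d_l: mean L2 distance to the reference, divided by the embedding
    dimension n_l."""
    if trace.embeddings.shape[0] < 1:
        raise ValueError("need at least one embedding")
    dists = np.linalg.norm(trace.embeddings - trace.reference, axis=1)
    return float(dists.mean() / trace.n_l)


def oversmoothing_report(model, records: Sequence[EVMPRecord],
                         base_record: EVMPRecord) -> pd.DataFrame:
    """Per-layer d_l table for a fitted deep-family estimator.

    Paired-encoder models trace the VarEncoder stream (the BaseEncoder sees
    the same base promoter for every record); the full-sequence baseline
    traces its single stream.  Layer 0 is the flattened raw input.  LSTM
    encoders report one row per time step.  Classical families have no
    layer embeddings (:class:`UnsupportedOperationError`).
    """
    if not getattr(model, "is_deep", False):
        raise UnsupportedOperationError(
            "over-smoothing diagnostics need a deep-family model")
    records = list(records)
    trace_records = model.layer_trace(records)
    trace_base = model.layer_trace([base_record])
    rows = []
    for (name, emb), (_, ref) in zip(trace_records, trace_base):
        t = EmbeddingTrace(name, ref[0], emb)
        rows.append({"layer": name, "n_l": t.n_l,
                     "d_l": avg_embedding_distance(t)})
    return pd.DataFrame(rows)


def input_d0_evmp(records: Sequence[EVMPRecord], base_record: EVMPRecord,
                  max_sites: int = 18) -> float:
    """d_0 of the mutation stream: flattened Vars+PE tensors against the
    zero-mutation reference record."""
    cfg = PEConfig()
    emb = np.stack([encode_vars_pe(r, cfg, max_sites).ravel()
                    for r in records])
    ref = encode_vars_pe(base_record, cfg, max_sites).ravel()
    return avg_embedding_distance(EmbeddingTrace("input", ref, emb))


def input_d0_full(variants: Sequence[Promoter], base: Promoter) -> float:
    """d_0 of the full-sequence stream: flattened variant one-hots against
    the base promoter's one-hot."""
    emb = np.stack([one_hot(v.sequence).ravel() for v in variants])
    ref = one_hot(base.sequence).ravel()
    return avg_embedding_distance(EmbeddingTrace("input", ref, emb))


def input_dispersion(lib: PromoterLibrary, k: int,
                     max_sites: int = 18) -> dict[str, float]:
    """Compare input-layer dispersion of the two representations on a
    library: returns ``{"d0_evmp": ..., "d0_full": ...}``."""
    records = [make_record(lib.base, v, k, lib.pad_length)
               for v in lib.variants]
    base_record = make_record(lib.base, Promoter("base_ref", lib.base.sequence),
                              k, lib.pad_length)
    return {
        "d0_evmp": input_d0_evmp(records, base_record, max_sites),
        "d0_full": input_d0_full(lib.variants, lib.base),
    }
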