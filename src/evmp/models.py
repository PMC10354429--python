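"""Promoter-strength regressors: paired-encoder models and baselines.

The central estimator is :class:`EVMPRegressor`: a BaseEncoder embeds the
base promoter S, a VarEncoder embeds the k-mer mutation set M(S, S'), and
the two embeddings are concatenated into a feed-forward head that regresses
log strength, trained with an L1 objective plus an L2 weight penalty

    min_w  sum_i |yhat_i - y_i| + lambda * ||w||^2 .

Deep families (``lstm``, ``transformer``) keep the two encoder streams
separate (Vars+PE mutation representation); classical families (``rf``,
``gbdt``, ``xgboost``, ``svm``) share a single model over the concatenated
base + Mask features.  :class:`FullSequenceRegressor` is the non-EVMP
baseline operating on the raw one-hot variant sequence with the same
encoder architectures and training budget, so the two are directly
comparable.

Both estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``) and compose with sklearn model selection; ``X`` is a list of
:class:`~evmp.align.EVMPRecord` (or of :class:`~evmp.seq.Promoter` for the
baseline) rather than a numeric matrix.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.svm import SVR

from . import nn
from .align import EVMPRecord
from .representation import (
    PEConfig,
    encode_base,
    encode_vars_pe,
    flatten_for_classical,
    pe_matrix,
    positional_encoding,
)
from .seq import N_CHANNELS, Promoter, one_hot

DEEP_FAMILIES = ("lstm", "transformer")
CLASSICAL_FAMILIES = ("rf", "gbdt", "xgboost", "svm")


class UnsupportedOperationError(RuntimeError):
    """Raised when an encoder-level operation is asked of a classical family."""


class TrainingDivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class Prediction:
    variant_id: str
    y_hat: float
    y: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y_hat):
            raise ValueError("prediction must be finite")


def loss(predictions: Sequence[Prediction], weights_norm_sq: float = 0.0,
         lam: float = 0.0) -> float:
    """The training objective: sum of absolute errors plus lambda * ||w||^2."""
    total = 0.0
    for p in predictions:
        if p.y is None:
            raise ValueError(f"prediction for {p.variant_id!r} has no label")
        total += abs(p.y_hat - p.y)
    return total + lam * weights_norm_sq


# ---------------------------------------------------------------------------
# deep networks

class _Encoder(nn.Module):
    """One stream (BaseEncoder or VarEncoder): a learned input projection
    followed by an LSTM or transformer stack, reduced to a fixed-width
    embedding (last hidden state / mean pooling).

    Inputs come as a pair ``(one_hot, pe_addend)``: the one-hot rows are
    projected to model width and the (constant) positional-encoding addend —
    already at model width — is added after the projection.  Passing
    ``pe_addend=None`` disables PE.
    """

    def __init__(self, family: str, hidden_size: int, n_layers: int,
                 n_heads: int, rng: np.random.Generator):
        self.family = family
        self.proj = nn.Linear(N_CHANNELS, hidden_size, rng)
        if family == "lstm":
            self.lstm = nn.LSTM(hidden_size, hidden_size, rng)
        else:
            self.layers = [
                nn.TransformerLayer(hidden_size, n_heads, 2 * hidden_size, rng)
                for _ in range(n_layers)
            ]

    def _embed_input(self, oh: nn.Tensor,
                     pe: Optional[np.ndarray]) -> nn.Tensor:
        h = self.proj(oh)
        if pe is not None:
            h = h + nn.Tensor(pe)
        return h

    def __call__(self, oh: nn.Tensor,
                 pe: Optional[np.ndarray] = None) -> nn.Tensor:
        h = self._embed_input(oh, pe)
        if self.family == "lstm":
            return self.lstm(h)[:, -1, :]
        for layer in self.layers:
            h = layer(h)
        return h.mean(axis=1)

    def layer_outputs(self, oh: np.ndarray, pe: Optional[np.ndarray]
                      ) -> list[tuple[str, np.ndarray]]:
        """Per-layer embeddings for over-smoothing tracing (eval mode, no
        grad).  LSTM reports each time step's hidden state; the transformer
        reports each block's flattened output."""
        h = self._embed_input(nn.Tensor(oh), pe)
        outs: list[tuple[str, np.ndarray]] = []
        if self.family == "lstm":
            hs = self.lstm(h).value  # (batch, time, hidden)
            for step in range(hs.shape[1]):
                outs.append((f"t{step}", hs[:, step, :]))
        else:
            for idx, layer in enumerate(self.layers, start=1):
                h = layer(h)
                v = h.value
                outs.append((f"layer{idx}", v.reshape(v.shape[0], -1)))
        return outs


class _PairedNet(nn.Module):
    """BaseEncoder + VarEncoder + FFN head (the paired deep model)."""

    def __init__(self, family: str, hidden_size: int, n_layers: int,
                 n_heads: int, ffn_hidden: int, rng: np.random.Generator):
        self.base_encoder = _Encoder(family, hidden_size, n_layers, n_heads, rng)
        self.var_encoder = _Encoder(family, hidden_size, n_layers, n_heads, rng)
        self.ffn1 = nn.Linear(2 * hidden_size, ffn_hidden, rng)
        self.ffn2 = nn.Linear(ffn_hidden, 1, rng)

    def __call__(self, base_oh, base_pe, var_oh, var_pe) -> nn.Tensor:
        e = nn.concat([self.base_encoder(nn.Tensor(base_oh), base_pe),
                       self.var_encoder(nn.Tensor(var_oh), var_pe)], axis=1)
        return self.ffn2(self.ffn1(e).relu()).reshape(-1)


class _SingleNet(nn.Module):
    """Single encoder + FFN head (the non-EVMP full-sequence baseline).
    The FFN head is excluded from the "encoder" for diagnostics."""

    def __init__(self, family: str, hidden_size: int, n_layers: int,
                 n_heads: int, ffn_hidden: int, rng: np.random.Generator):
        self.encoder = _Encoder(family, hidden_size, n_layers, n_heads, rng)
        self.ffn1 = nn.Linear(hidden_size, ffn_hidden, rng)
        self.ffn2 = nn.Linear(ffn_hidden, 1, rng)

    def __call__(self, oh, pe) -> nn.Tensor:
        return self.ffn2(
            self.ffn1(self.encoder(nn.Tensor(oh), pe)).relu()).reshape(-1)


def _fit_deep(net, inputs: tuple[np.ndarray, ...], y: np.ndarray,
              val_inputs: Optional[tuple[np.ndarray, ...]],
              y_val: Optional[np.ndarray], *, epochs: int, batch_size: int,
              learning_rate: float, weight_decay: float, patience: int,
              rng: np.random.Generator) -> list[dict]:
    """Shared minibatch L1 training loop with early stopping on val MAE.

    Returns the per-epoch history; leaves the network holding the
    best-validation parameters (or final parameters without validation).
    """
    n = len(y)
    opt = nn.Adam(net.parameters(), lr=learning_rate,
                  weight_decay=weight_decay)
    history: list[dict] = []
    best_val = np.inf
    best_state = [p.copy() for p in net.state_arrays()]
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = tuple(arr[idx] if arr is not None else None
                          for arr in inputs)
            pred = net(*batch)
            err = (pred - nn.Tensor(y[idx])).abs().mean()
            if not np.isfinite(err.value):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            err.backward()
            opt.step()
            epoch_loss += float(err.value) * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if val_inputs is not None:
            val_pred = _forward_numpy(net, val_inputs)
            val_mae = float(np.mean(np.abs(val_pred - y_val)))
            entry["val_mae"] = val_mae
            if val_mae < best_val - 1e-9:
                best_val = val_mae
                best_state = [p.copy() for p in net.state_arrays()]
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if val_inputs is not None and stale > patience:
            break
    if val_inputs is not None:
        net.load_state_arrays(best_state)
    return history


def _forward_numpy(net, inputs: tuple, batch_size: int = 512) -> np.ndarray:
    n = len(inputs[0])
    chunks = []
    for start in range(0, n, batch_size):
        batch = tuple(arr[start:start + batch_size] if arr is not None
                      else None for arr in inputs)
        chunks.append(net(*batch).value)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# estimators

class _DeepMixin:
    """Training/encoding machinery shared by the paired and baseline
    estimators (both expose the same evaluation interface)."""

    def _rng(self) -> np.random.Generator:
        return np.random.default_rng(self.random_state)

    def _make_classical(self):
        if self.family == "rf":
            return RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=self.random_state, n_jobs=1)
        if self.family == "gbdt":
            return GradientBoostingRegressor(
                n_estimators=self.n_estimators,
                random_state=self.random_state)
        if self.family == "xgboost":
            from xgboost import XGBRegressor
            return XGBRegressor(
                n_estimators=self.n_estimators,
                reg_lambda=self.weight_decay,
                random_state=self.random_state, n_jobs=1,
                verbosity=0)
        if self.family == "svm":
            return SVR(kernel="rbf", C=1.0)
        raise ValueError(f"unknown family {self.family!r}; choose from "
                         f"{DEEP_FAMILIES + CLASSICAL_FAMILIES}")

    @property
    def is_deep(self) -> bool:
        return self.family in DEEP_FAMILIES

    def _check_family(self) -> None:
        if self.family not in DEEP_FAMILIES + CLASSICAL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def _fit_core(self, inputs, y, val_inputs, y_val, make_net):
        y = np.asarray(y, dtype=float)
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        y_n = (y - self.y_mean_) / self.y_std_
        y_val_n = None
        if y_val is not None:
            y_val_n = (np.asarray(y_val, dtype=float) - self.y_mean_) / self.y_std_
        rng = self._rng()
        self.net_ = make_net(rng)
        self.history_ = _fit_deep(
            self.net_, inputs, y_n, val_inputs, y_val_n,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, patience=self.patience,
            rng=rng)

    def _predict_core(self, inputs) -> np.ndarray:
        return _forward_numpy(self.net_, inputs) * self.y_std_ + self.y_mean_

    def weights_norm_sq(self) -> float:
        """||w||^2 over all trainable parameters (deep families)."""
        if not self.is_deep:
            raise UnsupportedOperationError(
                "weights_norm_sq is only defined for deep families")
        return float(sum((p ** 2).sum() for p in self.net_.state_arrays()))


class EVMPRegressor(_DeepMixin, RegressorMixin, BaseEstimator):
    """Paired-encoder promoter-strength regressor over EVMP records.

    Parameters
    ----------
    family : {"lstm", "transformer", "rf", "gbdt", "xgboost", "svm"}
        Encoder family.  Deep families use separate BaseEncoder/VarEncoder
        streams over the base one-hot (+PE) and the Vars+PE mutation tensor;
        classical families use a single shared model over the concatenated
        base + Mask flat features.
    k : int
        k-mer window size of the records (must match the records given to
        ``fit``/``predict``).
    max_sites : int
        Site capacity of the Vars+PE tensor; records with more mutation
        sites are rejected.
    add_pe : bool
        Add sinusoidal PE to the BaseEncoder input (deep families).
    weight_decay : float
        The lambda of the L1 + lambda*||w||^2 objective; realised as
        decoupled weight decay for deep families and mapped to each
        classical family's native L2 analog (xgboost ``reg_lambda``; RF,
        GBDT and SVR keep their native regularisers).
    random_state : int
        Seed for parameter init, batch order and any classical-family
        randomness; fixed seeds give reproducible training.

    Attributes
    ----------
    net_ / model_ : the fitted deep network or classical regressor.
    history_ : per-epoch train loss and validation MAE (deep families).
    """

    def __init__(self, family: str = "rf", k: int = 5, max_sites: int = 18,
                 add_pe: bool = True, pe_mode: str = "projected",
                 hidden_size: int = 32,
                 n_layers: int = 2, n_heads: int = 4, ffn_hidden: int = 64,
                 epochs: int = 60, batch_size: int = 128,
                 learning_rate: float = 1e-2, weight_decay: float = 1e-5,
                 patience: int = 10, val_fraction: float = 0.1,
                 n_estimators: int = 200, random_state: int = 0):
        self.family = family
        self.k = k
        self.max_sites = max_sites
        self.add_pe = add_pe
        self.pe_mode = pe_mode
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_hidden = ffn_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.patience = patience
        self.val_fraction = val_fraction
        self.n_estimators = n_estimators
        self.random_state = random_state

    # -- encodings -----------------------------------------------------------
    def _deep_inputs(self, records: Sequence[EVMPRecord]) -> tuple:
        """Network inputs ``(base_oh, base_pe, var_oh, var_pe)``.

        The variant stream packs the k-row site blocks (ascending position)
        against the *end* of the ``k * max_sites`` window: an all-zero
        prefix leaves the recurrent state untouched, so right-alignment
        emulates variable-length packing and the final hidden state sits
        directly after the last real window.  With ``pe_mode="projected"``
        PE addends live at model width and are injected after the input
        projection; ``pe_mode="onehot"`` instead bakes the 5-channel PE
        into the one-hot rows (the raw Vars+PE tensor layout).
        """
        if self.pe_mode not in ("projected", "onehot"):
            raise ValueError(f"unknown pe_mode {self.pe_mode!r}")
        L = records[0].length
        k = self.k
        T = k * self.max_sites
        projected = self.pe_mode == "projected"
        d_pe = self.hidden_size if projected else N_CHANNELS
        pe_table = pe_matrix(L, PEConfig(d_pe=d_pe)) if self.add_pe else None

        base_cache: dict[str, np.ndarray] = {}
        bases = []
        for r in records:
            key = r.base.sequence
            if key not in base_cache:
                if projected or not self.add_pe:
                    base_cache[key] = one_hot(r.base.sequence)
                else:
                    base_cache[key] = encode_base(r.base, PEConfig(),
                                                  add_pe=True)
            bases.append(base_cache[key])
        base_oh = np.stack(bases)
        base_pe = None
        if projected and self.add_pe:
            base_pe = np.broadcast_to(pe_table, (len(records), L, d_pe))

        var_oh = np.zeros((len(records), T, N_CHANNELS))
        var_pe = np.zeros((len(records), T, d_pe)) if (projected and
                                                       self.add_pe) else None
        for n_rec, r in enumerate(records):
            if r.n_sites > self.max_sites:
                raise ValueError(
                    f"record {r.variant_id!r} has {r.n_sites} sites, "
                    f"exceeding max_sites={self.max_sites}")
            n = r.n_sites
            for j, m in enumerate(r.mutations):
                row = T - (n - j) * k
                block = one_hot(m.window)
                if projected:
                    if self.add_pe:
                        var_pe[n_rec, row:row + k] = pe_table[m.site.position]
                elif self.add_pe:
                    block = block + positional_encoding(m.site.position,
                                                        PEConfig())
                var_oh[n_rec, row:row + k] = block
        return base_oh, base_pe, var_oh, var_pe

    def _classical_inputs(self, records: Sequence[EVMPRecord]) -> np.ndarray:
        return np.stack([flatten_for_classical(r) for r in records])

    def _check_records(self, records: Sequence[EVMPRecord]) -> None:
        if not records:
            raise ValueError("no records given")
        for r in records:
            if r.k != self.k:
                raise ValueError(
                    f"record {r.variant_id!r} has k={r.k}, estimator expects "
                    f"k={self.k}")

    @staticmethod
    def _labels(records: Sequence[EVMPRecord], y) -> np.ndarray:
        if y is not None:
            return np.asarray(y, dtype=float)
        labels = [r.strength for r in records]
        if any(v is None for v in labels):
            raise ValueError("unlabeled records and no y given")
        return np.asarray(labels, dtype=float)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X: Sequence[EVMPRecord], y=None, *,
            X_val: Optional[Sequence[EVMPRecord]] = None, y_val=None):
        """Fit on EVMP records.  ``y`` defaults to the records' strengths.
        For deep families an explicit validation set (``X_val``/``y_val``)
        drives early stopping; without one, ``val_fraction`` of the
        training variants is held out internally."""
        self._check_family()
        self._check_records(X)
        y = self._labels(X, y)
        if not self.is_deep:
            self.model_ = self._make_classical()
            self.model_.fit(self._classical_inputs(X), y)
            self.history_ = []
            return self

        X = list(X)
        if X_val is None and self.val_fraction > 0 and len(X) >= 10:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
            X = [X[i] for i in train_idx]
            y = y[train_idx]
        val_inputs = self._deep_inputs(X_val) if X_val is not None else None
        y_val_arr = np.asarray(self._labels(X_val, y_val), dtype=float) \
            if X_val is not None else None

        def make_net(rng):
            return _PairedNet(self.family, self.hidden_size, self.n_layers,
                              self.n_heads, self.ffn_hidden, rng)

        self._fit_core(self._deep_inputs(X), y, val_inputs, y_val_arr,
                       make_net)
        return self

    def predict(self, X: Sequence[EVMPRecord]) -> np.ndarray:
        self._check_records(X)
        if self.is_deep:
            return self._predict_core(self._deep_inputs(X))
        return self.model_.predict(self._classical_inputs(X))

    def predictions(self, X: Sequence[EVMPRecord]) -> list[Prediction]:
        y_hat = self.predict(X)
        return [Prediction(r.variant_id, float(v), r.strength)
                for r, v in zip(X, y_hat)]

    # -- encoder-level ops ----------------------------------------------------
    def _require_deep(self) -> None:
        if not self.is_deep:
            raise UnsupportedOperationError(
                f"family {self.family!r} has no separate encoder streams")

    def embed_base(self, X: Sequence[EVMPRecord]) -> np.ndarray:
        """e_base = BaseEncoder(S) for each record, shape (n, hidden)."""
        self._require_deep()
        base_oh, base_pe, _, _ = self._deep_inputs(X)
        return self.net_.base_encoder(nn.Tensor(base_oh), base_pe).value

    def embed_vars(self, X: Sequence[EVMPRecord]) -> np.ndarray:
        """e_var = VarEncoder(M(S, S')) for each record, shape (n, hidden)."""
        self._require_deep()
        _, _, var_oh, var_pe = self._deep_inputs(X)
        return self.net_.var_encoder(nn.Tensor(var_oh), var_pe).value

    def layer_trace(self, X: Sequence[EVMPRecord]
                    ) -> list[tuple[str, np.ndarray]]:
        """Per-layer embeddings of the VarEncoder stream for over-smoothing
        diagnostics; layer 0 is the flattened raw Vars+PE tensor."""
        self._require_deep()
        cfg = PEConfig()
        raw = np.stack([encode_vars_pe(r, cfg, self.max_sites).ravel()
                        for r in X])
        _, _, var_oh, var_pe = self._deep_inputs(X)
        trace = [("input", raw)]
        trace.extend(self.net_.var_encoder.layer_outputs(var_oh, var_pe))
        return trace

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        _save_estimator(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "EVMPRegressor":
        return _load_estimator(cls, path)

    def _make_net_for_load(self, rng):
        return _PairedNet(self.family, self.hidden_size, self.n_layers,
                          self.n_heads, self.ffn_hidden, rng)


class FullSequenceRegressor(_DeepMixin, RegressorMixin, BaseEstimator):
    """Non-EVMP baseline: the same encoder families applied to the raw
    one-hot variant sequence (plus PE for deep families).  Shares the
    evaluation interface of :class:`EVMPRegressor`."""

    def __init__(self, family: str = "rf", add_pe: bool = True,
                 pe_mode: str = "projected",
                 hidden_size: int = 32, n_layers: int = 2, n_heads: int = 4,
                 ffn_hidden: int = 64, epochs: int = 60,
                 batch_size: int = 128, learning_rate: float = 1e-2,
                 weight_decay: float = 1e-5, patience: int = 10,
                 val_fraction: float = 0.1, n_estimators: int = 200,
                 random_state: int = 0):
        self.family = family
        self.add_pe = add_pe
        self.pe_mode = pe_mode
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_hidden = ffn_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.patience = patience
        self.val_fraction = val_fraction
        self.n_estimators = n_estimators
        self.random_state = random_state

    @staticmethod
    def _sequences(X) -> list[str]:
        seqs = []
        for item in X:
            seqs.append(item.sequence if isinstance(item, Promoter) else str(item))
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("all sequences must share the padded length")
        return seqs

    def _inputs(self, X) -> tuple:
        seqs = self._sequences(X)
        mats = np.stack([one_hot(s) for s in seqs])
        if not self.is_deep:
            return (mats.reshape(len(seqs), -1),)
        L = mats.shape[1]
        pe = None
        if self.add_pe:
            if self.pe_mode == "projected":
                table = pe_matrix(L, PEConfig(d_pe=self.hidden_size))
                pe = np.broadcast_to(table, (len(seqs), L, self.hidden_size))
            elif self.pe_mode == "onehot":
                mats = mats + pe_matrix(L)[None, :, :]
            else:
                raise ValueError(f"unknown pe_mode {self.pe_mode!r}")
        return (mats, pe)

    @staticmethod
    def _labels(X, y) -> np.ndarray:
        if y is not None:
            return np.asarray(y, dtype=float)
        labels = [p.strength if isinstance(p, Promoter) else None for p in X]
        if any(v is None for v in labels):
            raise ValueError("unlabeled promoters and no y given")
        return np.asarray(labels, dtype=float)

    def fit(self, X, y=None, *, X_val=None, y_val=None):
        self._check_family()
        if len(X) == 0:
            raise ValueError("no sequences given")
        y = self._labels(X, y)
        if not self.is_deep:
            self.model_ = self._make_classical()
            self.model_.fit(self._inputs(X)[0], y)
            self.history_ = []
            return self

        X = list(X)
        if X_val is None and self.val_fraction > 0 and len(X) >= 10:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
            X = [X[i] for i in train_idx]
            y = y[train_idx]
        val_inputs = self._inputs(X_val) if X_val is not None else None
        y_val_arr = np.asarray(self._labels(X_val, y_val), dtype=float) \
            if X_val is not None else None

        def make_net(rng):
            return _SingleNet(self.family, self.hidden_size, self.n_layers,
                              self.n_heads, self.ffn_hidden, rng)

        self._fit_core(self._inputs(X), y, val_inputs, y_val_arr, make_net)
        return self

    def predict(self, X) -> np.ndarray:
        if self.is_deep:
            return self._predict_core(self._inputs(X))
        return self.model_.predict(self._inputs(X)[0])

    def predictions(self, X) -> list[Prediction]:
        y_hat = self.predict(X)
        out = []
        for item, v in zip(X, y_hat):
            vid = item.id if isinstance(item, Promoter) else "<seq>"
            strength = item.strength if isinstance(item, Promoter) else None
            out.append(Prediction(vid, float(v), strength))
        return out

    def embed_base(self, X) -> np.ndarray:
        """Encoder embedding of the full sequence (the baseline "encoder"
        excludes the FFN head)."""
        if not self.is_deep:
            raise UnsupportedOperationError(
                f"family {self.family!r} has no encoder stream")
        mats, pe = self._inputs(X)
        return self.net_.encoder(nn.Tensor(mats), pe).value

    def layer_trace(self, X) -> list[tuple[str, np.ndarray]]:
        """Per-layer embeddings of the full-sequence stream, flattened
        one-hot (+5-channel PE if baked in) input first (layer 0)."""
        if not self.is_deep:
            raise UnsupportedOperationError(
                f"family {self.family!r} exposes no layer embeddings")
        mats, pe = self._inputs(X)
        trace = [("input", mats.reshape(len(X), -1))]
        trace.extend(self.net_.encoder.layer_outputs(mats, pe))
        return trace

    def save(self, path: str | Path) -> None:
        _save_estimator(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "FullSequenceRegressor":
        return _load_estimator(cls, path)

    def _make_net_for_load(self, rng):
        return _SingleNet(self.family, self.hidden_size, self.n_layers,
                          self.n_heads, self.ffn_hidden, rng)


# ---------------------------------------------------------------------------
# persistence (model archive directory: config + parameters + history)

def _save_estimator(est, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    config = {"class": type(est).__name__, "params": est.get_params()}
    (path / "config.json").write_text(json.dumps(config, indent=2))
    (path / "history.json").write_text(json.dumps(est.history_, indent=2))
    if est.is_deep:
        arrays = {f"p{i}": a for i, a in enumerate(est.net_.state_arrays())}
        np.savez(path / "weights.npz", y_mean=est.y_mean_, y_std=est.y_std_,
                 **arrays)
    else:
        with open(path / "model.pkl", "wb") as fh:
            pickle.dump(est.model_, fh)


def _load_estimator(cls, path: str | Path):
    path = Path(path)
    config = json.loads((path / "config.json").read_text())
    if config["class"] != cls.__name__:
        raise ValueError(
            f"archive holds a {config['class']}, not a {cls.__name__}")
    est = cls(**config["params"])
    est.history_ = json.loads((path / "history.json").read_text())
    if est.is_deep:
        data = np.load(path / "weights.npz")
        est.y_mean_ = float(data["y_mean"])
        est.y_std_ = float(data["y_std"])
        est.net_ = est._make_net_for_load(np.random.default_rng(0))
        n_params = len(est.net_.parameters())
        est.net_.load_state_arrays([data[f"p{i}"] for i in range(n_params)])
    else:
        with open(path / "model.pkl", "rb") as fh:
            est.model_ = pickle.load(fh)
    return est


def load_model(path: str | Path):
    """Load either estimator class from a model archive directory."""
    config = json.loads((Path(path) / "config.json").read_text())
    cls = {"EVMPRegressor": EVMPRegressor,
           "FullSequenceRegressor": FullSequenceRegressor}[config["class"]]
    return cls.load(path)


# ---------------------------------------------------------------------------
# functional wrappers

def train(records: Sequence[EVMPRecord], family: str = "rf",
          **config) -> EVMPRegressor:
    """Fit an :class:`EVMPRegressor` on labelled EVMP records."""
    return EVMPRegressor(family=family,
                         k=records[0].k if records else 5,
                         **config).fit(records)


def train_baseline(lib, family: str = "rf", **config) -> FullSequenceRegressor:
    """Fit the non-EVMP full-sequence baseline on a labelled library."""
    est = FullSequenceRegressor(family=family, **config)
    return est.fit(lib.variants)


def predict(model, records: Sequence[EVMPRecord]) -> list[Prediction]:
    """Per-record predictions from a fitted estimator."""
    return model.predictions(records)
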