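"""Numeric mutation representations: Vars+PE, Mask, and base encodings.

Two paradigms turn the k-mer mutation set M(S, S') into tensors:

* **Vars+PE** — the windows are stacked as one-hot rows and every one of the
  k rows of a window is shifted by the *same* sinusoidal positional encoding
  PE(p) of its mutation-site position p.  Listing windows destroys base
  order, so the PE carries the positional information.  Paired with the deep
  encoders by default.
* **Mask** — the variant is kept at full length but every position that
  appears in no window is blanked to B; base order is intact so no PE is
  needed.  Paired with the classical regressors by default.

All encoders here are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import EVMPRecord
from .seq import BLANK, N_CHANNELS, Promoter, one_hot


@dataclass(frozen=True)
class PEConfig:
    """Sinusoidal positional-encoding configuration.

    Channels alternate sin/cos on a geometric frequency ladder:
    ``PE(p)[2i] = sin(p / base^(2i/d))``, ``PE(p)[2i+1] = cos(...)``;
    for odd ``d_pe`` the last channel is a sin.  ``d_pe`` defaults to 5 so
    the encoding can be added directly to one-hot rows.
    """

    d_pe: int = N_CHANNELS
    wavelength_base: float = 10000.0

    def __post_init__(self) -> None:
        if self.d_pe < 1:
            raise ValueError("d_pe must be positive")


def positional_encoding(p: int, config: PEConfig = PEConfig()) -> np.ndarray:
    """PE(p) as a length-``d_pe`` vector with entries in [-1, 1]."""
    if p < 0:
        raise ValueError("position must be non-negative")
    d = config.d_pe
    i = np.arange(d)
    freq = config.wavelength_base ** (-(2 * (i // 2)) / d)
    angle = p * freq
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def pe_matrix(length: int, config: PEConfig = PEConfig()) -> np.ndarray:
    """Rows PE(0) .. PE(length-1), shape ``(length, d_pe)``."""
    return np.stack([positional_encoding(p, config) for p in range(length)])


def encode_vars_pe(
    record: EVMPRecord,
    config: PEConfig = PEConfig(),
    max_sites: int = 18,
) -> np.ndarray:
    """Vars+PE tensor of fixed shape ``(k * max_sites, d_pe)``.

    Site blocks are ordered by ascending position; block j holds the k
    one-hot rows of window j, each shifted by the identical PE of the
    mutation-site position.  Blocks past the actual site count are zero.
    ``d_pe`` must equal the one-hot channel count (5) for the additive
    composition.
    """
    if config.d_pe != N_CHANNELS:
        raise ValueError(
            f"d_pe must equal the one-hot channel count {N_CHANNELS} when PE "
            "is added at the one-hot level"
        )
    if record.n_sites > max_sites:
        raise ValueError(
            f"record {record.variant_id!r} has {record.n_sites} mutation "
            f"sites, exceeding max_sites={max_sites}; raise max_sites"
        )
    k = record.k
    out = np.zeros((k * max_sites, config.d_pe))
    for j, mut in enumerate(record.mutations):
        block = one_hot(mut.window) + positional_encoding(mut.site.position, config)
        out[j * k:(j + 1) * k] = block
    return out


def mask_string(record: EVMPRecord) -> str:
    """The masked variant as a string: window positions keep the variant
    base, everything else is B."""
    chars = [BLANK] * record.length
    for mut in record.mutations:
        for idx, char in zip(mut.indices(), mut.window):
            if 0 <= idx < record.length:
                chars[idx] = char
    return "".join(chars)


def encode_mask(record: EVMPRecord) -> np.ndarray:
    """Mask tensor of shape ``(L, 5)``: row j is the one-hot of the variant
    base if position j lies inside some k-mer window, else one-hot(B)."""
    return one_hot(mask_string(record))


def encode_base(
    base: Promoter,
    config: PEConfig = PEConfig(),
    add_pe: bool = False,
) -> np.ndarray:
    """One-hot of the base promoter, optionally with PE(p) added to each row
    (the BaseEncoder input for the deep families)."""
    mat = one_hot(base.sequence)
    if add_pe:
        if config.d_pe != N_CHANNELS:
            raise ValueError(
                f"d_pe must equal {N_CHANNELS} to add PE at the one-hot level"
            )
        mat = mat + pe_matrix(len(base.sequence), config)
    return mat


def save_representations(records, path_prefix, which: str = "both",
                         max_sites: int = 18,
                         config: PEConfig = PEConfig()) -> None:
    """Serialise encoded tensors for a record set: ``<prefix>.npz`` holding
    the stacked arrays plus a ``<prefix>.json`` sidecar describing shapes,
    channel layout and record ids."""
    import json
    from pathlib import Path

    records = list(records)
    if which not in ("vars_pe", "mask", "both"):
        raise ValueError(f"unknown representation {which!r}")
    arrays: dict[str, np.ndarray] = {}
    sidecar: dict = {
        "n_records": len(records),
        "variant_ids": [r.variant_id for r in records],
        "k": records[0].k if records else None,
        "channel_order": ["A", "T", "C", "G", "B"],
    }
    if which in ("vars_pe", "both"):
        arrays["vars_pe"] = np.stack(
            [encode_vars_pe(r, config, max_sites) for r in records])
        sidecar["vars_pe"] = {
            "shape": list(arrays["vars_pe"].shape),
            "layout": "k rows per site block, ascending site position, "
                      "zero-padded to max_sites blocks; one-hot + PE(site)",
            "max_sites": max_sites, "d_pe": config.d_pe,
        }
    if which in ("mask", "both"):
        arrays["mask"] = np.stack([encode_mask(r) for r in records])
        sidecar["mask"] = {
            "shape": list(arrays["mask"].shape),
            "layout": "one row per promoter position; variant base inside "
                      "windows, B outside",
        }
    prefix = Path(path_prefix)
    np.savez(prefix.with_suffix(".npz"), **arrays)
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def flatten_for_classical(record: EVMPRecord) -> np.ndarray:
    """Concatenated flat features for the shared-encoder classical families:
    base one-hot block first, Mask block second; length ``2 * L * 5``."""
    return np.concatenate([
        one_hot(record.base.sequence).ravel(),
        encode_mask(record).ravel(),
    ])
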