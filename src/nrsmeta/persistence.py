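"""Serialization of trained model bundles (.fcm files).

Binary container, little-endian throughout:

    magic "FCM2" | u16 format_version | u32 header JSON length | header JSON
    then per bundle:
        u32 bundle JSON length | bundle JSON
        per FCM table: u64 n_contexts | n int64 keys (sorted) | n*4 int64 counts

The header JSON carries tool_version, the reference snapshot hash, the
parameter digest of the mixture configuration and the bundle count; it can
be read without touching the count tables (``model_info``).  Keys are
written sorted, so save -> load -> save reproduces the file byte for byte.

Loading enforces compatibility: wrong magic, unknown format version or a
parameter digest differing from an expected configuration are rejected with
specific errors, so stale or mismatched models never reach the encoder.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import BinaryIO, Sequence

import numpy as np

from . import __version__
from .compressor import (
    MixtureConfig,
    ModelBundle,
    mixture_from_dict,
    mixture_to_dict,
    parameter_digest,
)
from .models import FCMCounts

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "ModelFileError",
    "save_bundle",
    "save_bundles",
    "load_bundle",
    "load_bundles",
    "model_info",
]

MAGIC = b"FCM2"
FORMAT_VERSION = 1


class ModelFileError(ValueError):
    """Raised when a model file is missing, malformed or incompatible."""


def _read_exact(fh: BinaryIO, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise ModelFileError(f"truncated model file while reading {what}")
    return data


def save_bundles(bundles: Sequence[ModelBundle], path: str | Path) -> None:
    """Write one or more trained bundles to a .fcm file (deterministic layout)."""
    if not bundles:
        raise ValueError("no bundles to save")
    header = {
        "tool_version": __version__,
        "format_version": FORMAT_VERSION,
        "n_bundles": len(bundles),
        "parameter_digest": parameter_digest(bundles[0].config).hex(),
        "labels": [b.label for b in bundles],
        "reference_hashes": [
            b.provenance.get("reference_hash", "") for b in bundles
        ],
        "n_models": len(bundles[0].config.models),
    }
    header_blob = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as out:
        out.write(MAGIC)
        out.write(struct.pack("<H", FORMAT_VERSION))
        out.write(struct.pack("<I", len(header_blob)))
        out.write(header_blob)
        for bundle in bundles:
            meta = {
                "label": bundle.label,
                "config": mixture_to_dict(bundle.config),
                "provenance": bundle.provenance,
            }
            blob = json.dumps(meta, sort_keys=True, separators=(",", ":")).encode()
            out.write(struct.pack("<I", len(blob)))
            out.write(blob)
            for counts in bundle.counts:
                keys, mat = counts.as_arrays()
                out.write(struct.pack("<Q", keys.size))
                out.write(keys.astype("<i8").tobytes())
                out.write(np.ascontiguousarray(mat, dtype="<i8").tobytes())


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    save_bundles([bundle], path)


def _read_header(fh: BinaryIO) -> dict:
    magic = _read_exact(fh, 4, "magic")
    if magic != MAGIC:
        raise ModelFileError("not a model file (bad magic)")
    (version,) = struct.unpack("<H", _read_exact(fh, 2, "format version"))
    if version != FORMAT_VERSION:
        raise ModelFileError(
            f"incompatible model version {version} (expected {FORMAT_VERSION})"
        )
    (hlen,) = struct.unpack("<I", _read_exact(fh, 4, "header length"))
    try:
        return json.loads(_read_exact(fh, hlen, "header"))
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"corrupt model header: {exc}") from exc


def load_bundles(
    path: str | Path, expected_config: MixtureConfig | None = None
) -> list[ModelBundle]:
    """Load every bundle in the file, verifying compatibility first."""
    if not Path(path).exists():
        raise FileNotFoundError(f"model file not found: {path}")
    bundles: list[ModelBundle] = []
    with open(path, "rb") as fh:
        header = _read_header(fh)
        if expected_config is not None:
            if header.get("parameter_digest") != parameter_digest(expected_config).hex():
                raise ModelFileError(
                    "model/parameters mismatch: the file was trained under a "
                    "different mixture configuration"
                )
        for _ in range(int(header["n_bundles"])):
            (blen,) = struct.unpack("<I", _read_exact(fh, 4, "bundle metadata length"))
            meta = json.loads(_read_exact(fh, blen, "bundle metadata"))
            config = mixture_from_dict(meta["config"])
            counts_list: list[FCMCounts] = []
            for idx in config.fcm_indices:
                (n_ctx,) = struct.unpack("<Q", _read_exact(fh, 8, "table size"))
                keys = np.frombuffer(
                    _read_exact(fh, 8 * n_ctx, "context keys"), dtype="<i8"
                )
                mat = np.frombuffer(
                    _read_exact(fh, 32 * n_ctx, "counts"), dtype="<i8"
                ).reshape(n_ctx, 4)
                counts = FCMCounts(config.models[idx].order)
                for k, row in zip(keys.tolist(), mat.tolist()):
                    counts.table[k] = list(row)
                counts.total_events = int(mat.sum())
                counts.as_arrays()
                counts_list.append(counts)
            bundles.append(
                ModelBundle(
                    label=meta["label"],
                    config=config,
                    counts=counts_list,
                    provenance=meta.get("provenance", {}),
                )
            )
        if fh.read(1):
            raise ModelFileError("trailing data after last bundle")
    return bundles


def load_bundle(
    path: str | Path, expected_config: MixtureConfig | None = None
) -> ModelBundle:
    bundles = load_bundles(path, expected_config)
    if len(bundles) != 1:
        raise ModelFileError(f"expected a single bundle, file holds {len(bundles)}")
    return bundles[0]


def model_info(path: str | Path) -> str:
    """Header-only metadata (never loads the count tables), one key: value per line."""
    if not Path(path).exists():
        raise FileNotFoundError(f"model file not found: {path}")
    with open(path, "rb") as fh:
        header = _read_header(fh)
    lines = [
        f"tool_version: {header.get('tool_version', '?')}",
        f"format_version: {header.get('format_version', '?')}",
        f"n_bundles: {header.get('n_bundles', '?')}",
        f"n_models: {header.get('n_models', '?')}",
        f"parameter_digest: {header.get('parameter_digest', '?')}",
    ]
    for label, ref_hash in zip(
        header.get("labels", []), header.get("reference_hashes", [])
    ):
        lines.append(f"bundle: {label} reference_hash: {ref_hash}")
    return "\n".join(lines) + "\n"
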