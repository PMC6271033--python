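"""Deterministic single-file model archives.

Layout: 8-byte magic, 8-byte little-endian manifest length, UTF-8 JSON
manifest (sorted keys), then the raw C-order little-endian array blocks in
manifest order.  Identical inputs produce identical bytes, which makes
rerun-to-rerun reproducibility checkable with a plain file compare.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_archive", "load_archive"]

_MAGIC = b"HSIARCH1"


def save_archive(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    entries = []
    blobs = []
    offset = 0
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        arr = arr.astype(arr.dtype.newbyteorder("<"), copy=False)
        blob = arr.tobytes()
        entries.append(
            {"name": name, "dtype": arr.dtype.str, "shape": list(arr.shape),
             "offset": offset, "nbytes": len(blob)}
        )
        blobs.append(blob)
        offset += len(blob)
    manifest = json.dumps(
        {"entries": entries, "meta": meta or {}}, sort_keys=True, separators=(",", ":")
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(manifest).to_bytes(8, "little"))
        fh.write(manifest)
        for blob in blobs:
            fh.write(blob)


def load_archive(path) -> tuple[dict[str, np.ndarray], dict]:
    data = Path(path).read_bytes()
    if data[:8] != _MAGIC:
        raise ValueError(f"{path} is not an hsiauth model archive")
    mlen = int.from_bytes(data[8:16], "little")
    manifest = json.loads(data[16 : 16 + mlen].decode())
    base = 16 + mlen
    arrays = {}
    for e in manifest["entries"]:
        start = base + e["offset"]
        arr = np.frombuffer(data[start : start + e["nbytes"]], dtype=np.dtype(e["dtype"]))
        arrays[e["name"]] = arr.reshape(e["shape"]).copy()
    return arrays, manifest.get("meta", {})
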