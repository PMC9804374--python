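"""TSV output with JSON metadata sidecars and content checksums."""

from __future__ import annotations

import hashlib
import json
import os
from typing import Any, Dict, Optional

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "file_sha256"]


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(path: str, frame: pd.DataFrame, metadata: Optional[Dict[str, Any]] = None) -> str:
    """Write a DataFrame as TSV plus a ``<path>.meta.json`` sidecar.

    The sidecar records the column list, row count, a sha256 of the TSV
    and any caller metadata; returns the checksum.
    """
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    digest = file_sha256(path)
    meta = {
        "columns": list(map(str, frame.columns)),
        "n_rows": int(len(frame)),
        "sha256": digest,
        **(metadata or {}),
    }
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return digest


def read_tsv(path: str, verify: bool = True) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, optionally verifying its checksum."""
    if verify and os.path.exists(path + ".meta.json"):
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        if meta.get("sha256") and meta["sha256"] != file_sha256(path):
            raise ValueError(f"checksum mismatch for {path} (file was modified)")
    return pd.read_csv(path, sep="\t")
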