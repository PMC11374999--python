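"""Canonical serialization and checksums for layer content.

Every layer payload is reduced to a canonical UTF-8 byte string before
hashing so that checksums are bit-reproducible across platforms and across
save/export round trips. Three payload shapes are supported:

* tabular (``pandas.DataFrame``) -> TSV with a fixed column order and rows
  sorted lexicographically by their serialized form;
* sequence mappings (``dict[str, str]``, e.g. FASTA-like content) -> ``>id``
  blocks sorted by id;
* plain text (``str``, e.g. a newick tree) -> the text itself.

SHA-256 is used throughout.
"""

from __future__ import annotations

import hashlib
import io
from typing import Union

import pandas as pd

Payload = Union[pd.DataFrame, "dict[str, str]", str]


def canonical_bytes(content: Payload) -> bytes:
    """Serialize *content* to its canonical byte representation."""
    if isinstance(content, pd.DataFrame):
        return _dataframe_bytes(content)
    if isinstance(content, dict):
        out = io.StringIO()
        for key in sorted(content):
            out.write(f">{key}\n{content[key]}\n")
        return out.getvalue().encode("utf-8")
    if isinstance(content, str):
        return content.encode("utf-8")
    raise TypeError(f"unsupported payload type: {type(content).__name__}")


def _dataframe_bytes(df: pd.DataFrame) -> bytes:
    # Column order is part of the canonical form: keep the frame's order so
    # re-serialization of an imported TSV is stable; sort rows by content.
    body = df.astype(str)
    rows = sorted("\t".join(r) for r in body.itertuples(index=False, name=None))
    header = "\t".join(str(c) for c in df.columns)
    return ("\n".join([header, *rows]) + "\n").encode("utf-8")


def checksum(content: Payload) -> str:
    """Hex SHA-256 digest of the canonical serialization of *content*."""
    return hashlib.sha256(canonical_bytes(content)).hexdigest()
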