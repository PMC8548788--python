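"""Packaged reference tables.

The published study tables travel with the package as checksummed CSV
fixtures: batch provenance and similarity/score/ranking (table1), the L9
orthogonal design (table2), calibration curves (table3), validation RSDs
(table4), the RCF robustness grid (table5), per-batch ESM/QAMS contents
(table6), the explained-variance table (table7) and the rotated loading /
score-coefficient matrices (table8).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

_DATA_DIR = "data"

FIXTURES = (
    "table1_batches",
    "table2_orthogonal",
    "table3_calibration",
    "table4_validation",
    "table5_rcf",
    "table6_contents",
    "table7_variance",
    "table8_loadings",
)


def _read_bytes(filename: str) -> bytes:
    return resources.files("herbqc").joinpath(_DATA_DIR, filename).read_bytes()


def list_fixtures() -> list[str]:
    return list(FIXTURES)


def load_fixture(name: str, verify: bool = True) -> pd.DataFrame:
    """Load a named fixture table, verifying its sha256 checksum.

    Raises KeyError (listing the available names) for unknown fixtures and
    ValueError on checksum mismatch.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    raw = _read_bytes(f"{name}.csv")
    if verify:
        expected = json.loads(_read_bytes("checksums.json"))[f"{name}.csv"]
        digest = hashlib.sha256(raw).hexdigest()
        if digest != expected:
            raise ValueError(f"fixture {name!r} failed its checksum")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))
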