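"""Packaged reliability datasets and plain-text loaders.

Four classic univariate lifetime samples ship as text resources:

- ``failure_times``   : 84 failure times of aircraft windshields (1000 h units)
- ``gauge_lengths``   : 63 gauge-length (10 mm) strength observations of
  single carbon fibres (GPa)
- ``strength``        : 63 strength measurements of glass fibres
- ``student_grades``  : mathematics scores of 48 students in a slow-pace
  program

User data is read with :func:`read_numeric_vector`: comma- or
whitespace-separated finite reals, one optional header line.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np

from .nlw import DataSample

__all__ = ["DATASET_KEYS", "load_dataset", "read_numeric_vector"]

_EXPECTED_N = {
    "failure_times": 84,
    "gauge_lengths": 63,
    "strength": 63,
    "student_grades": 48,
}

DATASET_KEYS = tuple(_EXPECTED_N)


def load_dataset(key: str) -> DataSample:
    """Return one of the packaged datasets as an immutable DataSample."""
    if key not in _EXPECTED_N:
        raise KeyError(
            f"unknown dataset {key!r}; available: {', '.join(DATASET_KEYS)}")
    text = resources.files("lomaxg.data").joinpath(f"{key}.txt").read_text()
    values = np.array(text.split(), dtype=float)
    values.setflags(write=False)
    if values.size != _EXPECTED_N[key]:
        raise RuntimeError(f"packaged dataset {key} is corrupted: "
                           f"expected {_EXPECTED_N[key]} values, got {values.size}")
    return DataSample(values=values, name=key)


_TOKEN_RE = re.compile(r"[,\s]+")


def read_numeric_vector(path, name: str | None = None) -> DataSample:
    """Read an order-preserving numeric vector from a text file.

    Tokens may be separated by commas and/or whitespace.  A single
    non-numeric header line is skipped automatically.  Unparseable
    tokens raise a ValueError naming the token and its position.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    values: list[float] = []
    start = 0
    if lines:
        head = [t for t in _TOKEN_RE.split(lines[0]) if t]
        if head and not all(_is_number(t) for t in head):
            start = 1  # header line
    for ln, line in enumerate(lines[start:], start=start + 1):
        for col, tok in enumerate(t for t in _TOKEN_RE.split(line) if t):
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: cannot parse token {tok!r} "
                    f"(line {ln}, token {col + 1})") from None
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite value {tok!r} at line {ln}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return DataSample(values=np.array(values), name=name or str(path))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True
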