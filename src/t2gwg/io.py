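"""Dataset I/O and synthetic fixture generation.

Lifetime datasets are one numeric column: plain text (one value per line,
``#`` comments allowed) or CSV with a named column.  Three classic
reliability/survival datasets used throughout the lifetime-distribution
literature ship with the package as plain-text transcriptions from the
published articles (see :func:`load_dataset`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimation import METHODS
from .families import get_family

__all__ = ["LifetimeDataset", "read_lifetimes", "make_fixture", "load_dataset",
           "DATASETS"]

#: packaged datasets, transcribed from the published literature:
#: aarset    — lifetimes of 50 devices (Aarset 1987);
#: meeker    — running times of 30 devices (Meeker & Escobar 1998);
#: chemo     — survival times in years of 45 chemotherapy-only patients
#:             (Bekker, Roux & Mostert 2000)
DATASETS = ("aarset", "meeker", "chemo")


@dataclass(frozen=True)
class LifetimeDataset:
    """A sample of positive, fully observed lifetimes."""

    values: np.ndarray
    label: str = ""
    source: str = "synthetic"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("lifetimes must be positive and finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


def _validate_lines(values: np.ndarray, origin: str) -> None:
    bad = np.flatnonzero(~np.isfinite(values) | (values <= 0))
    if bad.size:
        lines = ", ".join(str(i + 1) for i in bad[:10])
        raise ValueError(
            f"{origin}: nonpositive or non-finite lifetimes at data line(s) {lines}")


def read_lifetimes(path: Union[str, Path], column: Optional[str] = None) -> LifetimeDataset:
    """Read a lifetime dataset from plain text or CSV.

    Plain text: one value per line, ``#`` comments skipped.  CSV: the
    ``column`` argument names the column; with a single numeric column it
    may be omitted.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines()
                  if ln.strip() and not ln.strip().startswith("#")), "")
    is_csv = ("," in first) or (column is not None)
    if is_csv:
        df = pd.read_csv(_io.StringIO(text), comment="#")
        if column is None:
            numeric = df.select_dtypes("number").columns
            if len(numeric) != 1:
                raise ValueError(f"{path}: specify 'column'; candidates: {list(df.columns)}")
            column = numeric[0]
        if column not in df.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        values = df[column].to_numpy(dtype=float)
    else:
        rows = [ln.strip() for ln in text.splitlines()
                if ln.strip() and not ln.strip().startswith("#")]
        try:
            values = np.array([float(r) for r in rows])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry ({exc})") from None
    _validate_lines(values, str(path))
    return LifetimeDataset(values=values, label=path.stem, source=str(path))


def load_dataset(name: str) -> LifetimeDataset:
    """Load one of the packaged literature datasets (see :data:`DATASETS`)."""
    if name not in DATASETS:
        raise ValueError(f"unknown dataset {name!r}; available: {DATASETS}")
    text = resources.files("t2gwg").joinpath(f"data/{name}.txt").read_text()
    values = np.array([float(ln) for ln in text.splitlines()
                       if ln.strip() and not ln.startswith("#")])
    return LifetimeDataset(values=values, label=name, source="packaged")


def make_fixture(family: str, params: Sequence[float], n: int,
                 seed: Optional[int] = None,
                 path: Optional[Union[str, Path]] = None) -> LifetimeDataset:
    """Draw a synthetic lifetime sample from a registered family.

    Deterministic under ``seed``; optionally written to ``path`` in the
    plain-text format read back by :func:`read_lifetimes` (17 significant
    digits, lossless round trip).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fam = get_family(family)
    model = fam.make(np.asarray(params, dtype=float))
    values = model.rvs(n, seed=seed)
    ds = LifetimeDataset(values=values, label=f"{family}-fixture", source="synthetic")
    if path is not None:
        header = f"# synthetic fixture: family={family} params={list(map(float, params))} n={n} seed={seed}\n"
        body = "\n".join(f"{v:.17g}" for v in ds.values)
        Path(path).write_text(header + body + "\n")
    return ds
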