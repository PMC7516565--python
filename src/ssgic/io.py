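"""Reading tabular datasets (CSV/TSV with header) into :class:`Dataset`."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .losses import Dataset

__all__ = ["read_dataset", "write_dataset"]


def read_dataset(path: str | Path, response: str = "y") -> Dataset:
    """Load a delimited file: the ``response`` column is y, all other
    numeric columns are predictors in file order. Tab-delimited files are
    detected by the ``.tsv`` suffix."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    y = df[response].to_numpy(dtype=float)
    Xdf = df.drop(columns=[response])
    return Dataset(Xdf.to_numpy(dtype=float), y, feature_names=list(Xdf.columns))


def write_dataset(data: Dataset, path: str | Path, response: str = "y") -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df[response] = data.y.astype(int) if set(data.y) <= {0.0, 1.0} else data.y
    df.to_csv(path, sep=sep, index=False)
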