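"""Delimited-text table I/O with a reproducibility header.

All pipeline outputs are plain TSV (or CSV) with leading ``#``-prefixed
header lines recording at minimum the seed and package version, so any
table is self-describing and re-runnable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FORMATS = {"tsv": "\t", "csv": ","}
FLOAT_FORMAT = "%.12g"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
    header: dict | None = None,
    index: bool = False,
) -> Path:
    path = Path(path)
    sep = FORMATS[fmt]
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=index, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    return pd.read_csv(path, sep=FORMATS[fmt], comment="#")
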