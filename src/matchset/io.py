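"""Count-table and metadata input/output.

The canonical on-disk format is a TSV/CSV count table with a header row of
OTU identifiers and a first column of sample identifiers (samples x OTUs);
transposed input is accepted with an orientation flag.  Metadata is a CSV
with a ``sample_id`` column; rows are re-indexed to the count-table sample
order, which is the single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MatchedDesign, Submodel

__all__ = ["CountTable", "read_count_table", "read_metadata", "write_results"]


@dataclass
class CountTable:
    """Samples x OTUs non-negative integer count matrix with identifiers."""

    counts: np.ndarray
    sample_ids: list
    otu_ids: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (samples x OTUs)")
        if not np.all(np.isfinite(c.astype(float))):
            raise ValueError("counts must be finite")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        self.counts = c
        self.sample_ids = list(self.sample_ids)
        self.otu_ids = list(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def read_count_table(path, orientation: str = "samples_x_otus") -> CountTable:
    """Read a TSV/CSV count table; ``orientation="otus_x_samples"`` transposes."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "otus_x_samples":
        df = df.T
    elif orientation != "samples_x_otus":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in count table {path}: {exc}") from exc
    if np.any(values < 0):
        raise ValueError("negative counts in table")
    return CountTable(values, [str(s) for s in df.index], [str(o) for o in df.columns])


def _expand_categorical(col: pd.Series, name: str) -> np.ndarray:
    """Indicator columns for a categorical variable; first observed level is reference."""
    levels = list(dict.fromkeys(col))
    out = np.zeros((len(col), len(levels) - 1))
    for j, lv in enumerate(levels[1:]):
        out[:, j] = (col == lv).to_numpy(dtype=float)
    if out.shape[1] == 0:
        raise ValueError(f"variable {name!r} is constant")
    return out


def read_metadata(
    path,
    set_id_col: str,
    variable_cols: list[str],
    confounder_cols: list[str] | None = None,
    sample_order: list | None = None,
    sample_id_col: str = "sample_id",
    adjust_set_id: bool = True,
) -> MatchedDesign:
    """Read a metadata CSV into a :class:`MatchedDesign`.

    ``variable_cols`` are the tested submodels, in testing order; categorical
    columns are expanded to indicator columns.  When ``sample_order`` (usually
    the count-table sample ids) is given, rows are aligned to it and a missing
    sample is an error.
    """
    df = pd.read_csv(path)
    if sample_id_col not in df.columns:
        raise ValueError(f"metadata lacks a {sample_id_col!r} column")
    df[sample_id_col] = df[sample_id_col].astype(str)
    if df[sample_id_col].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    df = df.set_index(sample_id_col)
    if sample_order is not None:
        missing = [s for s in sample_order if str(s) not in df.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        df = df.loc[[str(s) for s in sample_order]]

    def to_submodels(cols: list[str]) -> list[Submodel]:
        out = []
        for name in cols:
            if name not in df.columns:
                raise ValueError(f"metadata lacks column {name!r}")
            col = df[name]
            if col.isna().any():
                raise ValueError(f"missing values in variable {name!r}")
            if col.dtype == object or str(col.dtype) == "category":
                out.append(Submodel(name, _expand_categorical(col, name)))
            else:
                out.append(Submodel(name, col.to_numpy(dtype=float)))
        return out

    return MatchedDesign(
        sample_ids=list(df.index),
        set_ids=df[set_id_col].to_numpy(),
        submodels=to_submodels(variable_cols),
        confounders=to_submodels(confounder_cols or []),
        adjust_set_id=adjust_set_id,
    )


def write_results(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a results table as TSV with run metadata in header comments.

    Floats are written at six significant digits; identical runs produce
    identical files.
    """
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    return pd.read_csv(path, sep="\t", comment="#")
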