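"""Reading and writing abundance tables and coefficient matrices.

Tables are delimited text (tab or comma, auto-detected from the file
extension) with a header row and an ID column.  Counts or proportions are
converted to row compositions; zeros must be explicit because compositional
zeros carry information, so missing cells are an error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simplex import CoefficientMatrix, CompositionTable

logger = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_table(path, orientation: str = "samples-by-features",
               normalize: bool = True) -> CompositionTable:
    """Read a delimited abundance table into a CompositionTable.

    Parameters
    ----------
    path
        TSV or CSV file with a header row and leading ID column.
    orientation
        ``"samples-by-features"`` (rows are samples) or
        ``"features-by-samples"`` (the file is transposed).
    normalize
        Divide each sample row by its total (counts -> proportions).
    """
    if orientation not in ("samples-by-features", "features-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "features-by-samples":
        frame = frame.T
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs: {dups}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if np.any(np.isnan(values)):
        raise ValueError(
            f"missing values in {path}; compositional zeros must be explicit")
    if np.any(values < 0):
        raise ValueError(f"negative entries in {path}")
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        bad = [str(frame.index[i]) for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    if normalize:
        values = values / totals[:, None]
    return CompositionTable(values,
                            sample_ids=[str(i) for i in frame.index],
                            feature_ids=[str(c) for c in frame.columns])


def align_tables(x: CompositionTable, y: CompositionTable):
    """Inner-join two tables on sample IDs, in x's row order.

    Returns the aligned ``(x, y)`` pair and logs any dropped samples.
    """
    common = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if not common:
        raise ValueError("tables share no sample IDs")
    dropped = (set(x.sample_ids) | set(y.sample_ids)) - set(common)
    if dropped:
        logger.warning("dropping %d unmatched sample(s): %s",
                       len(dropped), sorted(dropped))
    xi = [x.sample_ids.index(s) for s in common]
    yi = [y.sample_ids.index(s) for s in common]
    return (
        CompositionTable(x.values[xi], sample_ids=common, feature_ids=list(x.feature_ids)),
        CompositionTable(y.values[yi], sample_ids=common, feature_ids=list(y.feature_ids)),
    )


def write_coefficients(B: CoefficientMatrix, path, centered: bool = False) -> None:
    """Write a coefficient matrix as a labelled delimited table.

    With ``centered=True`` the barycenter 1/q is subtracted from every entry
    (the deviation matrix is the meaningful object to visualize, since the
    raw columns all sum to one).
    """
    B.to_dataframe(centered=centered).to_csv(path, sep=_sep_for(path))


def read_coefficients(path, centered: bool = False) -> CoefficientMatrix:
    """Read a coefficient matrix written by :func:`write_coefficients`."""
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = frame.to_numpy(dtype=float)
    if centered:
        values = values + 1.0 / values.shape[0]
    return CoefficientMatrix(values,
                             row_ids=[str(i) for i in frame.index],
                             col_ids=[str(c) for c in frame.columns])


def write_table(table: CompositionTable, path) -> None:
    """Write a composition table as delimited text (samples by features)."""
    table.to_dataframe().to_csv(path, sep=_sep_for(path))


def write_provenance(path, command: str, params: dict, seed, version: str) -> None:
    """Record how a result was produced (command, config echo, seed)."""
    record = {"command": command, "params": params, "seed": seed,
              "package": "cocreg", "version": version}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
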