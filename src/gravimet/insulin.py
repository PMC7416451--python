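"""Composite OGTT/C-peptide insulin-sensitivity index.

The index is a scaled variant of the Radaelli OGTT composite,

    IS = 1000 / sqrt(FPG * FCP * G * C)

where FPG and FCP are fasting plasma glucose (mmol/l) and fasting
C-peptide (ug/l), and G and C are the means of the fasting and 1 h
glucose and C-peptide values.  Units are taken as given; the index is
dimensionless up to the 1000 scaling and strictly decreasing in every
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OGTTRecord", "is_ogtt_cpep", "index_table"]

#: column names expected in a subjects table carrying OGTT measurements
OGTT_COLUMNS = ("fpg", "g1h", "fcp", "cp1h")


@dataclass(frozen=True)
class OGTTRecord:
    """Per-subject OGTT measurements.

    Attributes
    ----------
    fpg : float
        Fasting plasma glucose, mmol/l.
    g1h : float
        1 h plasma glucose, mmol/l.
    fcp : float
        Fasting C-peptide, ug/l.
    cp1h : float
        1 h C-peptide, ug/l.
    """

    fpg: float
    g1h: float
    fcp: float
    cp1h: float

    def validate(self) -> None:
        for name in OGTT_COLUMNS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"OGTT component {name!r} must be positive and finite, got {v!r}")


def is_ogtt_cpep(rec: OGTTRecord) -> float:
    """Insulin-sensitivity index from one OGTT record.

    Returns ``1000 / sqrt(fpg * fcp * G * C)`` with ``G = (fpg + g1h)/2``
    and ``C = (fcp + cp1h)/2``.  Raises :class:`ValueError` naming the
    offending field for non-positive or non-finite inputs.
    """
    rec.validate()
    g_mean = 0.5 * (rec.fpg + rec.g1h)
    c_mean = 0.5 * (rec.fcp + rec.cp1h)
    return 1000.0 / math.sqrt(rec.fpg * rec.fcp * g_mean * c_mean)


def _index_vector(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised index + validity mask over a subjects table."""
    vals = {c: df[c].to_numpy(dtype=float) for c in OGTT_COLUMNS}
    valid = np.ones(len(df), dtype=bool)
    for c in OGTT_COLUMNS:
        valid &= np.isfinite(vals[c]) & (vals[c] > 0)
    g_mean = 0.5 * (vals["fpg"] + vals["g1h"])
    c_mean = 0.5 * (vals["fcp"] + vals["cp1h"])
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = 1000.0 / np.sqrt(vals["fpg"] * vals["fcp"] * g_mean * c_mean)
    idx[~valid] = np.nan
    return idx, valid


def index_table(subjects: pd.DataFrame, log: bool = False) -> tuple[pd.DataFrame, int]:
    """Join the insulin-sensitivity index onto a subjects table.

    Parameters
    ----------
    subjects
        Table with columns ``fpg, g1h, fcp, cp1h`` (one OGTT record per row).
    log
        If True, append ``log_is_ogtt_cpep`` (natural log) as well; the
        scale on which the index is analysed downstream is configurable.

    Returns
    -------
    (table, n_excluded)
        Copy of the input with an ``is_ogtt_cpep`` column, rows with
        invalid OGTT values dropped, and the count of exclusions.
    """
    missing = [c for c in OGTT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table lacks OGTT columns: {missing}")
    idx, valid = _index_vector(subjects)
    out = subjects.copy()
    out["is_ogtt_cpep"] = idx
    n_excluded = int((~valid).sum())
    out = out.loc[valid].copy()
    if log:
        out["log_is_ogtt_cpep"] = np.log(out["is_ogtt_cpep"].to_numpy())
    return out, n_excluded
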