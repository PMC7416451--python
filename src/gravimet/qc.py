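"""Metabolite matrix container and preprocessing.

Preprocessing follows the study protocol for a mixed targeted /
non-targeted metabolomics panel: class-specific log transforms,
per-batch median centring (a simple stand-in for QC-pool based batch
correction), a single-pass >=5 SD outlier screen computed on observed
cells, and exclusion of subjects with more than ten outlying
metabolites.  Censored (below-detection) cells are carried as NaN with
an explicit mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteMatrix",
    "OutlierReport",
    "apply_transforms",
    "mask_outliers",
    "exclude_outlier_subjects",
    "batch_center",
    "delta_matrix",
]

#: metabolite classes used for network colouring and transform rules
METABOLITE_CLASSES = (
    "amino acid",
    "acylcarnitine",
    "fatty acid",
    "carbohydrate",
    "organic acid",
    "lipid",
)

#: transform rule: natural log for these targeted classes/names
_LN_CLASSES = {"acylcarnitine"}
_LN_NAMES = {"3-OHB", "3_ohb", "3ohb"}


@dataclass
class MetaboliteMatrix:
    """Subjects x metabolites abundance matrix with censoring mask.

    Attributes
    ----------
    values : DataFrame
        Abundances; NaN marks censored (below detection) or masked cells.
    meta : DataFrame
        Per-metabolite metadata indexed like ``values.columns`` with at
        least columns ``class`` and ``arm`` (targeted | nontargeted |
        clinical).
    timepoint : str
        "fasting", "1h" or "delta".
    transform : str
        "raw", "transformed" or "delta"; double-transforming is rejected.
    batch : Series
        Per-subject batch label aligned to ``values.index``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    timepoint: str
    transform: str = "raw"
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            raise ValueError("meta index must match value columns")
        if self.batch is not None and not self.batch.index.equals(self.values.index):
            raise ValueError("batch labels must align with subject index")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-cell indicator."""
        return self.values.notna()

    def copy(self) -> "MetaboliteMatrix":
        return replace(
            self,
            values=self.values.copy(),
            meta=self.meta.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )


@dataclass
class OutlierReport:
    """Result of the 5 SD outlier screen."""

    per_metabolite: pd.Series
    per_subject: pd.Series
    skipped: list = field(default_factory=list)
    n_nonpositive_logged: int = 0

    @property
    def n_masked(self) -> int:
        return int(self.per_metabolite.sum())


def _ln_columns(meta: pd.DataFrame) -> pd.Index:
    cls = meta["class"].astype(str)
    lower_names = pd.Index(meta.index.astype(str)).str.lower()
    is_targeted = meta["arm"].isin(["targeted", "clinical"]).to_numpy()
    take = is_targeted & (cls.isin(_LN_CLASSES).to_numpy() | lower_names.isin(_LN_NAMES))
    return meta.index[take]


def apply_transforms(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, int]:
    """Apply class-specific log transforms.

    Natural log for acylcarnitines and 3-OHB; log2 for non-targeted peak
    areas; all other targeted/clinical metabolites pass through.
    Non-positive values scheduled for a log are set censored; the count
    is returned alongside the transformed matrix.
    """
    if m.transform != "raw":
        raise ValueError(f"matrix already transformed (state={m.transform!r})")
    out = m.copy()
    n_bad = 0
    ln_cols = _ln_columns(out.meta)
    log2_cols = out.meta.index[out.meta["arm"] == "nontargeted"]
    for cols, fn in ((ln_cols, np.log), (log2_cols, np.log2)):
        if len(cols) == 0:
            continue
        block = out.values[cols].to_numpy(dtype=float)
        bad = np.isfinite(block) & (block <= 0)
        n_bad += int(bad.sum())
        block[bad] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            out.values[cols] = fn(block)
    out.transform = "transformed"
    return out, n_bad


def mask_outliers(m: MetaboliteMatrix, sd_cut: float = 5.0) -> tuple[MetaboliteMatrix, OutlierReport]:
    """Single-pass outlier screen: mask cells >= ``sd_cut`` SDs from the mean.

    Means and SDs are computed over observed cells only; the screen is
    not iterated after masking.  Metabolites with fewer than 3 observed
    values are skipped; SD=0 columns produce no masks.
    """
    if m.transform == "raw":
        raise ValueError("apply transforms before outlier screening")
    out = m.copy()
    vals = out.values.to_numpy(dtype=float)
    n_obs = np.isfinite(vals).sum(axis=0)
    mu = np.nanmean(np.where(np.isfinite(vals), vals, np.nan), axis=0, keepdims=True)
    sd = np.nanstd(np.where(np.isfinite(vals), vals, np.nan), axis=0, ddof=1, keepdims=True)
    skipped = [c for c, n in zip(out.values.columns, n_obs) if n < 3]
    with np.errstate(invalid="ignore"):
        z_ok = sd > 0
        dev = np.abs(vals - mu)
        flag = np.isfinite(vals) & z_ok & (dev >= sd_cut * sd)
    flag[:, n_obs < 3] = False
    vals = vals.copy()
    vals[flag] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    report = OutlierReport(
        per_metabolite=pd.Series(flag.sum(axis=0), index=out.values.columns, name="n_outliers"),
        per_subject=pd.Series(flag.sum(axis=1), index=out.values.index, name="n_outliers"),
        skipped=skipped,
    )
    return out, report


def exclude_outlier_subjects(
    m: MetaboliteMatrix, report: OutlierReport, max_outliers: int = 10
) -> tuple[MetaboliteMatrix, list]:
    """Drop subjects with strictly more than ``max_outliers`` outlying metabolites."""
    per_subject = report.per_subject.reindex(m.values.index).fillna(0)
    removed = list(per_subject.index[per_subject > max_outliers])
    out = m.copy()
    out.values = out.values.drop(index=removed)
    if out.batch is not None:
        out.batch = out.batch.drop(index=removed)
    return out, removed


def batch_center(m: MetaboliteMatrix, arms=None) -> MetaboliteMatrix:
    """Per metabolite, subtract the batch median and add back the grand median.

    ``arms`` restricts centring to the named assay arms (e.g. only the
    batch-sensitive non-targeted GC-MS features); None centres every
    metabolite.  Batches with zero observed values for a metabolite are
    left untouched for that metabolite, as are all-censored metabolites.
    """
    if m.batch is None:
        raise ValueError("batch labels required for batch centring")
    out = m.copy()
    cols = out.values.columns if arms is None else out.meta.index[out.meta["arm"].isin(arms)]
    vals = out.values[cols]
    grand = vals.median(axis=0, skipna=True)
    batch_med = vals.groupby(out.batch, observed=True).transform("median")
    adjusted = vals - batch_med + grand
    # cells in a batch with no observed values keep their original value
    out.values[cols] = adjusted.where(batch_med.notna(), vals)
    return out


def delta_matrix(fasting: MetaboliteMatrix, one_hour: MetaboliteMatrix) -> MetaboliteMatrix:
    """Cellwise 1 h minus fasting; a cell is observed only if both are.

    Panels must match in subjects, metabolites and transform state.
    """
    problems = []
    if not fasting.values.index.equals(one_hour.values.index):
        problems.append("subject index mismatch")
    if not fasting.values.columns.equals(one_hour.values.columns):
        problems.append("metabolite panel mismatch")
    if fasting.transform != one_hour.transform:
        problems.append(
            f"transform state mismatch ({fasting.transform!r} vs {one_hour.transform!r})"
        )
    if problems:
        raise ValueError("; ".join(problems))
    return MetaboliteMatrix(
        values=one_hour.values - fasting.values,
        meta=fasting.meta.copy(),
        timepoint="delta",
        transform="delta",
        batch=None if fasting.batch is None else fasting.batch.copy(),
    )
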