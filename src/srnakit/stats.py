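"""Sample merging, normalization, detection and differential expression.

Per-sample four-column count files (DB, Name, ID, Count) are merged into a
molecule x sample matrix; counts-per-million rescales each library to 10^6;
the detection filter flags molecules with raw count >= 5 (the default
threshold); and case/control differential expression uses the two-sided
Mann-Whitney U (Wilcoxon rank-sum) test per molecule, with optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotate import read_count_table

#: Raw-count detection threshold: a molecule is "detected" in a sample when
#: its read count is at least this.
DEFAULT_DETECTION_THRESHOLD = 5

META_COLUMNS = ["DB", "Name", "ID"]


def merge_samples(
    samples: Sequence[tuple[str, "str | pd.DataFrame"]],
) -> pd.DataFrame:
    """Merge per-sample count files into one molecule x sample matrix.

    ``samples`` is an ordered list of ``(sample_name, path_or_table)``. Rows
    are the union of molecules (keyed by DB, Name, ID) across samples; a
    molecule absent from a sample gets count 0. Column order follows input
    order. The result has a (DB, Name, ID) MultiIndex and one integer column
    per sample.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    names = [name for name, _ in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    columns = []
    for name, source in samples:
        table = read_count_table(source) if isinstance(source, str) else source.copy()
        if table["Count"].lt(0).any():
            raise ValueError(f"sample {name}: negative counts")
        if table.duplicated(subset=META_COLUMNS).any():
            raise ValueError(f"sample {name}: duplicate molecule rows")
        columns.append(table.set_index(META_COLUMNS)["Count"].rename(name))
    merged = pd.concat(columns, axis=1, join="outer").fillna(0)
    return merged.astype(int)


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: rescale each sample column to sum to 10^6."""
    sums = table.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, zero.index))}")
    return table / sums * 1e6


def detection_filter(
    table: pd.DataFrame, threshold: int = DEFAULT_DETECTION_THRESHOLD
) -> pd.DataFrame:
    """Boolean detection matrix on raw counts: detected iff count >= threshold."""
    return table >= threshold


def detected_sets(
    table: pd.DataFrame, threshold: int = DEFAULT_DETECTION_THRESHOLD
) -> dict[str, set]:
    """Per-sample sets of detected molecule keys."""
    det = detection_filter(table, threshold)
    return {col: set(det.index[det[col]]) for col in det.columns}


def mann_whitney_row(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for one molecule; returns (U, p).

    The exact null distribution is used when both groups are small
    (min(n) <= 8) and the pooled values are tie-free; otherwise the normal
    approximation with tie and continuity corrections. An all-constant row is
    non-discriminating by construction: p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties or min(len(x), len(y)) > 8 else "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_de(
    table: pd.DataFrame,
    case: Sequence[str],
    control: Sequence[str],
    normalize: "str | None" = "cpm",
) -> pd.DataFrame:
    """Case-versus-control differential expression, one test per molecule.

    ``normalize="cpm"`` (the default pipeline behaviour) tests CpM-normalized
    values; ``normalize=None`` tests raw counts. The returned table carries
    the U statistic (case group), two-sided p, group medians, the direction of
    the median difference (+1 case-higher, -1 control-higher, 0 tied) and a
    ``constant`` flag for rows with no variation.
    """
    if not case or not control:
        raise ValueError("need at least one case and one control sample")
    missing = [s for s in list(case) + list(control) if s not in table.columns]
    if missing:
        raise ValueError(f"unknown sample(s): {missing}")
    if set(case) & set(control):
        raise ValueError("a sample cannot be both case and control")
    values = cpm_normalize(table) if normalize == "cpm" else table
    rows = []
    for key, row in values.iterrows():
        x = row[list(case)].to_numpy(dtype=float)
        y = row[list(control)].to_numpy(dtype=float)
        u, p = mann_whitney_row(x, y)
        med_case, med_control = float(np.median(x)), float(np.median(y))
        rows.append(
            {
                "U": u,
                "p_value": p,
                "median_case": med_case,
                "median_control": med_control,
                "direction": int(np.sign(med_case - med_control)),
                "constant": bool(np.all(np.concatenate([x, y]) == x[0])),
            }
        )
    return pd.DataFrame(rows, index=values.index)


def adjust_pvalues(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]
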