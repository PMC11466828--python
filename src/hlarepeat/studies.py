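"""Published per-patient mismatch counts from the two third-party-MSC
kidney-transplant cohorts.

These are the printed split-antigen and solvent-accessible amino-acid
mismatch counts for the Liège cohort (ten patients, MSC donors chosen
without HLA selection) and the Neptune cohort (ten patients, MSC donors
selected to avoid repeated split-antigen mismatches at HLA-A, -B, -DR and
-DQ; one DQ repeat was accepted for lack of a suitable product). Each
patient has three comparisons — kidney donor vs recipient, MSC donor vs
recipient, and their repeated intersection — with split counts at A, B, C,
DR, DQ and amino-acid counts per locus group. Two Liège patients (L3, L8)
lack amino-acid counts because no material remained for high-resolution
typing; their entries are None.

The underlying typings were never published, so these counts are inputs to
the cohort statistics, not quantities the package recomputes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

SPLIT_COLS = ["A", "B", "C", "DR", "DQ"]
AA_COLS = ["aa_class_I", "aa_DR", "aa_DQB"]

#: patients excluded from amino-acid analysis (no high-resolution typing)
LIEGE_EXCLUDED = ("L3", "L8")

# (patient, comparison) -> [A, B, C, DR, DQ, class_I, DR, DQB]; None = untyped
_LIEGE = {
    ("L1", "kidney"):   [2, 1, 2, 1, 1, 12, 9, 14],
    ("L1", "msc"):      [1, 0, 1, 1, 1, 12, 1, 13],
    ("L1", "repeated"): [0, 0, 0, 0, 1, 4, 0, 13],
    ("L2", "kidney"):   [1, 0, 1, 1, 1, 10, 4, 21],
    ("L2", "msc"):      [0, 1, 1, 0, 1, 5, 0, 12],
    ("L2", "repeated"): [0, 0, 0, 0, 0, 2, 0, 8],
    ("L3", "kidney"):   [1, 1, 0, 0, 1, None, None, None],
    ("L3", "msc"):      [1, 1, 1, 1, 2, None, None, None],
    ("L3", "repeated"): [1, 1, 0, 0, 1, None, None, None],
    ("L4", "kidney"):   [1, 1, 1, 1, 0, 7, 15, 0],
    ("L4", "msc"):      [2, 2, 2, 2, 2, 18, 26, 15],
    ("L4", "repeated"): [0, 0, 0, 0, 0, 6, 15, 0],
    ("L5", "kidney"):   [1, 1, 1, 1, 1, 15, 16, 9],
    ("L5", "msc"):      [2, 1, 1, 1, 1, 18, 3, 8],
    ("L5", "repeated"): [1, 0, 0, 0, 0, 11, 3, 1],
    ("L6", "kidney"):   [1, 2, 2, 1, 1, 18, 16, 2],
    ("L6", "msc"):      [2, 2, 2, 2, 2, 18, 21, 10],
    ("L6", "repeated"): [1, 1, 1, 1, 1, 13, 16, 2],
    ("L7", "kidney"):   [1, 1, 1, 1, 1, 17, 15, 23],
    ("L7", "msc"):      [1, 1, 2, 2, 2, 12, 29, 28],
    ("L7", "repeated"): [0, 0, 0, 1, 1, 5, 15, 23],
    ("L8", "kidney"):   [2, 2, 2, 0, 0, None, None, None],
    ("L8", "msc"):      [2, 2, 1, 2, 2, None, None, None],
    ("L8", "repeated"): [0, 0, 0, 0, 0, None, None, None],
    ("L9", "kidney"):   [2, 1, 2, 1, 1, 7, 4, 16],
    ("L9", "msc"):      [2, 2, 2, 2, 1, 10, 36, 22],
    ("L9", "repeated"): [0, 0, 0, 0, 0, 0, 3, 11],
    ("L10", "kidney"):  [0, 0, 2, 1, 1, 5, 11, 12],
    ("L10", "msc"):     [2, 1, 1, 1, 1, 15, 17, 16],
    ("L10", "repeated"): [0, 0, 0, 0, 0, 1, 5, 3],
}

_NEPTUNE = {
    ("N1", "kidney"):   [1, 1, 1, 0, 1, 11, 0, 4],
    ("N1", "msc"):      [2, 1, 2, 2, 1, 12, 8, 11],
    ("N1", "repeated"): [0, 0, 0, 0, 0, 5, 0, 3],
    ("N2", "kidney"):   [2, 2, 1, 2, 2, 12, 22, 26],
    ("N2", "msc"):      [0, 1, 2, 2, 2, 11, 31, 19],
    ("N2", "repeated"): [0, 0, 0, 0, 1, 3, 8, 18],  # DQ repeat accepted
    ("N3", "kidney"):   [1, 2, 1, 1, 1, 8, 25, 8],
    ("N3", "msc"):      [1, 2, 1, 0, 0, 14, 0, 0],
    ("N3", "repeated"): [0, 0, 0, 0, 0, 5, 0, 0],
    ("N4", "kidney"):   [0, 1, 1, 1, 1, 4, 4, 18],
    ("N4", "msc"):      [1, 2, 2, 1, 1, 10, 11, 5],
    ("N4", "repeated"): [0, 0, 1, 0, 0, 3, 0, 2],
    ("N5", "kidney"):   [1, 2, 1, 1, 1, 9, 3, 14],
    ("N5", "msc"):      [1, 0, 1, 2, 1, 7, 5, 7],
    ("N5", "repeated"): [0, 0, 0, 0, 0, 3, 0, 2],
    ("N6", "kidney"):   [1, 2, 1, 0, 1, 15, 0, 1],
    ("N6", "msc"):      [1, 2, 1, 2, 2, 12, 19, 19],
    ("N6", "repeated"): [0, 0, 0, 0, 0, 7, 0, 1],
    ("N7", "kidney"):   [0, 1, 1, 1, 1, 7, 11, 19],
    ("N7", "msc"):      [0, 1, 1, 2, 1, 3, 5, 7],
    ("N7", "repeated"): [0, 0, 0, 0, 0, 2, 1, 2],
    ("N8", "kidney"):   [2, 0, 2, 1, 1, 10, 24, 14],
    ("N8", "msc"):      [0, 2, 0, 1, 1, 4, 16, 18],
    ("N8", "repeated"): [0, 0, 0, 0, 0, 0, 7, 4],
    ("N9", "kidney"):   [1, 2, 1, 2, 1, 11, 22, 9],
    ("N9", "msc"):      [0, 2, 2, 2, 2, 13, 29, 9],
    ("N9", "repeated"): [0, 0, 0, 0, 0, 4, 10, 3],
    ("N10", "kidney"):  [0, 0, 0, 1, 1, 0, 20, 22],
    ("N10", "msc"):     [1, 2, 0, 2, 2, 9, 38, 25],
    ("N10", "repeated"): [0, 0, 0, 0, 0, 0, 15, 14],
}


def _table(data: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=SPLIT_COLS + AA_COLS)
    df.index = pd.MultiIndex.from_tuples(df.index,
                                         names=["patient_id", "comparison"])
    return df.astype(float)


def liege_table() -> pd.DataFrame:
    """Per-patient mismatch counts of the unselected (Liège) cohort."""
    return _table(_LIEGE)


def neptune_table() -> pd.DataFrame:
    """Per-patient mismatch counts of the split-antigen-selected (Neptune)
    cohort."""
    return _table(_NEPTUNE)


def repeated_aa_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient repeated amino-acid counts (rows with data only), shaped
    for :func:`hlarepeat.cohort.summarize_cohort`."""
    rep = table.xs("repeated", level="comparison")[AA_COLS]
    rep = rep.rename(columns=lambda c: c.removeprefix("aa_"))
    return rep.dropna()


def repeated_split_totals(table: pd.DataFrame) -> pd.Series:
    """Cohort-wide sums of the repeated split-antigen columns."""
    rep = table.xs("repeated", level="comparison")[SPLIT_COLS]
    return rep.sum(axis=0).astype(int)


def cohort_totals(table: pd.DataFrame) -> np.ndarray:
    """Per-patient total repeated amino-acid mismatches (class I + DR + DQB),
    analyzable patients only, in patient order."""
    rep = repeated_aa_counts(table)
    return rep.sum(axis=1).to_numpy()
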