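"""Cohort aggregation and the two-cohort nonparametric comparison.

Per-patient repeated amino-acid mismatch counts are summarized per locus
group (class I, DR, DQB) as median and interquartile range, and patient
totals (class I + DR + DQB) are compared between cohorts with the
Mann-Whitney rank-sum test: mid-ranks for ties, two-sided p from the normal
approximation with tie-corrected variance and no continuity correction, with
an exact-permutation p computed alongside whenever the combined sample is
small enough to enumerate.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mismatch import LOCUS_GROUPS, TriadReport

EXACT_ENUMERATION_LIMIT = 20


class EmptyCohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSummary:
    cohort_id: str
    n_analyzed: int
    excluded: tuple[str, ...]
    group_counts: pd.DataFrame  # index patient_id, columns class_I/DR/DQB/total
    medians: dict[str, float]
    iqr: dict[str, tuple[float, float]]

    @property
    def totals(self) -> pd.Series:
        return self.group_counts["total"]


def _counts_frame(reports: Iterable[TriadReport]) -> pd.DataFrame:
    rows = {}
    for rep in reports:
        rows[rep.patient_id] = {g: rep.repeated_aa_count(g) for g in LOCUS_GROUPS}
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_cohort(reports: Iterable[TriadReport] | pd.DataFrame,
                     cohort_id: str = "cohort",
                     exclude: Iterable[str] = ()) -> CohortSummary:
    """Summarize repeated amino-acid mismatch counts over a cohort.

    ``reports`` may be TriadReports or a DataFrame of per-patient counts
    (index patient_id, columns class_I, DR, DQB). Patients in ``exclude``
    (e.g. no material for high-resolution typing) are dropped from the
    medians and listed on the summary. Even-n medians are the mean of the
    two central order statistics; the IQR is the 25th-75th percentile.
    """
    if isinstance(reports, pd.DataFrame):
        counts = reports[list(LOCUS_GROUPS)].copy()
    else:
        counts = _counts_frame(reports)
    exclude = tuple(str(e) for e in exclude)
    counts = counts.drop(index=[e for e in exclude if e in counts.index])
    counts = counts.dropna()
    if counts.empty:
        raise EmptyCohortError(f"cohort {cohort_id}: no analyzable patients")
    counts["total"] = counts[list(LOCUS_GROUPS)].sum(axis=1)
    medians = {c: float(counts[c].median()) for c in counts.columns}
    iqr = {c: (float(counts[c].quantile(0.25)), float(counts[c].quantile(0.75)))
           for c in counts.columns}
    return CohortSummary(cohort_id=cohort_id, n_analyzed=len(counts),
                         excluded=exclude, group_counts=counts,
                         medians=medians, iqr=iqr)


@dataclass(frozen=True)
class TwoCohortTest:
    """Mann-Whitney result.

    ``p_asymptotic`` is the tie-corrected normal approximation without
    continuity correction. ``p_exact`` is the conventional two-sided
    permutation p (all relabelings whose U deviates from its mean at least
    as much as observed). ``p_exact_mid`` is the mid-p variant (half weight
    on the observed tie class), the exact counterpart of the uncorrected
    normal approximation. Exact values are None when the combined sample is
    too large to enumerate.
    """

    u: float
    z: float
    p_asymptotic: float
    p_exact: float | None
    p_exact_mid: float | None
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    n1 = len(a)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 exact_limit: int = EXACT_ENUMERATION_LIMIT) -> TwoCohortTest:
    """Two-sided Mann-Whitney rank-sum test.

    The headline p uses the normal approximation with tie-corrected variance
    and no continuity correction. When ``len(a)+len(b) <= exact_limit`` the
    exact permutation p (proportion of group relabelings whose U deviates
    from its mean at least as much as observed) is enumerated and reported
    alongside. Degenerate input with zero variance across the pooled sample
    yields p = 1 with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    mu = n1 * n2 / 2

    if np.ptp(pooled) == 0:
        warnings.warn("pooled sample has zero variance; p set to 1")
        return TwoCohortTest(u=mu, z=0.0, p_asymptotic=1.0, p_exact=1.0,
                             p_exact_mid=0.5, median_a=float(np.median(a)),
                             median_b=float(np.median(b)), n_a=n1, n_b=n2)

    u = _u_statistic(a, b)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    z = (u - mu) / math.sqrt(var)
    p_asym = float(2 * stats.norm.sf(abs(z)))

    p_exact = p_exact_mid = None
    if n <= exact_limit:
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        dev_obs = abs(u - mu)
        beyond = 0
        at = 0
        total = 0
        for idx in combinations(range(n), n1):
            dev = abs(ranks[list(idx)].sum() - offset - mu)
            if dev > dev_obs + 1e-9:
                beyond += 1
            elif dev > dev_obs - 1e-9:
                at += 1
            total += 1
        p_exact = (beyond + at) / total
        p_exact_mid = (beyond + 0.5 * at) / total

    return TwoCohortTest(u=u, z=z, p_asymptotic=min(1.0, p_asym),
                         p_exact=p_exact, p_exact_mid=p_exact_mid,
                         median_a=float(np.median(a)),
                         median_b=float(np.median(b)), n_a=n1, n_b=n2)


def compare_cohorts(summary_a: CohortSummary,
                    summary_b: CohortSummary) -> TwoCohortTest:
    """Mann-Whitney on the per-patient total repeated amino-acid mismatches."""
    return mann_whitney(summary_a.totals.to_numpy(), summary_b.totals.to_numpy())


def dsa_association(summaries: Iterable[CohortSummary],
                    dsa_status: Mapping[str, bool]) -> pd.DataFrame:
    """Descriptive stratification of repeated-mismatch totals by DSA status.

    Returns per-stratum n, median and IQR of the total repeated amino-acid
    mismatch counts; raises if any analyzed patient lacks a DSA status.
    No model is fitted — counts in both strata are reported for inspection.
    """
    frames = []
    for s in summaries:
        df = s.group_counts.copy()
        df["cohort"] = s.cohort_id
        frames.append(df)
    allc = pd.concat(frames)
    missing = [p for p in allc.index if p not in dsa_status]
    if missing:
        raise ValueError(f"DSA status undefined for patients: {missing}")
    allc["dsa"] = [bool(dsa_status[p]) for p in allc.index]
    rows = []
    for flag, grp in allc.groupby("dsa"):
        rows.append({"dsa": flag, "n": len(grp),
                     "median_total": float(grp["total"].median()),
                     "q25": float(grp["total"].quantile(0.25)),
                     "q75": float(grp["total"].quantile(0.75))})
    if not any(r["dsa"] for r in rows):
        rows.append({"dsa": True, "n": 0, "median_total": float("nan"),
                     "q25": float("nan"), "q75": float("nan")})
    return pd.DataFrame(rows).set_index("dsa").sort_index()


def residue_tally(reports: Iterable[TriadReport], group: str, position: int,
                  residue: str,
                  dsa_against: Mapping[str, bool] | None = None) -> dict:
    """Tally patients whose triads repeat a named residue mismatch and how
    many of them formed an antibody against it (e.g. the 55R question)."""
    from .mismatch import PositionResidue
    target = PositionResidue(group, position, residue)
    carriers = [r.patient_id for r in reports if target in r.repeated_aa[group]]
    with_dsa = [p for p in carriers if dsa_against and dsa_against.get(p, False)]
    return {"residue": target.label(), "group": group,
            "patients_repeated": carriers, "n_repeated": len(carriers),
            "n_with_dsa_against": len(with_dsa), "patients_with_dsa": with_dsa}
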