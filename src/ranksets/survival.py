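"""Survival evaluation of core gene sets by score splits and log-rank tests.

Each core gene set scores every sample by the plain column sum of its
probes' expression values.  Samples are split either at the median score or
into lowest versus highest score quartiles, and the two groups are compared
with the standard two-group log-rank test (chi-square on one degree of
freedom).  Five values are reported per set: all samples at the median, all
samples by quartiles, ER-positive samples at the median and by quartiles,
and ER-negative samples at the median only — the ER-negative stratum is
too small to quarter.  Cohorts without ER annotation get the two
all-sample values only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .consolidation import GeneSetFamily
from .dataio import ClinicalTable, ExpressionMatrix

__all__ = [
    "SurvivalResult",
    "column_sum_score",
    "median_split",
    "quartile_split",
    "logrank",
    "evaluate_family",
    "results_to_table",
]

#: The five (stratum, split) evaluations reported per core gene set.
FIVE_WAY = (
    ("all", "median"),
    ("all", "quartiles"),
    ("ER+", "median"),
    ("ER+", "quartiles"),
    ("ER-", "median"),
)


@dataclass(frozen=True)
class SurvivalResult:
    """One log-rank evaluation of one gene-set family."""

    family_id: str
    stratum: str  # all / ER+ / ER-
    split: str  # median / quartiles
    chi2: float
    p: float
    n_group_low: int
    n_group_high: int
    n_events: int
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p <= 0.05)


def column_sum_score(m: ExpressionMatrix, probes) -> np.ndarray:
    """Per-sample sum of the listed probes' expression values (no weights)."""
    probes = list(probes)
    if not probes:
        raise ValueError("empty probe list")
    index = {p: i for i, p in enumerate(m.probe_ids)}
    unknown = [p for p in probes if p not in index]
    if unknown:
        raise KeyError(f"probes absent from matrix: {unknown}")
    rows = [index[p] for p in probes]
    return m.values[rows].sum(axis=0)


def median_split(scores: np.ndarray) -> np.ndarray:
    """Group labels at the median: 0 = low (score <= median), 1 = high."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 4:
        raise ValueError("median split needs at least 4 samples")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate split: all scores identical")
    med = np.median(scores)
    group = (scores > med).astype(int)
    if group.all() or not group.any():
        raise ValueError("degenerate split: one group is empty")
    return group


def quartile_split(scores: np.ndarray) -> np.ndarray:
    """Labels: 0 = lowest floor(n/4) scorers, 1 = highest, -1 = excluded.

    Ties at the quartile boundaries are resolved by ascending sample index
    (stable sort), so group sizes are exactly ``floor(n/4)`` each.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 8:
        raise ValueError("quartile split needs at least 8 samples")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate split: all scores identical")
    q = n // 4
    order = np.lexsort((np.arange(n), scores))
    labels = np.full(n, -1, dtype=int)
    labels[order[:q]] = 0
    labels[order[-q:]] = 1
    return labels


def logrank(time, event, group) -> tuple:
    """Two-group log-rank test; returns ``(chi2, p)`` on 1 df.

    At each distinct event time the observed number of group-1 events is
    compared with its expectation under the hypergeometric model given the
    risk sets; tied events are handled by the usual simultaneous-risk-set
    convention (censorings at a time remain at risk for events at that
    time).  ``chi2 = (sum(O - E))^2 / sum(V)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if not (time.shape == event.shape == group.shape):
        raise ValueError("time, event and group must have equal length")
    if (time < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be binary")
    if not np.isin(group, (0, 1)).all():
        raise ValueError("group must be binary")
    if group.all() or not group.any():
        raise ValueError("both groups must be nonempty")
    if event.sum() == 0:
        warnings.warn("no events observed; log-rank is undefined (chi2=0)")
        return 0.0, 1.0

    ut, inv = np.unique(time, return_inverse=True)
    k = ut.shape[0]
    c_total = np.bincount(inv, minlength=k).astype(float)
    c1 = np.bincount(inv, weights=group, minlength=k)
    d_total = np.bincount(inv, weights=event, minlength=k)
    d1 = np.bincount(inv, weights=event * group, minlength=k)
    # subjects at risk just before each unique time
    n_total = time.shape[0] - np.concatenate(([0.0], np.cumsum(c_total)[:-1]))
    n1 = group.sum() - np.concatenate(([0.0], np.cumsum(c1)[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1 / n_total
        expected = d_total * frac
        var = np.where(
            n_total > 1,
            d_total * frac * (1 - frac) * (n_total - d_total)
            / np.maximum(n_total - 1, 1),
            0.0,
        )
    has_events = d_total > 0
    o_minus_e = float((d1 - expected)[has_events].sum())
    v = float(var[has_events].sum())
    if v == 0:
        warnings.warn("zero log-rank variance; returning chi2=0")
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def _one_result(
    family_id, stratum, split, scores, time, event
) -> SurvivalResult:
    try:
        if split == "median":
            labels = median_split(scores)
        else:
            labels = quartile_split(scores)
        keep = labels >= 0
        chi2, p = logrank(time[keep], event[keep], labels[keep])
        return SurvivalResult(
            family_id=family_id,
            stratum=stratum,
            split=split,
            chi2=chi2,
            p=p,
            n_group_low=int((labels == 0).sum()),
            n_group_high=int((labels == 1).sum()),
            n_events=int(event[keep].sum()),
        )
    except ValueError as exc:
        warnings.warn(f"{family_id} [{stratum}/{split}]: {exc}")
        return SurvivalResult(
            family_id=family_id,
            stratum=stratum,
            split=split,
            chi2=float("nan"),
            p=float("nan"),
            n_group_low=0,
            n_group_high=0,
            n_events=0,
            note=str(exc),
        )


def evaluate_family(
    m: ExpressionMatrix, clinical: ClinicalTable, family: GeneSetFamily
) -> list:
    """Five-way log-rank evaluation of a family's core gene set.

    The clinical table is aligned to the matrix sample order; samples with
    no clinical row are excluded.  When no sample carries a known ER
    status the two ER strata are skipped and only the two all-sample
    results are returned.  The ER-negative stratum is never split by
    quartiles.  Degenerate splits yield NaN results with a note rather
    than aborting the run.
    """
    clin = clinical.align(m.sample_ids)
    probes = family.core_probes or family.all_probes
    if not probes:
        warnings.warn(f"family {family.family_id} has no core probes; skipped")
        return []
    scores = column_sum_score(m, probes)
    er = np.asarray(clin.er_status)
    valid = ~np.isnan(clin.time)
    strata = {
        "all": valid,
        "ER+": valid & (er == "positive"),
        "ER-": valid & (er == "negative"),
    }
    er_known = bool((valid & (er != "unknown")).any())
    if not er_known:
        warnings.warn("ER status not available; reporting all-sample splits only")
    results = []
    for stratum, split in FIVE_WAY:
        if stratum != "all" and not er_known:
            continue
        mask = strata[stratum]
        results.append(
            _one_result(
                family.family_id,
                stratum,
                split,
                scores[mask],
                clin.time[mask],
                clin.event[mask],
            )
        )
    return results


def results_to_table(results: list) -> pd.DataFrame:
    """One row per family, a (chi2, p) column pair per stratum/split, with a
    significance flag at p <= 0.05 (the bold entries of the report table)."""
    rows: dict = {}
    for r in results:
        row = rows.setdefault(r.family_id, {"family_id": r.family_id})
        key = f"{r.stratum}_{r.split}"
        row[f"chi2_{key}"] = r.chi2
        row[f"p_{key}"] = r.p
        row[f"sig_{key}"] = r.significant
    return pd.DataFrame(list(rows.values()))
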