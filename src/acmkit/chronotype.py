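"""Objective chronotype classification and agreement with the questionnaire.

Subjects are split by the 20/60/20 percentile rule on the night phase marker of
TAP: the earliest 20 % are early types (E), the latest 20 % late types (L), the
remaining 60 % neither (N).  Because NPMs are clock times, they are first
unwrapped onto a continuous axis centred on the cohort circular mean so a
subject at 23:50 ranks earlier than one at 04:00.  The same rule applied to
MSFsc gives the questionnaire-based classes, and the two label vectors are
compared in a 3 x 3 agreement matrix summarised as coincidence, one-step error
and opposite-extreme percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import unwrap_about

CLASSES = ("E", "N", "L")
_RANK = {"E": 0, "N": 1, "L": 2}


@dataclass
class Classification:
    """Result of a 20/60/20 percentile classification."""

    subject_ids: list[str]
    labels: list[str]
    values: np.ndarray          # unwrapped axis actually ranked
    e_cut: float                # highest value classified E
    l_cut: float                # lowest value classified L

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.subject_ids, self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "label": self.labels, "value": self.values}
        )


def _quantile_split(subject_ids: list[str], values: np.ndarray) -> Classification:
    n = values.size
    if n < 5:
        raise ValueError("at least 5 subjects required for the 20/60/20 split")
    k = math.ceil(0.2 * n)
    order = np.argsort(values, kind="stable")  # stable: ties by input order
    sorted_vals = values[order]
    if sorted_vals[k - 1] == sorted_vals[n - k]:
        warnings.warn(
            "no spread between the 20% and 80% cut values; "
            "all subjects classified N",
            stacklevel=3,
        )
        labels = ["N"] * n
        return Classification(
            subject_ids=list(subject_ids),
            labels=labels,
            values=values,
            e_cut=float("nan"),
            l_cut=float("nan"),
        )
    for boundary in (k - 1, n - k - 1):
        if sorted_vals[boundary] == sorted_vals[boundary + 1]:
            warnings.warn(
                "tied values span a percentile boundary; "
                "tie broken by subject order",
                stacklevel=3,
            )
    labels = np.full(n, "N", dtype=object)
    labels[order[:k]] = "E"
    labels[order[n - k :]] = "L"
    return Classification(
        subject_ids=list(subject_ids),
        labels=list(labels),
        values=values,
        e_cut=float(sorted_vals[k - 1]),
        l_cut=float(sorted_vals[n - k]),
    )


def classify_by_npm(npms: dict[str, float]) -> Classification:
    """20/60/20 split on night phase markers (clock hours).

    NPMs are unwrapped about the cohort circular mean before ranking, so the
    split is invariant to rotating all clock times by a constant.
    """
    ids = list(npms.keys())
    values = unwrap_about(np.array([npms[s] for s in ids], dtype=float))
    return _quantile_split(ids, values)


def classify_by_msfsc(msfsc_values: dict[str, float]) -> Classification:
    """The same 20/60/20 percentile rule applied to MSFsc clock times."""
    ids = list(msfsc_values.keys())
    values = unwrap_about(np.array([msfsc_values[s] for s in ids], dtype=float))
    return _quantile_split(ids, values)


@dataclass
class AgreementMatrix:
    """3 x 3 counts of ACM-based vs questionnaire-based chronotype labels."""

    counts: np.ndarray  # rows: ACM class E/N/L; cols: MSFsc class E/N/L

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def coincidence_pct(self) -> float:
        return 100.0 * np.trace(self.counts) / self.n

    @property
    def one_step_pct(self) -> float:
        c = self.counts
        one = c[0, 1] + c[1, 0] + c[1, 2] + c[2, 1]
        return 100.0 * one / self.n

    @property
    def opposite_pct(self) -> float:
        return 100.0 * (self.counts[0, 2] + self.counts[2, 0]) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"acm_{c}" for c in CLASSES],
            columns=[f"msf_{c}" for c in CLASSES],
        )

    def summary(self) -> dict:
        return {
            "n": self.n,
            "coincidence_pct": self.coincidence_pct,
            "one_step_pct": self.one_step_pct,
            "opposite_pct": self.opposite_pct,
            "counts": self.counts.tolist(),
        }


def agreement(acm: dict[str, str], msf: dict[str, str]) -> AgreementMatrix:
    """Cross-tabulate two label dicts over the same subject set."""
    if set(acm) != set(msf):
        raise ValueError("ACM and MSFsc classifications cover different subjects")
    counts = np.zeros((3, 3), dtype=int)
    for s in acm:
        counts[_RANK[acm[s]], _RANK[msf[s]]] += 1
    return AgreementMatrix(counts=counts)
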