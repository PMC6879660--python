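"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by direct enumeration / plain Python
loops, sharing no code path with the package internals they verify.
"""

from __future__ import annotations

import numpy as np


def ml_window_brute_force(values, width_slots: int):
    """All circular window means by explicit slicing; returns (best_mean, onset)
    for both max and min with earliest-onset tie-break."""
    values = list(values)
    p = len(values)
    means = []
    for start in range(p):
        window = [values[(start + k) % p] for k in range(width_slots)]
        means.append(sum(window) / width_slots)
    best_max = max(means)
    best_min = min(means)
    return (
        (best_max, means.index(best_max)),
        (best_min, means.index(best_min)),
    )


def iqd_filter_brute_force(values, valid):
    """Re-apply the rate-of-change rule by hand: quartiles of the valid values,
    then flag any valid epoch whose jump from the previous valid epoch of the
    *input* exceeds Q3 - Q1."""
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    vv = values[valid]
    q1, q3 = np.percentile(vv, [25, 75])
    iqd = q3 - q1
    out = valid.copy()
    prev = None
    for i in range(len(values)):
        if not valid[i]:
            continue
        if prev is not None and abs(values[i] - values[prev]) > iqd:
            out[i] = False
        prev = i  # reference is the previous valid epoch of the input
    return out


def sleep_probability_count(binary_matrix):
    """Direct-count cohort sleep probability: binary_matrix is
    (n_subjects, n_days, slots); returns percent asleep per slot."""
    m = np.asarray(binary_matrix, float)
    per_subject = m.mean(axis=1)          # each subject's daily probability
    return per_subject.mean(axis=0) * 100.0
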