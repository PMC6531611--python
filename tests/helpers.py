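"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each rule by direct enumeration, independently
of the package implementation they check.
"""

from __future__ import annotations

import numpy as np


def onset_oracle(counts, offwrist, threshold=10, k=5, convention="active"):
    """Forward scan: first index t with a worn epoch > threshold followed by
    k worn epochs <= threshold.  Returns the epoch index or None."""
    n = len(counts)
    for t in range(n - k):
        if offwrist[t] or counts[t] <= threshold:
            continue
        ok = True
        for j in range(t + 1, t + 1 + k):
            if offwrist[j] or counts[j] > threshold:
                ok = False
                break
        if ok:
            return t if convention == "active" else t + 1
    return None


def offset_oracle(counts, offwrist, threshold=10, k=5):
    """Backward scan: last index t with a worn epoch > threshold preceded by
    k worn epochs <= threshold."""
    n = len(counts)
    for t in range(n - 1, k - 1, -1):
        if offwrist[t] or counts[t] <= threshold:
            continue
        ok = True
        for j in range(t - k, t):
            if offwrist[j] or counts[j] > threshold:
                ok = False
                break
        if ok:
            return t
    return None


def nonwear_oracle(minute_sums, min_len=90, spike_max=2, flank=30):
    """All maximal qualifying non-wear intervals by direct enumeration.

    An interval [s, e) qualifies when it is at least ``min_len`` minutes,
    starts and ends on zero minutes, and every interior nonzero run is at
    most ``spike_max`` minutes with at least ``flank`` consecutive zero
    minutes immediately on each side (inside the interval).  Maximal means
    not contained in a longer qualifying interval.
    """
    x = np.asarray(minute_sums)
    n = len(x)
    zero = x == 0

    def qualifies(s, e):
        if e - s < min_len or not zero[s] or not zero[e - 1]:
            return False
        i = s
        while i < e:
            if zero[i]:
                i += 1
                continue
            j = i
            while j < e and not zero[j]:
                j += 1
            if j - i > spike_max:
                return False
            # zeros immediately before and after the run, inside [s, e)
            before = 0
            b = i - 1
            while b >= s and zero[b]:
                before += 1
                b -= 1
            after = 0
            a = j
            while a < e and zero[a]:
                after += 1
                a += 1
            if before < flank or after < flank:
                return False
            i = j
        return True

    # candidate boundaries are zero-run starts/ends; a maximal interval
    # cannot begin or end strictly inside a zero run
    starts = [i for i in range(n) if zero[i] and (i == 0 or not zero[i - 1])]
    ends = [i + 1 for i in range(n) if zero[i] and (i + 1 == n or not zero[i + 1])]
    qual = [(s, e) for s in starts for e in ends if e > s and qualifies(s, e)]
    maximal = [
        (s, e) for s, e in qual
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in qual)
    ]
    return sorted(maximal)


def cluster_oracle(is_mvpa, window=120):
    """Exhaustive scan for the window holding the most MVPA minutes;
    earliest window on ties.  Returns (start index, count) or None."""
    x = np.asarray(is_mvpa, dtype=int)
    if len(x) < window:
        return None
    best_s, best_c = 0, -1
    for s in range(len(x) - window + 1):
        c = int(x[s: s + window].sum())
        if c > best_c:
            best_s, best_c = s, c
    return best_s, best_c


def dense_loglik(y, X, beta, person, day, sigma2_u, sigma2_e, rho):
    """Joint multivariate-normal log-density with the implied dense
    covariance, evaluated person-block by person-block."""
    from scipy.stats import multivariate_normal

    total = 0.0
    for pid in np.unique(person):
        m = person == pid
        d = day[m]
        D = np.abs(d[:, None] - d[None, :])
        V = sigma2_u + sigma2_e * rho ** D
        total += multivariate_normal.logpdf(y[m], mean=X[m] @ beta, cov=V)
    return float(total)
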