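"""Independent brute-force oracles used to cross-check the implementation.

These are literal, loop-by-loop transcriptions of the score definitions:
the running sum as two explicit cumulative fractions, the ES as a full scan
of |v(l)|, and the TCS as the rank distance |l_max - l_min|. They share no
code with the package and are deliberately unvectorized.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_running_sum(abs_t, hits, omega):
    """v(1..p) by direct double summation."""
    p = len(abs_t)
    gamma = sum(bool(h) for h in hits)
    denom = sum(abs_t[j] ** omega for j in range(p) if hits[j])
    v = []
    for l in range(1, p + 1):
        if denom > 0:
            hit_term = sum(abs_t[j] ** omega for j in range(l) if hits[j]) / denom
        else:
            hit_term = sum(1 for j in range(l) if hits[j]) / gamma
        if gamma < p:
            miss_term = sum(1 for j in range(l) if not hits[j]) / (p - gamma)
        else:
            miss_term = 0.0
        v.append(hit_term - miss_term)
    return v


def naive_scores(abs_t, hits, omega):
    """(es, l_max, l_min, tcs_raw, tcs) by full scans with smallest-rank ties."""
    p = len(abs_t)
    v = naive_running_sum(abs_t, hits, omega)
    es, l_max = -1.0, 0
    for l in range(1, p + 1):
        if abs(v[l - 1]) > es:
            es, l_max = abs(v[l - 1]), l
    t_min, l_min = float("inf"), 0
    for j in range(1, p + 1):
        if abs(abs_t[j - 1]) < t_min:
            t_min, l_min = abs(abs_t[j - 1]), j
    tcs_raw = abs(l_max - l_min)
    return es, l_max, l_min, tcs_raw, tcs_raw / (p - 1)


def exhaustive_null_mean_es(abs_t, gamma, omega):
    """Exact average ES over every C(p, gamma) hit placement."""
    p = len(abs_t)
    total, count = 0.0, 0
    for combo in itertools.combinations(range(p), gamma):
        hits = [j in combo for j in range(p)]
        es, *_ = naive_scores(abs_t, hits, omega)
        total += es
        count += 1
    return total / count


def random_instance(rng, p_max=50, gamma_max=10, omegas=(0.0, 0.5, 1.0, 2.0)):
    """A random ranked-list instance: sorted |T|, random signs and hit set."""
    p = int(rng.integers(2, p_max + 1))
    gamma = int(rng.integers(1, min(gamma_max, p) + 1))
    omega = float(rng.choice(omegas))
    abs_t = np.sort(rng.exponential(1.0, size=p))[::-1].copy()
    signs = rng.choice([-1, 1], size=p)
    hits = np.zeros(p, dtype=bool)
    hits[rng.choice(p, size=gamma, replace=False)] = True
    return abs_t, signs, hits, omega
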