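"""Independent reference implementations used only to check kdsig's results.

These share no code with the package: the enrichment walk is a literal
position-by-position loop, and the Kaplan-Meier / log-rank references come
from lifelines.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(genes, metric, gene_set, weight):
    """Enrichment score by explicit enumeration of every list position."""
    members = set(gene_set)
    hits = [g in members for g in genes]
    n = len(genes)
    n_hit = sum(hits)
    assert 0 < n_hit < n
    denom_hit = sum(abs(metric[i]) ** weight for i in range(n) if hits[i])
    running = []
    total = 0.0
    for i in range(n):
        if hits[i]:
            if denom_hit > 0:
                total += abs(metric[i]) ** weight / denom_hit
            else:
                total += 1.0 / n_hit
        else:
            total -= 1.0 / (n - n_hit)
        running.append(total)
    best = 0.0
    for value in running:
        if abs(value) > abs(best):
            best = value
    return best, running


def km_by_hand(times, events):
    """Product-limit estimate via an explicit loop over distinct event times."""
    times = list(map(float, times))
    events = list(map(int, events))
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    surv = []
    s = 1.0
    for t in distinct:
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return np.array(distinct), np.array(surv)
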