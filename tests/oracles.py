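"""Brute-force verification oracles: direct per-event loops, no matrix algebra.

Each oracle re-derives its statistic from the list of (forecast category,
observed category) events, independently of the package implementation.
"""

import math


def table_to_events(counts):
    events = []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            events.extend([(i, j)] * int(c))
    return events


def oracle_hit_rate(events, i):
    hits = sum(1 for f, o in events if f == i and o == i)
    observed = sum(1 for _, o in events if o == i)
    if observed == 0:
        return math.nan
    return hits / observed


def oracle_false_alarm_ratio(events, i):
    hits = sum(1 for f, o in events if f == i and o == i)
    forecast = sum(1 for f, _ in events if f == i)
    if forecast == 0:
        return math.nan
    return (forecast - hits) / forecast


def _marginals(events, k):
    n = len(events)
    nf = [sum(1 for f, _ in events if f == i) for i in range(k)]
    no = [sum(1 for _, o in events if o == i) for i in range(k)]
    nfo = [sum(1 for f, o in events if f == i and o == i) for i in range(k)]
    return n, nf, no, nfo


def oracle_heidke(events, k):
    n, nf, no, nfo = _marginals(events, k)
    correct = sum(nfo) / n
    chance = sum(nf[i] * no[i] for i in range(k)) / n**2
    if chance == 1.0:
        return math.nan
    return (correct - chance) / (1.0 - chance)


def oracle_peirce(events, k):
    n, nf, no, nfo = _marginals(events, k)
    correct = sum(nfo) / n
    chance = sum(nf[i] * no[i] for i in range(k)) / n**2
    denom = 1.0 - sum(o**2 for o in no) / n**2
    if denom == 0.0:
        return math.nan
    return (correct - chance) / denom


def oracle_gerrity_scores(events, k):
    """Scoring matrix s built element-by-element from the observed frequencies."""
    n = len(events)
    p = [sum(1 for _, o in events if o == i) / n for i in range(k)]
    a = []
    for i in range(1, k):
        cum = sum(p[:i])
        a.append((1.0 - cum) / cum)
    s = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(k):
            lo, hi = min(i, j), max(i, j)
            total = 0.0
            for r in range(lo):
                total += 1.0 / a[r]
            total -= hi - lo
            for r in range(hi, k - 1):
                total += a[r]
            s[i][j] = total / (k - 1)
    return s


def oracle_gerrity(events, k):
    s = oracle_gerrity_scores(events, k)
    return sum(s[f][o] for f, o in events) / len(events)
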