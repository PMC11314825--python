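"""Deliberately naive recurrence/RQA oracle used only by the tests.

Everything is written with explicit Python loops and first-principles
scans, independent of the vectorised implementation it checks (the
definitions — strict threshold inequality, boundary-corrected DET/LAM point
counts, natural-log entropy over l >= lmin — are of course shared).
"""

import math


def naive_embed(x, m, tau):
    n_vec = len(x) - (m - 1) * tau
    return [[x[i + j * tau] for j in range(m)] for i in range(n_vec)]


def naive_recurrence(points, frac):
    n = len(points)
    dist = [[math.dist(points[i], points[j]) for j in range(n)] for i in range(n)]
    dmax = max(max(row) for row in dist)
    eps = frac * dmax
    r = [[1 if (i == j or dist[i][j] < eps) else 0 for j in range(n)] for i in range(n)]
    return r, eps


def _runs(seq):
    """(length, spans_whole_line) for each maximal run of 1s."""
    out = []
    count = 0
    for v in seq:
        if v:
            count += 1
        elif count:
            out.append(count)
            count = 0
    if count:
        out.append(count)
    return [(ln, ln == len(seq)) for ln in out]


def naive_line_runs(r):
    n = len(r)
    diag = []
    for off in range(-(n - 1), n):
        line = [r[i][i + off] for i in range(max(0, -off), min(n, n - off))]
        diag.extend(_runs(line))
    vert = []
    for j in range(n):
        vert.extend(_runs([r[i][j] for i in range(n)]))
    return diag, vert


def naive_features(r, lmin=2, vmin=2):
    n = len(r)
    total = sum(sum(row) for row in r)
    diag, vert = naive_line_runs(r)
    rec = total / n**2

    det_points = sum(ln for ln, full in diag if ln >= lmin or full)
    lam_points = sum(ln for ln, full in vert if ln >= vmin or full)
    det = det_points / total if total else 0.0
    lam = lam_points / total if total else 0.0

    dlens = [ln for ln, _ in diag if ln >= lmin]
    vlens = [ln for ln, _ in vert if ln >= vmin]
    l_mean = sum(dlens) / len(dlens) if dlens else 0.0
    tt = sum(vlens) / len(vlens) if vlens else 0.0

    entr = 0.0
    if dlens:
        counts = {}
        for ln in dlens:
            counts[ln] = counts.get(ln, 0) + 1
        for c in counts.values():
            p = c / len(dlens)
            entr -= p * math.log(p)

    l_max = max((ln for ln, _ in diag), default=0)
    return {
        "recurrence_rate": rec,
        "determinism": det,
        "entropy": entr,
        "trapping_time": tt,
        "laminarity": lam,
        "l_mean": l_mean,
        "l_max_norm": l_max / n,
    }
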