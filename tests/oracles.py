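"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths (and lifelines):
plain-Python loops implementing the textbook definitions.
"""

import math


def product_limit(times, events):
    """Kaplan-Meier by direct product over distinct event times.

    Returns (event_times, survival) with deaths processed before
    censorings at tied times.
    """
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e})
    s = 1.0
    out_t, out_s = [], []
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei)
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


def product_limit_median(times, events):
    """Smallest event time where the survival curve reaches <= 0.5."""
    out_t, out_s = product_limit(times, events)
    for t, s in zip(out_t, out_s):
        if s <= 0.5 + 1e-12:
            return t
    return None


def brute_nn_annotation(coords, records, radius=2.0, fraction=0.25, min_cohort=10):
    """Reference implementation of neighbor-cohort survival annotation.

    coords: dict sample_id -> (x, y); records: list of objects with
    sample_id, time_years, event, subtype, dataset.  Full distance matrix,
    explicit constraint filtering, half-away-from-zero rounding.
    """
    result = {}
    strata = {}
    for r in records:
        strata.setdefault((r.subtype, r.dataset), []).append(r)
    for stratum in strata.values():
        n = len(stratum)
        k = math.floor(fraction * n + 0.5)
        for r in stratum:
            x0, y0 = coords[r.sample_id][0], coords[r.sample_id][1]
            dists = []
            for other in stratum:
                if other.sample_id == r.sample_id:
                    continue
                x1, y1 = coords[other.sample_id][0], coords[other.sample_id][1]
                dists.append((math.hypot(x1 - x0, y1 - y0), other))
            dists.sort(key=lambda pair: pair[0])
            cohort = [o for dist, o in dists if dist <= radius][:k]
            if len(cohort) < min_cohort:
                result[r.sample_id] = None
                continue
            med = product_limit_median(
                [o.time_years for o in cohort], [o.event for o in cohort]
            )
            result[r.sample_id] = med
    return result


def brute_gsva_walk(expr_stat_column, gene_names, member_genes, tau=1.0):
    """Max-deviation-difference KS walk score for one sample, from scratch.

    expr_stat_column: per-gene expression-level statistic for the sample.
    """
    p = len(gene_names)
    order = sorted(range(p), key=lambda i: -expr_stat_column[i])
    # rank p for the highest statistic, 1 for the lowest
    rank = {}
    for pos, gi in enumerate(order):
        rank[gi] = p - pos
    members = set(member_genes)
    in_set = [gene_names[gi] in members for gi in order]
    weights = [abs(rank[gi] - p / 2.0) ** tau for gi in order]
    denom_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = p - sum(in_set)
    walk, v = [], 0.0
    for w, m in zip(weights, in_set):
        if m:
            v += w / denom_in
        else:
            v -= 1.0 / n_out
        walk.append(v)
    return max(max(walk), 0.0) + min(min(walk), 0.0)
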