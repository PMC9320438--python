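"""Brute-force reference implementations used as test oracles.

Deliberately naive and separate from the package: extrema are found by an
O(n*k) neighbour scan over differing values, then gated sequentially by the
amplitude rule.  Used to cross-check the production extrema search.
"""

from __future__ import annotations


def reference_extrema(xs, ts, min_gap: float):
    """(idx, t, x, kind) tuples matching the gated alternating extrema."""
    xs = [float(v) for v in xs]
    n = len(xs)
    if n < 3:
        return []

    candidates = []
    for i in range(1, n - 1):
        if xs[i] == xs[i - 1]:
            continue  # only the first index of a plateau may be an extremum
        j = i - 1  # previous differing value (always exists: xs[i-1] != xs[i])
        k = i + 1
        while k < n and xs[k] == xs[i]:
            k += 1
        if k >= n:
            continue  # plateau runs into the trace end
        if xs[j] < xs[i] and xs[k] < xs[i]:
            candidates.append((i, "max"))
        elif xs[j] > xs[i] and xs[k] > xs[i]:
            candidates.append((i, "min"))

    accepted = []
    for i, kind in candidates:
        if not accepted:
            accepted.append((i, kind))
            continue
        li, lkind = accepted[-1]
        if kind == lkind:
            more_extreme = xs[i] > xs[li] if kind == "max" else xs[i] < xs[li]
            if more_extreme:
                accepted[-1] = (i, kind)
        elif abs(xs[i] - xs[li]) > min_gap:
            accepted.append((i, kind))
    return [(i, float(ts[i]), xs[i], kind) for i, kind in accepted]
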