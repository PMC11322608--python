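"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, no shared code with the package) so it can serve as an independent
reference.
"""

from __future__ import annotations

import math


def f1_brute(focus, other):
    tp = fp = fn = 0
    for f, o in zip(focus, other):
        if f == 1 and o == 1:
            tp += 1
        elif f == 0 and o == 1:
            fp += 1
        elif f == 1 and o == 0:
            fn += 1
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def zscore_brute(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)
    if sd == 0:
        return [0.0] * n
    return [(v - mean) / sd for v in values]


def auroc_brute(pos, neg):
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def features_brute(occupied, llps, idr, rbp, mlos, ppi_edges):
    """Six-feature values for one bin.

    occupied: list of cap names occupying the bin; llps/idr/rbp: sets of cap
    names; mlos: dict cap -> set of MLO names; ppi_edges: set of frozensets.
    """
    n = len(occupied)
    if n == 0:
        return None
    f_llps = sum(1 for c in occupied if c in llps) / n
    f_idr = sum(1 for c in occupied if c in idr) / n
    f_rbp = sum(1 for c in occupied if c in rbp) / n
    all_mlos = set()
    for c in occupied:
        all_mlos |= mlos.get(c, set())
    best = 0
    for mlo in all_mlos:
        best = max(best, sum(1 for c in occupied if mlo in mlos.get(c, set())))
    f_mlo = best / n
    if n < 2:
        f_ppi = 0.0
    else:
        hits = 0
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((occupied[i], occupied[j])) in ppi_edges:
                    hits += 1
        f_ppi = hits / (n * (n - 1) / 2)
    return {"F_LLPS": f_llps, "F_MLO": f_mlo, "F_IDR": f_idr,
            "F_PPI": f_ppi, "F_RBP": f_rbp}


def ncpr_brute(seq, window=10):
    out = []
    for i in range(len(seq) - window + 1):
        net = 0
        for aa in seq[i : i + window]:
            if aa in "RKH":
                net += 1
            elif aa in "DE":
                net -= 1
        out.append(net / window)
    return out


def charged_blocks_brute(seq, window=10, threshold=0.5):
    """(start, end, sign) triples after merging overlapping same-sign windows."""
    ncpr = ncpr_brute(seq, window)
    blocks = []
    for sign, test in (("+", lambda v: v > threshold), ("-", lambda v: v < -threshold)):
        spans = [(i, i + window) for i, v in enumerate(ncpr) if test(v)]
        merged = []
        for s, e in spans:
            if merged and s < merged[-1][1]:  # overlap with previous block
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        blocks.extend((s, e, sign) for s, e in merged)
    return sorted(blocks)
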