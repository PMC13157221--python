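"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: explicit dictionaries
keyed by symbol tuples, no context packing, no caching, no JIT.  They are
slow and only run on tiny inputs.
"""

from __future__ import annotations

import math


def oracle_train(order: int, records, use_inverted_repeats: bool = False) -> dict:
    """Context-tuple -> [4 counts] by direct enumeration."""
    table: dict[tuple, list[int]] = {}
    for seq in records:
        seq = [int(s) for s in seq]
        variants = [seq]
        if use_inverted_repeats:
            variants.append([3 - s for s in reversed(seq)])
        for s in variants:
            for i in range(order, len(s)):
                ctx = tuple(s[i - order : i])
                row = table.setdefault(ctx, [0, 0, 0, 0])
                row[s[i]] += 1
    return table


def oracle_code_length(target, models, gamma: float):
    """Mixture code length recomputed from scratch.

    ``models`` is a list of dicts with keys: order, alpha, table (from
    oracle_train), stmm (bool), and for STMMs max_subs and window.
    Returns (total_bits, per_symbol_bits).
    """
    target = [int(s) for s in target]
    m = len(models)
    weights = [1.0 / m] * m
    histories: list[list[int]] = [[] for _ in models]
    subs_used = [0] * m
    flags = [[0] * mod.get("window", 1) for mod in models]
    total = 0.0
    per: list[float] = []
    for i, a in enumerate(target):
        probs = []
        for j, mod in enumerate(models):
            k = mod["order"]
            if mod["stmm"]:
                slot = i % mod["window"]
                subs_used[j] -= flags[j][slot]
                flags[j][slot] = 0
            recorded = a
            if i < k:
                p = 0.25
            else:
                ctx = tuple(histories[j][-k:]) if k else ()
                row = mod["table"].get(ctx)
                if row is None:
                    p = 0.25
                    best = 0
                else:
                    tot = sum(row)
                    p = (row[a] + mod["alpha"]) / (tot + 4.0 * mod["alpha"])
                    best = max(range(4), key=lambda s: (row[s], -s))
                if mod["stmm"] and a != best and subs_used[j] < mod["max_subs"]:
                    recorded = best
                    flags[j][i % mod["window"]] = 1
                    subs_used[j] += 1
            histories[j].append(recorded if mod["stmm"] else a)
            probs.append(p)
        pmix = sum(w * p for w, p in zip(weights, probs))
        bits = -math.log2(pmix)
        total += bits
        per.append(bits)
        weights = [w**gamma * p for w, p in zip(weights, probs)]
        z = sum(weights)
        weights = [w / z for w in weights]
    return total, per


def auroc_pairwise(scores, labels) -> float:
    """O(n^2) rank estimator: P(random positive outscores random negative),
    ties credited one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def naive_segments(values, threshold: float, min_length: int):
    """Direct re-scan segmentation: maximal runs of value >= threshold."""
    out = []
    n = len(values)
    i = 0
    while i < n:
        if values[i] >= threshold:
            j = i
            while j < n and values[j] >= threshold:
                j += 1
            if j - i >= min_length:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out
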