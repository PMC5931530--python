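"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python run
enumeration for recurrence statistics and naive O(N^2) template
counting for sample entropy, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_naive(x, m: int, r_abs: float) -> float:
    """Naive sample entropy by explicit template comparison."""
    x = list(map(float, x))
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def _runs(bits) -> list[int]:
    out, run = [], 0
    for v in bits:
        if v:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def rqa_naive(matrix, l_min: int = 2, v_min: int = 2,
              loi_excluded: bool = True) -> dict[str, float]:
    """All seven recurrence statistics by exhaustive run enumeration."""
    m = np.asarray(matrix, dtype=bool).copy()
    n = m.shape[0]
    if loi_excluded:
        for i in range(n):
            m[i, i] = False
        denom = n * n - n
    else:
        denom = n * n
    rr = m.sum() / denom if denom else 0.0

    diag_runs: list[int] = []
    offsets = [k for k in range(-(n - 1), n) if k != 0 or not loi_excluded]
    for k in offsets:
        diag_runs.extend(_runs([m[i, i + k]
                                for i in range(max(0, -k), min(n, n - k))]))
    vert_runs: list[int] = []
    for j in range(n):
        vert_runs.extend(_runs([m[i, j] for i in range(n)]))

    def stats(runs: list[int], lmin: int):
        total = sum(runs)
        kept = [r for r in runs if r >= lmin]
        longest = max(runs) if runs else 0.0
        if not kept or total == 0:
            return 0.0, float(longest), 0.0, 0.0
        frac = sum(kept) / total
        mean_len = sum(kept) / len(kept)
        from collections import Counter
        counts = Counter(kept)
        ent = -sum((c / len(kept)) * math.log(c / len(kept))
                   for c in counts.values())
        return frac, float(longest), mean_len, ent

    det, l_max, l_mean, l_entr = stats(diag_runs, l_min)
    lam, _, tt, _ = stats(vert_runs, v_min)
    return {"RR": float(rr), "DET": det, "LAM": lam, "L_max": l_max,
            "L_entr": l_entr, "L_mean": l_mean, "TT": tt}
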