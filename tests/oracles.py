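"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and literal coordinate
lists, sharing no code with the package, so agreement between the two
routes is meaningful.
"""

import numpy as np

# cubic-convolution kernel, evaluated branch by branch


def oracle_kernel(x, a=-1.0):
    x = abs(float(x))
    if x < 1.0:
        return (a + 2.0) * x * x * x - (a + 3.0) * x * x + 1.0
    if x < 2.0:
        return a * x * x * x - 5.0 * a * x * x + 8.0 * a * x - 4.0 * a
    return 0.0


def oracle_bicubic_at(block, s, t, a=-1.0):
    """Triple-loop weighted sum over a 4x4 block for fractional offsets (s, t)."""
    total = 0.0
    for m in range(4):
        wr = oracle_kernel(s - (m - 1), a)
        for n in range(4):
            wc = oracle_kernel(t - (n - 1), a)
            total += wr * wc * block[m][n]
    return total


# literal snake orders for a 4x4 window (hand-constructed)

SNAKE4 = {
    "H": [(0, 0), (0, 1), (0, 2), (0, 3), (1, 3), (1, 2), (1, 1), (1, 0),
          (2, 0), (2, 1), (2, 2), (2, 3), (3, 3), (3, 2), (3, 1), (3, 0)],
    "V": [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (2, 1), (1, 1), (0, 1),
          (0, 2), (1, 2), (2, 2), (3, 2), (3, 3), (2, 3), (1, 3), (0, 3)],
    "DM": [(3, 0), (3, 1), (2, 0), (1, 0), (2, 1), (3, 2), (3, 3), (2, 2),
           (1, 1), (0, 0), (0, 1), (1, 2), (2, 3), (1, 3), (0, 2), (0, 3)],
    "DA": [(0, 0), (1, 0), (0, 1), (0, 2), (1, 1), (2, 0), (3, 0), (2, 1),
           (1, 2), (0, 3), (1, 3), (2, 2), (3, 1), (3, 2), (2, 3), (3, 3)],
}

STENCILS4 = {
    "DM": [(0, 0, -1 / 16), (1, 1, 9 / 16), (2, 2, 9 / 16), (3, 3, -1 / 16)],
    "DA": [(0, 3, -1 / 16), (1, 2, 9 / 16), (2, 1, 9 / 16), (3, 0, -1 / 16)],
    "H": [(1, 0, -1 / 32), (1, 1, 9 / 32), (1, 2, 9 / 32), (1, 3, -1 / 32),
          (2, 0, -1 / 32), (2, 1, 9 / 32), (2, 2, 9 / 32), (2, 3, -1 / 32)],
    "V": [(0, 1, -1 / 32), (1, 1, 9 / 32), (2, 1, 9 / 32), (3, 1, -1 / 32),
          (0, 2, -1 / 32), (1, 2, 9 / 32), (2, 2, 9 / 32), (3, 2, -1 / 32)],
}


def oracle_variation(window, valid, order):
    """Sum of |differences| between consecutive valid snake elements."""
    seq = [window[r][c] for (r, c) in order if valid[r][c]]
    return sum(abs(seq[i + 1] - seq[i]) for i in range(len(seq) - 1)), max(len(seq) - 1, 0)


def oracle_step2_center(window, valid, min_support=0.5, tie_tol=1e-9):
    """Fully looped reference for one step-2 center value.

    Returns (value, ok, chosen) where chosen is the direction key or "ISO".
    """
    stats = {d: oracle_variation(window, valid, SNAKE4[d]) for d in ("H", "V", "DM", "DA")}
    counts = [c for (_, c) in stats.values()]
    variations = sorted(stats.items(), key=lambda kv: kv[1][0])
    chosen = "ISO"
    if max(counts) > 0 and not any(c < max(counts) / 2 for c in counts):
        vmin = variations[0][1][0]
        v2 = variations[1][1][0]
        if v2 - vmin > tie_tol * (1.0 + vmin):
            chosen = variations[0][0]
    if chosen == "ISO":
        w4 = [oracle_kernel(d, -0.5) for d in (1.5, 0.5, 0.5, 1.5)]
        stencil = [(r, c, w4[r] * w4[c]) for r in range(4) for c in range(4)]
    else:
        stencil = STENCILS4[chosen]
    num = den = absm = 0.0
    for r, c, w in stencil:
        if valid[r][c]:
            num += w * window[r][c]
            den += w
            absm += abs(w)
    ok = absm >= min_support and abs(den) > 1e-9
    return (num / den if ok else 0.0), ok, chosen
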