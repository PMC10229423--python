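"""Independent brute-force oracles shared across test modules."""

import numpy as np


def bh_step_up(p):
    """Benjamini–Hochberg step-up, straight from the definition.

    Sort ascending, walk from the largest p down taking the running
    minimum of p_(k) * n / k, then map back to the input order.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q
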