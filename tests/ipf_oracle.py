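"""Brute-force iterative proportional fitting oracle.

Deliberately independent of the package implementation: plain Python
loops over explicit cell coordinates, no shared code, no vectorised
margin tricks.  Used only to cross-check the raking module.
"""

import itertools

import numpy as np


def brute_force_ipf(seed_table, margins, max_iter=10000, stop=1e-13):
    """margins: list of (kept_axes tuple, target array over those axes)."""
    table = np.array(seed_table, dtype=float)
    shape = table.shape
    cells = list(itertools.product(*[range(k) for k in shape]))
    for _ in range(max_iter):
        worst = 0.0
        for kept_axes, target in margins:
            # current margin, one entry at a time
            current = np.zeros_like(np.asarray(target, dtype=float))
            for cell in cells:
                key = tuple(cell[ax] for ax in kept_axes)
                current[key] += table[cell]
            for cell in cells:
                key = tuple(cell[ax] for ax in kept_axes)
                if current[key] > 0:
                    table[cell] *= target[key] / current[key]
                else:
                    table[cell] = 0.0
            worst = max(worst, float(np.max(np.abs(current - target))))
        if worst < stop:
            break
    return table
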