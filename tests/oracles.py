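"""Independent brute-force oracles, deliberately written with plain loops
and kept free of the package's vectorized implementations."""

from __future__ import annotations

import numpy as np

# Same declared tie-break priority: soft(3) > fat(2) > lung(1) > background(0).
_PRIORITY = (3, 2, 1, 0)


def brute_force_fill(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reference wavefront majority fill with synchronous passes."""
    lab = labels.astype(int).copy()
    assigned = ~mask.astype(bool)
    shape = lab.shape
    while not assigned.all():
        frontier = []
        for idx in zip(*np.nonzero(~assigned)):
            counts = {0: 0, 1: 0, 2: 0, 3: 0}
            seen = 0
            for axis in range(3):
                for step in (-1, 1):
                    nb = list(idx)
                    nb[axis] += step
                    if not (0 <= nb[axis] < shape[axis]):
                        continue
                    nb = tuple(nb)
                    if assigned[nb]:
                        counts[lab[nb]] += 1
                        seen += 1
            if seen > 0:
                best = max(_PRIORITY, key=lambda c: (counts[c], -_PRIORITY.index(c)))
                frontier.append((idx, best))
        if not frontier:
            raise RuntimeError("oracle fill cannot progress")
        for idx, val in frontier:
            lab[idx] = val
            assigned[idx] = True
    return lab.astype(labels.dtype)
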