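"""Shared brute-force oracles used by the test suite."""

import numpy as np


def flood_fill(mask, connectivity):
    """Independent BFS connected-components labeling of a boolean 3D mask."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        component, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            component.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(frozenset(component))
    return set(components)
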