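"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_oracle(mask, connectivity):
    """BFS connected-component labeling, independent of scipy."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels, nxt


def brute_force_filter(mask, cell, min_area, max_gap, connectivity=8):
    """Patch filter oracle: flood fill + exhaustive pairwise cell distances,
    iterated to a fixed point."""
    labels, n = flood_fill_oracle(mask, connectivity)
    cells = {i: np.argwhere(labels == i) for i in range(1, n + 1)}
    areas = {i: len(c) * cell**2 for i, c in cells.items()}
    retained = set(cells)
    while True:
        drop = set()
        for i in retained:
            if areas[i] >= min_area:
                continue
            gap = np.inf
            for j in retained - {i}:
                d = (
                    np.sqrt(
                        (
                            (cells[i][:, None, :] - cells[j][None, :, :]).astype(float)
                            ** 2
                        ).sum(-1)
                    ).min()
                    * cell
                )
                gap = min(gap, max(d - cell, 0.0))
            if gap > max_gap:
                drop.add(i)
        if not drop:
            break
        retained -= drop
    out = np.zeros_like(mask, dtype=bool)
    for i in retained:
        out[labels == i] = True
    return out


def same_partition(a, b):
    """True if two label grids induce the same partition of the cells."""
    pairs = set(zip(a.ravel(), b.ravel()))
    return len({x for x, _ in pairs}) == len(pairs) == len({y for _, y in pairs})
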