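"""Independent brute-force oracles for metric verification.

Pure-Python flood fill and explicit adjacency enumeration — deliberately
naive and slow, sharing no code path with the package implementation.
"""

import numpy as np


def flood_fill_patches(window, connectivity=8):
    """List of patches (each a set of (r, c)) via stack-based flood fill."""
    w = np.asarray(window)
    nrows, ncols = w.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = set()
    patches = []
    for r in range(nrows):
        for c in range(ncols):
            if w[r, c] != 1 or (r, c) in seen:
                continue
            patch = set()
            stack = [(r, c)]
            while stack:
                rr, cc = stack.pop()
                if (rr, cc) in patch:
                    continue
                patch.add((rr, cc))
                for dr, dc in steps:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < nrows and 0 <= nc < ncols
                            and w[nr, nc] == 1 and (nr, nc) not in patch):
                        stack.append((nr, nc))
            seen |= patch
            patches.append(patch)
    return patches


def enumerate_edge_length(window, pixel_size, count_boundary=False):
    """Edge length by checking all four sides of every forest pixel."""
    w = np.asarray(window)
    nrows, ncols = w.shape
    n = 0
    for r in range(nrows):
        for c in range(ncols):
            if w[r, c] != 1:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < nrows and 0 <= nc < ncols:
                    if w[nr, nc] == 0:
                        n += 1
                elif count_boundary:
                    n += 1
    return n * pixel_size


def brute_cell_metrics(window, pixel_size, cell_area, connectivity=8,
                       count_boundary=False):
    """ED/PD/MPA/FC by direct application of their definitions."""
    patches = flood_fill_patches(window, connectivity)
    e = enumerate_edge_length(window, pixel_size, count_boundary)
    n = len(patches)
    forest_px = int((np.asarray(window) == 1).sum())
    if n == 0:
        return {"ED": 0.0, "PD": 0.0, "MPA": None, "FC": 0.0}
    total_px = sum(len(p) for p in patches)
    return {
        "ED": e / cell_area * 10_000.0,
        "PD": n / cell_area * 10_000.0 * 100.0,
        "MPA": total_px * pixel_size ** 2 / 10_000.0 / n,
        "FC": forest_px * pixel_size ** 2 / cell_area,
    }
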