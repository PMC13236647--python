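"""Independent brute-force implementations used as test oracles."""

from __future__ import annotations

import numpy as np


def brute_force_landscape(values, nodata, cell_size, connectivity):
    """Landscape metrics by explicit BFS patch search and pairwise edge
    counting — an independent oracle for small rasters."""
    values = np.asarray(values)
    rows, cols = values.shape
    if nodata is None:
        valid = np.ones_like(values, dtype=bool)
    else:
        valid = values != nodata
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [
            (-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1),
        ]
    else:
        raise ValueError("connectivity must be 4 or 8")

    seen = np.zeros_like(valid)
    patch_sizes = []
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c] or seen[r, c]:
                continue
            cls = values[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in steps:
                    nr, nc = rr + dr, cc + dc
                    if (
                        0 <= nr < rows
                        and 0 <= nc < cols
                        and valid[nr, nc]
                        and not seen[nr, nc]
                        and values[nr, nc] == cls
                    ):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            patch_sizes.append(size)

    area = float(valid.sum()) * cell_size * cell_size
    edge = 0.0
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < rows
                    and 0 <= nc < cols
                    and valid[nr, nc]
                    and values[nr, nc] != values[r, c]
                ):
                    edge += cell_size

    _, counts = np.unique(values[valid], return_counts=True)
    p = counts / counts.sum()
    return {
        "lpi": 100.0 * max(patch_sizes) * cell_size * cell_size / area,
        "pd": len(patch_sizes) / area * 10_000 * 100,
        "ed": edge / (area / 10_000),
        "shdi": float(-(p * np.log(p)).sum()),
    }
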