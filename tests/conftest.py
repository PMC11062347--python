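import numpy as np
import pytest

from echomorph import RoiPolygon, UltrasoundFrame


@pytest.fixture
def flat_frame():
    """100x100 8-bit frame, constant 128, isotropic 0.01 cm/px."""
    return UltrasoundFrame(
        np.full((100, 100), 128, dtype=np.uint8), 8, 0.01, 0.01, source_id="flat"
    )


@pytest.fixture
def unit_frame():
    """Small frame with 1 cm/px spacing for hand-computable geometry."""
    return UltrasoundFrame(np.zeros((20, 20), dtype=np.uint8), 8, 1.0, 1.0, source_id="unit")


@pytest.fixture
def triangle_roi():
    return RoiPolygon([(0, 0), (4, 0), (0, 4)], image_id="tri")


def brute_force_mask(vertices, width, height):
    """Independent boundary-inclusive point-in-polygon rasterizer.

    Even-odd ray casting plus an explicit on-segment check, evaluated at
    every pixel center — the oracle for the production rasterizer.
    """
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            px, py = float(c), float(r)
            on_edge = False
            inside = False
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                # on-segment check
                cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
                if abs(cross) < 1e-9:
                    if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and \
                       min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                        on_edge = True
                        break
                # ray casting: horizontal ray to +x
                if (y1 > py) != (y2 > py):
                    xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xin:
                        inside = not inside
            mask[r, c] = on_edge or inside
    return mask


def largest_four_connected(mask):
    """Independent BFS largest-4-connected-component selector, matching the
    production rasterization rule without sharing its scipy.ndimage path."""
    mask = mask.copy()
    seen = np.zeros_like(mask)
    best = None
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = []
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                if best is None or len(comp) > len(best):
                    best = comp
    out = np.zeros_like(mask)
    for r, c in best or []:
        out[r, c] = True
    return out


def brute_force_auc(pos, neg):
    """Pairwise-comparison AUC with half credit for ties (the oracle)."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
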