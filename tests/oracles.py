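"""Independent brute-force oracles for the texture matrices.

Everything here enumerates voxels, pairs, runs, zones, and neighborhoods
with explicit Python loops — no shared code with the vectorized
implementation beyond the direction table, which is part of the matrix
definitions themselves.
"""

import numpy as np

from fluorad.features.texture import DIRECTIONS_13

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inb(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def glcm_oracle(lv, ng):
    out = np.zeros((len(DIRECTIONS_13), ng, ng))
    for di, d in enumerate(DIRECTIONS_13):
        for idx in np.ndindex(lv.shape):
            a = lv[idx]
            if a == 0:
                continue
            j = tuple(i + o for i, o in zip(idx, d))
            if _inb(j, lv.shape) and lv[j] > 0:
                out[di, a - 1, lv[j] - 1] += 1
                out[di, lv[j] - 1, a - 1] += 1
    return out


def glrlm_oracle(lv, ng):
    runs = []  # (direction, level, length)
    lmax = 1
    for di, d in enumerate(DIRECTIONS_13):
        for idx in np.ndindex(lv.shape):
            a = lv[idx]
            if a == 0:
                continue
            prev = tuple(i - o for i, o in zip(idx, d))
            if _inb(prev, lv.shape) and lv[prev] == a:
                continue  # not the start of a run
            length = 1
            cur = idx
            while True:
                nxt = tuple(i + o for i, o in zip(cur, d))
                if _inb(nxt, lv.shape) and lv[nxt] == a:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((di, a, length))
            lmax = max(lmax, length)
    out = np.zeros((len(DIRECTIONS_13), ng, lmax))
    for di, a, length in runs:
        out[di, a - 1, length - 1] += 1
    return out


def glszm_oracle(lv, ng):
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for idx in np.ndindex(lv.shape):
        if lv[idx] == 0 or seen[idx]:
            continue
        level = lv[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for o in _OFFSETS_26:
                nb = tuple(i + oo for i, oo in zip(cur, o))
                if _inb(nb, lv.shape) and not seen[nb] and lv[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((level, size))
    smax = max((s for _, s in zones), default=1)
    out = np.zeros((ng, smax))
    for level, size in zones:
        out[level - 1, size - 1] += 1
    return out


def gldm_oracle(lv, ng, alpha=0):
    deps = []
    for idx in np.ndindex(lv.shape):
        a = lv[idx]
        if a == 0:
            continue
        dep = 1  # the center voxel depends on itself
        for o in _OFFSETS_26:
            nb = tuple(i + oo for i, oo in zip(idx, o))
            if _inb(nb, lv.shape) and lv[nb] > 0 and abs(lv[nb] - a) <= alpha:
                dep += 1
        deps.append((a, dep))
    dmax = max(d for _, d in deps)
    out = np.zeros((ng, dmax))
    for a, dep in deps:
        out[a - 1, dep - 1] += 1
    return out


def ngtdm_oracle(lv, ng):
    out = np.zeros((ng, 2))
    for idx in np.ndindex(lv.shape):
        a = lv[idx]
        if a == 0:
            continue
        vals = []
        for o in _OFFSETS_26:
            nb = tuple(i + oo for i, oo in zip(idx, o))
            if _inb(nb, lv.shape) and lv[nb] > 0:
                vals.append(lv[nb])
        if not vals:
            continue
        out[a - 1, 0] += 1
        out[a - 1, 1] += abs(a - sum(vals) / len(vals))
    return out


def pad_to_match(a, b):
    """Zero-pad the last axis of the smaller matrix so shapes agree."""
    if a.shape == b.shape:
        return a, b
    width = max(a.shape[-1], b.shape[-1])

    def pad(m):
        pads = [(0, 0)] * (m.ndim - 1) + [(0, width - m.shape[-1])]
        return np.pad(m, pads)

    return pad(a), pad(b)
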