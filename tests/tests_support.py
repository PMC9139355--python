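"""Shared helpers for the test suite: toy cases and independent
brute-force texture formulas (pure-Python enumeration, no package
kernels)."""

import itertools

import numpy as np

from phymri.constants import MAP_SPECS

_DIRS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
_NEIGH = [d for d in itertools.product((-1, 0, 1), repeat=3)
          if d != (0, 0, 0)]


def toy_feature_case(rng, label="GBM", shape=(14, 14, 8)):
    x, y, z = np.mgrid[:shape[0], :shape[1], :shape[2]]
    c = [(s - 1) / 2 for s in shape]
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + ((z - c[2]) * 1.5) ** 2
    tumor = r2 <= 9
    edema = (r2 <= 20) & ~tumor
    images = {}
    for name in ("CET1w", "FLAIR"):
        images[name] = rng.normal(0.0, 1.0, shape)
    for name, spec in MAP_SPECS.items():
        mid = 0.5 * (spec.vmin + spec.vmax)
        width = 0.1 * (spec.vmax - spec.vmin)
        images[name] = np.clip(rng.normal(mid, width, shape),
                               spec.vmin, spec.vmax)
    return {"images": images, "masks": {"tumor": tumor, "edema": edema},
            "spacing": (1.0, 1.0, 1.0), "label": label}


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def brute_glcm_contrast_avg(levels, ng):
    """Direction-averaged GLCM contrast by explicit pair enumeration."""
    vals = []
    shape = levels.shape
    nzidx = np.nonzero(levels)
    box = tuple(slice(a.min(), a.max() + 1) for a in nzidx)
    lv = levels[box]
    shape = lv.shape
    for d in _DIRS:
        pairs = []
        for p in itertools.product(*map(range, shape)):
            if lv[p] == 0:
                continue
            for sign in (1, -1):
                q = tuple(pi + sign * di for pi, di in zip(p, d))
                if _inside(shape, q) and lv[q] > 0:
                    pairs.append((lv[p], lv[q]))
        if pairs:
            total = len(pairs)
            vals.append(sum((i - j) ** 2 for i, j in pairs) / total)
    return float(np.mean(vals)) if vals else 0.0


def brute_glrlm_long_run_avg(levels, ng):
    """Direction-averaged long-run emphasis from explicit run walking."""
    nzidx = np.nonzero(levels)
    lv = levels[tuple(slice(a.min(), a.max() + 1) for a in nzidx)]
    shape = lv.shape
    vals = []
    for d in _DIRS:
        runs = []
        for p in itertools.product(*map(range, shape)):
            i = lv[p]
            if i == 0:
                continue
            prev = tuple(pi - di for pi, di in zip(p, d))
            if _inside(shape, prev) and lv[prev] == i:
                continue
            length, q = 1, tuple(pi + di for pi, di in zip(p, d))
            while _inside(shape, q) and lv[q] == i:
                length += 1
                q = tuple(qi + di for qi, di in zip(q, d))
            runs.append(length)
        if runs:
            vals.append(sum(l**2 for l in runs) / len(runs))
    return float(np.mean(vals)) if vals else 0.0


def _zones(lv):
    visited = np.zeros(lv.shape, bool)
    shape = lv.shape
    out = []
    for start in itertools.product(*map(range, shape)):
        if visited[start] or lv[start] == 0:
            continue
        lvl, stack, size = lv[start], [start], 0
        visited[start] = True
        while stack:
            p = stack.pop()
            size += 1
            for d in _NEIGH:
                q = tuple(pi + di for pi, di in zip(p, d))
                if _inside(shape, q) and not visited[q] and lv[q] == lvl:
                    visited[q] = True
                    stack.append(q)
        out.append((int(lvl), size))
    return out


def brute_glszm_small_area(levels, ng):
    nzidx = np.nonzero(levels)
    lv = levels[tuple(slice(a.min(), a.max() + 1) for a in nzidx)]
    zones = _zones(lv)
    return sum(1.0 / s**2 for _, s in zones) / len(zones)


def brute_gldm_large_dependence(levels, ng):
    nzidx = np.nonzero(levels)
    lv = levels[tuple(slice(a.min(), a.max() + 1) for a in nzidx)]
    shape = lv.shape
    deps = []
    for p in itertools.product(*map(range, shape)):
        i = lv[p]
        if i == 0:
            continue
        dep = 1
        for d in _NEIGH:
            q = tuple(pi + di for pi, di in zip(p, d))
            if _inside(shape, q) and lv[q] > 0 and lv[q] == i:
                dep += 1
        deps.append(dep)
    return sum(d**2 for d in deps) / len(deps)


def brute_ngtdm_coarseness(levels, ng):
    nzidx = np.nonzero(levels)
    lv = levels[tuple(slice(a.min(), a.max() + 1) for a in nzidx)]
    shape = lv.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for p in itertools.product(*map(range, shape)):
        i = lv[p]
        if i == 0:
            continue
        neigh = [lv[tuple(pi + di for pi, di in zip(p, d))]
                 for d in _NEIGH
                 if _inside(shape, tuple(pi + di for pi, di in zip(p, d)))
                 and lv[tuple(pi + di for pi, di in zip(p, d))] > 0]
        if neigh:
            s[i - 1] += abs(i - np.mean(neigh))
            n[i - 1] += 1
    N = n.sum()
    den = float(((n / N) * s).sum())
    return min(1.0 / den, 1e6) if den > 0 else 1e6
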