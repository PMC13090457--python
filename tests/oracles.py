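"""Independent brute-force oracles, deliberately naive and separate from the
package's code paths."""

import itertools

import numpy as np


def brute_surface_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs nearest-background distance for every foreground voxel."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for z, y, x in fg:
        d2 = ((bg - (z, y, x)) ** 2).sum(axis=1)
        out[z, y, x] = np.sqrt(d2.min())
    return out


def brute_ball_erosion(mask: np.ndarray, depth: int) -> np.ndarray:
    """Keep a foreground voxel iff every voxel within Euclidean radius
    ``depth`` of it (inside or outside the grid) is foreground."""
    offsets = [
        (dz, dy, dx)
        for dz in range(-depth, depth + 1)
        for dy in range(-depth, depth + 1)
        for dx in range(-depth, depth + 1)
        if dz * dz + dy * dy + dx * dx <= depth * depth
    ]
    out = np.zeros_like(mask)
    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        ok = True
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]):
                ok = False
                break
            if not mask[zz, yy, xx]:
                ok = False
                break
        if ok:
            out[z, y, x] = True
    return out


_NEIGHBORS = {
    6: [d for d in itertools.product((-1, 0, 1), repeat=3)
        if sum(abs(v) for v in d) == 1],
    18: [d for d in itertools.product((-1, 0, 1), repeat=3)
         if 1 <= sum(abs(v) for v in d) <= 2],
    26: [d for d in itertools.product((-1, 0, 1), repeat=3)
         if any(d)],
}


def union_find_components(mask: np.ndarray, connectivity: int) -> int:
    """Connected-component count by explicit union-find over voxel pairs."""
    voxels = [tuple(v) for v in np.argwhere(mask)]
    index = {v: i for i, v in enumerate(voxels)}
    parent = list(range(len(voxels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for v in voxels:
        for d in _NEIGHBORS[connectivity]:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            j = index.get(w)
            if j is not None:
                ri, rj = find(index[v]), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(voxels))})


def enumerate_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by itertools enumeration (mid-ranks)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    absd = np.abs(d)
    # mid-ranks by explicit averaging of tied sort positions
    order = np.argsort(absd)
    ranks = np.empty(len(d))
    i = 0
    sorted_abs = absd[order]
    while i < len(d):
        j = i
        while j < len(d) and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)
        i = j
    w_obs = float(np.sum(np.sign(d) * ranks))
    hits = total = 0
    for signs in itertools.product((-1.0, 1.0), repeat=len(d)):
        w = float(np.dot(signs, ranks))
        total += 1
        if abs(w) >= abs(w_obs) - 1e-9:
            hits += 1
    return hits / total


def ellipsoid_offset_inner_volume(a, b, c, depth, h):
    """Volume of {x inside the ellipsoid : dist(x, surface) > depth} by
    fine-grid integration with exact point-to-surface distances.

    The nearest surface point of an interior point x satisfies
    q_i = a_i^2 x_i / (a_i^2 + t) with t the root of
    sum(a_i^2 x_i^2 / (a_i^2 + t)^2) = 1 in (-min(a_i)^2, 0]; the distance
    follows as |x - q|. Solved by vectorized bisection.
    """
    axes = np.array([a, b, c], dtype=float)
    grids = [np.arange(-ax + h / 2, ax, h) for ax in axes]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij", sparse=True)
    inside = (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 < 1.0
    pts = np.stack(
        [np.broadcast_to(g, inside.shape)[inside] for g in (zz, yy, xx)], axis=1
    )
    a2 = axes**2
    lo = np.full(len(pts), -a2.min() * (1 - 1e-12))
    hi = np.zeros(len(pts))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = np.sum(a2 * pts**2 / (a2 + mid[:, None]) ** 2, axis=1)
        too_deep = f < 1.0  # t too large (surface overshot): move down
        hi = np.where(too_deep, mid, hi)
        lo = np.where(too_deep, lo, mid)
    t = 0.5 * (lo + hi)
    dist = np.sqrt(np.sum((pts * t[:, None] / (a2 + t[:, None])) ** 2, axis=1))
    return float(np.count_nonzero(dist > depth) * h**3)
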