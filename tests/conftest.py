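import numpy as np
import pytest

from lungmorph import VoxelMask, menger_sponge

SPACING = (1.0, 1.0, 2.5)


def make_mask(fg, spacing=SPACING):
    return VoxelMask(foreground=np.asarray(fg, dtype=bool), spacing=spacing)


def random_mask(shape, density, seed, spacing=SPACING):
    rng = np.random.default_rng(seed)
    fg = rng.random(shape) < density
    if not fg.any():
        fg.flat[0] = True
    return make_mask(fg, spacing)


@pytest.fixture(scope="session")
def sponge2():
    return menger_sponge(2)


@pytest.fixture(scope="session")
def sponge3():
    return menger_sponge(3)


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute force)

def boxcount_oracle(fg, eps):
    """Triple loop over origin-anchored cubes."""
    nx, ny, nz = fg.shape
    count = 0
    for i in range(0, nx, eps):
        for j in range(0, ny, eps):
            for k in range(0, nz, eps):
                if fg[i:i + eps, j:j + eps, k:k + eps].any():
                    count += 1
    return count


def lacunarity_oracle(fg, eps):
    """Enumerate every gliding box; Lambda = var/mean^2 of masses."""
    nx, ny, nz = fg.shape
    masses = []
    for i in range(nx - eps + 1):
        for j in range(ny - eps + 1):
            for k in range(nz - eps + 1):
                masses.append(int(fg[i:i + eps, j:j + eps, k:k + eps].sum()))
    masses = np.asarray(masses, dtype=float)
    return masses.var() / masses.mean() ** 2


def flood_fill_oracle(fg):
    """BFS 26-connected components; returns list of voxel-coordinate sets."""
    from collections import deque

    fg = np.asarray(fg, dtype=bool)
    seen = np.zeros_like(fg)
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(fg)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(w, fg.shape)) and fg[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def dijkstra_oracle(fg, source, target):
    """Pure-python Dijkstra on the 26-connected weighted voxel graph."""
    import heapq
    import math

    fg = np.asarray(fg, dtype=bool)
    offsets = [
        ((dx, dy, dz), math.sqrt(dx * dx + dy * dy + dz * dz))
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    dist = {tuple(source): 0.0}
    heap = [(0.0, tuple(source))]
    target = tuple(target)
    while heap:
        d, v = heapq.heappop(heap)
        if v == target:
            return d
        if d > dist.get(v, np.inf):
            continue
        for off, w in offsets:
            u = tuple(a + b for a, b in zip(v, off))
            if all(0 <= c < s for c, s in zip(u, fg.shape)) and fg[u]:
                nd = d + w
                if nd < dist.get(u, np.inf) - 1e-15:
                    dist[u] = nd
                    heapq.heappush(heap, (nd, u))
    return np.inf


def mst_total_oracle(d):
    """Minimum total weight over all labeled spanning trees (Pruefer)."""
    from itertools import product

    n = d.shape[0]
    if n == 2:
        return d[0, 1]
    best = np.inf
    for seq in product(range(n), repeat=n - 2):
        # decode the Pruefer sequence into tree edges
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        total = 0.0
        seq_list = list(seq)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        import heapq as hq

        hq.heapify(leaves)
        for v in seq_list:
            leaf = hq.heappop(leaves)
            total += d[leaf, v]
            degree[leaf] = 0
            degree[v] -= 1
            if degree[v] == 1:
                hq.heappush(leaves, v)
        u, v = (i for i in range(n) if degree[i] == 1)
        total += d[u, v]
        best = min(best, total)
    return best


def km_oracle(times, events):
    """Hand product-limit estimator at each distinct event time."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    surv = 1.0
    out = []
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        surv *= 1.0 - d / n_at_risk
        out.append((t, surv))
    return out


def logrank_oracle(times, events, group):
    """Observed-minus-expected log-rank by explicit risk-table enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def concordance_oracle(times, risk, events):
    """Exhaustive O(n^2) Harrell's C: higher risk concordant with earlier event."""
    n = len(times)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for one covariate, distinct times."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll
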