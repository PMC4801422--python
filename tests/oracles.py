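"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over definitions, on purpose:
these functions must not share code with the package implementations
they are used to check.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# Threshold criteria, evaluated candidate by candidate
# ---------------------------------------------------------------------------

def _norm(hist):
    hist = np.asarray(hist, dtype=float)
    return hist / hist.sum()


def _split_ok(p, t):
    return p[: t + 1].sum() > 0 and p[t + 1 :].sum() > 0


def scan_shannon_entropy(hist):
    """Argmax over t of the two-class Shannon entropy sum (Kapur)."""
    p = _norm(hist)
    best_t, best = None, -np.inf
    for t in range(255):
        if not _split_ok(p, t):
            continue
        p1 = p[: t + 1].sum()
        val = 0.0
        for q in p[: t + 1]:
            if q > 0:
                q = q / p1
                val -= q * math.log(q)
        p2 = 1.0 - p1
        for q in p[t + 1 :]:
            if q > 0:
                q = q / p2
                val -= q * math.log(q)
        if val > best + 1e-12:
            best, best_t = val, t
    return best_t


def scan_renyi_order(hist, rho):
    """Argmax over t of the two-class Renyi entropy sum at order rho != 1."""
    p = _norm(hist)
    best_t, best = None, -np.inf
    for t in range(255):
        if not _split_ok(p, t):
            continue
        p1 = p[: t + 1].sum()
        p2 = 1.0 - p1
        s1 = sum((q / p1) ** rho for q in p[: t + 1] if q > 0)
        s2 = sum((q / p2) ** rho for q in p[t + 1 :] if q > 0)
        val = (math.log(s1) + math.log(s2)) / (1.0 - rho)
        if val > best + 1e-12:
            best, best_t = val, t
    return best_t


def renyi_combined(hist):
    """Three-order Renyi threshold via the published weighting rule."""
    t1 = scan_shannon_entropy(hist)
    t2 = scan_renyi_order(hist, 0.5)
    t3 = scan_renyi_order(hist, 2.0)
    t_lo, t_mid, t_hi = sorted((t1, t2, t3))
    if abs(t_lo - t_mid) <= 5:
        beta = (1, 2, 1) if abs(t_mid - t_hi) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t_mid - t_hi) <= 5 else (1, 2, 1)
    p = _norm(hist)
    cum = np.cumsum(p)
    omega = cum[t_hi] - cum[t_lo]
    t_star = (
        t_lo * (cum[t_lo] + 0.25 * omega * beta[0])
        + 0.25 * t_mid * omega * beta[1]
        + t_hi * (1.0 - cum[t_hi] + 0.25 * omega * beta[2])
    )
    return int(round(t_star))


def scan_li(hist):
    """Argmin over t of Li's cross entropy (direct evaluation)."""
    p = _norm(hist)
    best_t, best = None, np.inf
    for t in range(255):
        if not _split_ok(p, t):
            continue
        val = 0.0
        for side in (range(0, t + 1), range(t + 1, 256)):
            idx = list(side)
            mass = sum(p[i] for i in idx)
            mean = sum(i * p[i] for i in idx) / mass if mass > 0 else 0.0
            for i in idx:
                if p[i] > 0 and i > 0 and mean > 0:
                    val += i * p[i] * math.log(i / mean)
        if val < best - 1e-12:
            best, best_t = val, t
    return best_t


def scan_huang(hist):
    """Argmin over t of Huang & Wang's fuzziness measure."""
    p = _norm(hist)
    nz = np.nonzero(p)[0]
    c = float(nz[-1] - nz[0])
    best_t, best = None, np.inf
    for t in range(255):
        if not _split_ok(p, t):
            continue
        m0 = p[: t + 1].sum()
        m1 = p[t + 1 :].sum()
        mu0 = sum(i * p[i] for i in range(t + 1)) / m0
        mu1 = sum(i * p[i] for i in range(t + 1, 256)) / m1
        val = 0.0
        for i in range(256):
            if p[i] == 0:
                continue
            mu = mu0 if i <= t else mu1
            u = 1.0 / (1.0 + abs(i - mu) / c)
            if 0 < u < 1:
                val += p[i] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        if val < best - 1e-12:
            best, best_t = val, t
    return best_t


def scan_moments(hist):
    """Tsai rule: t whose below-threshold mass is closest to p0."""
    p = _norm(hist)
    m1 = sum(i * p[i] for i in range(256))
    m2 = sum(i**2 * p[i] for i in range(256))
    m3 = sum(i**3 * p[i] for i in range(256))
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    best_t, best = None, np.inf
    cum = 0.0
    for t in range(255):
        cum += p[t]
        if not _split_ok(p, t):
            continue
        err = abs(cum - p0)
        if err < best - 1e-12:
            best, best_t = err, t
    return best_t


def random_mixture_histogram(rng, n=100_000):
    """Two-Gaussian mixture histogram with randomized parameters."""
    mu1 = rng.uniform(20, 90)
    mu2 = rng.uniform(140, 230)
    sd1 = rng.uniform(5, 20)
    sd2 = rng.uniform(5, 20)
    w = rng.uniform(0.25, 0.75)
    n1 = int(n * w)
    v = np.concatenate(
        [rng.normal(mu1, sd1, n1), rng.normal(mu2, sd2, n - n1)]
    ).clip(0, 255)
    return np.bincount(v.astype(int), minlength=256)[:256]


# ---------------------------------------------------------------------------
# Geometry and graph oracles
# ---------------------------------------------------------------------------

def pixelwise_max_projection(stack):
    stack = np.asarray(stack)
    out = np.zeros(stack.shape[1:], dtype=stack.dtype)
    for y in range(stack.shape[1]):
        for x in range(stack.shape[2]):
            best = stack[0, y, x]
            for z in range(1, stack.shape[0]):
                if stack[z, y, x] > best:
                    best = stack[z, y, x]
            out[y, x] = best
    return out


def point_in_polygon(px, py, verts, tol=1e-9):
    """Even-odd test for a single point, boundary inclusive."""
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if (
            min(x1, x2) - tol <= px <= max(x1, x2) + tol
            and min(y1, y2) - tol <= py <= max(y1, y2) + tol
            and abs(cross) < tol * max(1.0, math.hypot(x2 - x1, y2 - y1))
        ):
            return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def longest_endpoint_path(graph):
    """Exhaustive DFS over simple edge paths of a weighted multigraph.

    ``graph`` is a networkx MultiGraph with 'length_um' edge weights.
    Considers every node pair plus self-loop cycle lengths.
    """
    best = 0.0
    edges = [
        (u, v, k, d["length_um"]) for u, v, k, d in graph.edges(keys=True, data=True)
    ]
    for u, v, k, w in edges:
        if u == v:
            best = max(best, w)

    def dfs(node, used, acc):
        nonlocal best
        best = max(best, acc)
        for u, v, k, w in edges:
            if k is None:
                continue
            if u == node and (u, v, k) not in used and u != v:
                dfs(v, used | {(u, v, k)}, acc + w)
            elif v == node and (u, v, k) not in used and u != v:
                dfs(u, used | {(u, v, k)}, acc + w)

    for start in graph.nodes:
        dfs(start, frozenset(), 0.0)
    return best


def local_maxima_26(stack):
    """All voxels >= every 26-neighbor, by explicit comparison."""
    stack = np.asarray(stack)
    nz, ny, nx = stack.shape
    out = np.zeros(stack.shape, dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = stack[z, y, x]
                ok = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                if stack[zz, yy, xx] > v:
                                    ok = False
                if ok:
                    out[z, y, x] = True
    return out


def grey_dilate_then_erode(stack, footprint):
    """Two-pass morphological closing by explicit min/max loops."""
    stack = np.asarray(stack, dtype=float)
    offs = [tuple(o) for o in np.argwhere(footprint) - np.array(footprint.shape) // 2]
    nz, ny, nx = stack.shape

    def apply(op, data, pad):
        out = np.empty_like(data)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    vals = []
                    for dz, dy, dx in offs:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                            vals.append(data[zz, yy, xx])
                        else:
                            vals.append(pad)
                    out[z, y, x] = op(vals)
        return out

    dil = apply(max, stack, -np.inf)
    return apply(min, dil, np.inf)
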