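"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over definitions, so
it shares no code path with the package implementation it checks.
"""

import numpy as np


def brute_force_hausdorff(a, b):
    """max over both directions of the farthest nearest-neighbor distance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def directed(p, q):
        worst = 0.0
        for pi in p:
            best = np.inf
            for qi in q:
                d = np.hypot(pi[0] - qi[0], pi[1] - qi[1])
                if d < best:
                    best = d
            if best > worst:
                worst = best
        return worst

    return max(directed(a, b), directed(b, a))


def brute_force_region_means(image, phi, eps):
    """Per-pixel Heaviside-weighted means, plain accumulation loops."""
    num_i = den_i = num_o = den_o = 0.0
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi[r, c] / eps))
            num_i += image[r, c] * h
            den_i += h
            num_o += image[r, c] * (1.0 - h)
            den_o += 1.0 - h
    return num_i / den_i, num_o / den_o


def brute_force_cv_update(image, phi, mu, nu, lam_in, lam_out, dt, eps):
    """Termwise evaluation of the CV evolution update on a small grid.

    Uses the same finite-difference convention as the implementation
    (np.gradient central differences, one-sided at borders; gradient
    magnitude floored at 1e-8) but written as explicit loops.
    """
    h, w = image.shape

    def grad(f):
        gr = np.zeros_like(f)
        gc = np.zeros_like(f)
        for r in range(h):
            for c in range(w):
                gr[r, c] = (
                    f[min(r + 1, h - 1), c] - f[max(r - 1, 0), c]
                ) / (min(r + 1, h - 1) - max(r - 1, 0))
                gc[r, c] = (
                    f[r, min(c + 1, w - 1)] - f[r, max(c - 1, 0)]
                ) / (min(c + 1, w - 1) - max(c - 1, 0))
        return gr, gc

    c_i, c_o = brute_force_region_means(image, phi, eps)
    gr, gc = grad(phi)
    norm = np.maximum(np.sqrt(gr**2 + gc**2), 1e-8)
    nrr, _ = grad(gr / norm)
    _, ncc = grad(gc / norm)
    curv = nrr + ncc
    new = np.zeros_like(phi)
    for r in range(h):
        for c in range(w):
            delta = (eps / np.pi) / (eps**2 + phi[r, c] ** 2)
            force = (
                mu * curv[r, c]
                - nu
                - lam_in * (image[r, c] - c_i) ** 2
                + lam_out * (image[r, c] - c_o) ** 2
            )
            new[r, c] = phi[r, c] + dt * delta * force
    return new


def brute_force_window_means(image, phi, rows, cols, eps):
    """Weighted means over an explicit index set, plain loops."""
    num_u = den_u = num_v = den_v = 0.0
    for r in rows:
        for c in cols:
            h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi[r, c] / eps))
            num_u += image[r, c] * h
            den_u += h
            num_v += image[r, c] * (1.0 - h)
            den_v += 1.0 - h
    return num_u / den_u, num_v / den_v


def brute_force_histogram_probs(samples, n_bins, lo, hi):
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for s in samples:
        s = min(max(s, lo), hi)
        b = int((s - lo) / width)
        if b == n_bins:  # s == hi lands in the last bin
            b -= 1
        counts[b] += 1
    total = sum(counts)
    return [c / total for c in counts]


def brute_force_entropy(samples, n_bins, lo, hi):
    probs = brute_force_histogram_probs(samples, n_bins, lo, hi)
    return -sum(p * np.log(p) for p in probs if p > 0)


def brute_force_local_force(image, phi, rows, cols, eps, n_bins, lo, hi, floor):
    """Straight-line evaluation of one window's summed fitting force."""
    u, v = brute_force_window_means(image, phi, rows, cols, eps)
    inside = [image[r, c] for r in rows for c in cols if phi[r, c] > 0]
    outside = [image[r, c] for r in rows for c in cols if phi[r, c] <= 0]
    e_in = max(brute_force_entropy(inside, n_bins, lo, hi), floor)
    e_out = max(brute_force_entropy(outside, n_bins, lo, hi), floor)
    total = 0.0
    for r in rows:
        for c in cols:
            delta = (eps / np.pi) / (eps**2 + phi[r, c] ** 2)
            total += delta * (
                e_in * (image[r, c] - u) ** 2 - e_out * (image[r, c] - v) ** 2
            )
    return total


def brute_force_circle_accumulator(edges, radii):
    """Vote counting for the circular Hough transform, plain loops.

    For each edge pixel and each radius, votes go to every accumulator cell
    (center) whose distance to the edge pixel rounds to that radius; votes
    are normalized by the number of cells at that radius from a point.
    """
    h, w = edges.shape
    acc = np.zeros((len(radii), h, w))
    er, ec = np.nonzero(edges)
    for ri, rad in enumerate(radii):
        hits = np.zeros((h, w))
        per_point = 0
        offsets = []
        for dr in range(-rad, rad + 1):
            for dc in range(-rad, rad + 1):
                if round(np.hypot(dr, dc)) == rad:
                    offsets.append((dr, dc))
        per_point = len(offsets)
        for pr, pc in zip(er, ec):
            for dr, dc in offsets:
                rr, cc = pr + dr, pc + dc
                if 0 <= rr < h and 0 <= cc < w:
                    hits[rr, cc] += 1
        acc[ri] = hits / max(per_point, 1)
    return acc
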