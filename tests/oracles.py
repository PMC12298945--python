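"""Independent brute-force reimplementations of the energy kernels.

Everything here is written as plain double loops straight from the
textbook formulas, deliberately sharing no code with the package, so it
can serve as an oracle for the vectorized kernels.
"""

import math

import numpy as np

KE = 332.0637


def brute_coulomb(coords, charges, idx_a, idx_b):
    total = 0.0
    for i in idx_a:
        for j in idx_b:
            r = math.dist(coords[i], coords[j])
            total += KE * charges[i] * charges[j] / r
    return total


def brute_lj(coords, rmin_half, eps, idx_a, idx_b):
    total = 0.0
    for i in idx_a:
        for j in idx_b:
            r = math.dist(coords[i], coords[j])
            rm = rmin_half[i] + rmin_half[j]
            e = math.sqrt(eps[i] * eps[j])
            total += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
    return total


def brute_obc2_radii(coords, rho, screen, offset=0.09,
                     alpha=1.0, beta=0.8, gamma=4.85):
    n = len(coords)
    red = [rho[i] - offset for i in range(n)]
    radii = []
    for i in range(n):
        integral = 0.0
        for j in range(n):
            if j == i:
                continue
            r = math.dist(coords[i], coords[j])
            sr = screen[j] * red[j]
            if r + sr <= red[i]:
                continue
            upper = r + sr
            lower = max(abs(r - sr), red[i])
            term = 0.5 * (
                1 / lower - 1 / upper
                + 0.25 * (r - sr * sr / r) * (1 / upper ** 2 - 1 / lower ** 2)
                + 0.5 / r * math.log(lower / upper)
            )
            if red[i] < sr - r:
                term += 1 / red[i] - 1 / lower
            integral += term
        psi = integral * red[i]
        arg = alpha * psi - beta * psi ** 2 + gamma * psi ** 3
        radii.append(1.0 / (1.0 / red[i] - math.tanh(arg) / rho[i]))
    return np.array(radii)


def brute_gb_energy(coords, charges, radii, eps_in=1.0, eps_out=78.5):
    n = len(coords)
    pref = -0.5 * KE * (1 / eps_in - 1 / eps_out)
    total = 0.0
    for i in range(n):
        for j in range(n):
            r2 = math.dist(coords[i], coords[j]) ** 2
            rr = radii[i] * radii[j]
            fgb = math.sqrt(r2 + rr * math.exp(-r2 / (4 * rr)))
            total += pref * charges[i] * charges[j] / fgb
    return total


def brute_sasa(coords, radii, probe, points):
    """Shrake-Rupley with an externally supplied unit point set so the
    quadrature matches; occlusion logic is the naive triple loop."""
    n = len(coords)
    areas = []
    for i in range(n):
        big = radii[i] + probe
        exposed = 0
        for p in points:
            pt = coords[i] + big * p
            ok = True
            for j in range(n):
                if j == i:
                    continue
                if math.dist(pt, coords[j]) <= radii[j] + probe:
                    ok = False
                    break
            if ok:
                exposed += 1
        areas.append(4 * math.pi * big ** 2 * exposed / len(points))
    return np.array(areas)


def random_system(seed, n_atoms=8, box=7.0, min_dist=1.6):
    """Random parameterized point cloud with a receptor/ligand split."""
    rng = np.random.default_rng(seed)
    coords = []
    while len(coords) < n_atoms:
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - c) >= min_dist for c in coords):
            coords.append(cand)
    coords = np.array(coords)
    charges = rng.uniform(-0.8, 0.8, size=n_atoms)
    rmin_half = rng.uniform(1.3, 2.1, size=n_atoms)
    eps = rng.uniform(0.02, 0.25, size=n_atoms)
    rho = rng.uniform(1.2, 2.0, size=n_atoms)
    screen = rng.uniform(0.7, 0.9, size=n_atoms)
    n_a = n_atoms // 2
    return coords, charges, rmin_half, eps, rho, screen, n_a
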