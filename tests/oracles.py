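"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: plain loops,
explicit minimum-image arithmetic and exhaustive enumeration, so they can
serve as oracles for the production implementations.
"""

import itertools
import math

import numpy as np


def mi(vec, box):
    """Minimum image of a displacement vector, componentwise."""
    if box is None:
        return vec
    return [v - b * round(v / b) for v, b in zip(vec, box)]


def dist(a, b, box):
    v = mi([a[0] - b[0], a[1] - b[1], a[2] - b[2]], box)
    return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)


def brute_hbonds(coords, topology, donors, acceptors, box,
                 d_cut=2.5, angle_cut=120.0):
    """All-pairs hydrogen-bond scan; returns (donor, hydrogen, acceptor) tuples."""
    found = []
    for d in donors:
        rec = topology.atom(d)
        if not (rec.is_donor_heavy and rec.bound_hydrogens):
            continue
        for h in rec.bound_hydrogens:
            for a in acceptors:
                if a in (d, h) or not topology.atom(a).is_acceptor:
                    continue
                r = dist(coords[a], coords[h], box)
                if r >= d_cut:
                    continue
                vhd = mi([coords[d][k] - coords[h][k] for k in range(3)], box)
                vha = mi([coords[a][k] - coords[h][k] for k in range(3)], box)
                num = sum(x * y for x, y in zip(vhd, vha))
                den = math.sqrt(sum(x * x for x in vhd)) * \
                    math.sqrt(sum(x * x for x in vha))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, num / den))))
                if ang > angle_cut:
                    found.append((d, h, a))
    return found


def brute_single_linkage(matrix, cutoff):
    """Union-find connected components on distances strictly below cutoff."""
    n = len(matrix)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i][j] < cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def brute_lj_coulomb(coords, charges, sigmas, epsilons, group_a, group_b, box,
                     ke=1389.35458):
    """Double-loop LJ + Coulomb with Lorentz-Berthelot combining."""
    e_vdw = 0.0
    e_coul = 0.0
    for i in group_a:
        for j in group_b:
            r = dist(coords[i], coords[j], box)
            s = 0.5 * (sigmas[i] + sigmas[j])
            e = math.sqrt(epsilons[i] * epsilons[j])
            sr6 = (s / r) ** 6
            e_vdw += 4.0 * e * (sr6 * sr6 - sr6)
            e_coul += ke * charges[i] * charges[j] / r
    return e_vdw, e_coul


def brute_water_bridges(edges, ligand_sites, protein_sites, water_ids,
                        max_waters=2):
    """Exhaustive path enumeration on an undirected site/water edge set.

    ``edges`` is a set of frozensets over node labels; returns a set of
    (ligand_site, water_chain_tuple, protein_site).
    """
    bridges = set()
    for lsite in ligand_sites:
        for psite in protein_sites:
            for n_w in range(1, max_waters + 1):
                for chain in itertools.permutations(water_ids, n_w):
                    nodes = [("L", lsite)] + [("W", w) for w in chain] + \
                        [("P", psite)]
                    if all(frozenset((u, v)) in edges
                           for u, v in zip(nodes, nodes[1:])):
                        bridges.add((lsite, chain, psite))
    return bridges


def brute_kabsch_rmsd(mobile, reference, n_starts=60, seed=0):
    """Best RMSD over rotations found by multi-start local minimisation."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ R.T - ref) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    return best
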