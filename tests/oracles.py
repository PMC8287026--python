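"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration and direct
paraxial ray transfer — and shares no code with the package's own
algorithms.
"""

import itertools
import math

import numpy as np


def enumerate_path_cost(nodes, grads, max_jump_px, skip_cost=2.5, eps=1e-6):
    """Minimum surface cost by enumerating every choose-or-skip assignment.

    Mirrors the segmentation cost model by definition: node cost
    2 - normalised gradient + eps, skip cost per skipped non-empty column,
    jump limit scaled by column separation, at least two selected nodes.
    Returns inf when no feasible assignment exists.
    """
    n = len(nodes)
    nonempty = [i for i in range(n) if len(nodes[i])]
    if len(nonempty) < 2:
        return np.inf
    allg = np.concatenate([np.asarray(grads[i], dtype=float) for i in nonempty])
    gmin, gmax = allg.min(), allg.max()
    span = gmax - gmin

    def node_cost(i, a):
        ghat = (grads[i][a] - gmin) / span if span > 0 else 1.0
        return 2.0 - ghat + eps

    best = np.inf
    options = [list(range(len(nodes[i]))) + [None] for i in nonempty]
    for combo in itertools.product(*options):
        chosen = [(i, a) for i, a in zip(nonempty, combo) if a is not None]
        if len(chosen) < 2:
            continue
        cost = skip_cost * (len(nonempty) - len(chosen))
        feasible = True
        prev = None
        for i, a in chosen:
            cost += node_cost(i, a)
            if prev is not None:
                pi, pa = prev
                if abs(nodes[i][a] - nodes[pi][pa]) > max_jump_px * (i - pi):
                    feasible = False
                    break
            prev = (i, a)
        if feasible:
            best = min(best, cost)
    return best


def mann_whitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group labels.

    For tie-free pooled data: U of x is computed for every C(n1+n2, n1)
    assignment of ranks to the first group; p = 2 * min(P(U <= u), P(U >= u))
    capped at 1.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(pooled, n1):
        us.append(sum(ranks[v] for v in combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def raytrace_axial_length(se_d, radius_mm, n_medium, lens_distance_mm, lens_power_d):
    """Axial length by direct ABCD ray-transfer through the schematic eye.

    A paraxial ray from the far point is propagated through the corneal
    surface and the thin lens; the axial length is where the ray crosses
    the axis.  Independent of the vergence-chain implementation.
    """
    fc = (n_medium - 1.0) * 1000.0 / radius_mm  # diopters
    d = lens_distance_mm / 1000.0
    # ray from the far point at height y=1 on the cornea: slope u = -y/l
    # with far-point distance l, so the reduced angle (omega = n*u) is
    # -vergence * y, vergence = se_d in air
    y = 1.0
    omega = -se_d * y
    omega = omega - fc * y              # corneal refraction
    y2 = y + (d / n_medium) * omega     # translate to the lens in the medium
    omega2 = omega - lens_power_d * y2  # thin-lens refraction
    if omega2 >= 0 or y2 <= 0:
        return math.inf
    t = -y2 * n_medium / omega2         # axial distance to the crossing
    return lens_distance_mm + t * 1000.0
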