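"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive quantities by a different route than the
package: the TSCE hazard by numerical integration of the characteristic
ODEs (scipy), and the frontier geometry by exhaustive pairwise dominance
plus leave-one-out envelope evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from ctscreen.natural_history import _history_segments


def tsce_ode_oracle(smoking, t, params):
    """(cumulative hazard, hazard) at age t via segment-wise ODE integration
    of the backward Riccati system for (Phi, Psi, H, h)."""
    segs = _history_segments(smoking, params, t)
    phi, psi, H, h = 1.0, -segs[-1][5], 0.0, 0.0
    for a, b, nu, al, be, mu in reversed(segs):
        def rhs(s, y, nu=nu, al=al, be=be, mu=mu):
            phi, psi, H, h = y
            return [-(al * phi * phi - (al + be + mu) * phi + be),
                    -(2 * al * phi - (al + be + mu)) * psi,
                    -nu * (1 - phi),
                    nu * psi]
        sol = solve_ivp(rhs, (b, a), [phi, psi, H, h], rtol=1e-11, atol=1e-16)
        phi, psi, H, h = sol.y[:, -1]
    return H, h


def dominated_oracle(x, y):
    """O(n^2) pairwise dominance: <= screens and >= benefit, one strict."""
    n = len(x)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (x[j] <= x[i] and y[j] >= y[i]
                    and (x[j] < x[i] or y[j] > y[i])):
                out[i] = True
                break
    return out


def envelope_value_oracle(query_x, x, y):
    """Concave-envelope value at ``query_x`` by maximizing over all chords
    between anchor/support points (origin, non-dominated points, and the
    flat extension to the largest screen count)."""
    keep = ~dominated_oracle(x, y)
    px = np.concatenate([[0.0], np.asarray(x, float)[keep],
                         [float(np.max(x))]])
    py = np.concatenate([[0.0], np.asarray(y, float)[keep],
                         [float(np.max(y))]])
    best = -np.inf
    for i in range(len(px)):
        if px[i] == query_x:
            best = max(best, py[i])
        for j in range(len(px)):
            lo, hi = sorted((px[i], px[j]))
            if lo <= query_x <= hi and hi > lo:
                lam = (query_x - px[i]) / (px[j] - px[i])
                best = max(best, py[i] + lam * (py[j] - py[i]))
    return best


def frontier_oracle(x, y):
    """(efficient_mask, distances) by brute force, on normalized benefit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    norm = y / y.max() if y.max() > 0 else y
    dom = dominated_oracle(x, norm)
    dist = np.array([max(envelope_value_oracle(x[i], x, norm) - norm[i], 0.0)
                     for i in range(len(x))])
    efficient = np.zeros(len(x), dtype=bool)
    for i in range(len(x)):
        if dom[i] or dist[i] > 1e-12:
            continue
        # hull vertex iff the envelope without this point falls below it
        others = np.ones(len(x), dtype=bool)
        others[i] = False
        env_wo = envelope_value_oracle(x[i], x[others], norm[others])
        efficient[i] = env_wo < norm[i] - 1e-12
    dist[efficient] = 0.0
    return efficient, dist


def consensus_oracle(deciles, decile_cut=3, min_variants=3):
    """Direct rule evaluation. ``deciles[sex][variant]`` maps label->decile;
    returns the sorted consensus list."""
    per_sex = {}
    for sex, per_variant in deciles.items():
        labels = set.union(*(set(d) for d in per_variant))
        ok = set()
        for lab in labels:
            count = sum(1 for d in per_variant if d[lab] <= decile_cut)
            if count >= min_variants:
                ok.add(lab)
        per_sex[sex] = ok
    return sorted(set.intersection(*per_sex.values()))
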