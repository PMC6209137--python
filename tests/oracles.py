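"""Independent brute-force oracles used to cross-check the implementation.

The isotopomer solver here deliberately avoids the package's cumomer
cascade: it enumerates the full isotopomer balance system over all labeled
forms of every balanced pool and solves it as one (generally nonlinear)
root-finding problem. Feasible only for tiny networks, which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root


def species_isotopomers(pattern, purity):
    """Isotopomer distribution of one tracer species, positions independent."""
    n = len(pattern)
    probs = [purity if b else 0.0 for b in pattern]
    out = np.zeros(1 << n)
    for mask in range(1 << n):
        val = 1.0
        for i in range(n):
            p = probs[i]
            val *= p if (mask >> i) & 1 else (1.0 - p)
        out[mask] = val
    return out


def mixture_isotopomers(species, fractions):
    out = np.zeros(1 << len(species[0].pattern))
    for sp, f in zip(species, fractions):
        out += f * species_isotopomers(sp.pattern, sp.purity)
    return out


def brute_force_labeling(network, flux_state, input_iso):
    """Solve the full isotopomer balance system of all balanced pools.

    ``input_iso`` maps input pool names to isotopomer distributions.
    Returns pool -> isotopomer fraction vector.
    """
    mets = network.metabolite_index
    pools = [m for m in network.balanced_pools() if m.n_carbons > 0]
    sizes = {m.name: 1 << m.n_carbons for m in pools}
    offsets = {}
    off = 0
    for m in pools:
        offsets[m.name] = off
        off += sizes[m.name]
    total = off

    directed = []
    for r in network.reactions:
        directed.append((r, +1, flux_state.forward(r.name)))
        if r.reversible:
            directed.append((r, -1, flux_state.backward(r.name)))

    balanced = set(sizes)

    def unpack(x):
        vals = {p: x[offsets[p] : offsets[p] + sizes[p]] for p in sizes}
        vals.update(input_iso)
        return vals

    def residual(x):
        vals = unpack(x)
        res = np.zeros(total)
        outflux = {p: 0.0 for p in sizes}
        for r, d, f in directed:
            educt_side = r.educt_instances if d > 0 else r.product_instances
            for met, _ in educt_side:
                if met in outflux:
                    outflux[met] += f
        for r, d, f in directed:
            if f == 0.0:
                continue
            educt_side = r.educt_instances if d > 0 else r.product_instances
            product_side = r.product_instances if d > 0 else r.educt_instances
            amap = r.atom_map()
            origin = amap if d > 0 else {v: k for k, v in amap.items()}
            for pi, (pmet, _) in enumerate(product_side):
                if pmet not in balanced:
                    continue
                npc = mets[pmet].n_carbons
                for sigma in range(1 << npc):
                    # per educt instance: required bits on mapped positions
                    need = {}
                    for c in range(npc):
                        ei, epos = origin[(pi, c)]
                        maskbits, valbits = need.get(ei, (0, 0))
                        maskbits |= 1 << epos
                        if (sigma >> c) & 1:
                            valbits |= 1 << epos
                        need[ei] = (maskbits, valbits)
                    prod = f
                    for ei, (maskbits, valbits) in need.items():
                        emet = educt_side[ei][0]
                        vec = vals[emet]
                        prod *= sum(
                            vec[iso]
                            for iso in range(vec.size)
                            if (iso & maskbits) == valbits
                        )
                    res[offsets[pmet] + sigma] += prod
        for p in sizes:
            sl = slice(offsets[p], offsets[p] + sizes[p])
            res[sl] -= outflux[p] * x[sl]
        return res

    x0 = np.zeros(total)
    for p in sizes:
        x0[offsets[p]] = 1.0  # start unlabeled
    sol = root(residual, x0, method="hybr", tol=1e-12)
    assert sol.success, f"brute-force solver failed: {sol.message}"
    vals = unpack(sol.x)
    return {p: vals[p] for p in sizes}
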