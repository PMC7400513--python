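"""Brute-force isotopomer oracle via full cumomer enumeration.

Used solely to verify the EMU cascade on small networks. Every cumomer
(metabolite x carbon subset) of every balanced metabolite is enumerated;
the level-k balances are linear given levels < k because a bimolecular
condensation factorizes into a product of lower-level cumomers. The exact
steady-state cumomer solution is Moebius-inverted to isotopomer fractions
and marginalized to MIDs.

The total isotopomer state space is capped (sum of 2^n over balanced
metabolites <= 2^20); larger models must use the EMU path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .emu import MIDVector, _species_position_probs
from .errors import EMUSingularityError, StateSpaceError, UnreachableEMUError
from .network import FluxVector, NetworkModel

MAX_STATE_SPACE = 2 ** 20


class CumomerSolution:
    """Exact steady-state cumomer fractions for one tracer experiment."""

    def __init__(self, model: NetworkModel, fluxes: FluxVector, tracers: list):
        self.model = model
        self.tracers = list(tracers)
        self._solve(fluxes)

    def _input_cumomer(self, met, subset):
        n = self.model.metabolites[met].n_carbons
        total = 0.0
        for frac, probs in _species_position_probs(met, n, self.tracers):
            total += frac * float(np.prod([probs[i] for i in subset])) if subset else frac
        return total

    def _solve(self, fluxes: FluxVector):
        model = self.model
        mets = model.metabolites
        balanced = [m for m in model.balanced_ids if mets[m].n_carbons > 0]
        if sum(2 ** mets[m].n_carbons for m in balanced) > MAX_STATE_SPACE:
            raise StateSpaceError(
                "isotopomer state space exceeds the brute-force limit (2^20)"
            )
        inputs = set(model.input_ids())

        # direction-expanded reaction variants
        entries = []  # (flux, weight, subs, smaps, prods, pmaps)
        cons = {m: 0.0 for m in balanced}
        for r in model.reactions:
            for sense in (+1, -1) if r.reversible else (+1,):
                flux = fluxes.forward(r.id) if sense > 0 else fluxes.backward(r.id)
                if sense > 0:
                    subs, prods = r.substrates, r.products
                else:
                    subs, prods = r.products, r.substrates
                for m, c in subs:
                    if m in cons:
                        cons[m] += c * flux
                if not r.mapped:
                    continue
                variants = r.map_variants(mets)
                if sense < 0:
                    variants = [(w, pm, sm) for (w, sm, pm) in variants]
                for weight, smaps, pmaps in variants:
                    entries.append((flux, weight, subs, smaps, prods, pmaps))

        # unknown index per level
        self.x: dict = {}  # (met, frozenset) -> value
        levels: dict = {}
        for m in balanced:
            for k in range(1, mets[m].n_carbons + 1):
                for subset in combinations(range(mets[m].n_carbons), k):
                    levels.setdefault(k, []).append((m, frozenset(subset)))

        for k in sorted(levels):
            unknowns = levels[k]
            index = {u: i for i, u in enumerate(unknowns)}
            n = len(unknowns)
            A = np.zeros((n, n))
            b = np.zeros(n)
            for (met, subset), i in index.items():
                A[i, i] -= cons[met]
                produced = False
                for flux, weight, subs, smaps, prods, pmaps in entries:
                    if flux == 0.0:
                        continue
                    for (pm, _), pmap in zip(prods, pmaps):
                        if pm != met or not pmap:
                            continue
                        produced = True
                        needed = {pmap[p] for p in subset}
                        parts = []
                        for (sm, _), smap in zip(subs, smaps):
                            pos = frozenset(
                                j for j, ch in enumerate(smap) if ch in needed
                            )
                            if pos:
                                parts.append((sm, pos))
                        val = weight * flux
                        # at most one part can sit at the current level
                        prod_known = 1.0
                        current = None
                        for sm, pos in parts:
                            if sm in inputs:
                                prod_known *= self._input_cumomer(sm, pos)
                            elif len(pos) == k:
                                current = (sm, pos)
                            else:
                                prod_known *= self.x[(sm, pos)]
                        if current is not None:
                            A[i, index[current]] += val * prod_known
                        else:
                            b[i] -= val * prod_known
                if not produced and cons[met] > 0:
                    raise UnreachableEMUError(
                        f"balanced metabolite {met!r} consumed but never produced"
                    )
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                raise EMUSingularityError(k, [f"{m}:{sorted(s)}" for m, s in unknowns]) from None
            for u, i in index.items():
                self.x[u] = float(sol[i])

        self._inputs = inputs

    # -- queries -----------------------------------------------------------

    def cumomer(self, met, subset) -> float:
        subset = frozenset(subset)
        if met in self._inputs:
            return self._input_cumomer(met, subset)
        if not subset:
            return 1.0
        return self.x[(met, subset)]

    def isotopomers(self, met, positions=None) -> dict:
        """Exact labeling-pattern fractions over the given 0-based positions
        (default: the full backbone). Keys are tuples of labeled positions."""
        if positions is None:
            positions = tuple(range(self.model.metabolites[met].n_carbons))
        pos = list(positions)
        out = {}
        for k in range(len(pos) + 1):
            for labeled in combinations(pos, k):
                rest = [p for p in pos if p not in labeled]
                total = 0.0
                for j in range(len(rest) + 1):
                    for extra in combinations(rest, j):
                        total += (-1) ** j * self.cumomer(met, set(labeled) | set(extra))
                out[tuple(sorted(labeled))] = total
        return out

    def mid(self, met, positions=None) -> np.ndarray:
        iso = self.isotopomers(met, positions)
        n = max(len(k) for k in iso)
        mid = np.zeros(n + 1)
        for labeled, p in iso.items():
            mid[len(labeled)] += p
        return mid


def brute_force_mids(
    model: NetworkModel,
    fluxes: FluxVector,
    tracers: list,
    fragments: list,
    mixing_fractions=None,
) -> dict:
    """Exact fragment MIDs by full cumomer enumeration (verification oracle).

    Mirrors :func:`fluxtrace.emu.simulate_mids` for the same fragment list.
    """
    sol = CumomerSolution(model, fluxes, tracers)
    rules = model.mixing_rules
    out = {}
    for frag in fragments:
        if frag.metabolite in rules:
            contributors = rules[frag.metabolite]
            fracs = (mixing_fractions or {}).get(frag.metabolite)
            mid = np.zeros(frag.n_carbons + 1)
            for c in contributors:
                w = fracs[c] if fracs else 1.0 / len(contributors)
                mid += w * sol.mid(c, frag.positions)
        else:
            mid = sol.mid(frag.metabolite, frag.positions)
        out[frag.id] = MIDVector(id=frag.id, masses=mid, space="backbone")
    return out
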