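"""Steady-state MID simulation by EMU decomposition.

An elementary metabolite unit (EMU) is a subset of a metabolite's carbons.
Starting from the observed fragment backbones, the network is decomposed
into the minimal set of EMUs whose mass isotopomer distributions (MIDs)
determine the observations; EMUs of equal size satisfy a linear balance
system whose inhomogeneous terms are convolutions of smaller (or input)
EMU MIDs, so the cascade is solved dense-LU layer by layer in increasing
size.

Reversible reactions enter as two opposing direction fluxes (forward =
net+ + exchange, backward = net- + exchange); rotationally symmetric
molecules contribute equal-weight alternative atom maps, which is what
generates positional scrambling through fumarate and succinate.

Tracer purity is applied positionally and independently (a "99% purity"
position is 13C with p = 0.99); unlabeled positions of input substrates
carry the natural 13C fraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import EMUSingularityError, FragmentFormulaError, UnreachableEMUError
from .network import FluxVector, NetworkModel

#: Natural abundance of 13C used for unlabeled tracer positions.
NAT_C13 = 0.0107

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    out: dict = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise FragmentFormulaError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not out:
        raise FragmentFormulaError(f"cannot parse formula {formula!r}")
    return out


@dataclass(frozen=True)
class TracerSpec:
    """One isotopic species of a labelled substrate.

    ``labeled_positions`` are 1-based carbon indices; ``purity`` is the
    per-position 13C enrichment; ``fraction`` supports tracer mixtures
    (fractions of species of one substrate must sum to <= 1, the remainder
    being unlabeled material at natural abundance).
    """

    substrate: str
    labeled_positions: tuple
    purity: float = 1.0
    fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("tracer purity must be in (0, 1]")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("tracer fraction must be in (0, 1]")


@dataclass(frozen=True)
class FragmentSpec:
    """An observed GC-MS fragment: backbone carbons of a (possibly mixed)
    metabolite pool plus the elemental formula of the derivatized ion."""

    id: str
    metabolite: str
    positions: tuple  # 0-based backbone carbon indices
    formula: dict

    def __post_init__(self):
        if self.formula.get("C", 0) < len(self.positions):
            raise FragmentFormulaError(
                f"fragment {self.id!r}: formula has {self.formula.get('C', 0)} carbons "
                f"but tracks {len(self.positions)} backbone positions"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.positions)


def load_fragments(path) -> list:
    """Read a fragment table (TSV: id, metabolite, carbons, formula).

    The carbon field is a 1-based range ("1-4") or list ("1,2,4").
    """
    frags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fid, met, carbons, formula = [f.strip() for f in line.split("\t")]
            if "-" in carbons:
                a, b = carbons.split("-")
                positions = tuple(range(int(a) - 1, int(b)))
            else:
                positions = tuple(int(c) - 1 for c in carbons.split(","))
            frags.append(
                FragmentSpec(
                    id=fid, metabolite=met, positions=positions, formula=parse_formula(formula)
                )
            )
    return frags


@dataclass
class MIDVector:
    """Fractional abundances of the M+0..M+n mass isotopologues."""

    id: str
    masses: np.ndarray
    space: str = "backbone"  # or "derivatized-raw"

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n(self) -> int:
        return len(self.masses) - 1

    def check_normalized(self, tol=1e-9):
        if np.any(self.masses < -tol) or abs(self.masses.sum() - 1.0) > tol:
            raise ValueError(f"MID {self.id!r} is not a normalized distribution")


# ---------------------------------------------------------------------------
# input (substrate) MIDs

def _species_position_probs(spec, n_carbons, tracers):
    """Yield (fraction, per-position 13C probabilities) for one substrate."""
    own = [t for t in tracers if t.substrate == spec]
    total = sum(t.fraction for t in own)
    if total > 1.0 + 1e-9:
        raise ValueError(f"tracer fractions for {spec!r} exceed 1")
    for t in own:
        probs = np.full(n_carbons, NAT_C13)
        for p in t.labeled_positions:
            if not (1 <= p <= n_carbons):
                raise ValueError(f"tracer position {p} outside {spec!r} backbone")
            probs[p - 1] = t.purity
        yield t.fraction, probs
    if total < 1.0 - 1e-12:
        yield 1.0 - total, np.full(n_carbons, NAT_C13)


def input_emu_mid(met_id, positions, n_carbons, tracers) -> np.ndarray:
    """MID of an input-substrate EMU under positional independence."""
    mid = np.zeros(len(positions) + 1)
    for frac, probs in _species_position_probs(met_id, n_carbons, tracers):
        part = np.array([1.0])
        for pos in positions:
            p = probs[pos]
            part = np.convolve(part, [1.0 - p, p])
        mid += frac * part
    return mid


def substrate_isotopomers(met_id, n_carbons, tracers) -> np.ndarray:
    """Full isotopomer distribution (length 2^n) of an input substrate;
    bit i of the state index is carbon i's label."""
    dist = np.zeros(2 ** n_carbons)
    for frac, probs in _species_position_probs(met_id, n_carbons, tracers):
        p = np.ones(1)
        for i in range(n_carbons):
            p = np.concatenate([p * (1 - probs[i]), p * probs[i]])
        dist += frac * p
    return dist


# ---------------------------------------------------------------------------
# EMU network construction

@dataclass
class _Layer:
    size: int
    emus: list  # list[(met, positions)]
    met_row: np.ndarray  # row -> met index into cons matrix
    a_entries: tuple  # (rows, cols, dirs, weights) arrays
    b_entries: list  # (row, dir, weight, parts); part = ("x", layer, row) | ("in", met, positions)


class EMUNetwork:
    """Compiled EMU decomposition of a model for a set of fragments."""

    def __init__(self, model: NetworkModel, fragments: list):
        self.model = model
        self.fragments = list(fragments)
        self._compile()

    # -- construction ------------------------------------------------------

    def _compile(self):
        model = self.model
        mets = model.metabolites
        self.input_ids = set(model.input_ids())

        # flux directions
        self.directions = []  # (reaction, sense)
        for r in model.reactions:
            self.directions.append((r, +1))
            if r.reversible:
                self.directions.append((r, -1))
        n_dirs = len(self.directions)

        # per-direction variants and consumption coefficients
        producers: dict = {}  # met -> [(dir_idx, weight, subs, smaps, prod_met, pmap)]
        met_ids = list(mets)
        met_idx = {m: i for i, m in enumerate(met_ids)}
        cons = np.zeros((len(met_ids), n_dirs))
        for d, (r, sense) in enumerate(self.directions):
            if sense > 0:
                subs, smaps = r.substrates, r.substrate_maps
                prods, pmaps = r.products, r.product_maps
            else:
                subs, smaps = r.products, r.product_maps
                prods, pmaps = r.substrates, r.substrate_maps
            for m, c in subs:
                cons[met_idx[m], d] += c
            if not r.mapped:
                continue
            for weight, v_smaps, v_pmaps in self._variants(r, sense):
                for (pm, _), pmap in zip(prods, v_pmaps):
                    if pmap:
                        producers.setdefault(pm, []).append(
                            (d, weight, subs, v_smaps, pmap)
                        )
        self._cons = cons
        self._met_idx = met_idx
        self._producers = producers

        # decomposition BFS from fragment backbone EMUs
        targets = []
        for f in self.fragments:
            if f.metabolite in model.mixing_rules:
                for contrib in model.mixing_rules[f.metabolite]:
                    targets.append((contrib, f.positions))
            else:
                targets.append((f.metabolite, f.positions))
            parent_n = mets[
                f.metabolite
            ].n_carbons
            if any(p >= parent_n for p in f.positions):
                raise FragmentFormulaError(
                    f"fragment {f.id!r} tracks positions outside its parent backbone"
                )

        terms: dict = {}  # (met, positions) -> list[(dir, weight, parts)]
        queue = [t for t in targets if t[0] not in self.input_ids]
        seen = set(queue)
        while queue:
            met, positions = queue.pop()
            letter_terms = []
            for d, weight, subs, smaps, pmap in producers.get(met, []):
                needed = {pmap[p] for p in positions}
                parts = []
                for (sm, _), smap in zip(subs, smaps):
                    pos_s = tuple(i for i, ch in enumerate(smap) if ch in needed)
                    if pos_s:
                        parts.append((sm, pos_s))
                found = sum(len(p[1]) for p in parts)
                if found != len(positions):
                    raise UnreachableEMUError(
                        f"carbons of EMU {met}:{positions} lost in reaction "
                        f"{self.directions[d][0].id}"
                    )
                letter_terms.append((d, weight, parts))
                for sm, pos_s in parts:
                    key = (sm, pos_s)
                    if sm not in self.input_ids and key not in seen:
                        seen.add(key)
                        queue.append(key)
            if not letter_terms:
                raise UnreachableEMUError(
                    f"EMU {met}:{tuple(p + 1 for p in positions)} has no producing "
                    "reaction and is not a labelled input"
                )
            terms[(met, positions)] = letter_terms
        self._terms = terms

        # layer compilation
        sizes = sorted({len(pos) for _, pos in terms})
        emu_layer: dict = {}
        self.layers: list = []
        for li, size in enumerate(sizes):
            emus = sorted([e for e in terms if len(e[1]) == size])
            row_of = {e: i for i, e in enumerate(emus)}
            for e in emus:
                emu_layer[e] = (li, row_of[e])
            ar, ac, ad, aw = [], [], [], []
            b_entries = []
            for e in emus:
                i = row_of[e]
                for d, weight, parts in terms[e]:
                    if (
                        len(parts) == 1
                        and parts[0][0] not in self.input_ids
                        and len(parts[0][1]) == size
                    ):
                        ar.append(i)
                        ac.append(row_of[parts[0]])
                        ad.append(d)
                        aw.append(weight)
                    else:
                        refs = []
                        for sm, pos_s in parts:
                            if sm in self.input_ids:
                                refs.append(("in", sm, pos_s))
                            else:
                                lj, rj = emu_layer[(sm, pos_s)]
                                refs.append(("x", lj, rj))
                        b_entries.append((i, d, weight, refs))
            self.layers.append(
                _Layer(
                    size=size,
                    emus=emus,
                    met_row=np.array([met_idx[e[0]] for e in emus]),
                    a_entries=(
                        np.array(ar, dtype=int),
                        np.array(ac, dtype=int),
                        np.array(ad, dtype=int),
                        np.array(aw, dtype=float),
                    ),
                    b_entries=b_entries,
                )
            )
        self._emu_layer = emu_layer
        self._targets = targets

    def _variants(self, reaction, sense):
        variants = reaction.map_variants(self.model.metabolites)
        if sense > 0:
            return variants
        return [(w, pmaps, smaps) for (w, smaps, pmaps) in variants]

    @property
    def emus(self) -> list:
        """All EMUs solved by the cascade, as (metabolite, 1-based positions)."""
        return sorted(
            (m, tuple(p + 1 for p in pos)) for (m, pos) in self._terms
        )

    # -- simulation --------------------------------------------------------

    def direction_fluxes(self, flux: FluxVector) -> np.ndarray:
        f = np.empty(len(self.directions))
        for d, (r, sense) in enumerate(self.directions):
            net = flux.net.get(r.id, 0.0)
            exch = flux.exchange.get(r.id, 0.0) if r.reversible else 0.0
            if sense > 0:
                f[d] = max(net, 0.0) + exch
            else:
                f[d] = max(-net, 0.0) + exch
        return f

    def simulate(self, flux: FluxVector, experiments: dict, mixing_fractions=None):
        """Solve the cascade for one or more parallel tracer experiments.

        ``experiments`` maps experiment id -> list[TracerSpec]; returns
        {experiment id: {fragment id: MID array (backbone space)}}.
        All experiments share the flux-dependent layer matrices, so the LU
        factorization is reused across tracers.
        """
        return self.simulate_from_directions(
            self.direction_fluxes(flux), experiments, mixing_fractions
        )

    def simulate_from_directions(self, f, experiments: dict, mixing_fractions=None):
        """Core cascade solve from a precomputed direction-flux array."""
        mets = self.model.metabolites
        exp_ids = list(experiments)

        input_cache: dict = {}

        def input_mid(exp, met, positions):
            key = (exp, met, positions)
            if key not in input_cache:
                input_cache[key] = input_emu_mid(
                    met, positions, mets[met].n_carbons, experiments[exp]
                )
            return input_cache[key]

        X: list = []  # X[layer][exp] = (n_rows, size+1)
        for li, layer in enumerate(self.layers):
            n = len(layer.emus)
            width = layer.size + 1
            cons = self._cons[layer.met_row] @ f
            A = np.zeros((n, n))
            A[np.arange(n), np.arange(n)] = -cons
            ar, ac, ad, aw = layer.a_entries
            if len(ar):
                np.add.at(A, (ar, ac), aw * f[ad])
            B = np.zeros((n, width * len(exp_ids)))
            for i, d, weight, refs in layer.b_entries:
                val = weight * f[d]
                if val == 0.0:
                    continue
                for k, exp in enumerate(exp_ids):
                    mid = None
                    for ref in refs:
                        if ref[0] == "in":
                            part = input_mid(exp, ref[1], ref[2])
                        else:
                            part = X[ref[1]][k][ref[2]]
                        mid = part if mid is None else np.convolve(mid, part)
                    B[i, k * width : (k + 1) * width] -= val * mid
            try:
                sol = np.linalg.solve(A, B)
            except np.linalg.LinAlgError:
                raise EMUSingularityError(
                    layer.size, [f"{m}:{tuple(q + 1 for q in p)}" for m, p in layer.emus]
                ) from None
            if not np.all(np.isfinite(sol)):
                raise EMUSingularityError(
                    layer.size, [f"{m}:{tuple(q + 1 for q in p)}" for m, p in layer.emus]
                )
            X.append([sol[:, k * width : (k + 1) * width] for k in range(len(exp_ids))])

        out = {}
        for k, exp in enumerate(exp_ids):
            frag_mids = {}
            for frag in self.fragments:
                frag_mids[frag.id] = self._fragment_mid(
                    frag, X, k, exp, input_mid, mixing_fractions
                )
            out[exp] = frag_mids
        return out

    def _fragment_mid(self, frag, X, k, exp, input_mid, mixing_fractions):
        rules = self.model.mixing_rules
        if frag.metabolite in rules:
            contributors = rules[frag.metabolite]
            fracs = None
            if mixing_fractions and frag.metabolite in mixing_fractions:
                fracs = mixing_fractions[frag.metabolite]
            mid = np.zeros(frag.n_carbons + 1)
            for c in contributors:
                w = fracs[c] if fracs else 1.0 / len(contributors)
                mid += w * self._emu_mid(c, frag.positions, X, k, exp, input_mid)
            return mid
        return self._emu_mid(frag.metabolite, frag.positions, X, k, exp, input_mid)

    def _emu_mid(self, met, positions, X, k, exp, input_mid):
        if met in self.input_ids:
            return input_mid(exp, met, positions)
        li, row = self._emu_layer[(met, positions)]
        return X[li][k][row]


def decompose(model: NetworkModel, fragments: list) -> EMUNetwork:
    """Build the minimal EMU cascade sufficient for the given fragments."""
    return EMUNetwork(model, fragments)


def simulate_mids(
    emunet: EMUNetwork, fluxes: FluxVector, tracers: list, mixing_fractions=None
) -> dict:
    """Backbone-space MIDs of every fragment for a single tracer experiment.

    Returns {fragment id: MIDVector}.
    """
    raw = emunet.simulate(fluxes, {"_": tracers}, mixing_fractions)["_"]
    return {
        fid: MIDVector(id=fid, masses=mid, space="backbone") for fid, mid in raw.items()
    }
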