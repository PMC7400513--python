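"""Compartmentalized, atom-mapped metabolic network models.

A network model is the substrate for every downstream computation: it
declares metabolites (with compartment, carbon count, rotational symmetry
and whether the pool is balanced at steady state), reactions with letter
atom mappings, a lumped biomass drain scaled by dry cell weight, and
mixing rules that combine compartment pools into the virtual pools that
GC-MS measurements actually see.

The on-disk dialect is a tab-separated text file with ``# metabolites``,
``# reactions``, ``# biomass`` and ``# mixing`` sections::

    # reactions
    FH<TAB>fum (ABCD) --> mal_m (ABCD)<TAB>1<TAB>-3000<TAB>3000

Symmetric molecules (fumarate, succinate) carry a single written map; the
loader expands it into equal-weight alternative maps, one per carbon-chain
orientation, which is what produces positional scrambling downstream.

Flux units are nmol/10^6 cells/h throughout; time is in hours.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    AtomMapError,
    CarbonBalanceError,
    FluxBoundError,
    InfeasibleConstraintError,
    ModelFormatError,
    UndeclaredMetaboliteError,
)

COMPARTMENTS = ("cytosol", "mitochondria", "extracellular", "mixing")

#: Default dry cell weight, pg/cell, for scaling biomass precursor demands.
DEFAULT_DCW_PG = 514.0


@dataclass(frozen=True)
class MetaboliteSpec:
    id: str
    compartment: str
    n_carbons: int
    symmetric: bool = False
    is_balanced: bool = True

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelFormatError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.n_carbons < 0:
            raise ModelFormatError(f"metabolite {self.id!r}: negative carbon count")
        if self.symmetric and self.n_carbons < 2:
            raise ModelFormatError(
                f"metabolite {self.id!r}: symmetry is meaningless below 2 carbons"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction with letter atom maps.

    ``substrates``/``products`` are lists of ``(metabolite_id, coefficient)``
    instance terms, parallel to ``substrate_maps``/``product_maps`` which
    hold the letter string of each instance ('' for unmapped instances such
    as biomass precursors).
    """

    id: str
    substrates: tuple
    products: tuple
    substrate_maps: tuple
    product_maps: tuple
    reversible: bool = False
    lower: float = 0.0
    upper: float = 3000.0

    @property
    def mapped(self) -> bool:
        return any(self.substrate_maps) or any(self.product_maps)

    def validate_atom_map(self):
        sub_letters = "".join(self.substrate_maps)
        prod_letters = "".join(self.product_maps)
        for side, letters in (("substrate", sub_letters), ("product", prod_letters)):
            if len(set(letters)) != len(letters):
                raise CarbonBalanceError(
                    self.id, f"duplicate carbon letter on {side} side"
                )
        if sorted(sub_letters) != sorted(prod_letters):
            missing = set(sub_letters) ^ set(prod_letters)
            raise CarbonBalanceError(
                self.id,
                f"substrate and product carbons differ (unmatched: {sorted(missing)})",
            )
        for (met, coeff), m in list(zip(self.substrates, self.substrate_maps)) + list(
            zip(self.products, self.product_maps)
        ):
            if m and coeff != 1:
                raise AtomMapError(
                    f"reaction {self.id!r}: mapped instance of {met!r} must have "
                    f"stoichiometric coefficient 1 (got {coeff})"
                )
        if not self.reversible and self.lower < 0:
            raise ModelFormatError(
                f"reaction {self.id!r}: irreversible reaction with negative lower bound"
            )

    def map_variants(self, metabolites: dict) -> list:
        """Equal-weight atom-map alternatives from molecular symmetry.

        Returns a list of ``(weight, substrate_maps, product_maps)``; a
        rotationally symmetric linear skeleton contributes its reversed
        orientation for every mapped instance.
        """
        slots = []
        for (met, _), m in list(zip(self.substrates, self.substrate_maps)) + list(
            zip(self.products, self.product_maps)
        ):
            if m and metabolites[met].symmetric:
                slots.append((m, m[::-1]))
            else:
                slots.append((m,))
        n_sub = len(self.substrates)
        variants = []
        for combo in itertools.product(*slots):
            weight = 1.0 / np.prod([len(s) for s in slots])
            variants.append(
                (float(weight), tuple(combo[:n_sub]), tuple(combo[n_sub:]))
            )
        return variants


@dataclass
class BiomassSpec:
    """Lumped biomass precursor drain.

    ``coefficients`` map metabolite ids to nmol of precursor per 10^6 cells
    per unit of growth rate; the drain flux of metabolite *m* is
    ``mu * coefficients[m]``. Coefficients are derived from per-gram-DCW
    demands scaled by the dry cell weight (pg/cell).
    """

    coefficients: dict = field(default_factory=dict)
    dry_cell_weight: float = DEFAULT_DCW_PG

    def __post_init__(self):
        for met, c in self.coefficients.items():
            if c < 0:
                raise ModelFormatError(f"biomass coefficient for {met!r} is negative")

    @classmethod
    def from_demands(cls, demands_per_mg_dcw: dict, dcw_pg: float = DEFAULT_DCW_PG):
        mg_per_1e6_cells = dcw_pg * 1e6 / 1e9  # pg/cell -> mg per 10^6 cells
        coeff = {m: d * mg_per_1e6_cells for m, d in demands_per_mg_dcw.items()}
        return cls(coefficients=coeff, dry_cell_weight=dcw_pg)


BIOMASS_ID = "BIOMASS"


@dataclass
class NetworkModel:
    metabolites: dict  # id -> MetaboliteSpec
    reactions: list  # list[Reaction], BIOMASS appended last when present
    biomass: BiomassSpec | None = None
    mixing_rules: dict = field(default_factory=dict)  # pool id -> [contributor ids]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_ids(self) -> list:
        return [m for m, spec in self.metabolites.items() if spec.is_balanced]

    def input_ids(self) -> list:
        """Unbalanced metabolites consumed by some reaction: label sources."""
        consumed = set()
        for r in self.reactions:
            consumed.update(m for m, _ in r.substrates)
            if r.reversible:
                consumed.update(m for m, _ in r.products)
        return [
            m
            for m in self.metabolites
            if not self.metabolites[m].is_balanced and m in consumed
        ]

    def stoichiometric_matrix(self):
        """S over balanced metabolites (rows) x reactions (columns)."""
        bal = self.balanced_ids
        row = {m: i for i, m in enumerate(bal)}
        S = np.zeros((len(bal), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.substrates:
                if m in row:
                    S[row[m], j] -= c
            for m, c in r.products:
                if m in row:
                    S[row[m], j] += c
        return S, bal


@dataclass
class FluxVector:
    """Net flux per reaction plus nonnegative exchange flux per reversible
    reaction (nmol/10^6 cells/h)."""

    net: dict
    exchange: dict = field(default_factory=dict)

    def __post_init__(self):
        for rid, e in self.exchange.items():
            if e < 0:
                raise FluxBoundError(f"exchange flux for {rid!r} is negative")

    def forward(self, rid: str) -> float:
        return max(self.net.get(rid, 0.0), 0.0) + self.exchange.get(rid, 0.0)

    def backward(self, rid: str) -> float:
        return max(-self.net.get(rid, 0.0), 0.0) + self.exchange.get(rid, 0.0)

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector(
            net={r: v * factor for r, v in self.net.items()},
            exchange={r: v * factor for r, v in self.exchange.items()},
        )


@dataclass
class FluxParameterization:
    """Affine map from a handful of free reaction fluxes to the full
    steady-state net-flux vector: ``v(u) = v0 + T (u - u0)``."""

    reaction_ids: list
    free_flux_ids: list
    v0: np.ndarray
    T: np.ndarray  # (n_reactions, n_free)
    fixed_constraints: dict
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    @property
    def n_free(self) -> int:
        return len(self.free_flux_ids)

    @property
    def u0(self) -> np.ndarray:
        return self.v0[[self._index[r] for r in self.free_flux_ids]]

    def full_vector(self, free_values) -> np.ndarray:
        u = np.asarray(free_values, dtype=float)
        if u.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free values, got shape {u.shape}"
            )
        return self.v0 + self.T @ (u - self.u0)

    def free_values(self, flux: "FluxVector") -> np.ndarray:
        return np.array([flux.net[r] for r in self.free_flux_ids])

    def reaction_row(self, rid: str):
        """(offset, row) such that v_rid(u) = offset + row @ u."""
        i = self._index[rid]
        return self.v0[i] - self.T[i] @ self.u0, self.T[i].copy()


# ---------------------------------------------------------------------------
# model file I/O

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coeff>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?"
    r"(?P<met>[A-Za-z_]\w*)\s*(?:\(\s*(?P<map>[A-Za-z]*)\s*\))?\s*$"
)


def _parse_side(side: str, rid: str):
    terms, maps = [], []
    side = side.strip()
    if not side:
        return tuple(terms), tuple(maps)
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise AtomMapError(f"reaction {rid!r}: cannot parse term {term.strip()!r}")
        coeff = float(m.group("coeff") or 1.0)
        terms.append((m.group("met"), coeff))
        maps.append(m.group("map") or "")
    return tuple(terms), tuple(maps)


def parse_reaction_equation(rid, equation, reversible=False, lower=0.0, upper=3000.0):
    if "-->" not in equation:
        raise ModelFormatError(f"reaction {rid!r}: missing '-->' in equation")
    left, right = equation.split("-->", 1)
    subs, smaps = _parse_side(left, rid)
    prods, pmaps = _parse_side(right, rid)
    return Reaction(
        id=rid,
        substrates=subs,
        products=prods,
        substrate_maps=smaps,
        product_maps=pmaps,
        reversible=bool(reversible),
        lower=float(lower),
        upper=float(upper),
    )


def _iter_sections(path):
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                section = line.lstrip("# ").strip().lower()
                continue
            yield section, lineno, line


def load_model(path) -> NetworkModel:
    """Load and validate a model file in the tab-separated dialect.

    Raises a named validation error (atom map, undeclared metabolite,
    carbon imbalance) identifying the offending reaction.
    """
    metabolites: dict = {}
    reactions: list = []
    mixing: dict = {}
    biomass_demands: dict = {}
    dcw = DEFAULT_DCW_PG

    for section, lineno, line in _iter_sections(path):
        fields = [f.strip() for f in line.split("\t")]
        if section == "metabolites":
            if len(fields) != 5:
                raise ModelFormatError(f"line {lineno}: expected 5 metabolite fields")
            mid, comp, ncarb, sym, bal = fields
            metabolites[mid] = MetaboliteSpec(
                id=mid,
                compartment=comp,
                n_carbons=int(ncarb),
                symmetric=bool(int(sym)),
                is_balanced=bool(int(bal)),
            )
        elif section == "reactions":
            if len(fields) != 5:
                raise ModelFormatError(f"line {lineno}: expected 5 reaction fields")
            rid, equation, rev, lo, hi = fields
            reactions.append(
                parse_reaction_equation(rid, equation, int(rev), float(lo), float(hi))
            )
        elif section == "biomass":
            key, value = fields[0], fields[1]
            if key == "dry_cell_weight_pg":
                dcw = float(value)
            else:
                biomass_demands[key] = float(value)
        elif section == "mixing":
            pool, contributors = fields[0], fields[1]
            mixing[pool] = [c.strip() for c in contributors.split(",")]
        else:
            raise ModelFormatError(f"line {lineno}: data outside a known section")

    biomass = None
    if biomass_demands:
        biomass = BiomassSpec.from_demands(biomass_demands, dcw)
        subs = tuple((m, c) for m, c in biomass.coefficients.items())
        reactions.append(
            Reaction(
                id=BIOMASS_ID,
                substrates=subs,
                products=(),
                substrate_maps=tuple("" for _ in subs),
                product_maps=(),
                reversible=False,
                lower=0.0,
                upper=10.0,
            )
        )

    model = NetworkModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass=biomass,
        mixing_rules=mixing,
    )
    _check_model(model)
    return model


def _check_model(model: NetworkModel):
    for r in model.reactions:
        for (m, _), amap in list(zip(r.substrates, r.substrate_maps)) + list(
            zip(r.products, r.product_maps)
        ):
            if m not in model.metabolites:
                raise UndeclaredMetaboliteError(
                    f"reaction {r.id!r} references undeclared metabolite {m!r}"
                )
            spec = model.metabolites[m]
            if amap and len(amap) != spec.n_carbons:
                raise AtomMapError(
                    f"reaction {r.id!r}: map {amap!r} for {m!r} has "
                    f"{len(amap)} letters but the metabolite has {spec.n_carbons} carbons"
                )
        r.validate_atom_map()
    for pool, contributors in model.mixing_rules.items():
        if pool not in model.metabolites:
            raise UndeclaredMetaboliteError(f"mixing pool {pool!r} undeclared")
        for c in contributors:
            if c not in model.metabolites:
                raise UndeclaredMetaboliteError(
                    f"mixing contributor {c!r} of pool {pool!r} undeclared"
                )


def write_model(model: NetworkModel, path):
    with open(path, "w") as fh:
        fh.write("# metabolites\n")
        for m in model.metabolites.values():
            fh.write(
                f"{m.id}\t{m.compartment}\t{m.n_carbons}\t{int(m.symmetric)}"
                f"\t{int(m.is_balanced)}\n"
            )
        fh.write("\n# reactions\n")
        for r in model.reactions:
            if r.id == BIOMASS_ID:
                continue

            def side(terms, maps):
                parts = []
                for (met, coeff), amap in zip(terms, maps):
                    c = "" if coeff == 1 else f"{coeff:g} "
                    parts.append(f"{c}{met} ({amap})" if amap else f"{c}{met}")
                return " + ".join(parts)

            eq = f"{side(r.substrates, r.substrate_maps)} --> {side(r.products, r.product_maps)}"
            fh.write(f"{r.id}\t{eq}\t{int(r.reversible)}\t{r.lower:g}\t{r.upper:g}\n")
        if model.biomass is not None:
            fh.write("\n# biomass\n")
            fh.write(f"dry_cell_weight_pg\t{model.biomass.dry_cell_weight:g}\n")
            mg = model.biomass.dry_cell_weight * 1e6 / 1e9
            for met, coeff in model.biomass.coefficients.items():
                fh.write(f"{met}\t{coeff / mg:g}\n")
        if model.mixing_rules:
            fh.write("\n# mixing\n")
            for pool, contributors in model.mixing_rules.items():
                fh.write(f"{pool}\t{','.join(contributors)}\n")


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    findings: list  # list of (severity, code, message)

    @property
    def violations(self) -> list:
        return [f for f in self.findings if f[0] == "error"]

    @property
    def ok(self) -> bool:
        return not self.violations

    def as_text(self) -> str:
        if not self.findings:
            return "model OK: no findings"
        return "\n".join(f"[{sev}] {code}: {msg}" for sev, code, msg in self.findings)

    def as_json(self) -> str:
        return json.dumps(
            [
                {"severity": sev, "code": code, "message": msg}
                for sev, code, msg in self.findings
            ],
            indent=2,
        )


def validate(model: NetworkModel) -> ValidationReport:
    """Audit a loaded model: per-reaction carbon balance, dead-end balanced
    metabolites, pools unreachable from any extracellular input, and mixing
    rules with fewer than two contributors."""
    findings = []
    for r in model.reactions:
        try:
            r.validate_atom_map()
        except (CarbonBalanceError, AtomMapError, ModelFormatError) as exc:
            findings.append(("error", "carbon-balance", str(exc)))

    produced, consumed = set(), set()
    for r in model.reactions:
        consumed.update(m for m, _ in r.substrates)
        produced.update(m for m, _ in r.products)
        if r.reversible:
            produced.update(m for m, _ in r.substrates)
            consumed.update(m for m, _ in r.products)
    for m in model.balanced_ids:
        if m in produced and m not in consumed:
            findings.append(
                ("error", "dead-end", f"balanced metabolite {m!r} is produced but never consumed")
            )
        elif m in consumed and m not in produced:
            findings.append(
                ("error", "dead-end", f"balanced metabolite {m!r} is consumed but never produced")
            )
        elif m not in produced and m not in consumed:
            findings.append(("warning", "orphan", f"metabolite {m!r} unused"))

    # reachability from extracellular inputs through reactions
    reachable = {
        m
        for m in model.metabolites
        if model.metabolites[m].compartment == "extracellular"
    }
    changed = True
    while changed:
        changed = False
        for r in model.reactions:
            if any(m in reachable for m, _ in r.substrates) or (
                r.reversible and any(m in reachable for m, _ in r.products)
            ):
                new = {m for m, _ in r.substrates + r.products} - reachable
                if new:
                    reachable |= new
                    changed = True
    for m in model.balanced_ids:
        if m not in reachable:
            findings.append(
                ("error", "unreachable", f"metabolite {m!r} unreachable from any extracellular pool")
            )

    for pool, contributors in model.mixing_rules.items():
        if len(contributors) < 2:
            findings.append(
                ("error", "mixing-rule", f"mixing pool {pool!r} has fewer than 2 contributors")
            )
        if pool in model.metabolites and model.metabolites[pool].is_balanced:
            findings.append(
                ("error", "mixing-rule", f"mixing pool {pool!r} must be non-balanced")
            )
    return ValidationReport(findings=findings)


# ---------------------------------------------------------------------------
# steady-state parameterization

def parameterize(
    model: NetworkModel, fixed: dict | None = None, preferred_free: list | None = None
) -> FluxParameterization:
    """Null-space parameterization of the steady-state flux cone.

    ``fixed`` pins named reaction net fluxes to values; the remaining degrees
    of freedom are exposed as actual reaction fluxes (chosen by pivoted QR
    for conditioning, with ``preferred_free`` reactions tried first).
    """
    fixed = dict(fixed or {})
    S, _ = model.stoichiometric_matrix()
    rids = model.reaction_ids
    idx = {r: i for i, r in enumerate(rids)}
    n = len(rids)

    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    for rid, value in fixed.items():
        if rid not in idx:
            raise KeyError(f"fixed constraint on unknown reaction {rid!r}")
        e = np.zeros(n)
        e[idx[rid]] = 1.0
        rows.append(e[None, :])
        rhs.append(np.array([value]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)

    v0, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ v0 - b
    scale = max(1.0, np.abs(b).max())
    if np.abs(resid).max() > 1e-7 * scale:
        worst = int(np.argmax(np.abs(resid)))
        name = (
            f"balance of {model.balanced_ids[worst]!r}"
            if worst < S.shape[0]
            else f"fixed constraint on {list(fixed)[worst - S.shape[0]]!r}"
        )
        raise InfeasibleConstraintError(
            f"fixed constraints are inconsistent; largest conflict at {name} "
            f"(residual {resid[worst]:.3g})"
        )

    N = scipy.linalg.null_space(A)
    d = N.shape[1]
    if d == 0:
        T = np.zeros((n, 0))
        free_ids: list = []
    else:
        order = list(range(n))
        if preferred_free:
            pref = [idx[r] for r in preferred_free if r in idx]
            order = pref + [i for i in order if i not in set(pref)]
        chosen: list = []
        for i in order:
            if len(chosen) == d:
                break
            trial = chosen + [i]
            if np.linalg.matrix_rank(N[trial, :], tol=1e-10) == len(trial):
                chosen.append(i)
        if len(chosen) < d:
            raise InfeasibleConstraintError("could not select independent free fluxes")
        M = N[chosen, :]
        T = N @ np.linalg.inv(M)
        free_ids = [rids[i] for i in chosen]

    return FluxParameterization(
        reaction_ids=list(rids),
        free_flux_ids=free_ids,
        v0=v0,
        T=T,
        fixed_constraints=fixed,
    )


def expand(
    parameterization: FluxParameterization,
    free_values,
    model: NetworkModel | None = None,
    exchange: dict | None = None,
    check_bounds: bool = True,
    bound_tol: float = 1e-6,
) -> FluxVector:
    """Expand free flux values into a full steady-state FluxVector."""
    v = parameterization.full_vector(free_values)
    net = dict(zip(parameterization.reaction_ids, v))
    if check_bounds and model is not None:
        violations = []
        for r in model.reactions:
            x = net[r.id]
            if x < r.lower - bound_tol or x > r.upper + bound_tol:
                violations.append(f"{r.id}={x:.4g} outside [{r.lower:g}, {r.upper:g}]")
        if violations:
            raise FluxBoundError("; ".join(violations))
    return FluxVector(net=net, exchange=dict(exchange or {}))


def steady_state_residual(model: NetworkModel, flux: FluxVector) -> float:
    """max |S v| over balanced metabolites."""
    S, _ = model.stoichiometric_matrix()
    v = np.array([flux.net[r] for r in model.reaction_ids])
    return float(np.abs(S @ v).max())
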