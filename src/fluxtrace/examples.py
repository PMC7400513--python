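"""Small example networks for demonstrations and oracle verification.

Each builder returns ``(model, fluxes, tracers, fragments)`` with a state
space small enough for the brute-force isotopomer oracle: a linear chain,
a converging diamond with a carbon rearrangement, a cleavage/condensation
pair, a reversible isomerase with exchange, a (de)activatable symmetric
fumarate step, and a closed TCA-style loop with two symmetric
intermediates.
"""

from __future__ import annotations

from .emu import FragmentSpec, TracerSpec
from .network import FluxVector, MetaboliteSpec, NetworkModel, parse_reaction_equation


def build_model(metabolites, reactions, mixing=None) -> NetworkModel:
    """Assemble a model from terse specs.

    ``metabolites``: (id, n_carbons, balanced[, symmetric]) tuples (balanced
    pools land in the cytosol, the rest are extracellular); ``reactions``:
    (id, equation, reversible) tuples in the model-file equation dialect.
    """
    mets = {}
    for row in metabolites:
        mid, ncarb, balanced = row[:3]
        sym = row[3] if len(row) > 3 else False
        mets[mid] = MetaboliteSpec(
            id=mid,
            compartment="cytosol" if balanced else "extracellular",
            n_carbons=ncarb,
            symmetric=sym,
            is_balanced=balanced,
        )
    rxns = []
    for rid, eq, rev in reactions:
        rxns.append(
            parse_reaction_equation(rid, eq, rev, -3000.0 if rev else 0.0, 3000.0)
        )
    model = NetworkModel(metabolites=mets, reactions=rxns, mixing_rules=mixing or {})
    for r in model.reactions:
        r.validate_atom_map()
    return model


def frag(fid, met, n, formula=None) -> FragmentSpec:
    return FragmentSpec(
        id=fid, metabolite=met, positions=tuple(range(n)),
        formula={"C": n} if formula is None else formula,
    )


def toy_chain():
    model = build_model(
        [("src_e", 2, False), ("A", 2, True), ("B", 2, True), ("snk_e", 2, False)],
        [("U", "src_e (AB) --> A (AB)", 0),
         ("R1", "A (AB) --> B (AB)", 0),
         ("X", "B (AB) --> snk_e (AB)", 0)],
    )
    fluxes = FluxVector(net={"U": 10.0, "R1": 10.0, "X": 10.0})
    tracers = [TracerSpec("src_e", (1, 2), purity=0.97)]
    return model, fluxes, tracers, [frag("B12", "B", 2)]


def toy_diamond():
    model = build_model(
        [("src_e", 3, False), ("A", 3, True), ("B", 3, True),
         ("C", 3, True), ("D", 3, True), ("snk_e", 3, False)],
        [("U", "src_e (ABC) --> A (ABC)", 0),
         ("AB", "A (ABC) --> B (ABC)", 0),
         ("AC", "A (ABC) --> C (CBA)", 0),
         ("BD", "B (ABC) --> D (ABC)", 0),
         ("CD", "C (ABC) --> D (ABC)", 0),
         ("X", "D (ABC) --> snk_e (ABC)", 0)],
    )
    fluxes = FluxVector(net={"U": 10.0, "AB": 6.0, "AC": 4.0, "BD": 6.0,
                             "CD": 4.0, "X": 10.0})
    tracers = [TracerSpec("src_e", (1,), purity=0.99)]
    return model, fluxes, tracers, [frag("D", "D", 3), frag("A", "A", 3)]


def toy_cleave():
    model = build_model(
        [("hex_e", 4, False), ("H", 4, True), ("X", 2, True),
         ("Y", 2, True), ("Z", 4, True), ("snk_e", 4, False)],
        [("U", "hex_e (ABCD) --> H (ABCD)", 0),
         ("CLV", "H (ABCD) --> X (AB) + Y (CD)", 0),
         ("CND", "X (AB) + Y (CD) --> Z (CADB)", 0),
         ("OUT", "Z (ABCD) --> snk_e (ABCD)", 0)],
    )
    fluxes = FluxVector(net={"U": 5.0, "CLV": 5.0, "CND": 5.0, "OUT": 5.0})
    tracers = [TracerSpec("hex_e", (1, 2), purity=0.99)]
    return model, fluxes, tracers, [frag("Z", "Z", 4), frag("X", "X", 2)]


def toy_reversible():
    model = build_model(
        [("src_e", 2, False), ("A", 2, True), ("B", 2, True), ("snk_e", 2, False)],
        [("U", "src_e (AB) --> A (AB)", 0),
         ("REV", "A (AB) --> B (BA)", 1),
         ("X", "B (AB) --> snk_e (AB)", 0)],
    )
    fluxes = FluxVector(net={"U": 10.0, "REV": 10.0, "X": 10.0},
                        exchange={"REV": 25.0})
    tracers = [TracerSpec("src_e", (1,), purity=0.99)]
    return model, fluxes, tracers, [frag("A", "A", 2), frag("B", "B", 2)]


def toy_symmetric_fumarate(symmetric=True):
    model = build_model(
        [("src_e", 4, False), ("F", 4, True, symmetric), ("M", 4, True),
         ("snk_e", 4, False)],
        [("U", "src_e (ABCD) --> F (ABCD)", 0),
         ("FH", "F (ABCD) --> M (ABCD)", 1),
         ("OUT", "M (ABCD) --> snk_e (ABCD)", 0)],
    )
    fluxes = FluxVector(net={"U": 10.0, "FH": 10.0, "OUT": 10.0},
                        exchange={"FH": 8.0})
    tracers = [TracerSpec("src_e", (1, 2), purity=1.0)]
    return model, fluxes, tracers, [frag("M", "M", 4),
                                    FragmentSpec("M12", "M", (0, 1), {"C": 2})]


def toy_tca_loop():
    model = build_model(
        [("ac_e", 2, False), ("acc", 2, True), ("oaa", 4, True),
         ("cit", 6, True), ("akg", 5, True), ("suc", 4, True, True),
         ("fum", 4, True, True), ("mal", 4, True), ("co2_e", 1, False)],
        [("ACU", "ac_e (ab) --> acc (ab)", 0),
         ("CS", "oaa (ABCD) + acc (ab) --> cit (ABCDab)", 0),
         ("IDH", "cit (ABCDEF) --> co2_e (A) + akg (BCDEF)", 0),
         ("AKGDH", "akg (ABCDE) --> co2_e (A) + suc (BCDE)", 0),
         ("SDH", "suc (ABCD) --> fum (ABCD)", 1),
         ("FH", "fum (ABCD) --> mal (ABCD)", 1),
         ("MDH", "mal (ABCD) --> oaa (ABCD)", 0)],
    )
    fluxes = FluxVector(
        net={r: 7.0 for r in model.reaction_ids},
        exchange={"SDH": 3.0, "FH": 12.0},
    )
    tracers = [TracerSpec("ac_e", (1, 2), purity=0.99)]
    return model, fluxes, tracers, [frag("mal", "mal", 4), frag("cit", "cit", 6)]


TOY_BUILDERS = {
    "chain": toy_chain,
    "diamond": toy_diamond,
    "cleave": toy_cleave,
    "reversible": toy_reversible,
    "symmetric_fumarate": toy_symmetric_fumarate,
    "tca_loop": toy_tca_loop,
}
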