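"""Cofactor balances and ATP pathway attribution.

Given a flux distribution and per-reaction cofactor coefficients (NADH by
compartment, NADPH, FADH2, substrate-level ATP, GTP as ATP-equivalent),
this module totals production and consumption per cofactor and attributes
ATP production to glycolysis (substrate-level phosphorylation of the
glycolytic reactions), the TCA cycle (GTP plus oxidative phosphorylation
of mitochondrial NADH and FADH2 at the configured P/O ratios) and an
"other" bucket (non-TCA mitochondrial NADH and net cytosolic NADH assumed
shuttled at no ATP cost). All entries are linear in the fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._data import data_path
from .errors import FluxtraceError
from .exoflux import round_half_away
from .network import FluxVector, NetworkModel


@dataclass
class CofactorStoichiometry:
    """reaction id -> {cofactor: coefficient per unit flux}."""

    coefficients: dict

    @classmethod
    def from_tsv(cls, path) -> "CofactorStoichiometry":
        coeff: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rid, cof, value = line.split("\t")
                coeff.setdefault(rid, {})[cof] = float(value)
        return cls(coefficients=coeff)

    @classmethod
    def default(cls) -> "CofactorStoichiometry":
        return cls.from_tsv(data_path("cofactor_stoichiometry.tsv"))

    def coefficient(self, rid: str, cofactor: str) -> float:
        return self.coefficients.get(rid, {}).get(cofactor, 0.0)


@dataclass
class ATPConfig:
    """Energetic accounting parameters.

    po_nadh: ATP per NADH oxidized by OxPHOS (P/O ratio).
    po_fadh2: ATP per FADH2; default preserves the conventional 1.5/2.5
    efficiency ratio relative to NADH.
    """

    po_nadh: float = 2.3
    po_fadh2: float = 2.3 * 1.5 / 2.5
    glycolysis_reactions: tuple = ("GLUT", "PFKALD", "GAPD", "PK")
    tca_reactions: tuple = ("PDH", "CS", "IDH", "AKGDH", "SDH", "MDH")
    gtp_as_atp: bool = True

    def __post_init__(self):
        if self.po_nadh <= 0 or self.po_fadh2 <= 0:
            raise ValueError("P/O ratios must be positive")


@dataclass
class CofactorBalance:
    production: dict
    consumption: dict
    per_reaction: dict  # cofactor -> {reaction: signed contribution}

    def net(self, cofactor: str) -> float:
        return self.production.get(cofactor, 0.0) - self.consumption.get(cofactor, 0.0)


def cofactor_balance(
    model: NetworkModel,
    fluxes: FluxVector,
    stoich: CofactorStoichiometry | None = None,
    strict: bool = False,
) -> CofactorBalance:
    """Total production and consumption per cofactor (net-flux x coefficient).

    In strict mode a reaction carrying flux without any cofactor row raises
    a coverage error, so silent omissions cannot skew an energy budget.
    """
    stoich = stoich or CofactorStoichiometry.default()
    production: dict = {}
    consumption: dict = {}
    per_reaction: dict = {}
    for rid, v in fluxes.net.items():
        rows = stoich.coefficients.get(rid)
        if rows is None:
            if strict and abs(v) > 1e-9:
                raise FluxtraceError(
                    f"strict cofactor accounting: reaction {rid!r} carries flux "
                    "but has no cofactor row"
                )
            continue
        for cof, c in rows.items():
            contribution = c * v
            per_reaction.setdefault(cof, {})[rid] = contribution
            if contribution >= 0:
                production[cof] = production.get(cof, 0.0) + contribution
            else:
                consumption[cof] = consumption.get(cof, 0.0) - contribution
    return CofactorBalance(
        production=production, consumption=consumption, per_reaction=per_reaction
    )


@dataclass
class ATPLedger:
    """ATP fluxes (nmol/10^6 cells/h) attributed to pathways."""

    glycolysis: float
    tca: float
    other: float
    consumption: float
    per_reaction: dict = field(default_factory=dict)

    @property
    def total_net(self) -> float:
        return self.glycolysis + self.tca + self.other - self.consumption

    def rows(self) -> dict:
        return {
            "glycolysis": self.glycolysis,
            "tca_cycle": self.tca,
            "other_production": self.other,
            "consumption": self.consumption,
            "total_net": self.total_net,
        }


def atp_production(
    fluxes: FluxVector,
    stoich: CofactorStoichiometry | None = None,
    config: ATPConfig | None = None,
) -> ATPLedger:
    """Attribute ATP production to glycolysis / TCA cycle / other.

    Glycolysis is substrate-level only (net of the kinase steps); the TCA
    row adds OxPHOS ATP from mitochondrial NADH and FADH2 of TCA reactions
    at the configured P/O ratios plus succinyl-CoA-synthetase GTP; ATP
    consumed by anaplerosis, biosynthesis and biomass forms the consumption
    total. Every entry is linear in the fluxes.
    """
    stoich = stoich or CofactorStoichiometry.default()
    config = config or ATPConfig()
    glyc = set(config.glycolysis_reactions)
    tca = set(config.tca_reactions)

    glycolysis = 0.0
    tca_atp = 0.0
    other = 0.0
    consumption = 0.0
    per_reaction: dict = {}

    nadh_c_net = 0.0
    for rid, v in fluxes.net.items():
        rows = stoich.coefficients.get(rid, {})
        atp = rows.get("atp", 0.0) * v
        gtp = rows.get("gtp", 0.0) * v if config.gtp_as_atp else 0.0
        nadh_m = rows.get("nadh_m", 0.0) * v
        fadh2 = rows.get("fadh2", 0.0) * v
        nadh_c_net += rows.get("nadh_c", 0.0) * v

        contribution = 0.0
        if rid in glyc:
            glycolysis += atp
            contribution += atp
        else:
            if atp >= 0:
                other += atp
            else:
                consumption += -atp
            contribution += atp
        if rid in tca:
            ox = config.po_nadh * nadh_m + config.po_fadh2 * fadh2 + gtp
            tca_atp += ox
            contribution += ox
        else:
            ox = config.po_nadh * nadh_m + config.po_fadh2 * fadh2 + gtp
            other += ox
            contribution += ox
        if contribution != 0.0:
            per_reaction[rid] = contribution

    # cytosolic NADH shuttled to OxPHOS at no ATP cost; attributed to "other"
    if nadh_c_net > 0:
        other += config.po_nadh * nadh_c_net
        per_reaction["cytosolic_nadh_shuttle"] = config.po_nadh * nadh_c_net

    ledger = ATPLedger(
        glycolysis=glycolysis,
        tca=tca_atp,
        other=other,
        consumption=consumption,
        per_reaction=per_reaction,
    )
    for name, value in (("glycolysis", glycolysis), ("tca_cycle", tca_atp)):
        if value < 0:
            raise FluxtraceError(
                f"{name} ATP total is negative ({value:.3g}); check the pathway "
                "membership sets and cofactor signs"
            )
    return ledger


def ledger_report(parental, fhdim) -> pd.DataFrame:
    """Comparative ATP table: per-row difference (parental - altered, 1
    decimal) and fold change (altered / parental, 2 decimals).

    Accepts ATPLedger objects or plain {row: value} mappings (e.g. printed
    reference values).
    """
    rows_p = parental.rows() if isinstance(parental, ATPLedger) else dict(parental)
    rows_f = fhdim.rows() if isinstance(fhdim, ATPLedger) else dict(fhdim)
    records = []
    for name in rows_p:
        if name not in rows_f:
            continue
        p, f = rows_p[name], rows_f[name]
        records.append(
            {
                "pathway": name,
                "parental": round_half_away(p, 1),
                "fhdim": round_half_away(f, 1),
                "difference": round_half_away(p - f, 1),
                "fold_change": round_half_away(f / p, 2) if p != 0 else np.nan,
            }
        )
    return pd.DataFrame(records)
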