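"""Natural isotope abundance correction for derivatized GC-MS fragments.

A measured fragment ion carries, besides its tracked backbone carbons,
derivatization atoms (Si, C, H, N, O, S from TBDMS/TMS/methoxime groups)
whose heavy natural isotopes shift the measured mass distribution. The
forward model is a correction matrix whose column j is the mass-shift
distribution of the ion given j labelled backbone carbons, obtained by
convolving per-element multinomial shift distributions over all
non-tracer atoms. Correction solves the truncated linear system by
nonnegative least squares and renormalizes, which keeps noisy measured
MIDs on the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from ._data import data_path

from .emu import FragmentSpec, MIDVector
from .errors import FragmentFormulaError

#: Raw MIDs keep this many masses beyond M+n to capture Si/S isotope tails.
TAIL_MASSES = 4

#: Condition number above which a conditioning warning is attached.
CONDITION_LIMIT = 1e8


@dataclass
class AbundanceTable:
    """Per-element isotope mass-shift probabilities (index = shift in Da)."""

    elements: dict

    def __post_init__(self):
        for el, probs in self.elements.items():
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(f"abundances for {el!r} must be >= 0 and sum to 1")
            self.elements[el] = p

    def __getitem__(self, element):
        return self.elements[element]

    @classmethod
    def from_tsv(cls, path) -> "AbundanceTable":
        elements = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                elements[fields[0]] = [float(x) for x in fields[1:]]
        return cls(elements=elements)

    @classmethod
    def default(cls) -> "AbundanceTable":
        """IUPAC standard natural abundances shipped with the package."""
        return cls.from_tsv(data_path("isotope_abundances.tsv"))


def _n_fold(dist: np.ndarray, n: int) -> np.ndarray:
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, dist)
    return out


def natural_shift_distribution(fragment: FragmentSpec, table: AbundanceTable) -> np.ndarray:
    """Mass-shift distribution of all non-tracer atoms of the ion."""
    counts = dict(fragment.formula)
    n_backbone = fragment.n_carbons
    if counts.get("C", 0) < n_backbone:
        raise FragmentFormulaError(
            f"fragment {fragment.id!r}: fewer formula carbons than tracked backbone"
        )
    counts["C"] = counts.get("C", 0) - n_backbone
    dist = np.array([1.0])
    for el, n in counts.items():
        if n == 0:
            continue
        if el not in table.elements:
            raise FragmentFormulaError(
                f"fragment {fragment.id!r}: no abundance data for element {el!r}"
            )
        dist = np.convolve(dist, _n_fold(table[el], n))
    return dist


@dataclass
class CorrectionMatrix:
    """Maps a backbone MID (length n+1) to the raw measured MID
    (length n+1+TAIL_MASSES, truncated)."""

    fragment_id: str
    matrix: np.ndarray
    full_distribution: np.ndarray  # untruncated non-tracer shift distribution
    condition: float

    @property
    def n_backbone(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def n_raw(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path):
        """Export the matrix for audit: rows = raw masses, cols = M+j."""
        with open(path, "w") as fh:
            fh.write(f"# fragment {self.fragment_id}, condition {self.condition:.6g}\n")
            fh.write("mass\t" + "\t".join(f"M+{j}" for j in range(self.matrix.shape[1])) + "\n")
            for i, row in enumerate(self.matrix):
                fh.write(f"{i}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def build_matrix(fragment: FragmentSpec, table: AbundanceTable | None = None) -> CorrectionMatrix:
    table = table or AbundanceTable.default()
    dist = natural_shift_distribution(fragment, table)
    n = fragment.n_carbons
    rows = n + 1 + TAIL_MASSES
    M = np.zeros((rows, n + 1))
    for j in range(n + 1):
        length = min(len(dist), rows - j)
        M[j : j + length, j] = dist[:length]
    cond = float(np.linalg.cond(M))
    colsums = M.sum(axis=0)
    if np.any(colsums < 0.5):
        warnings.warn(
            f"fragment {fragment.id!r}: correction matrix column sum below 0.5; "
            "the retained mass window truncates most of the isotope envelope",
            stacklevel=2,
        )
    return CorrectionMatrix(
        fragment_id=fragment.id, matrix=M, full_distribution=dist, condition=cond
    )


def convolve_natural(
    mid: MIDVector, fragment: FragmentSpec, table: AbundanceTable | None = None,
    matrix: CorrectionMatrix | None = None, renormalize: bool = True,
) -> MIDVector:
    """Forward model: backbone MID -> raw derivatized-ion MID."""
    cm = matrix if matrix is not None else build_matrix(fragment, table)
    raw = cm.matrix @ np.asarray(mid.masses, dtype=float)
    if renormalize:
        raw = raw / raw.sum()
    return MIDVector(id=mid.id, masses=raw, space="derivatized-raw")


def correct_mid(
    raw: MIDVector, fragment: FragmentSpec, table: AbundanceTable | None = None,
    matrix: CorrectionMatrix | None = None,
) -> MIDVector:
    """Invert the natural-abundance forward model by NNLS + renormalization."""
    cm = matrix if matrix is not None else build_matrix(fragment, table)
    y = np.asarray(raw.masses, dtype=float)
    if len(y) < cm.n_backbone + 1:
        raise ValueError(
            f"raw MID for {fragment.id!r} has {len(y)} masses; need at least "
            f"{cm.n_backbone + 1}"
        )
    if np.any(y < 0):
        warnings.warn(
            f"fragment {fragment.id!r}: negative raw intensities clipped to zero",
            stacklevel=2,
        )
        y = np.clip(y, 0.0, None)
    if cm.condition > CONDITION_LIMIT:
        warnings.warn(
            f"fragment {fragment.id!r}: ill-conditioned correction matrix "
            f"(cond {cm.condition:.3g})",
            stacklevel=2,
        )
    rows = min(len(y), cm.n_raw)
    # scale target to the retained window so the normalized solution is exact
    x, _ = nnls(cm.matrix[:rows], y[:rows])
    total = x.sum()
    if total <= 0:
        raise ValueError(f"correction of {fragment.id!r} produced an empty MID")
    return MIDVector(id=raw.id, masses=x / total, space="backbone")
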