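"""Physicochemical sequence features for tail-anchored protein analysis.

Two quantities drive organelle selection of tail-anchored (TA) membrane
proteins: the hydrophobicity of the C-terminal transmembrane domain (TMD)
and the net charge of the luminal tail that follows it.  This module
computes both:

* GRAVY (Grand Average of Hydropathicity) — the arithmetic mean of
  Kyte–Doolittle hydropathy values over a sequence.  Values above ~1.6
  indicate a credible membrane-spanning helix; ER-destined TMDs tend to
  be the most hydrophobic.

* Net charge at a given pH — a Henderson–Hasselbalch sum over ionizable
  groups.  Each basic group (Arg, Lys, His side chains, free N-terminus)
  contributes ``+1 / (1 + 10**(pH - pKa))`` and each acidic group (Asp,
  Glu, Cys, Tyr side chains, free C-terminus) contributes
  ``-1 / (1 + 10**(pKa - pH))``.  Tail fragments are treated as free
  peptides with both termini ionizable, which is how the published
  mutant-series values (+4.9 / +2.9 / +0.9 for the ACBD5 tail variants)
  are reproduced.

Ambiguous residues (B, Z, X, U, ...) are rejected: both hydropathy and
charge are undefined for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import Segmentation

__all__ = [
    "KYTE_DOOLITTLE",
    "AMINO_ACIDS",
    "PkaTable",
    "DEFAULT_PKA",
    "FeatureVector",
    "gravy",
    "net_charge",
    "compute_features",
    "round_half_away",
]

#: Kyte–Doolittle hydropathy scale (dimensionless, per residue).
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: The 20 standard amino-acid letters accepted everywhere in the package.
AMINO_ACIDS: frozenset[str] = frozenset(KYTE_DOOLITTLE)


def _check_sequence(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"{what} contains non-standard residue letter(s): "
            + ", ".join(sorted(bad))
        )
    return seq


@dataclass(frozen=True)
class PkaTable:
    """pKa values of ionizable groups used by :func:`net_charge`.

    The defaults are a Sillero-type table chosen so that tail charges of
    free peptides at pH 7 match the values reported for the ACBD5 mutant
    series to one decimal.  Swap the table (or load one from a key=value
    file) to use a different convention.
    """

    n_terminus: float = 8.0
    c_terminus: float = 3.1
    basic: Mapping[str, float] = field(
        default_factory=lambda: {"H": 6.5, "K": 10.0, "R": 12.0}
    )
    acidic: Mapping[str, float] = field(
        default_factory=lambda: {"D": 4.4, "E": 4.4, "C": 8.5, "Y": 10.0}
    )

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"pKa for {name} must be a positive real, got {value}")

    def items(self):
        yield "n_terminus", self.n_terminus
        yield "c_terminus", self.c_terminus
        yield from self.basic.items()
        yield from self.acidic.items()

    @classmethod
    def from_file(cls, path: str | Path) -> "PkaTable":
        """Read a ``group=pKa`` per-line file (``#`` comments allowed).

        Group keys: ``n_terminus``, ``c_terminus`` and single residue
        letters out of D, E, C, Y (acidic) / H, K, R (basic).
        """
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = float(raw)
        basic = {k: values.pop(k) for k in ("H", "K", "R") if k in values}
        acidic = {k: values.pop(k) for k in ("D", "E", "C", "Y") if k in values}
        default = cls()
        return cls(
            n_terminus=values.pop("n_terminus", default.n_terminus),
            c_terminus=values.pop("c_terminus", default.c_terminus),
            basic={**default.basic, **basic},
            acidic={**default.acidic, **acidic},
        )


DEFAULT_PKA = PkaTable()


def gravy(seq: str) -> float:
    """Mean Kyte–Doolittle hydropathy of *seq* (GRAVY)."""
    seq = _check_sequence(seq)
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def net_charge(
    seq: str,
    pH: float = 7.0,
    *,
    free_nterm: bool = True,
    free_cterm: bool = True,
    pka: PkaTable = DEFAULT_PKA,
) -> float:
    """Net charge of *seq* at *pH*, in elementary charge units.

    Henderson–Hasselbalch sum over side chains plus (optionally) the free
    termini.  Full precision is returned; round with
    :func:`round_half_away` to one decimal for presentation.
    """
    seq = _check_sequence(seq, "peptide")
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    charge = 0.0
    if free_nterm:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    if free_cterm:
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for residue in seq:
        if residue in pka.basic:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka.basic[residue]))
        elif residue in pka.acidic:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.acidic[residue] - pH))
    return charge


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 0.25 → 0.3, −0.25 → −0.3 at 1 dp)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class FeatureVector:
    """Per-protein physicochemical features used throughout the package.

    ``tail_charge`` and ``upstream_charge`` are in elementary charge
    units at the analysis pH (default 7.0); GRAVY values are
    dimensionless; ``tail_length`` counts residues C-terminal of the TMD.
    """

    tmd_gravy: float
    tail_charge: float
    tail_length: int
    upstream_charge: float
    upstream_gravy: float

    def __post_init__(self) -> None:
        for name in ("tmd_gravy", "tail_charge", "upstream_charge", "upstream_gravy"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite feature {name}")
        if self.tail_length < 0:
            raise ValueError("negative tail_length")


def compute_features(
    seg: "Segmentation",
    pH: float = 7.0,
    *,
    pka: PkaTable = DEFAULT_PKA,
) -> FeatureVector:
    """Features of a segmented C-terminus (see :mod:`tapredict.segmentation`).

    Empty tail or upstream regions contribute charge 0.0 and GRAVY 0.0;
    an empty TMD is an error.
    """
    if not seg.tmd_seq:
        raise ValueError("segmentation has an empty TMD")

    def _charge(s: str) -> float:
        return net_charge(s, pH, pka=pka) if s else 0.0

    return FeatureVector(
        tmd_gravy=gravy(seg.tmd_seq),
        tail_charge=_charge(seg.tail_seq),
        tail_length=len(seg.tail_seq),
        upstream_charge=_charge(seg.upstream_seq),
        upstream_gravy=gravy(seg.upstream_seq) if seg.upstream_seq else 0.0,
    )
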