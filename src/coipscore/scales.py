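"""Amino-acid property index tables and the pKa set for pI calculation.

The five 20-value property tables are configuration, not ground truth: they
are synthetic stand-in tables assembled for this package from standard
published propensity and hydropathy compilations, keyed by the citation whose
property they represent.  Each table follows the stated sign convention and
covers exactly the 20 standard residues; swapping in a different AAindex-style
vector of the same shape changes numbers but not the analysis machinery, which
is why every test on them is property-based.

Sign conventions (higher value means *more* of the named property):

* ``helicity``        — alpha-helix forming propensity
* ``amphiphilicity``  — preference for the membrane/water interface
* ``coil``            — random-coil / turn propensity
* ``beta_sheet``      — beta-sheet forming propensity
* ``hydrophobicity``  — hydropathy (positive = hydrophobic)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical residue order used for every 20-vector in the package
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class PropertyScale:
    """A 20-value amino-acid property index."""

    name: str
    values: dict[str, float]
    citation_key: str
    _vector: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if set(self.values) != set(AA_ORDER):
            raise ValueError(f"scale {self.name!r} must define exactly the 20 standard residues")
        vec = np.array([self.values[aa] for aa in AA_ORDER], dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"scale {self.name!r} contains non-finite values")
        object.__setattr__(self, "_vector", vec)

    @property
    def vector(self) -> np.ndarray:
        """Values in :data:`AA_ORDER` order."""
        return self._vector


def _scale(name: str, citation: str, table: str) -> PropertyScale:
    values = {}
    for entry in table.split():
        aa, v = entry.split(":")
        values[aa] = float(v)
    return PropertyScale(name=name, values=values, citation_key=citation)


#: alpha-helix propensity (stand-in values: classical helix propensity table)
HELICITY = _scale(
    "helicity",
    "koehl-levitt-1999",
    "A:1.42 R:0.98 N:0.67 D:1.01 C:0.70 Q:1.11 E:1.51 G:0.57 H:1.00 I:1.08 "
    "L:1.21 K:1.16 M:1.45 F:1.13 P:0.57 S:0.77 T:0.83 W:1.08 Y:0.69 V:1.06",
)

#: interface preference (stand-in values: interfacial partitioning free
#: energies, sign-flipped so aromatic/interface residues score high)
AMPHIPHILICITY = _scale(
    "amphiphilicity",
    "cornette-1987",
    "A:-0.17 R:-0.81 N:-0.42 D:-1.23 C:0.24 Q:-0.58 E:-2.02 G:-0.01 H:-0.96 "
    "I:0.31 L:0.56 K:-0.99 M:0.23 F:1.13 P:-0.45 S:-0.13 T:-0.14 W:1.85 "
    "Y:0.94 V:-0.07",
)

#: random-coil / turn propensity (stand-in values: classical turn table)
COIL = _scale(
    "coil",
    "ptitsyn-finkelstein-1983",
    "A:0.66 R:0.95 N:1.56 D:1.46 C:1.19 Q:0.98 E:0.74 G:1.56 H:0.95 I:0.47 "
    "L:0.59 K:1.01 M:0.60 F:0.60 P:1.52 S:1.43 T:0.96 W:0.96 Y:1.14 V:0.50",
)

#: beta-sheet propensity (stand-in values: classical sheet propensity table)
BETA_SHEET = _scale(
    "beta_sheet",
    "crawford-1973",
    "A:0.83 R:0.93 N:0.89 D:0.54 C:1.19 Q:1.10 E:0.37 G:0.75 H:0.87 I:1.60 "
    "L:1.30 K:0.74 M:1.05 F:1.38 P:0.55 S:0.75 T:1.19 W:1.37 Y:1.47 V:1.70",
)

#: hydropathy (stand-in values: classical hydropathy table)
HYDROPHOBICITY = _scale(
    "hydrophobicity",
    "fasman-1989",
    "A:1.8 R:-4.5 N:-3.5 D:-3.5 C:2.5 Q:-3.5 E:-3.5 G:-0.4 H:-3.2 I:4.5 "
    "L:3.8 K:-3.9 M:1.9 F:2.8 P:-1.6 S:-0.8 T:-0.7 W:-0.9 Y:-1.3 V:4.2",
)

#: the five scales used by the interactor-vs-proteome comparison
DEFAULT_SCALES: dict[str, PropertyScale] = {
    s.name: s for s in (HELICITY, AMPHIPHILICITY, COIL, BETA_SHEET, HYDROPHOBICITY)
}


# --- isoelectric point -------------------------------------------------------
# IPC_protein pKa set (Kozlowski 2016, IPC 1.0); cysteine is treated as an
# ionizable acid per this set.

PKA_NTERM = 9.094
PKA_CTERM = 2.869

#: side-chain pKa of acidic groups (deprotonated form carries charge -1)
PKA_ACIDIC = {"C": 7.555, "D": 3.872, "E": 4.412, "Y": 10.85}

#: side-chain pKa of basic groups (protonated form carries charge +1)
PKA_BASIC = {"H": 5.637, "K": 9.052, "R": 11.84}
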