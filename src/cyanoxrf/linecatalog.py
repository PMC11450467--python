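"""K-shell emission line catalog for elements Z = 13 (Al) through 30 (Zn).

Energies are Kα1/Kβ1 centroids in keV from standard X-ray emission tables;
the Kβ/Kα entry is the fixed area ratio used as a constraint during peak
fitting. The table is an ordinary dict and may be edited or replaced by the
caller — nothing downstream assumes these particular numbers, only that the
same catalog is used for forward simulation and fitting.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EmissionLine:
    """K-line set of one element."""

    symbol: str
    Z: int
    ka_keV: float
    kb_keV: float
    kb_ka_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 < self.kb_ka_ratio < 1.0):
            raise ValueError(f"{self.symbol}: Kβ/Kα ratio must be in (0,1)")
        if self.ka_keV <= 0 or self.kb_keV <= self.ka_keV:
            raise ValueError(f"{self.symbol}: require 0 < Kα < Kβ energy")


#: symbol -> (Z, Kα keV, Kβ keV, Kβ/Kα area ratio)
_TABLE = {
    "Al": (13, 1.487, 1.557, 0.013),
    "Si": (14, 1.740, 1.836, 0.027),
    "P": (15, 2.013, 2.139, 0.041),
    "S": (16, 2.307, 2.464, 0.052),
    "Cl": (17, 2.622, 2.815, 0.062),
    "Ar": (18, 2.957, 3.191, 0.072),
    "K": (19, 3.312, 3.590, 0.110),
    "Ca": (20, 3.690, 4.012, 0.118),
    "Sc": (21, 4.088, 4.460, 0.122),
    "Ti": (22, 4.508, 4.931, 0.126),
    "V": (23, 4.949, 5.427, 0.128),
    "Cr": (24, 5.411, 5.946, 0.130),
    "Mn": (25, 5.895, 6.490, 0.131),
    "Fe": (26, 6.398, 7.058, 0.133),
    "Co": (27, 6.925, 7.649, 0.134),
    "Ni": (28, 7.472, 8.264, 0.135),
    "Cu": (29, 8.041, 8.905, 0.136),
    "Zn": (30, 8.631, 9.572, 0.138),
}


class LineCatalog:
    """Lookup of K-shell lines, element symbol -> :class:`EmissionLine`."""

    def __init__(self, lines: dict[str, EmissionLine] | None = None):
        if lines is None:
            lines = {
                sym: EmissionLine(sym, z, ka, kb, r)
                for sym, (z, ka, kb, r) in _TABLE.items()
            }
        self._lines = dict(lines)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._lines

    def __getitem__(self, symbol: str) -> EmissionLine:
        try:
            return self._lines[symbol]
        except KeyError:
            raise KeyError(
                f"element {symbol!r} not in line catalog "
                f"(covers {', '.join(self._lines)})"
            ) from None

    def elements(self) -> list[str]:
        return list(self._lines)

    def excitable(self, incident_keV: float) -> list[str]:
        """Elements whose Kα line lies below the incident energy."""
        return [s for s, ln in self._lines.items() if ln.ka_keV < incident_keV]


def default_catalog() -> LineCatalog:
    return LineCatalog()
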