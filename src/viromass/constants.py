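"""Physical constants and nucleic-acid semantics.

The per-monomer molecular weights are the working values used throughout the
package to convert between DNA mass and genome copies: with Avogadro's number
6.022e23 /mol and 331.2 g/mol per ssDNA nucleotide, a 1.8 kb ssDNA genome
weighs 9.90e-19 g and a 24.9 kb genome 1.37e-17 g; the dsDNA weight per base
pair is exactly twice the ssDNA weight per nucleotide, so a 50 kb dsDNA genome
weighs 5.5e-17 g.  The constants are configurable (e.g. to use 330/660 g/mol
conventions) but the dsDNA/ssDNA factor-of-two relation is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

AVOGADRO = 6.022e23
"""Avogadro's number, 1/mol."""


class NucleicAcidType(str, Enum):
    """Closed enumeration of the two DNA strandedness classes handled here."""

    SSDNA = "ssDNA"
    DSDNA = "dsDNA"

    @classmethod
    def coerce(cls, value: "NucleicAcidType | str") -> "NucleicAcidType":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown nucleic-acid type {value!r}; expected 'ssDNA' or 'dsDNA'"
            ) from None


@dataclass(frozen=True)
class Constants:
    """Mass-conversion constants.

    Attributes
    ----------
    avogadro : float
        Avogadro's number, 1/mol.
    mw_ss_per_nt : float
        Mean molecular weight of one ssDNA nucleotide, g/mol.
    mw_ds_per_bp : float
        Mean molecular weight of one dsDNA base pair, g/mol.  Must equal
        ``2 * mw_ss_per_nt``.
    """

    avogadro: float = AVOGADRO
    mw_ss_per_nt: float = 331.2
    mw_ds_per_bp: float = 662.4

    def __post_init__(self) -> None:
        if self.avogadro <= 0 or self.mw_ss_per_nt <= 0 or self.mw_ds_per_bp <= 0:
            raise ValueError("all constants must be strictly positive")
        if abs(self.mw_ds_per_bp - 2.0 * self.mw_ss_per_nt) > 1e-9 * self.mw_ds_per_bp:
            raise ValueError(
                "mw_ds_per_bp must equal 2 * mw_ss_per_nt "
                f"(got {self.mw_ds_per_bp} vs 2*{self.mw_ss_per_nt})"
            )

    def mw_per_monomer(self, na_type: NucleicAcidType | str) -> float:
        """Molecular weight per genome-length unit (nt for ssDNA, bp for dsDNA)."""
        na = NucleicAcidType.coerce(na_type)
        return self.mw_ss_per_nt if na is NucleicAcidType.SSDNA else self.mw_ds_per_bp


DEFAULT_CONSTANTS = Constants()
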