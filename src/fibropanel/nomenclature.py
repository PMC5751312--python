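"""Legacy mature-chain vs native-protein residue numbering.

Fibrinogen mutations are traditionally named on the mature chain (after
signal-peptide cleavage), e.g. ``Aα(16)Arg>Cys``, while variant databases use
HGVS numbering on the native protein including the signal peptide, e.g.
``p.Arg35Cys``.  The two schemes differ by the chain's signal-peptide length:
19 residues for the Aα chain (FGA), 30 for Bβ (FGB) and 26 for γ (FGG).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .model import DEFAULT_SIGNAL_PEPTIDE_OFFSETS, GENES

_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=|\*)$")

#: Greek chain letters used in legacy names, per gene.
CHAIN_NAMES = {"FGA": "Aα", "FGB": "Bβ", "FGG": "γ"}


def _offset(gene: str, offsets: dict[str, int] | None) -> int:
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}; allowed: {', '.join(GENES)}")
    table = offsets if offsets is not None else DEFAULT_SIGNAL_PEPTIDE_OFFSETS
    return table[gene]


def legacy_to_native(gene: str, legacy_position: int, offsets: dict[str, int] | None = None) -> int:
    """Convert a mature-chain residue number to native-protein numbering."""
    if legacy_position < 1:
        raise ValueError(f"legacy position must be >= 1, got {legacy_position}")
    return legacy_position + _offset(gene, offsets)


def native_to_legacy(gene: str, native_position: int, offsets: dict[str, int] | None = None) -> int:
    """Convert native-protein numbering back to the mature-chain scheme.

    Raises ValueError for residues within the signal peptide, which have no
    legacy name.
    """
    off = _offset(gene, offsets)
    if native_position <= off:
        raise ValueError(
            f"native position {native_position} lies in the {gene} signal peptide "
            f"(first {off} residues) and has no legacy-scheme name"
        )
    return native_position - off


@dataclass(frozen=True)
class ResidueName:
    """A residue-level mutation name in either numbering scheme."""

    gene: str
    scheme: str  # "legacy" or "native"
    position: int
    aa_ref: str
    aa_alt: str

    def __post_init__(self) -> None:
        if self.scheme not in ("legacy", "native"):
            raise ValueError(f"scheme must be 'legacy' or 'native', got {self.scheme!r}")
        if self.position < 1:
            raise ValueError("position must be positive")

    def to_native(self, offsets: dict[str, int] | None = None) -> "ResidueName":
        if self.scheme == "native":
            return self
        return ResidueName(
            self.gene, "native", legacy_to_native(self.gene, self.position, offsets),
            self.aa_ref, self.aa_alt,
        )

    def to_legacy(self, offsets: dict[str, int] | None = None) -> "ResidueName":
        if self.scheme == "legacy":
            return self
        return ResidueName(
            self.gene, "legacy", native_to_legacy(self.gene, self.position, offsets),
            self.aa_ref, self.aa_alt,
        )

    @property
    def protein_change(self) -> str:
        """HGVS-style string; only meaningful for the native scheme."""
        return f"p.{self.aa_ref}{self.position}{self.aa_alt}"

    @property
    def legacy_name(self) -> str:
        chain = CHAIN_NAMES[self.gene]
        return f"{chain}({self.position}){self.aa_ref} > {self.aa_alt}"


def parse_protein_change(gene: str, text: str, scheme: str = "native") -> ResidueName:
    """Parse a ``p.<Aaa><Pos><Aaa>`` pattern into a :class:`ResidueName`."""
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse protein change {text!r} (expected p.<Aaa><Pos><Aaa>)")
    aa_ref, pos, aa_alt = m.group(1), int(m.group(2)), m.group(3)
    return ResidueName(gene, scheme, pos, aa_ref, aa_alt)
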