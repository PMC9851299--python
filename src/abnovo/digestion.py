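"""In-silico proteolytic digestion.

Cleavage rules follow the ExPASy conventions for the proteases used in
multi-enzyme antibody digests.  A rule names the recognized residues, the
side of the recognized residue that is cut, and residues that block the
cut when they follow it (trypsin and chymotrypsin do not cut before
proline).  Specificities for broad proteases (proteinase K, aLP) are
declared here, not measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class EnzymeRule:
    """A proteolytic cleavage rule.

    cut_side "C" cuts C-terminally of a target residue; "N" cuts
    N-terminally of it.  ``blocked_next_residues`` suppresses a C-side cut
    when the residue after the cut point is in the set.
    """

    name: str
    cut_side: str  # "C" or "N"
    target_residues: frozenset[str]
    blocked_next_residues: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cut_side not in ("C", "N"):
            raise ValueError(f"cut_side must be 'C' or 'N', got {self.cut_side!r}")
        if not self.target_residues:
            raise ValueError("target_residues must be non-empty")


def _rule(name: str, side: str, targets: str, blocked: str = "") -> EnzymeRule:
    return EnzymeRule(name, side, frozenset(targets), frozenset(blocked))


ENZYMES: dict[str, EnzymeRule] = {
    r.name: r
    for r in (
        _rule("trypsin", "C", "KR", "P"),
        _rule("lys-c", "C", "K"),
        _rule("lys-n", "N", "K"),
        _rule("asp-n", "N", "D"),
        _rule("glu-c", "C", "E"),
        _rule("chymotrypsin", "C", "FWYL", "P"),
        _rule("thermolysin", "N", "AFILMV"),
        _rule("elastase", "C", "AVSGLI"),
        _rule("alp", "C", "AFILVWY"),
        _rule("proteinase-k", "C", "AFILVWY"),
    )
}


def get_enzyme(enzyme: "EnzymeRule | str") -> EnzymeRule:
    if isinstance(enzyme, EnzymeRule):
        return enzyme
    try:
        return ENZYMES[enzyme.lower()]
    except KeyError:
        known = ", ".join(sorted(ENZYMES))
        raise KeyError(f"unknown enzyme {enzyme!r}; known enzymes: {known}") from None


@dataclass(frozen=True)
class DigestPeptide:
    """One digest product with 0-based half-open coordinates on the protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(protein: str, enzyme: "EnzymeRule | str") -> list[int]:
    """Internal cut positions p (cut between residues p-1 and p), sorted."""
    rule = get_enzyme(enzyme)
    sites = []
    for i, aa in enumerate(protein):
        if aa not in rule.target_residues:
            continue
        p = i + 1 if rule.cut_side == "C" else i
        if p <= 0 or p >= len(protein):
            continue
        if rule.cut_side == "C" and protein[p] in rule.blocked_next_residues:
            continue
        sites.append(p)
    return sorted(set(sites))


def digest(
    protein: str,
    enzyme: "EnzymeRule | str",
    max_missed_cleavages: int = 0,
) -> list[DigestPeptide]:
    """Digest a protein, returning peptides with coordinates.

    With 0 missed cleavages the products partition the protein; with m
    allowed missed cleavages every product spanning up to m internal cut
    sites is also returned, ordered by start then end.
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    bounds = [0] + cleavage_sites(protein, enzyme) + [len(protein)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                DigestPeptide(protein[start:end], start, end, j - i - 1)
            )
    return peptides
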