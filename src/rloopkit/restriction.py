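"""In-silico restriction digestion.

DRIP protocols fragment genomic DNA with a cocktail of restriction enzymes
before immunoprecipitation, so the natural counting unit for differential
R-loop analysis is the restriction fragment. This module scans a genome for
recognition sites of a (configurable) enzyme set and emits the fragment
tiling between consecutive cut positions.

The default enzyme panel is the five-enzyme DRIP cocktail (HindIII, EcoRI,
BsrGI, XbaI, SspI) with recognition sites and top-strand cut offsets from
the standard REBASE definitions. All five sites are palindromic, so a
top-strand scan finds every cut; this is asserted when the panel is built.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Enzyme",
    "RestrictionFragment",
    "builtin_enzymes",
    "get_enzyme",
    "digest",
    "write_fragments_bed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG",
    # N deliberately excluded from matching ambiguous genome bases; in a
    # *motif* N matches any unambiguous base.
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(site: str) -> str:
    return site.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset.

    ``cut_offset`` is the number of bases from the start of the recognition
    site to the cut position on the top strand (e.g. G^AATTC has offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or any(ch not in IUPAC for ch in site):
            raise ValueError(
                f"{self.name}: recognition site {self.recognition_site!r} "
                "is not a valid IUPAC DNA string"
            )
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site of "
                f"length {len(site)}"
            )
        object.__setattr__(self, "recognition_site", site)

    @property
    def is_palindromic(self) -> bool:
        return _revcomp(self.recognition_site) == self.recognition_site

    def _pattern(self) -> re.Pattern:
        # lookahead so overlapping occurrences each produce a cut
        body = "".join(
            ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]"
            for ch in self.recognition_site
        )
        return re.compile(f"(?=({body}))")

    def cut_positions(self, sequence: str) -> list[int]:
        """0-based cut positions on the top strand of ``sequence``.

        Ambiguous bases (anything other than ACGT) in the sequence never
        match a recognition site.
        """
        seq = sequence.upper()
        return [m.start() + self.cut_offset for m in self._pattern().finditer(seq)]


_BUILTINS = (
    Enzyme("HindIII", "AAGCTT", 1),
    Enzyme("EcoRI", "GAATTC", 1),
    Enzyme("BsrGI", "TGTACA", 1),
    Enzyme("XbaI", "TCTAGA", 1),
    Enzyme("SspI", "AATATT", 3),
)


def builtin_enzymes() -> tuple[Enzyme, ...]:
    """The five-enzyme DRIP digestion panel (all palindromic six-cutters)."""
    for enz in _BUILTINS:
        assert enz.is_palindromic, f"{enz.name} site is not palindromic"
    return _BUILTINS


def get_enzyme(name: str) -> Enzyme:
    for enz in _BUILTINS:
        if enz.name.lower() == name.lower():
            return enz
    known = ", ".join(e.name for e in _BUILTINS)
    raise KeyError(f"unknown enzyme {name!r}; built-ins are: {known}")


@dataclass(frozen=True)
class RestrictionFragment:
    """A fragment between two consecutive cut positions (0-based half-open).

    ``left_enzyme``/``right_enzyme`` name the enzyme whose cut produced each
    boundary, or "chrom_end" at chromosome termini.
    """

    id: str
    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


def digest(
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme] | None = None,
) -> list[RestrictionFragment]:
    """Digest ``genome`` (mapping chrom -> sequence) with ``enzymes``.

    Returns fragments that tile each chromosome exactly: sorted,
    non-overlapping, with union [0, len). Duplicate cut positions (two
    enzymes cutting at the same base) are collapsed; cuts at position 0 or
    at the chromosome end produce no zero-length fragment. An empty genome
    yields an empty list; a zero-length chromosome is an error.
    """
    if enzymes is None:
        enzymes = builtin_enzymes()
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("enzyme set must be non-empty")

    fragments: list[RestrictionFragment] = []
    for chrom, seq in genome.items():
        length = len(seq)
        if length == 0:
            raise ValueError(f"chromosome {chrom!r} has zero length")
        cuts: dict[int, str] = {}
        for enz in enzymes:
            for pos in enz.cut_positions(seq):
                if 0 < pos < length:
                    # first enzyme listed wins on coincident cuts
                    cuts.setdefault(pos, enz.name)
        boundaries = [0] + sorted(cuts) + [length]
        names = ["chrom_end"] + [cuts[p] for p in sorted(cuts)] + ["chrom_end"]
        for i in range(len(boundaries) - 1):
            start, end = boundaries[i], boundaries[i + 1]
            fragments.append(
                RestrictionFragment(
                    id=f"{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    left_enzyme=names[i],
                    right_enzyme=names[i + 1],
                )
            )
    return fragments


def write_fragments_bed(fragments: Iterable[RestrictionFragment], path) -> None:
    """Write fragments as BED6 plus two columns for the flanking enzymes."""
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(
                f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.id}\t0\t.\t"
                f"{frag.left_enzyme}\t{frag.right_enzyme}\n"
            )
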