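"""Recognition sites of restriction-modification (R-M) systems.

A recognition site is a short DNA word, possibly degenerate, written in the
15-letter IUPAC nucleotide alphabet (``GANTC``, ``YATR``, ...).  Each site is
attributed to one R-M system type (I, orthodox II, IIC/G, IIM, III, IV) and
carries two structural attributes that drive the downstream analysis:
degeneracy (any letter outside A/C/G/T) and palindromy (the word equals its
IUPAC reverse complement letter-for-letter, e.g. GATC or GANTC).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

__all__ = [
    "RMType",
    "RecognitionSite",
    "SiteCatalogue",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "parse_site",
    "reverse_complement",
    "is_palindromic",
    "resolve_type_conflicts",
    "augment_with_missing_palindromes",
    "all_palindromes",
    "read_catalogue",
    "write_catalogue",
]

#: IUPAC nucleotide codes mapped to the set of plain bases each matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Letter-wise IUPAC complement (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_PLAIN = frozenset("ACGT")


class RMType(str, enum.Enum):
    """R-M system type of a recognition site.

    ``II_orthodox`` is Type II excluding the single-polypeptide IIC/G subtypes
    and the methyl-directed IIM subtype, which behave differently and are kept
    apart throughout the analysis.
    """

    I = "I"
    II_orthodox = "II_orthodox"
    IIC_G = "IIC_G"
    IIM = "IIM"
    III = "III"
    IV = "IV"


#: Precedence used when one word is recognised by enzymes of several types:
#: orthodox Type II wins over everything, IIC/G wins over III; the remaining
#: order is a fixed convention to keep the catalogue deterministic.
TYPE_PRECEDENCE: tuple[RMType, ...] = (
    RMType.II_orthodox,
    RMType.IIC_G,
    RMType.III,
    RMType.I,
    RMType.IIM,
    RMType.IV,
)


@dataclass(frozen=True)
class RecognitionSite:
    """A validated IUPAC recognition-site word with derived attributes."""

    word: str
    rm_type: RMType = RMType.II_orthodox

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def is_degenerate(self) -> bool:
        return any(c not in _PLAIN for c in self.word)

    @property
    def is_palindromic(self) -> bool:
        return self.word == reverse_complement(self.word)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.word


def parse_site(raw: str, rm_type: RMType | str = RMType.II_orthodox) -> RecognitionSite:
    """Validate and canonicalise a raw site string.

    Input is case-folded to uppercase.  A letter outside the IUPAC alphabet is
    rejected with its 1-based position.
    """
    if not raw:
        raise ValueError("recognition site word must be non-empty")
    word = raw.strip().upper()
    for pos, letter in enumerate(word, start=1):
        if letter not in IUPAC_SETS:
            raise ValueError(
                f"invalid IUPAC letter {letter!r} at position {pos} in site {word!r}"
            )
    return RecognitionSite(word=word, rm_type=RMType(rm_type))


def reverse_complement(word: str) -> str:
    """Reverse complement of an IUPAC word, letter-for-letter.

    An involution: ``reverse_complement(reverse_complement(w)) == w``.
    """
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(word.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {word!r}") from None


def is_palindromic(word: str) -> bool:
    """True if the word equals its IUPAC reverse complement (string equality)."""
    w = word.upper()
    return w == reverse_complement(w)


def resolve_type_conflicts(types: set[RMType] | set[str]) -> RMType:
    """Collapse the types of all enzymes recognising one word to a single type.

    Orthodox Type II takes precedence over every other type, and IIC/G over
    Type III; remaining ties follow the fixed :data:`TYPE_PRECEDENCE` order.
    """
    if not types:
        raise ValueError("cannot resolve an empty set of R-M types")
    normalised = {RMType(t) for t in types}
    for t in TYPE_PRECEDENCE:
        if t in normalised:
            return t
    raise ValueError(f"unknown R-M types: {types}")  # pragma: no cover


@dataclass
class SiteCatalogue:
    """Catalogue of recognition sites, one entry per distinct word.

    ``provenance`` carries free text per word (source enzyme names or the
    marker ``"augmented"`` for palindromes added by
    :func:`augment_with_missing_palindromes`); ``experimentally_proven`` marks
    words with at least one experimentally characterised enzyme.
    """

    sites: dict[str, RecognitionSite] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    experimentally_proven: dict[str, bool] = field(default_factory=dict)

    def add(
        self,
        raw_word: str,
        rm_type: RMType | str,
        provenance: str = "",
        experimentally_proven: bool = False,
    ) -> RecognitionSite:
        """Add a site, resolving the R-M type against any existing entry."""
        site = parse_site(raw_word, rm_type)
        if site.word in self.sites:
            merged = resolve_type_conflicts({self.sites[site.word].rm_type, site.rm_type})
            site = RecognitionSite(site.word, merged)
            if provenance:
                old = self.provenance.get(site.word, "")
                provenance = f"{old};{provenance}" if old else provenance
            else:
                provenance = self.provenance.get(site.word, "")
            experimentally_proven = (
                experimentally_proven or self.experimentally_proven.get(site.word, False)
            )
        self.sites[site.word] = site
        self.provenance[site.word] = provenance
        self.experimentally_proven[site.word] = experimentally_proven
        return site

    def __contains__(self, word: str) -> bool:
        return word.upper() in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites.values())

    def words(self) -> list[str]:
        return sorted(self.sites)


def all_palindromes(length: int) -> list[str]:
    """All non-degenerate palindromes of even ``length`` (4**(L/2) words)."""
    if length % 2:
        return []  # a non-degenerate odd-length word cannot equal its revcomp
    half = length // 2
    out = []
    for left in itertools.product("ACGT", repeat=half):
        w = "".join(left)
        out.append(w + reverse_complement(w))
    return sorted(out)


def augment_with_missing_palindromes(cat: SiteCatalogue) -> SiteCatalogue:
    """Add every non-degenerate 4 bp and 6 bp palindrome missing from the catalogue.

    Added entries are typed orthodox Type II (the type of the large majority of
    short non-degenerate palindromic sites) with provenance ``"augmented"``.
    Idempotent: a second application adds nothing.  Mutates and returns ``cat``.
    """
    for length in (4, 6):
        for w in all_palindromes(length):
            if w not in cat.sites:
                cat.add(w, RMType.II_orthodox, provenance="augmented")
    return cat


def read_catalogue(path) -> SiteCatalogue:
    """Read a site catalogue TSV.

    Columns: ``word``, ``rm_type``, ``enzyme_names`` (semicolon-separated, may
    be empty), ``experimentally_proven`` (0/1).  ``#`` comment lines ignored.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"word", "rm_type", "enzyme_names", "experimentally_proven"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalogue TSV missing columns: {sorted(missing)}")
    cat = SiteCatalogue()
    for row in df.itertuples(index=False):
        cat.add(
            row.word,
            row.rm_type,
            provenance=row.enzyme_names,
            experimentally_proven=str(row.experimentally_proven).strip() == "1",
        )
    return cat


def write_catalogue(cat: SiteCatalogue, path) -> None:
    """Write a catalogue in the TSV layout accepted by :func:`read_catalogue`."""
    import pandas as pd

    rows = [
        {
            "word": w,
            "rm_type": cat.sites[w].rm_type.value,
            "enzyme_names": cat.provenance.get(w, ""),
            "experimentally_proven": int(cat.experimentally_proven.get(w, False)),
        }
        for w in cat.words()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
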