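"""Genomes, replicons, R-M annotations and forward-strand word counting.

A "genome" is the full replicon set of one organism — its chromosome(s) plus
any plasmids — never concatenated: windows do not span replicon boundaries.
Counting is forward-strand only and overlapping; a site and its reverse
complement are treated as distinct words, so a palindrome automatically
represents both strands.

The counting kernel encodes each base as a bitmask (A=1, C=2, G=4, T=8;
anything else, e.g. assembly-gap N, as 16) and each site letter as the union
of its IUPAC base bits, with site ``N`` additionally matching the gap bit.
A window matches when every position has a non-empty bit intersection, which
vectorises to a handful of numpy operations per site letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sites import IUPAC_SETS

__all__ = [
    "Replicon",
    "RMAnnotation",
    "Genome",
    "WordCount",
    "read_genome",
    "read_genome_collection",
    "count_occurrences",
    "count_in_array",
    "encode_sequence",
    "word_masks",
]

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_GAP_BIT = 16

# 256-entry lookup: ASCII byte -> base bitmask (gap bit for non-ACGT).
_ENCODE_LUT = np.full(256, _GAP_BIT, dtype=np.uint8)
for _b, _v in _BASE_BIT.items():
    _ENCODE_LUT[ord(_b)] = _v
    _ENCODE_LUT[ord(_b.lower())] = _v


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string into the uint8 bitmask array used by the counter."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def word_masks(word: str) -> np.ndarray:
    """Per-letter match masks of an IUPAC word (site N matches gap bases too)."""
    masks = np.empty(len(word), dtype=np.uint8)
    for i, letter in enumerate(word.upper()):
        try:
            bits = sum(_BASE_BIT[b] for b in IUPAC_SETS[letter])
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in {word!r}") from None
        if letter == "N":
            bits |= _GAP_BIT
        masks[i] = bits
    return masks


_MATCH_ALL = np.uint8(sum(_BASE_BIT.values()) | _GAP_BIT)


def count_in_array(arr: np.ndarray, masks: np.ndarray) -> int:
    """Number of forward-strand windows of ``arr`` matching the mask word."""
    n, L = arr.size, masks.size
    if n < L:
        return 0
    ok: np.ndarray | None = None
    for j in range(L):
        if masks[j] == _MATCH_ALL:  # site N: matches every base, skip
            continue
        hit = (arr[j : n - L + 1 + j] & masks[j]) != 0
        ok = hit if ok is None else (ok & hit)
    if ok is None:  # all-N word: every window matches
        return n - L + 1
    return int(ok.sum())


def match_positions(arr: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """0-based start positions of matching windows (used by the simulator)."""
    n, L = arr.size, masks.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        if masks[j] == _MATCH_ALL:
            continue
        ok &= (arr[j : n - L + 1 + j] & masks[j]) != 0
    return np.flatnonzero(ok)


@dataclass
class Replicon:
    """One DNA molecule of an organism, labelled chromosome or plasmid."""

    id: str
    sequence: str
    kind: str = "chromosome"  # "chromosome" | "plasmid"

    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        if self.kind not in ("chromosome", "plasmid"):
            raise ValueError(f"replicon kind must be chromosome|plasmid, got {self.kind!r}")
        self.sequence = self.sequence.upper()

    @property
    def encoded(self) -> np.ndarray:
        if self._encoded is None:
            self._encoded = encode_sequence(self.sequence)
        return self._encoded

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RMAnnotation:
    """One annotated R-M system gene: which site it recognises and where it sits.

    Coordinates are 1-based and inclusive of both ends (GenBank convention).
    ``encodes_rease`` distinguishes restriction endonuclease genes (which define
    actual site-genome pairs) from methyltransferase-only records.
    """

    site_word: str
    rm_type: str
    replicon_id: str
    gene_start: int
    gene_end: int
    encodes_rease: bool = True
    experimentally_proven: bool = False

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(
                f"annotation for {self.site_word}: gene_start {self.gene_start} "
                f"> gene_end {self.gene_end}"
            )


@dataclass
class Genome:
    """An organism: its replicons plus its R-M annotations and taxonomy labels."""

    organism_id: str
    species: str
    genus: str
    replicons: list[Replicon] = field(default_factory=list)
    rm_annotations: list[RMAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {r.id for r in self.replicons}
        for ann in self.rm_annotations:
            if ann.replicon_id not in ids:
                raise ValueError(
                    f"{self.organism_id}: annotation replicon {ann.replicon_id!r} "
                    "does not resolve to a replicon"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.replicons)

    def rease_annotations(self) -> list[RMAnnotation]:
        return [a for a in self.rm_annotations if a.encodes_rease]


@dataclass(frozen=True)
class WordCount:
    """Observed forward-strand occurrences of a word and the window count."""

    word: str
    observed: int
    windows: int

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= max(self.windows, 0):
            raise ValueError("observed count outside [0, windows]")


def count_occurrences(genome: Genome, word: str) -> WordCount:
    """Count forward-strand occurrences of an IUPAC word across all replicons.

    Overlapping matches are counted; windows never span replicons.  A word
    longer than every replicon yields ``WordCount(word, 0, 0)`` rather than an
    error, so that downstream code can flag the pair.
    """
    masks = word_masks(word)
    L = masks.size
    observed = 0
    windows = 0
    for rep in genome.replicons:
        observed += count_in_array(rep.encoded, masks)
        windows += max(0, len(rep) - L + 1)
    return WordCount(word=word.upper(), observed=observed, windows=windows)


def read_genome(fasta_paths, metadata: pd.DataFrame, organism_id: str) -> Genome:
    """Assemble one organism's Genome from FASTA file(s) and a metadata table.

    ``metadata`` columns: organism_id, species, genus, replicon_id, kind.
    Every metadata replicon must be present in the FASTA records and vice
    versa for records claimed by this organism.
    """
    from Bio import SeqIO

    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    records: dict[str, str] = {}
    for p in fasta_paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        for rec in SeqIO.parse(str(p), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    rows = metadata[metadata["organism_id"] == organism_id]
    if rows.empty:
        raise ValueError(f"no metadata rows for organism {organism_id!r}")
    replicons = []
    for row in rows.itertuples(index=False):
        if row.replicon_id not in records:
            raise ValueError(
                f"replicon {row.replicon_id!r} of {organism_id!r} missing from FASTA"
            )
        replicons.append(Replicon(row.replicon_id, records[row.replicon_id], row.kind))
    first = rows.iloc[0]
    return Genome(
        organism_id=organism_id,
        species=str(first["species"]),
        genus=str(first["genus"]),
        replicons=replicons,
    )


def read_genome_collection(
    fasta_paths,
    metadata_path,
    annotations_path=None,
) -> list[Genome]:
    """Read every organism listed in a metadata TSV, with optional annotations.

    Annotation TSV columns: organism_id, site_word, rm_type, replicon_id,
    gene_start, gene_end, encodes_rease (0/1), experimentally_proven (0/1).
    """
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    genomes = [
        read_genome(fasta_paths, metadata, oid)
        for oid in metadata["organism_id"].unique()
    ]
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
        by_org: dict[str, list[RMAnnotation]] = {}
        for row in ann.itertuples(index=False):
            by_org.setdefault(row.organism_id, []).append(
                RMAnnotation(
                    site_word=row.site_word.upper(),
                    rm_type=row.rm_type,
                    replicon_id=row.replicon_id,
                    gene_start=int(row.gene_start),
                    gene_end=int(row.gene_end),
                    encodes_rease=str(row.encodes_rease) == "1",
                    experimentally_proven=str(row.experimentally_proven) == "1",
                )
            )
        for g in genomes:
            g.rm_annotations = by_org.get(g.organism_id, [])
            Genome.__post_init__(g)  # re-validate replicon references
    return genomes
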