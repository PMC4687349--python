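"""Lifespan proxies for R-M systems.

Site avoidance accumulates over many generations, so recently acquired
systems should show weaker avoidance than long-resident ones.  Lifespan is
not directly observable; three proxies stratify the actual pairs instead:

* replicon of the REase genes — plasmid-borne systems circulate horizontally
  and are enriched for recent arrivals;
* prevalence among conspecific strains — a system annotated in most strains
  of a species has presumably resided there long; one found in few strains is
  likely a newcomer (species with fewer than five strains are not classified);
* compositional alien-fragment scores — an REase gene inside a fragment whose
  composition deviates from the genome background (as scored by an external
  horizontal-transfer predictor) is likely recently transferred.

A fourth view looks the other way: traces of *lost* systems, i.e. avoidance
of a site in a genome that does not encode the system while close relatives
(same species, or same genus) do.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import PairDataset
from .genomes import Genome
from .sites import parse_site

__all__ = [
    "AlienFragment",
    "split_by_replicon",
    "classify_prevalence",
    "prevalence_classes",
    "assign_alien_scores",
    "alien_ratio_bin",
    "trace_groups",
    "read_alien_fragments",
]

DEFAULT_RATIO_BINS = (0.0, 1.0, 2.0)  # 0 (not predicted), (0,1], (1,2], >2


@dataclass(frozen=True)
class AlienFragment:
    """A putative horizontally acquired segment with its predictor score."""

    replicon_id: str
    start: int  # 1-based, inclusive
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"fragment start {self.start} > end {self.end}")
        if self.score < 0:
            raise ValueError("fragment score must be non-negative")

    def overlaps(self, start: int, end: int) -> bool:
        """True when the fragment shares at least one base with [start, end]."""
        return self.start <= end and start <= self.end


def read_alien_fragments(path) -> dict[str, list[AlienFragment]]:
    """Read an alien-fragment TSV (replicon_id, start, end, score) per replicon."""
    df = pd.read_csv(path, sep="\t")
    frags: dict[str, list[AlienFragment]] = {}
    for row in df.itertuples(index=False):
        frags.setdefault(str(row.replicon_id), []).append(
            AlienFragment(str(row.replicon_id), int(row.start), int(row.end), float(row.score))
        )
    return frags


def _rease_kinds(genome: Genome, word: str) -> list[str]:
    kinds = []
    for ann in genome.rease_annotations():
        if parse_site(ann.site_word).word == word:
            kinds.append(genome.replicon(ann.replicon_id).kind)
    return kinds


def split_by_replicon(actual: PairDataset, genomes: list[Genome]) -> pd.DataFrame:
    """Label each actual pair plasmid- or chromosome-encoded.

    A pair is plasmid-encoded only when *every* REase annotation for the site
    lies on a plasmid; a mixed or chromosomal system counts as
    chromosome-encoded.  Returns the records with a ``replicon_kind_of_system``
    column added.
    """
    by_org = {g.organism_id: g for g in genomes}
    labels = []
    for row in actual.records.itertuples(index=False):
        genome = by_org[row.organism_id]
        kinds = _rease_kinds(genome, row.site_word)
        if not kinds:
            raise ValueError(
                f"no REase annotation for pair ({row.site_word}, {row.organism_id})"
            )
        labels.append("plasmid" if all(k == "plasmid" for k in kinds) else "chromosome")
    out = actual.records.copy()
    out["replicon_kind_of_system"] = labels
    return out


def classify_prevalence(n_with: int, n_total: int) -> str:
    """Prevalence class of a system within one species.

    rare: < 25 % of strains carry it; widespread: > 75 %; intermediate
    otherwise; unclassified when the species has fewer than five strains.
    """
    if n_total <= 0:
        raise ValueError("species must have at least one strain")
    if n_total < 5:
        return "unclassified"
    share = n_with / n_total
    if share < 0.25:
        return "rare"
    if share > 0.75:
        return "widespread"
    return "intermediate"


def prevalence_classes(actual: PairDataset, genomes: list[Genome]) -> pd.DataFrame:
    """Attach a ``prevalence_class`` column to the actual pairs.

    Prevalence is computed per (species, site word): the share of the
    species' strains that carry an REase annotation for that word (same-word
    matching as the proxy for same specificity).
    """
    strains_per_species: dict[str, set[str]] = {}
    carriers: dict[tuple[str, str], set[str]] = {}
    for g in genomes:
        strains_per_species.setdefault(g.species, set()).add(g.organism_id)
        for ann in g.rease_annotations():
            word = parse_site(ann.site_word).word
            carriers.setdefault((g.species, word), set()).add(g.organism_id)
    by_org_species = {g.organism_id: g.species for g in genomes}
    labels = []
    for row in actual.records.itertuples(index=False):
        species = by_org_species[row.organism_id]
        n_total = len(strains_per_species[species])
        n_with = len(carriers.get((species, row.site_word), set()))
        labels.append(classify_prevalence(n_with, n_total))
    out = actual.records.copy()
    out["prevalence_class"] = labels
    return out


def assign_alien_scores(
    genome: Genome,
    fragments: dict[str, list[AlienFragment]] | list[AlienFragment],
    threshold: float,
) -> pd.DataFrame:
    """Alien score per actual site word of one genome.

    Each REase gene takes the maximal score among fragments overlapping it
    (>= 1 shared base, same replicon), or 0 when no predicted fragment covers
    it.  A site recognised by several REases takes the *minimum* over its
    genes — one resident copy is enough to date the system.  The
    score/threshold ratio is emitted alongside for binned reporting.

    Returns columns: organism_id, site_word, alien_score, alien_ratio.
    """
    if threshold <= 0:
        raise ValueError("alien score threshold must be positive")
    if isinstance(fragments, list):
        by_rep: dict[str, list[AlienFragment]] = {}
        for f in fragments:
            by_rep.setdefault(f.replicon_id, []).append(f)
        fragments = by_rep
    gene_scores: dict[str, list[float]] = {}
    for ann in genome.rease_annotations():
        word = parse_site(ann.site_word).word
        score = 0.0
        for frag in fragments.get(ann.replicon_id, []):
            if frag.overlaps(ann.gene_start, ann.gene_end):
                score = max(score, frag.score)
        gene_scores.setdefault(word, []).append(score)
    rows = [
        {
            "organism_id": genome.organism_id,
            "site_word": word,
            "alien_score": min(scores),
            "alien_ratio": min(scores) / threshold,
        }
        for word, scores in sorted(gene_scores.items())
    ]
    return pd.DataFrame(rows, columns=["organism_id", "site_word", "alien_score", "alien_ratio"])


def alien_ratio_bin(ratio: float, edges=DEFAULT_RATIO_BINS) -> str:
    """Report bin for a score/threshold ratio: NP (0), (0,1], (1,2], >2 by default."""
    if ratio == 0:
        return "NP"
    lo = edges[0]
    for hi in edges[1:]:
        if lo < ratio <= hi:
            return f"({lo:g},{hi:g}]"
        lo = hi
    return f">{edges[-1]:g}"


def trace_groups(control: PairDataset, genomes: list[Genome]) -> pd.DataFrame:
    """Label each control pair by where the system is actually encoded.

    ``actual``: this genome encodes an REase for the word; ``species_trace``:
    it does not, but another strain of the same species does; ``genus_trace``:
    no strain of the species does, but another species of the genus does;
    ``background``: none of the above.  The labels partition the control set.
    """
    species_words: dict[str, set[str]] = {}
    genus_species_words: dict[str, dict[str, set[str]]] = {}
    actual_keys: set[tuple[str, str]] = set()
    for g in genomes:
        if not g.species or not g.genus:
            raise ValueError(f"genome {g.organism_id} lacks taxonomy labels")
        words = {parse_site(a.site_word).word for a in g.rease_annotations()}
        for w in words:
            actual_keys.add((g.organism_id, w))
            species_words.setdefault(g.species, set()).add(w)
            genus_species_words.setdefault(g.genus, {}).setdefault(g.species, set()).add(w)
    by_org = {g.organism_id: g for g in genomes}
    labels = []
    for row in control.records.itertuples(index=False):
        g = by_org[row.organism_id]
        w = row.site_word
        if (g.organism_id, w) in actual_keys:
            labels.append("actual")
        elif w in species_words.get(g.species, set()):
            labels.append("species_trace")
        elif any(
            w in words
            for sp, words in genus_species_words.get(g.genus, {}).items()
            if sp != g.species
        ):
            labels.append("genus_trace")
        else:
            labels.append("background")
    out = control.records.copy()
    out["trace_group"] = labels
    return out
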