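"""Named site-genome pair datasets.

The analysis contrasts the *actual* pairs — (site, genome) where the genome
encodes a restriction endonuclease recognising the site — against control
cohorts built from the same catalogue and genome collection:

* ``prokaryotic_control``: the full catalogue × genome cross product, of which
  the actual pairs are a subset;
* ``no_rm_control``: the control restricted to genomes with no R-M annotation
  at all (genomes whose lineage presumably never carried the systems);
* ``experimentally_proven``: the subset of actual pairs backed either by a
  gold-standard enzyme annotation or by a measured site methylation level
  strictly above 50 %;
* ``viral_control``: the same cross-product construction applied to a
  collection of (eukaryotic) viral genomes that never meet R-M systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contrast import ThresholdConfig, contrast_table
from .genomes import Genome
from .sites import SiteCatalogue, parse_site

__all__ = [
    "PairDataset",
    "build_control_pairs",
    "build_actual_pairs",
    "build_no_rm_subset",
    "mark_experimentally_proven",
]

DATASET_NAMES = (
    "actual",
    "experimentally_proven",
    "prokaryotic_control",
    "viral_control",
    "no_rm_control",
)


@dataclass
class PairDataset:
    """A named collection of contrast records with grouping columns."""

    name: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.name not in DATASET_NAMES:
            raise ValueError(f"unknown dataset name {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.records["organism_id"], self.records["site_word"]))

    def subset(self, mask, name: str | None = None) -> "PairDataset":
        return PairDataset(name or self.name, self.records[mask].reset_index(drop=True))


def _catalogue_types(catalogue: SiteCatalogue) -> dict[str, str]:
    return {w: catalogue.sites[w].rm_type.value for w in catalogue.words()}


def build_control_pairs(
    catalogue: SiteCatalogue,
    genomes: list[Genome],
    cfg: ThresholdConfig = ThresholdConfig(),
    name: str = "prokaryotic_control",
    with_markov: bool = False,
) -> PairDataset:
    """All catalogue-word × genome pairs (prokaryotic or viral control)."""
    records = contrast_table(
        genomes,
        catalogue.words(),
        cfg,
        with_markov=with_markov,
        rm_types=_catalogue_types(catalogue),
    )
    return PairDataset(name, records)


def build_actual_pairs(
    catalogue: SiteCatalogue,
    genomes: list[Genome],
    cfg: ThresholdConfig = ThresholdConfig(),
    control: PairDataset | None = None,
) -> PairDataset:
    """Pairs where the genome encodes a REase recognising the site.

    One record per distinct (site, genome) even when several REases recognise
    the word.  If a pre-computed control is given, its records are reused so
    that actual ⊆ control holds row-for-row; words annotated in a genome but
    missing from the catalogue are still computed (and logged) ad hoc.
    """
    wanted: set[tuple[str, str]] = set()
    extra_words: dict[str, list[Genome]] = {}
    for g in genomes:
        for ann in g.rease_annotations():
            word = parse_site(ann.site_word).word
            wanted.add((g.organism_id, word))
            if word not in catalogue:
                extra_words.setdefault(word, []).append(g)
    rows = []
    if control is not None:
        ctl = control.records
        keyed = ctl.set_index(["organism_id", "site_word"], drop=False)
        for key in sorted(wanted):
            if key in keyed.index:
                rows.append(keyed.loc[key])
    if rows or control is not None:
        records = pd.DataFrame(rows).reset_index(drop=True)
        missing = wanted - set(zip(records.get("organism_id", []), records.get("site_word", [])))
    else:
        records = pd.DataFrame()
        missing = wanted
    if missing:
        import logging

        by_org = {g.organism_id: g for g in genomes}
        words_by_org: dict[str, list[str]] = {}
        for oid, word in missing:
            if word not in catalogue:
                logging.getLogger(__name__).warning(
                    "annotated site %s absent from catalogue; computed ad hoc", word
                )
            words_by_org.setdefault(oid, []).append(word)
        extra_frames = [
            contrast_table([by_org[oid]], words, cfg, rm_types=_catalogue_types(catalogue))
            for oid, words in sorted(words_by_org.items())
        ]
        records = pd.concat([records, *extra_frames], ignore_index=True)
    if len(records):
        records = records.sort_values(["organism_id", "site_word"]).reset_index(drop=True)
    return PairDataset("actual", records)


def build_no_rm_subset(control: PairDataset, genomes: list[Genome]) -> PairDataset:
    """Restrict a control dataset to genomes with an empty annotation list."""
    no_rm = {g.organism_id for g in genomes if not g.rm_annotations}
    mask = control.records["organism_id"].isin(no_rm)
    return control.subset(mask, name="no_rm_control")


def mark_experimentally_proven(
    actual: PairDataset,
    genomes: list[Genome],
    methylation_calls: pd.DataFrame | None = None,
) -> PairDataset:
    """Subset of actual pairs with experimental support.

    A pair qualifies if (1) some REase annotation for the word carries the
    gold-standard flag, or (2) a methylation call for (site, genome) reports a
    methylated fraction strictly above 0.5.  ``methylation_calls`` columns:
    organism_id, site_word, fraction_methylated in [0, 1].
    """
    proven: set[tuple[str, str]] = set()
    for g in genomes:
        for ann in g.rease_annotations():
            if ann.experimentally_proven:
                proven.add((g.organism_id, parse_site(ann.site_word).word))
    if methylation_calls is not None and len(methylation_calls):
        frac = methylation_calls["fraction_methylated"].astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("methylation fraction outside [0, 1]")
        for row, f in zip(methylation_calls.itertuples(index=False), frac):
            if f > 0.5:
                proven.add((row.organism_id, row.site_word.upper()))
    keys = list(zip(actual.records["organism_id"], actual.records["site_word"]))
    mask = pd.Series([k in proven for k in keys], index=actual.records.index)
    return actual.subset(mask, name="experimentally_proven")
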