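"""Top-level modelling interface: SiteAvoidance -> SiteAvoidanceResults.

``SiteAvoidance`` bundles a genome collection with a recognition-site
catalogue and the classification thresholds; ``fit()`` computes the full
contrast table (observed counts, Karlin and optionally Markov expectations,
Kr/Mr, reliability filter, representation classes) for the control cross
product, carves out the named pair datasets, and returns a
``SiteAvoidanceResults`` object that exposes the cohort summaries, matched
thresholds, lifespan stratifications and trace analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohorts, lifespan
from .contrast import ThresholdConfig, estimate_kr_sd_by_complement
from .datasets import (
    PairDataset,
    build_actual_pairs,
    build_control_pairs,
    build_no_rm_subset,
    mark_experimentally_proven,
)
from .genomes import Genome
from .sites import SiteCatalogue

__all__ = ["SiteAvoidance", "SiteAvoidanceResults"]


@dataclass
class SiteAvoidance:
    """Site-avoidance analysis of a genome collection against a site catalogue."""

    genomes: list[Genome]
    catalogue: SiteCatalogue
    config: ThresholdConfig = field(default_factory=ThresholdConfig)
    with_markov: bool = False
    methylation_calls: pd.DataFrame | None = None
    alien_fragments: dict[str, list[lifespan.AlienFragment]] | None = None
    alien_threshold: float | None = None

    @classmethod
    def from_files(
        cls,
        fasta_paths,
        metadata_path,
        catalogue_path,
        annotations_path=None,
        methylation_path=None,
        alien_path=None,
        alien_threshold: float | None = None,
        config: ThresholdConfig | None = None,
        with_markov: bool = False,
    ) -> "SiteAvoidance":
        """Build the model from the on-disk formats (FASTA + TSV tables)."""
        from .genomes import read_genome_collection
        from .sites import read_catalogue

        genomes = read_genome_collection(fasta_paths, metadata_path, annotations_path)
        catalogue = read_catalogue(catalogue_path)
        methylation = (
            pd.read_csv(methylation_path, sep="\t") if methylation_path else None
        )
        fragments = lifespan.read_alien_fragments(alien_path) if alien_path else None
        return cls(
            genomes=genomes,
            catalogue=catalogue,
            config=config or ThresholdConfig(),
            with_markov=with_markov,
            methylation_calls=methylation,
            alien_fragments=fragments,
            alien_threshold=alien_threshold,
        )

    def fit(self) -> "SiteAvoidanceResults":
        """Compute the contrast tables and assemble the results object."""
        control = build_control_pairs(
            self.catalogue, self.genomes, self.config, with_markov=self.with_markov
        )
        actual = build_actual_pairs(
            self.catalogue, self.genomes, self.config, control=control
        )
        no_rm = build_no_rm_subset(control, self.genomes)
        proven = mark_experimentally_proven(actual, self.genomes, self.methylation_calls)
        return SiteAvoidanceResults(
            model=self,
            control=control,
            actual=actual,
            no_rm=no_rm,
            experimentally_proven=proven,
        )


@dataclass
class SiteAvoidanceResults:
    """Fitted contrast tables plus the cohort, lifespan and trace summaries."""

    model: SiteAvoidance
    control: PairDataset
    actual: PairDataset
    no_rm: PairDataset
    experimentally_proven: PairDataset

    @property
    def config(self) -> ThresholdConfig:
        return self.model.config

    def _passing(self, ds: PairDataset) -> pd.DataFrame:
        rec = ds.records
        return rec[rec["passes_min_expected"] & rec["kr"].notna()]

    # ------------------------------------------------------------------ cohorts
    def fraction_table(self, dataset: str = "actual", group_by="rm_type"):
        ds: PairDataset = getattr(self, dataset)
        return cohorts.fraction_table(ds.records, group_by, self.config)

    def type_summary(self) -> pd.DataFrame:
        """Under/normal/over fractions per R-M type across all datasets."""
        frames = []
        for name in ("actual", "experimentally_proven", "control", "no_rm"):
            ds: PairDataset = getattr(self, name)
            if not len(ds.records):
                continue
            tab = cohorts.fraction_table(ds.records, "rm_type", self.config).table
            tab.insert(0, "dataset", ds.name)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def matched_thresholds(self, f: float) -> pd.DataFrame:
        """Palindrome and non-palindrome Kr thresholds matched at control FPR f."""
        rows = []
        ctl = self._passing(self.control)
        for pal, label in ((True, "palindromic"), (False, "non_palindromic")):
            vals = ctl.loc[ctl["is_palindromic"] == pal, "kr"]
            if len(vals):
                rows.append(
                    {"stratum": label, "f": f,
                     "threshold": cohorts.matched_threshold(vals, f)}
                )
        return pd.DataFrame(rows)

    def excess_avoidance(self, f_grid, palindromic: bool | None = None) -> pd.DataFrame:
        """Y(f) curve of avoidance attributable to R-M systems."""
        act = self._passing(self.actual)
        ctl = self._passing(self.control)
        if palindromic is not None:
            act = act[act["is_palindromic"] == palindromic]
            ctl = ctl[ctl["is_palindromic"] == palindromic]
        return cohorts.excess_avoidance_curve(act["kr"], ctl["kr"], f_grid)

    def kr_histogram(self, dataset: str = "actual", bins: int = 41) -> pd.DataFrame:
        ds: PairDataset = getattr(self, dataset)
        return cohorts.kr_histogram(self._passing(ds)["kr"], bins=bins)

    def sd_by_complement(self, bin_edges=None) -> pd.DataFrame:
        """Kr noise vs expected count from complementary-site pairs (control)."""
        if bin_edges is None:
            bin_edges = np.arange(6.5, 60.5, 1.0)
        rec = self.control.records
        return estimate_kr_sd_by_complement(rec[rec["kr"].notna()], bin_edges)

    # ----------------------------------------------------------------- lifespan
    def replicon_split(self) -> pd.DataFrame:
        return lifespan.split_by_replicon(self.actual, self.model.genomes)

    def prevalence(self) -> pd.DataFrame:
        return lifespan.prevalence_classes(self.actual, self.model.genomes)

    def lifespan_summary(self) -> pd.DataFrame:
        """Fraction table over both lifespan proxies (replicon, prevalence)."""
        rep = self.replicon_split()
        prev = lifespan.prevalence_classes(self.actual, self.model.genomes)
        rep["prevalence_class"] = prev["prevalence_class"]
        frames = []
        for col in ("replicon_kind_of_system", "prevalence_class"):
            tab = cohorts.fraction_table(rep, col, self.config).table
            tab = tab.rename(columns={col: "stratum"})
            tab.insert(0, "proxy", col)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def alien_scores(self) -> pd.DataFrame:
        """Alien score/ratio per actual pair, with report bins."""
        if self.model.alien_fragments is None or self.model.alien_threshold is None:
            raise ValueError("model was built without alien fragments / threshold")
        frames = [
            lifespan.assign_alien_scores(
                g, self.model.alien_fragments, self.model.alien_threshold
            )
            for g in self.model.genomes
            if g.rease_annotations()
        ]
        scores = pd.concat(frames, ignore_index=True)
        merged = self.actual.records.merge(
            scores, on=["organism_id", "site_word"], how="left"
        )
        merged["alien_score"] = merged["alien_score"].fillna(0.0)
        merged["alien_ratio"] = merged["alien_ratio"].fillna(0.0)
        merged["alien_bin"] = [
            lifespan.alien_ratio_bin(r) for r in merged["alien_ratio"]
        ]
        return merged

    def trace_groups(self) -> pd.DataFrame:
        return lifespan.trace_groups(self.control, self.model.genomes)

    def trace_summary(self) -> pd.DataFrame:
        traced = self.trace_groups()
        tab = cohorts.fraction_table(traced, "trace_group", self.config).table
        return tab

    # ------------------------------------------------------------------ summary
    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        cfg = self.config
        lines = [
            "Site-avoidance analysis",
            "=" * 60,
            f"genomes: {len(self.model.genomes)}   catalogue sites: {len(self.model.catalogue)}",
            f"thresholds: under Kr <= {cfg.t_under}, over Kr >= {cfg.t_over}, "
            f"min expected {cfg.min_expected}",
            "",
            "Pairs per dataset (passing the expected-count filter / total):",
        ]
        for name in ("actual", "experimentally_proven", "control", "no_rm"):
            ds: PairDataset = getattr(self, name)
            lines.append(f"  {ds.name:22s} {len(self._passing(ds)):6d} / {len(ds):6d}")
        lines.append("")
        lines.append("Representation fractions by R-M type and dataset:")
        tab = self.type_summary()
        cols = ["dataset", "rm_type", "n_pairs", "fraction_under", "fraction_over"]
        lines.append(tab[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
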