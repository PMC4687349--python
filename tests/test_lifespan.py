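"""Lifespan proxies: replicon split, prevalence classes, alien scores, traces."""

import numpy as np
import pandas as pd
import pytest

from rmavoid.datasets import PairDataset, build_actual_pairs, build_control_pairs
from rmavoid.genomes import Genome, Replicon, RMAnnotation
from rmavoid.lifespan import (
    AlienFragment,
    alien_ratio_bin,
    assign_alien_scores,
    classify_prevalence,
    split_by_replicon,
    trace_groups,
)
from rmavoid.sites import RMType, SiteCatalogue
from rmavoid.synthetic import simulate_replicon


def genome_with(organism_id, species, genus, anns, with_plasmid=True, seed=0):
    reps = [Replicon("chr", simulate_replicon(20_000, seed=seed))]
    if with_plasmid:
        reps.append(Replicon("pls", simulate_replicon(5_000, seed=seed + 1), "plasmid"))
    return Genome(organism_id, species, genus, reps, anns)


def ann(word, replicon_id, start=100, end=1000, rease=True):
    return RMAnnotation(word, "II_orthodox", replicon_id, start, end, encodes_rease=rease)


def pairs_for(genomes):
    rows = [
        {"organism_id": g.organism_id, "site_word": w, "kr": 1.0,
         "passes_min_expected": True, "expected_karlin": 50.0}
        for g in genomes
        for w in sorted({a.site_word for a in g.rease_annotations()})
    ]
    return PairDataset("actual", pd.DataFrame(rows))


def test_split_by_replicon_rules():
    g1 = genome_with("o1", "sp", "gn", [ann("GATC", "pls")], seed=10)
    g2 = genome_with("o2", "sp", "gn", [ann("GATC", "pls"), ann("GATC", "chr")], seed=12)
    g3 = genome_with("o3", "sp", "gn", [ann("GATC", "chr")], with_plasmid=False, seed=14)
    out = split_by_replicon(pairs_for([g1, g2, g3]), [g1, g2, g3])
    labels = dict(zip(out["organism_id"], out["replicon_kind_of_system"]))
    assert labels == {"o1": "plasmid", "o2": "chromosome", "o3": "chromosome"}


@pytest.mark.parametrize(
    "n_with, n_total, expected",
    [
        (1, 8, "rare"),          # 12.5 % < 25 %
        (7, 8, "widespread"),    # 87.5 % > 75 %
        (3, 8, "intermediate"),
        (2, 4, "unclassified"),  # species below the five-strain minimum
        (2, 8, "intermediate"),  # exactly 25 % is not *less than* 25 %
        (6, 8, "intermediate"),  # exactly 75 % is not *more than* 75 %
    ],
)
def test_classify_prevalence(n_with, n_total, expected):
    assert classify_prevalence(n_with, n_total) == expected


def test_classify_prevalence_rejects_zero_strains():
    with pytest.raises(ValueError):
        classify_prevalence(0, 0)


def test_alien_score_rules():
    g = genome_with(
        "o1", "sp", "gn",
        [ann("GATC", "chr", 100, 1000), ann("GATC", "chr", 5000, 6000),
         ann("GAATTC", "chr", 9000, 9900)],
        with_plasmid=False, seed=20,
    )
    frags = [AlienFragment("chr", 500, 2000, 12.0)]
    out = assign_alien_scores(g, frags, threshold=10.0)
    scores = dict(zip(out["site_word"], out["alien_score"]))
    # two REases for GATC with gene scores {12, 0} -> pair takes the minimum
    assert scores["GATC"] == 0.0
    assert scores["GAATTC"] == 0.0  # no overlapping fragment
    ratios = dict(zip(out["site_word"], out["alien_ratio"]))
    assert ratios["GATC"] == 0.0

    single = assign_alien_scores(
        genome_with("o2", "sp", "gn", [ann("GATC", "chr", 100, 1000)],
                    with_plasmid=False, seed=21),
        frags, threshold=10.0,
    )
    assert single["alien_score"].iloc[0] == 12.0
    assert single["alien_ratio"].iloc[0] == pytest.approx(1.2)

    with pytest.raises(ValueError):
        assign_alien_scores(g, frags, threshold=0.0)


def test_alien_score_invariant_to_fragment_order_and_min_rule_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n_genes = int(rng.integers(1, 4))
        genes = []
        for _k in range(n_genes):
            s = int(rng.integers(1, 15_000))
            genes.append((s, s + int(rng.integers(50, 2000))))
        n_frags = int(rng.integers(0, 4))
        frags = []
        for _k in range(n_frags):
            s = int(rng.integers(1, 15_000))
            frags.append(
                AlienFragment("chr", s, s + int(rng.integers(100, 5000)),
                              float(rng.uniform(0, 30)))
            )
        g = Genome(
            "o", "sp", "gn", [Replicon("chr", "ACGT" * 5000)],
            [ann("GATC", "chr", s, e) for s, e in genes],
        )
        out = assign_alien_scores(g, frags, threshold=10.0)
        shuffled = list(frags)
        rng.shuffle(shuffled)
        out2 = assign_alien_scores(g, shuffled, threshold=10.0)
        assert out.equals(out2)
        # brute force: per gene the max overlapping score, per site the min over genes
        per_gene = [
            max([f.score for f in frags if f.start <= e and s <= f.end] or [0.0])
            for s, e in genes
        ]
        assert out["alien_score"].iloc[0] == pytest.approx(min(per_gene))
        assert out["alien_score"].iloc[0] <= min(per_gene) + 1e-12


def test_alien_ratio_bins():
    assert alien_ratio_bin(0.0) == "NP"
    assert alien_ratio_bin(0.4) == "(0,1]"
    assert alien_ratio_bin(1.0) == "(0,1]"
    assert alien_ratio_bin(1.7) == "(1,2]"
    assert alien_ratio_bin(2.5) == ">2"


def test_trace_groups_partition_and_rules():
    cat = SiteCatalogue()
    for w in ("GATC", "GAATTC", "CCGG"):
        cat.add(w, RMType.II_orthodox)
    genomes = [
        genome_with("a1", "spA", "gnX", [ann("GATC", "chr")], False, seed=30),
        genome_with("a2", "spA", "gnX", [], False, seed=31),          # sister strain
        genome_with("b1", "spB", "gnX", [], False, seed=32),          # same genus
        genome_with("c1", "spC", "gnY", [ann("GAATTC", "chr")], False, seed=33),
        genome_with("c2", "spC", "gnY", [], False, seed=34),
    ]
    control = build_control_pairs(cat, genomes)
    out = trace_groups(control, genomes)
    label = {
        (r.organism_id, r.site_word): r.trace_group
        for r in out.itertuples(index=False)
    }
    assert label[("a1", "GATC")] == "actual"
    assert label[("a2", "GATC")] == "species_trace"
    assert label[("b1", "GATC")] == "genus_trace"
    assert label[("c1", "GATC")] == "background"  # other genus only
    assert label[("c2", "GAATTC")] == "species_trace"
    assert label[("a1", "CCGG")] == "background"
    # the labels partition the control dataset
    assert len(out) == len(control)
    assert out["trace_group"].notna().all()


def test_trace_groups_requires_taxonomy():
    g = Genome("o", "", "gn", [Replicon("chr", "ACGTACGT")])
    cat = SiteCatalogue()
    cat.add("GATC", RMType.II_orthodox)
    control = build_control_pairs(cat, [g])
    with pytest.raises(ValueError, match="taxonomy"):
        trace_groups(control, [g])
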