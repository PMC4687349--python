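"""Seeded synthetic genome collections with planted site avoidance.

The generator emulates the statistical structure the analysis assumes in real
data: Markov-generated replicons of configurable composition, a species/genus
strain layout, R-M annotations on chromosomes or plasmids, imposed depletion
of chosen sites (the selection signature the pipeline is built to detect),
gold-standard flags, methylation calls, and alien-fragment tables with scores
and a threshold.  Every draw is seeded, and one SimulationSpec regenerates a
byte-identical fixture set.

Depletion destroys matches of a site by re-drawing one position of each
selected window until the window no longer matches, which preserves the
background composition; matches created incidentally elsewhere are tolerated
as realistic noise.  :func:`impose_site_depletion` destroys a fixed fraction
of the current matches; :func:`impose_avoidance` calibrates the destruction
so the planted signal has a known depth on the Kr scale (see its docstring
for why the two differ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomes import Genome, RMAnnotation, Replicon, match_positions, word_masks
from .lifespan import AlienFragment
from .sites import IUPAC_SETS, RMType, SiteCatalogue

__all__ = [
    "SpeciesPlan",
    "SystemPlan",
    "DepletionPlan",
    "SimulationSpec",
    "simulate_replicon",
    "impose_site_depletion",
    "impose_avoidance",
    "FixtureCollection",
    "build_fixture_collection",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def simulate_replicon(
    length: int,
    seed: int,
    order: int = 0,
    letter_freqs=None,
    transition=None,
) -> str:
    """Draw a DNA sequence from a seeded order-0/1/2 Markov chain.

    ``letter_freqs`` is the A/C/G/T distribution (order 0, and the initial
    state for higher orders); ``transition`` is a (4**order, 4) row-stochastic
    matrix conditioning each base on the previous ``order`` bases, contexts
    indexed base-4 with A=0, C=1, G=2, T=3.
    """
    if length <= 0:
        raise ValueError("replicon length must be positive")
    if order not in (0, 1, 2):
        raise ValueError("markov order must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    p0 = np.full(4, 0.25) if letter_freqs is None else np.asarray(letter_freqs, float)
    if p0.shape != (4,) or (p0 < 0).any() or not np.isclose(p0.sum(), 1.0):
        raise ValueError("letter frequencies must be 4 non-negative values summing to 1")
    if order == 0:
        idx = rng.choice(4, size=length, p=p0)
        return _BASES[idx].tobytes().decode("ascii")
    trans = np.asarray(transition, dtype=float)
    if trans.shape != (4**order, 4):
        raise ValueError(f"transition matrix must be ({4 ** order}, 4)")
    if (trans < 0).any() or not np.allclose(trans.sum(axis=1), 1.0):
        raise ValueError("transition rows must be probability distributions")
    cum = np.cumsum(trans, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.choice(4, size=order, p=p0)
    u = rng.random(length)
    ctx = 0
    for i in range(order):
        ctx = ctx * 4 + out[i]
    mod = 4 ** (order - 1)
    for i in range(order, length):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = (ctx % mod) * 4 + b if order > 1 else b
    return _BASES[out].tobytes().decode("ascii")


def impose_site_depletion(sequence: str, site_word: str, d: float, seed: int) -> str:
    """Destroy a seeded random fraction ``d`` of the site's current matches.

    Each selected window gets one random position re-drawn (uniformly over
    A/C/G/T) until that window no longer matches the site.  Overlapping
    matches may be destroyed collaterally; new matches created elsewhere are
    left alone.  d=0 returns the sequence unchanged; d=1 leaves no original
    match intact.
    """
    if not 0 <= d <= 1:
        raise ValueError("depletion fraction d must lie in [0, 1]")
    if d == 0:
        return sequence
    masks = word_masks(site_word)
    L = masks.size
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    from .genomes import encode_sequence  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    enc = encode_sequence(sequence)
    positions = match_positions(enc, masks)
    if positions.size == 0:
        warnings.warn(f"site {site_word} absent; depletion d={d} is a no-op")
        return sequence
    n_destroy = int(round(d * positions.size))
    chosen = rng.choice(positions, size=n_destroy, replace=False)
    allowed = {
        j: [b for b in "ACGT" if b not in IUPAC_SETS[site_word.upper()[j]]]
        for j in range(L)
    }
    mutable = [j for j, alts in allowed.items() if alts]
    if not mutable:
        raise ValueError(f"site {site_word} matches every base at every position")
    for start in np.sort(chosen):
        window = arr[start : start + L]
        enc_win = encode_sequence(window.tobytes().decode("ascii"))
        if match_positions(enc_win, masks).size == 0:
            continue  # already destroyed by an overlapping edit
        j = int(rng.choice(mutable))
        alts = allowed[j]
        arr[start + j] = ord(alts[int(rng.integers(len(alts)))])
    return arr.tobytes().decode("ascii")


def impose_avoidance(sequence: str, site_word: str, d: float, seed: int) -> str:
    """Plant avoidance of depth ``d`` on the Kr scale: deplete until Kr ≈ 1−d.

    Destroying a site instance also removes its subword occurrences, so the
    Karlin expectation shrinks alongside the observed count and destroying a
    fraction d of matches realises a Kr *above* 1−d.  Planted ground truth
    must live on the scale the study measures, so this wrapper destroys
    matches in calibrated batches (via :func:`impose_site_depletion`) until
    the sequence's own Kr reaches the target ``1 − d``.
    """
    if not 0 <= d <= 1:
        raise ValueError("avoidance depth d must lie in [0, 1]")
    if d == 0:
        return sequence
    from .contrast import expected_karlin
    from .genomes import Genome, Replicon, count_occurrences

    target_ratio = 1.0 - d
    rng = np.random.default_rng(seed)
    seq = sequence
    for _ in range(12):
        g = Genome("_", "_", "_", [Replicon("_", seq)])
        e = expected_karlin(g, site_word)
        obs = count_occurrences(g, site_word).observed
        if e is None or obs == 0:
            break
        target = target_ratio * e
        if obs <= target + max(1.0, 0.005 * e):
            break
        frac = min(1.0, (obs - target) / obs)
        seq = impose_site_depletion(
            seq, site_word, frac, int(rng.integers(2**31))
        )
    return seq


@dataclass(frozen=True)
class SpeciesPlan:
    """One species in the collection: its genus and how many strains it has."""

    species: str
    genus: str
    n_strains: int

    def organism_ids(self) -> list[str]:
        return [f"{self.species}_s{i + 1}" for i in range(self.n_strains)]


@dataclass(frozen=True)
class SystemPlan:
    """One planted R-M system: site, type, hosts, replicon and evidence flags.

    ``alien_score`` > 0 plants a predictor fragment covering the REase gene
    with that score (a recently transferred locus); 0 leaves the gene in
    background composition.
    """

    site_word: str
    rm_type: str = "II_orthodox"
    hosts: tuple[str, ...] = ()
    replicon_kind: str = "chromosome"
    encodes_rease: bool = True
    gold_standard: bool = False
    methylation: float | None = None
    alien_score: float = 0.0


@dataclass(frozen=True)
class DepletionPlan:
    """Imposed avoidance: destroy fraction ``d`` of a site in chosen organisms."""

    site_word: str
    organisms: tuple[str, ...]
    d: float


@dataclass
class SimulationSpec:
    """Full recipe for one synthetic collection; the seed makes it reproducible."""

    seed: int = 0
    chromosome_length: int = 100_000
    plasmid_length: int = 20_000
    markov_order: int = 0
    letter_freqs: tuple[float, float, float, float] | None = None
    transition: list | None = None
    species: list[SpeciesPlan] = field(default_factory=list)
    systems: list[SystemPlan] = field(default_factory=list)
    depletions: list[DepletionPlan] = field(default_factory=list)
    extra_catalogue_words: list[str] = field(default_factory=list)
    alien_threshold: float = 10.0

    def organism_ids(self) -> list[str]:
        return [oid for sp in self.species for oid in sp.organism_ids()]

    def validate(self) -> None:
        ids = set(self.organism_ids())
        if len(ids) != len(self.organism_ids()):
            raise ValueError("duplicate organism ids in species plan")
        for sys_plan in self.systems:
            for host in sys_plan.hosts:
                if host not in ids:
                    raise ValueError(f"system host {host!r} is not a planned organism")
        for dep in self.depletions:
            if not 0 <= dep.d <= 1:
                raise ValueError("depletion d must lie in [0, 1]")
            for oid in dep.organisms:
                if oid not in ids:
                    raise ValueError(f"depletion target {oid!r} is not a planned organism")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=raw.get("seed", 0),
            chromosome_length=raw.get("chromosome_length", 100_000),
            plasmid_length=raw.get("plasmid_length", 20_000),
            markov_order=raw.get("markov_order", 0),
            letter_freqs=tuple(raw["letter_freqs"]) if "letter_freqs" in raw else None,
            transition=raw.get("transition"),
            species=[SpeciesPlan(**s) for s in raw.get("species", [])],
            systems=[SystemPlan(**{**s, "hosts": tuple(s.get("hosts", ()))})
                     for s in raw.get("systems", [])],
            depletions=[DepletionPlan(**{**d, "organisms": tuple(d["organisms"])})
                        for d in raw.get("depletions", [])],
            extra_catalogue_words=list(raw.get("extra_catalogue_words", [])),
            alien_threshold=raw.get("alien_threshold", 10.0),
        )


@dataclass
class FixtureCollection:
    """In-memory result of a simulation: genomes plus all side tables."""

    genomes: list[Genome]
    catalogue: SiteCatalogue
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    methylation: pd.DataFrame
    alien_fragments: dict[str, list[AlienFragment]]
    alien_threshold: float

    def write(self, outdir) -> None:
        """Emit the pipeline's file formats (FASTA + TSVs) into ``outdir``."""
        from .sites import write_catalogue

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genomes.fasta", "w") as fh:
            for g in self.genomes:
                for rep in g.replicons:
                    fh.write(f">{rep.id}\n")
                    for i in range(0, len(rep.sequence), 80):
                        fh.write(rep.sequence[i : i + 80] + "\n")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.methylation.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
        write_catalogue(self.catalogue, outdir / "catalogue.tsv")
        frag_rows = [
            {"replicon_id": f.replicon_id, "start": f.start, "end": f.end, "score": f.score}
            for frags in self.alien_fragments.values()
            for f in frags
        ]
        pd.DataFrame(
            frag_rows, columns=["replicon_id", "start", "end", "score"]
        ).to_csv(outdir / "alien_fragments.tsv", sep="\t", index=False)
        with open(outdir / "alien_threshold.txt", "w") as fh:
            fh.write(f"{self.alien_threshold}\n")


def default_simulation_spec(seed: int = 0) -> SimulationSpec:
    """The package's reference study conditions for end-to-end runs.

    Three species of two genera, six strains each (species with >= 5 strains
    so prevalence is classifiable), 100 kb chromosomes of uniform
    composition:

    * ``Aquickia alpha`` carries a widespread (5/6 strains), long-resident,
      chromosome-encoded system for the palindrome GGATCC whose site is
      planted at avoidance depth d = 0.6 in every carrier — and also in the
      sixth, annotation-free strain, the planted *lost system* whose trace
      the pipeline should pick up;
    * ``Aquickia beta`` (same genus) carries a rare (1/6 strains),
      plasmid-encoded, recently acquired system for GAATTC: undepleted and
      covered by a high-scoring alien fragment;
    * ``Borrelica gamma`` encodes no R-M system at all (the no-R-M control).

    Four undepleted, unannotated words pad the catalogue as compositional
    controls.  Gold-standard and methylation evidence mark two of the
    widespread pairs as experimentally proven.
    """
    sp_a = SpeciesPlan("Aquickia_alpha", "Aquickia", 6)
    sp_b = SpeciesPlan("Aquickia_beta", "Aquickia", 6)
    sp_c = SpeciesPlan("Borrelica_gamma", "Borrelica", 6)
    carriers = tuple(sp_a.organism_ids()[:5])
    return SimulationSpec(
        seed=seed,
        chromosome_length=200_000,
        plasmid_length=40_000,
        species=[sp_a, sp_b, sp_c],
        systems=[
            SystemPlan(
                "GGATCC",
                hosts=carriers,
                replicon_kind="chromosome",
                gold_standard=True,
            ),
            SystemPlan(
                "GAATTC",
                hosts=(sp_b.organism_ids()[0],),
                replicon_kind="plasmid",
                alien_score=25.0,
                methylation=0.8,
            ),
        ],
        depletions=[
            # widespread system depleted in carriers AND in the sixth,
            # annotation-free strain: the planted lost-system trace
            DepletionPlan("GGATCC", tuple(sp_a.organism_ids()), d=0.6),
        ],
        extra_catalogue_words=["GANTC", "CCGG", "GCGC", "CATATG"],
        alien_threshold=10.0,
    )


_GENE_LENGTH = 900


def build_fixture_collection(spec: SimulationSpec, outdir=None) -> FixtureCollection:
    """Realise a SimulationSpec into genomes, catalogue and side tables.

    Per-organism seeds are derived deterministically from the spec seed via
    numpy's SeedSequence spawning, so adding organisms does not reshuffle the
    sequences of existing ones.  When ``outdir`` is given the file set is also
    written (byte-identical across runs with the same spec).
    """
    spec.validate()
    root_ss = np.random.SeedSequence(spec.seed)
    org_ids = spec.organism_ids()
    org_seeds = {oid: ss for oid, ss in zip(org_ids, root_ss.spawn(len(org_ids)))}

    systems_by_host: dict[str, list[SystemPlan]] = {}
    for sys_plan in spec.systems:
        for host in sys_plan.hosts:
            systems_by_host.setdefault(host, []).append(sys_plan)
    depletions_by_org: dict[str, list[DepletionPlan]] = {}
    for dep in spec.depletions:
        for oid in dep.organisms:
            depletions_by_org.setdefault(oid, []).append(dep)

    genomes: list[Genome] = []
    meta_rows, ann_rows, meth_rows = [], [], []
    alien_fragments: dict[str, list[AlienFragment]] = {}

    for sp in spec.species:
        for oid in sp.organism_ids():
            child = org_seeds[oid].spawn(4)
            chrom_seed = int(child[0].generate_state(1)[0] % (2**31))
            plasmid_seed = int(child[1].generate_state(1)[0] % (2**31))
            chrom_seq = simulate_replicon(
                spec.chromosome_length, chrom_seed, spec.markov_order,
                spec.letter_freqs, spec.transition,
            )
            needs_plasmid = any(
                s.replicon_kind == "plasmid" for s in systems_by_host.get(oid, [])
            )
            plasmid_seq = (
                simulate_replicon(
                    spec.plasmid_length, plasmid_seed, spec.markov_order,
                    spec.letter_freqs, spec.transition,
                )
                if needs_plasmid
                else None
            )
            # planted avoidance acts on every replicon of the organism
            dep_ss = child[2].spawn(max(1, len(depletions_by_org.get(oid, []))))
            for dep, dss in zip(depletions_by_org.get(oid, []), dep_ss):
                dseeds = dss.spawn(2)
                s1 = int(dseeds[0].generate_state(1)[0] % (2**31))
                chrom_seq = impose_avoidance(chrom_seq, dep.site_word, dep.d, s1)
                if plasmid_seq is not None:
                    s2 = int(dseeds[1].generate_state(1)[0] % (2**31))
                    plasmid_seq = impose_avoidance(
                        plasmid_seq, dep.site_word, dep.d, s2
                    )
            replicons = [Replicon(f"{oid}_chr", chrom_seq, "chromosome")]
            meta_rows.append(
                {"organism_id": oid, "species": sp.species, "genus": sp.genus,
                 "replicon_id": f"{oid}_chr", "kind": "chromosome"}
            )
            if plasmid_seq is not None:
                replicons.append(Replicon(f"{oid}_pls", plasmid_seq, "plasmid"))
                meta_rows.append(
                    {"organism_id": oid, "species": sp.species, "genus": sp.genus,
                     "replicon_id": f"{oid}_pls", "kind": "plasmid"}
                )
            annotations = []
            for k, sys_plan in enumerate(systems_by_host.get(oid, [])):
                rep_id = f"{oid}_pls" if sys_plan.replicon_kind == "plasmid" else f"{oid}_chr"
                start = 1000 + 3000 * k
                end = start + _GENE_LENGTH - 1
                annotations.append(
                    RMAnnotation(
                        site_word=sys_plan.site_word.upper(),
                        rm_type=sys_plan.rm_type,
                        replicon_id=rep_id,
                        gene_start=start,
                        gene_end=end,
                        encodes_rease=sys_plan.encodes_rease,
                        experimentally_proven=sys_plan.gold_standard,
                    )
                )
                ann_rows.append(
                    {"organism_id": oid, "site_word": sys_plan.site_word.upper(),
                     "rm_type": sys_plan.rm_type, "replicon_id": rep_id,
                     "gene_start": start, "gene_end": end,
                     "encodes_rease": int(sys_plan.encodes_rease),
                     "experimentally_proven": int(sys_plan.gold_standard)}
                )
                if sys_plan.alien_score > 0:
                    frag = AlienFragment(
                        rep_id, max(1, start - 500), end + 500, sys_plan.alien_score
                    )
                    alien_fragments.setdefault(rep_id, []).append(frag)
                if sys_plan.methylation is not None:
                    meth_rows.append(
                        {"organism_id": oid, "site_word": sys_plan.site_word.upper(),
                         "fraction_methylated": sys_plan.methylation}
                    )
            genomes.append(
                Genome(organism_id=oid, species=sp.species, genus=sp.genus,
                       replicons=replicons, rm_annotations=annotations)
            )

    catalogue = SiteCatalogue()
    for sys_plan in spec.systems:
        catalogue.add(sys_plan.site_word, sys_plan.rm_type, provenance="simulated",
                      experimentally_proven=sys_plan.gold_standard)
    for w in spec.extra_catalogue_words:
        if w.upper() not in catalogue.sites:
            catalogue.add(w, RMType.II_orthodox, provenance="simulated-control")

    fixture = FixtureCollection(
        genomes=genomes,
        catalogue=catalogue,
        metadata=pd.DataFrame(
            meta_rows, columns=["organism_id", "species", "genus", "replicon_id", "kind"]
        ),
        annotations=pd.DataFrame(
            ann_rows,
            columns=["organism_id", "site_word", "rm_type", "replicon_id",
                     "gene_start", "gene_end", "encodes_rease", "experimentally_proven"],
        ),
        methylation=pd.DataFrame(
            meth_rows, columns=["organism_id", "site_word", "fraction_methylated"]
        ),
        alien_fragments=alien_fragments,
        alien_threshold=spec.alien_threshold,
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture
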