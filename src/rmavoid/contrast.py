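"""Observed/expected contrast ratios for recognition-site words.

Two expectations are computed for each (site, genome) pair:

* ``expected_karlin`` — Karlin's compositional contrast expectation, realised
  as a masked-subword inclusion–exclusion.  For a word W of length L,

      E(W) = prod over non-empty S subset of {1..L} of
             N(mask(W, S)) ** ((-1) ** (|S| + 1))

  where mask(W, S) replaces the positions in S by N and every masked word is
  counted as a length-L window (the fully masked word therefore counts the
  total windows T).  For L=2 this reduces to N(w1·)N(·w2)/T and for L=3 to
  N(·w2w3) N(w1·w3) N(w1w2·) T / (N(w1··) N(·w2·) N(··w3)), the familiar
  closed forms.  The exponents sum to 1, so E scales linearly with the counts
  and the ratio Kr = observed / E is invariant under genome duplication.

* ``expected_markov`` — the maximal-order Markov expectation
  N(W[1..L-1]) N(W[2..L]) / N(W[2..L-1]), subword counts taken at their own
  lengths; for L=2 the mononucleotide product N(w1)N(w2)/T.

Kr is the primary deviation measure: its variance on control cohorts is
smaller than Mr's, and it handles degenerate words through the same masked
counting as the observed count.  A pair is classified underrepresented when
Kr <= 0.78 and overrepresented when Kr >= 1.23 (boundaries inclusive), and is
only trusted when the expected count reaches a minimum of 15 — below that the
ratio is too noisy, as the complementary-strand SD procedure
(:func:`estimate_kr_sd_by_complement`) shows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomes import Genome, count_in_array, count_occurrences, word_masks
from .sites import is_palindromic, reverse_complement

__all__ = [
    "ThresholdConfig",
    "ContrastRecord",
    "expected_karlin",
    "expected_markov",
    "classify_representation",
    "compute_contrast",
    "contrast_table",
    "apply_min_expected_filter",
    "estimate_kr_sd_by_complement",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Classification thresholds and the expected-count reliability filter.

    ``t_under``/``t_over`` are the Kr cutoffs for under-/overrepresentation,
    both inclusive.  ``min_expected`` is the smallest Karlin expectation at
    which a pair is considered reliable; the boundary is inclusive (>= 15).
    """

    t_under: float = 0.78
    t_over: float = 1.23
    min_expected: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.t_under < self.t_over:
            raise ValueError("thresholds must satisfy 0 < t_under < t_over")


def classify_representation(kr: float, cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Classify a Kr value: 'under' (<= t_under), 'over' (>= t_over) or 'normal'."""
    if kr < 0 or not math.isfinite(kr):
        raise ValueError(f"Kr must be a finite non-negative number, got {kr}")
    if kr <= cfg.t_under:
        return "under"
    if kr >= cfg.t_over:
        return "over"
    return "normal"


def _masked_counts(genome: Genome, word: str) -> dict[frozenset, int]:
    """Counts of every masked variant of ``word`` as length-L windows."""
    word = word.upper()
    L = len(word)
    counts: dict[frozenset, int] = {}
    for r in range(1, L + 1):
        for subset in itertools.combinations(range(L), r):
            masked = "".join("N" if i in subset else word[i] for i in range(L))
            masks = word_masks(masked)
            counts[frozenset(subset)] = sum(
                count_in_array(rep.encoded, masks) for rep in genome.replicons
            )
    return counts


def expected_karlin(genome: Genome, word: str) -> float | None:
    """Karlin expectation of ``word`` via masked-subword inclusion–exclusion.

    Returns ``None`` (undefined) when any masked-subword count is zero — the
    record is flagged and excluded downstream rather than aborting the run.
    Words of length 1 are rejected: the contrast is defined for L >= 2.
    """
    word = word.upper()
    if len(word) < 2:
        raise ValueError("Karlin expectation requires word length >= 2")
    counts = _masked_counts(genome, word)
    log_e = 0.0
    for subset, n in counts.items():
        if n == 0:
            return None
        sign = 1.0 if len(subset) % 2 == 1 else -1.0
        log_e += sign * math.log(n)
    return math.exp(log_e)


def expected_markov(genome: Genome, word: str) -> float | None:
    """Maximal-order Markov expectation of ``word``.

    For L >= 3: N(prefix) * N(suffix) / N(core), each counted at its own
    length.  For L == 2 the mononucleotide product N(w1)N(w2)/T is used.
    Returns ``None`` when a denominator count is zero.
    """
    word = word.upper()
    L = len(word)
    if L < 2:
        raise ValueError("Markov expectation requires word length >= 2")
    if L == 2:
        n1 = count_occurrences(genome, word[0]).observed
        wc2 = count_occurrences(genome, word[1])
        total = sum(len(rep) for rep in genome.replicons)
        if total == 0:
            return None
        return n1 * wc2.observed / total
    n_prefix = count_occurrences(genome, word[:-1]).observed
    n_suffix = count_occurrences(genome, word[1:]).observed
    n_core = count_occurrences(genome, word[1:-1]).observed
    if n_core == 0:
        return None
    return n_prefix * n_suffix / n_core


@dataclass
class ContrastRecord:
    """One site-genome pair: counts, expectations, ratios and flags."""

    site_word: str
    organism_id: str
    observed: int
    expected_karlin: float | None
    expected_markov: float | None
    kr: float | None
    mr: float | None
    passes_min_expected: bool
    representation: str | None  # 'under' | 'normal' | 'over' | None if undefined


def compute_contrast(
    genome: Genome,
    word: str,
    cfg: ThresholdConfig = ThresholdConfig(),
    with_markov: bool = False,
) -> ContrastRecord:
    """Compute the full contrast record for one (site, genome) pair."""
    observed = count_occurrences(genome, word).observed
    e_k = expected_karlin(genome, word)
    e_m = expected_markov(genome, word) if with_markov else None
    kr = observed / e_k if e_k else None
    mr = observed / e_m if e_m else None
    passes = e_k is not None and e_k >= cfg.min_expected
    rep = classify_representation(kr, cfg) if kr is not None else None
    return ContrastRecord(
        site_word=word.upper(),
        organism_id=genome.organism_id,
        observed=observed,
        expected_karlin=e_k,
        expected_markov=e_m,
        kr=kr,
        mr=mr,
        passes_min_expected=passes,
        representation=rep,
    )


def contrast_table(
    genomes: list[Genome],
    words: list[str],
    cfg: ThresholdConfig = ThresholdConfig(),
    with_markov: bool = False,
    rm_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Contrast records for the cross product of words and genomes.

    Returns a DataFrame in deterministic (organism_id, site_word) order with
    the grouping columns (rm_type, is_palindromic, species, genus) attached.
    """
    rows = []
    for genome in sorted(genomes, key=lambda g: g.organism_id):
        for word in sorted({w.upper() for w in words}):
            rec = compute_contrast(genome, word, cfg, with_markov=with_markov)
            rows.append(
                {
                    "organism_id": genome.organism_id,
                    "site_word": rec.site_word,
                    "rm_type": (rm_types or {}).get(rec.site_word, ""),
                    "is_palindromic": is_palindromic(rec.site_word),
                    "species": genome.species,
                    "genus": genome.genus,
                    "observed": rec.observed,
                    "expected_karlin": rec.expected_karlin,
                    "expected_markov": rec.expected_markov,
                    "kr": rec.kr,
                    "mr": rec.mr,
                    "passes_min_expected": rec.passes_min_expected,
                    "representation": rec.representation,
                }
            )
    return pd.DataFrame(rows)


def apply_min_expected_filter(
    records: pd.DataFrame, cfg: ThresholdConfig = ThresholdConfig()
) -> pd.DataFrame:
    """Re-evaluate the reliability flag and return only passing records.

    A record passes when its Karlin expectation is defined and at least
    ``cfg.min_expected`` (inclusive).  Cohort statistics must only use
    passing records.
    """
    records = records.copy()
    records["passes_min_expected"] = (
        records["expected_karlin"].notna()
        & (records["expected_karlin"] >= cfg.min_expected)
    )
    return records[records["passes_min_expected"]].reset_index(drop=True)


def estimate_kr_sd_by_complement(
    records: pd.DataFrame, bin_edges: np.ndarray | list[float]
) -> pd.DataFrame:
    """Per-bin SD of Kr estimated from complementary-strand site pairs.

    For each non-palindromic word w present together with its reverse
    complement in the same genome, the two Kr values are two equal-variance
    estimates of the same quantity, so each difference divided by sqrt(2)
    estimates the per-site noise.  Pairs are binned by the mean of the two
    expected counts; bins with fewer than two pairs get SD ``NaN``.

    Returns a DataFrame with columns bin_left, bin_right, n_pairs, sd.
    """
    edges = np.asarray(bin_edges, dtype=float)
    diffs_by_bin: dict[int, list[float]] = {i: [] for i in range(len(edges) - 1)}
    by_genome = records.groupby("organism_id")
    for _, sub in by_genome:
        kr = dict(zip(sub["site_word"], sub["kr"]))
        exp = dict(zip(sub["site_word"], sub["expected_karlin"]))
        seen = set()
        for w in kr:
            rc = reverse_complement(w)
            if w == rc or rc not in kr or (rc, w) in seen:
                continue
            seen.add((w, rc))
            if kr[w] is None or kr[rc] is None or pd.isna(kr[w]) or pd.isna(kr[rc]):
                continue
            mean_exp = 0.5 * (exp[w] + exp[rc])
            idx = np.searchsorted(edges, mean_exp, side="right") - 1
            if 0 <= idx < len(edges) - 1:
                diffs_by_bin[idx].append((kr[w] - kr[rc]) / math.sqrt(2.0))
    rows = []
    for i in range(len(edges) - 1):
        d = diffs_by_bin[i]
        sd = float(np.std(d, ddof=1)) if len(d) >= 2 else float("nan")
        rows.append(
            {"bin_left": edges[i], "bin_right": edges[i + 1], "n_pairs": len(d), "sd": sd}
        )
    return pd.DataFrame(rows)
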