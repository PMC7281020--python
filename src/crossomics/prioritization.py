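"""Gene ranking by metabolite-set enrichment (Fisher's exact test).

For each candidate gene the measured entities of a patient's Z-score
profile are cross-tabulated: in the gene's metabolite set or not, against
aberrant (Z beyond the paired biochemical thresholds) or not.  A one-sided
Fisher's exact test for over-representation gives the gene's p-value;
candidates are ranked ascending.  Genes whose set intersects no measured
entity, or whose set contains no aberrant entity, cannot be tested: they
are flagged *missed* and assigned p = 1.0, which under the worst-rank tie
rule places them in the final tie block of the list.

An entity belongs to a gene's set if any of its (isomeric) annotations is
among the set's metabolites.  The enrichment background is the set of all
measured (annotated, finite-Z) entities in the profile — enrichment is
judged relative to what the assay can see.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import InputError
from .metabolomics import ZScoreProfile, aberrant_entities
from .sets import GeneMetaboliteSet


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene's 2x2 table, p-value and missed flag.

    a: aberrant entities in the set; b: non-aberrant in the set;
    c: aberrant outside; d: non-aberrant outside.  a+b+c+d equals the
    number of measured entities.  missed implies p_value == 1.0.
    """

    gene: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    missed: bool


@dataclass
class PrioritizedGeneList:
    """Candidate genes ordered by ascending enrichment p-value.

    Ranks are 1-based and tied genes all receive the worst rank of their
    tie block, so a top-10 call is never an artifact of arbitrary
    within-tie ordering.
    """

    entries: list[EnrichmentResult]
    ranks: dict[str, int]

    def rank_of(self, gene: str) -> int | None:
        """1-based rank of ``gene``; ``None`` if it was not a candidate."""
        return self.ranks.get(gene)

    def top(self, k: int) -> list[EnrichmentResult]:
        return [r for r in self.entries if self.ranks[r.gene] <= k]

    def __len__(self) -> int:
        return len(self.entries)


@lru_cache(maxsize=100_000)
def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for a 2x2 table."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def fisher_pvalues_vectorized(
    a: np.ndarray, set_sizes: np.ndarray, n_aberrant: int, n_total: int
) -> np.ndarray:
    """One-sided Fisher p-values for many genes sharing one background.

    Equivalent to the per-table Fisher test: the one-sided p equals the
    hypergeometric upper tail P(X >= a) with population ``n_total``,
    ``n_aberrant`` successes and draws of ``set_sizes``.
    """
    a = np.asarray(a, dtype=np.int64)
    set_sizes = np.asarray(set_sizes, dtype=np.int64)
    return stats.hypergeom.sf(a - 1, n_total, n_aberrant, set_sizes)


def measured_set_entities(
    gene_set: GeneMetaboliteSet, profile: ZScoreProfile
) -> frozenset[str]:
    """Measured entities whose annotations intersect the gene's metabolites."""
    members = gene_set.metabolites()
    return frozenset(
        e for e in profile.measured_entities() if profile.annotations[e] & members
    )


def enrich_gene(
    gene_set: GeneMetaboliteSet,
    profile: ZScoreProfile,
    thresholds: tuple[float, float],
    two_sided: bool = False,
) -> EnrichmentResult:
    """Fisher enrichment of aberrant entities in one gene's metabolite set.

    Returns a missed result (p = 1.0) if the gene's set intersects no
    measured entity or contains no aberrant entity.
    """
    universe = profile.measured_entities()
    if not universe:
        raise InputError("profile has no measured entities")
    aberrant = aberrant_entities(profile, thresholds)
    in_set = measured_set_entities(gene_set, profile)
    a = len(in_set & aberrant)
    b = len(in_set) - a
    c = len(aberrant) - a
    d = len(universe) - a - b - c
    if not in_set or a == 0:
        return EnrichmentResult(gene_set.gene, a, b, c, d, 1.0, True)
    if two_sided:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        p = _fisher_greater(a, b, c, d)
    return EnrichmentResult(gene_set.gene, a, b, c, d, min(p, 1.0), False)


def _assign_ranks(p_values: list[float], method: str = "max") -> list[int]:
    """1-based ranks for ascending p-values with a tie rule.

    ``max`` (default): every member of a tie block gets the block's worst
    rank.  ``min`` and ``average`` follow the usual competition/midrank
    conventions.
    """
    p = np.asarray(p_values, dtype=float)
    if method == "max":
        return [int(np.sum(p <= v)) for v in p]
    if method == "min":
        return [int(np.sum(p < v)) + 1 for v in p]
    if method == "average":
        return list(stats.rankdata(p, method="average"))
    raise InputError(f"unknown tie rule {method!r}")


def prioritize(
    candidates: list[str],
    sets: dict[str, GeneMetaboliteSet],
    profile: ZScoreProfile,
    thresholds: tuple[float, float],
    tie_rule: str = "max",
    two_sided: bool = False,
) -> PrioritizedGeneList:
    """Rank candidate genes by enrichment p-value (lowest first).

    Candidates absent from ``sets`` are treated as having an empty set and
    are therefore missed.  Ordering is deterministic: ties are sorted with
    missed genes last, then alphabetically, and ranks follow ``tie_rule``.
    """
    if len(set(candidates)) != len(candidates):
        dupes = sorted({g for g in candidates if candidates.count(g) > 1})
        raise InputError(f"duplicate candidate gene names: {dupes}")
    results = []
    for gene in candidates:
        gset = sets.get(gene)
        if gset is None:
            gset = GeneMetaboliteSet(gene, {}, has_primary_reaction=False)
        results.append(enrich_gene(gset, profile, thresholds, two_sided=two_sided))
    results.sort(key=lambda r: (r.p_value, r.missed, r.gene))
    ranks = _assign_ranks([r.p_value for r in results], method=tie_rule)
    return PrioritizedGeneList(results, {r.gene: rk for r, rk in zip(results, ranks)})


def rank_of(listing: PrioritizedGeneList, gene: str) -> int | None:
    """1-based rank of ``gene`` in the listing; ``None`` if absent."""
    return listing.rank_of(gene)


def listing_to_frame(listing: PrioritizedGeneList):
    """TSV-ready table: rank, gene, p_value, a, b, c, d, missed."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rank": listing.ranks[r.gene],
                "gene": r.gene,
                "p_value": r.p_value,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "missed": r.missed,
            }
            for r in listing.entries
        ]
    )
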