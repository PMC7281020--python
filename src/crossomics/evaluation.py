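"""Diagnostic-value evaluation across the parameter grid.

The method has three tunable parameters: the maximum distance D to the
primary reaction (6 options), the extension stringency T (6 options) and
the paired biochemical Z-score thresholds (4 options) — 144 combinations
in all.  Because no real exomes are available, candidate gene lists are
simulated: 200 genes drawn at random from the protein-encoding universe
plus the patient's disease-causing gene, 201 candidates in total.  A
prioritization is *accurate* when the disease gene ranks within the top 10
of that list; the *diagnostic value* of a parameter combination is the
fraction of accurate analyses.

Gene sets depend only on (D, T), so the sweep builds 36 set collections
and reuses each across the four biochemical thresholds.  Likewise a gene's
enrichment p-value depends only on (gene, patient, combination) — not on
which other genes happen to be in the simulated exome — so p-values are
precomputed once per combination and the repetitions merely sample
candidate lists and read off the disease gene's rank.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .metabolomics import ZScoreProfile, aberrant_entities
from .network import GeneReactionMap, MetaboliteNetwork, remove_nonspecific
from .prioritization import fisher_pvalues_vectorized
from .sets import (
    MAX_DISTANCE_GRID,
    STRINGENCY_GRID,
    ExtensionParams,
    build_all_sets,
)

logger = logging.getLogger(__name__)

#: The four paired biochemical stringency thresholds (L, U) studied.
BST_GRID = ((-1.0, 1.5), (-1.5, 2.0), (-3.0, 3.0), (-5.0, 5.0))


@dataclass(frozen=True)
class ParameterCombination:
    """One cell of the 6 x 6 x 4 parameter grid."""

    max_distance: int
    extension_stringency: int
    thresholds: tuple[float, float]

    def label(self) -> str:
        low, high = self.thresholds
        return f"D={self.max_distance},T<={self.extension_stringency},BST=({low},{high})"


def default_grid() -> list[ParameterCombination]:
    """The full studied grid: 6 distances x 6 stringencies x 4 thresholds = 144."""
    return [
        ParameterCombination(d, t, bst)
        for d, t, bst in itertools.product(MAX_DISTANCE_GRID, STRINGENCY_GRID, BST_GRID)
    ]


@dataclass
class EvaluationConfig:
    """Sizes and seed for an evaluation run.

    ``n_background`` random genes plus the disease gene make the candidate
    list (201 by default); ``top_k`` is the rank cutoff for an accurate
    prioritization; ``n_repetitions`` analyses per patient are split
    ``n_splits`` times into test/validation partitions of sizes
    (``n_test``, ``n_repetitions - n_test``).
    """

    n_background: int = 200
    top_k: int = 10
    n_repetitions: int = 1000
    n_test: int = 980
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_background, self.top_k, self.n_repetitions, self.n_splits) < 1:
            raise ConfigurationError("all evaluation sizes must be positive")
        if not (0 < self.n_test < self.n_repetitions):
            raise ConfigurationError("n_test must satisfy 0 < n_test < n_repetitions")

    @property
    def list_length(self) -> int:
        return self.n_background + 1


@dataclass
class CohortPatient:
    """One patient: identifier, causal gene, averaged Z-score profile."""

    patient_id: str
    disease_gene: str
    profile: ZScoreProfile


@dataclass
class SweepResult:
    """Aggregated sweep output.

    ``table`` has one row per combination, sorted by descending diagnostic
    value, in the layout: rank, diagnostic_value, missed_fraction,
    max_distance, extension_stringency, bst_low, bst_high.  ``ranks`` and
    ``missed`` hold, per combination, (n_patients, n_repetitions) arrays of
    the disease gene's rank and missed flag.
    """

    combinations: list[ParameterCombination]
    patients: list[str]
    ranks: dict[ParameterCombination, np.ndarray]
    missed: dict[ParameterCombination, np.ndarray]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def best(self) -> ParameterCombination:
        row = self.table.iloc[0]
        return ParameterCombination(
            int(row.max_distance),
            int(row.extension_stringency),
            (float(row.bst_low), float(row.bst_high)),
        )

    def diagnostic_value_of(self, combo: ParameterCombination, top_k: int = 10) -> float:
        return float(np.mean(self.ranks[combo] <= top_k))

    def per_patient_ranks(self, combo: ParameterCombination) -> pd.DataFrame:
        return pd.DataFrame(self.ranks[combo].T, columns=self.patients)


def simulate_wes(
    universe: list[str],
    disease_gene: str,
    n_background: int = 200,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Simulate one exome: random background genes plus the disease gene.

    ``n_background`` distinct genes are drawn without replacement from the
    universe excluding the disease gene, and the disease gene is appended,
    giving exactly ``n_background + 1`` distinct candidates.
    """
    if disease_gene not in universe:
        raise ConfigurationError(f"disease gene {disease_gene!r} not in universe")
    pool = [g for g in universe if g != disease_gene]
    if len(pool) < n_background:
        raise ConfigurationError(
            f"universe of {len(universe)} genes too small for "
            f"{n_background} background genes plus the disease gene"
        )
    rng = rng if rng is not None else np.random.default_rng()
    chosen = rng.choice(len(pool), size=n_background, replace=False)
    return [pool[i] for i in chosen] + [disease_gene]


def diagnostic_value(ranks, top_k: int = 10) -> float:
    """Fraction of analyses with disease-gene rank <= top_k.

    ``ranks`` may contain ``None`` (gene absent from the candidate list),
    which counts as a failure.
    """
    arr = [r for r in ranks]
    if not arr:
        raise ConfigurationError("no ranks supplied")
    hits = sum(1 for r in arr if r is not None and r <= top_k)
    return hits / len(arr)


def missed_fraction(missed_flags) -> float:
    """Fraction of analyses whose disease gene was flagged missed."""
    flags = list(missed_flags)
    if not flags:
        raise ConfigurationError("no analyses supplied")
    return sum(bool(f) for f in flags) / len(flags)


def split_test_validation(
    n_repetitions: int = 1000,
    n_test: int = 980,
    n_splits: int = 10,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random test/validation partitions of the repetition indices.

    Each of ``n_splits`` independent splits draws ``n_test`` repetition
    indices at random; the validation set is the complement.
    """
    if not (0 < n_test < n_repetitions):
        raise ConfigurationError("need 0 < n_test < n_repetitions")
    rng = rng if rng is not None else np.random.default_rng()
    splits = []
    for _ in range(n_splits):
        test = np.sort(rng.choice(n_repetitions, size=n_test, replace=False))
        mask = np.ones(n_repetitions, dtype=bool)
        mask[test] = False
        splits.append((test, np.flatnonzero(mask)))
    return splits


def random_chance_baseline(
    list_length: int = 201,
    top_k: int = 10,
    n_patients: int = 97,
    n_repetitions: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Monte-Carlo diagnostic value expected from random prioritization.

    Per draw: a simulated disease gene is a uniform position in
    1..list_length; a simulated top-``top_k`` is a uniform ``top_k``-subset
    of those positions; a hit is the disease position falling inside the
    subset.  Repeated ``n_repetitions`` times for ``n_patients`` simulated
    disease genes.  The analytic expectation is top_k / list_length
    (10/201 ≈ 0.0498 at the defaults).
    """
    if not 0 < top_k < list_length:
        raise ConfigurationError("need 0 < top_k < list_length")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_patients * n_repetitions
    hits = 0
    chunk = 20_000
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        disease = rng.integers(0, list_length, size=m)
        keys = rng.random((m, list_length))
        top = np.argpartition(keys, top_k - 1, axis=1)[:, :top_k]
        hits += int(np.sum(np.any(top == disease[:, None], axis=1)))
    return hits / n


def _per_combo_pvalues(
    sets_by_dt: dict,
    combo: ParameterCombination,
    gene_order: list[str],
    profile: ZScoreProfile,
    membership_cache: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """p-value vector and missed mask over ``gene_order`` for one patient."""
    key = (combo.max_distance, combo.extension_stringency, profile.owner)
    if key not in membership_cache:
        sets = sets_by_dt[(combo.max_distance, combo.extension_stringency)]
        measured = sorted(profile.measured_entities())
        idx = {e: i for i, e in enumerate(measured)}
        mat = np.zeros((len(gene_order), len(measured)), dtype=bool)
        for gi, gene in enumerate(gene_order):
            gset = sets.get(gene)
            members = gset.metabolites() if gset is not None else frozenset()
            if not members:
                continue
            for e in measured:
                if profile.annotations[e] & members:
                    mat[gi, idx[e]] = True
        membership_cache[key] = (mat, measured)
    mat, measured = membership_cache[key]
    aberrant = aberrant_entities(profile, combo.thresholds)
    ab_vec = np.array([e in aberrant for e in measured], dtype=bool)
    a = mat.astype(np.int64) @ ab_vec.astype(np.int64)
    set_sizes = mat.sum(axis=1, dtype=np.int64)
    n_total = len(measured)
    n_aberrant = int(ab_vec.sum())
    p = fisher_pvalues_vectorized(a, set_sizes, n_aberrant, n_total)
    missed = (set_sizes == 0) | (a == 0)
    p = np.where(missed, 1.0, p)
    return np.minimum(p, 1.0), missed


def parameter_sweep(
    cohort: list[CohortPatient],
    network: MetaboliteNetwork,
    gene_map: GeneReactionMap,
    grid: list[ParameterCombination] | None = None,
    config: EvaluationConfig | None = None,
    blacklist=None,
    universe: list[str] | None = None,
) -> SweepResult:
    """Evaluate diagnostic value and missed fraction over a parameter grid.

    For every combination and repetition, a fresh simulated exome is drawn
    per patient, the candidate genes are ranked by enrichment p-value
    (worst-rank ties), and the disease gene's rank is recorded.  Candidate
    lists are shared across combinations within a (patient, repetition)
    analysis so parameter effects are compared on identical exomes.
    The per-(patient, repetition) random streams are derived from the
    config seed, making the whole sweep reproducible.

    ``universe`` is the gene pool exomes are sampled from; it defaults to
    the gene map's genes, and genes in it that have no mapped reaction are
    treated as empty-set (missed) candidates.
    """
    grid = grid if grid is not None else default_grid()
    config = config if config is not None else EvaluationConfig()
    if blacklist is not None:
        network = remove_nonspecific(network, blacklist)

    universe = list(universe) if universe is not None else gene_map.genes
    dt_pairs = sorted({(c.max_distance, c.extension_stringency) for c in grid})
    sets_by_dt = {}
    for d, t in dt_pairs:
        params = ExtensionParams(max_distance=d, extension_stringency=t, blacklist=frozenset())
        sets_by_dt[(d, t)] = build_all_sets(gene_map, network, params)

    gene_idx = {g: i for i, g in enumerate(universe)}
    n_pat, n_rep = len(cohort), config.n_repetitions

    # candidate index matrices per patient: (n_rep, list_length)
    root = np.random.SeedSequence(config.seed)
    patient_seqs = root.spawn(n_pat)
    candidates: list[np.ndarray] = []
    for pi, patient in enumerate(cohort):
        rep_seqs = patient_seqs[pi].spawn(n_rep)
        mats = np.empty((n_rep, config.list_length), dtype=np.int64)
        for ri in range(n_rep):
            genes = simulate_wes(
                universe,
                patient.disease_gene,
                config.n_background,
                np.random.default_rng(rep_seqs[ri]),
            )
            mats[ri] = [gene_idx[g] for g in genes]
        candidates.append(mats)

    membership_cache: dict = {}
    ranks: dict[ParameterCombination, np.ndarray] = {}
    missed: dict[ParameterCombination, np.ndarray] = {}
    rows = []
    for combo in grid:
        rk = np.empty((n_pat, n_rep), dtype=np.int64)
        ms = np.empty((n_pat, n_rep), dtype=bool)
        for pi, patient in enumerate(cohort):
            p_all, missed_all = _per_combo_pvalues(
                sets_by_dt, combo, universe, patient.profile, membership_cache
            )
            di = gene_idx[patient.disease_gene]
            p_dis = p_all[di]
            p_cand = p_all[candidates[pi]]  # (n_rep, list_length)
            rk[pi] = np.sum(p_cand <= p_dis, axis=1)
            ms[pi] = missed_all[di]
        ranks[combo] = rk
        missed[combo] = ms
        rows.append(
            {
                "diagnostic_value": float(np.mean(rk <= config.top_k)),
                "missed_fraction": float(np.mean(ms)),
                "max_distance": combo.max_distance,
                "extension_stringency": combo.extension_stringency,
                "bst_low": combo.thresholds[0],
                "bst_high": combo.thresholds[1],
            }
        )

    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["diagnostic_value", "max_distance", "extension_stringency", "bst_low"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return SweepResult([c for c in grid], [p.patient_id for p in cohort], ranks, missed, table)
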