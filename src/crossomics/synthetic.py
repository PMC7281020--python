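"""Synthetic networks, gene maps and patient cohorts with implanted signal.

Every other module is testable offline through this generator.  It
emulates, at configurable scale, the study design the method was built
for: a sparse bipartite metabolite-reaction network with a few promiscuous
hub metabolites (to exercise the extension-stringency gate), a
gene-to-primary-reaction assignment with a fraction of unmapped genes
(whose disease cases can never be prioritized), a monoisotopic mass table
with occasional isomer pairs sharing a mass (to exercise entity
collapsing), and intensity profiles in which metabolites near a patient's
disease reaction are shifted against lognormal control noise.

Signal is implanted in intensity space — a metabolite at distance d from
the disease gene's primary reaction has its intensity scaled so that the
Z-score computed downstream by the metabolomics module comes out near
beta * delta**d — so the pipeline's own Z computation, annotation and
isomer collapsing are on the path between the generator and any recovered
signal.  Elevations and decreases alternate with distance parity so both
halves of the paired biochemical threshold are exercised.

What this does not emulate: real metabolic network topology, adducts and
in-source fragments, batch effects, or treatment-driven partial
normalization (a ``treated_fraction`` nulls signal entirely instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import CohortPatient
from .metabolomics import (
    PeakTable,
    annotate_peaks,
    profiles_by_patient,
)
from .network import GeneReactionMap, MetaboliteNetwork, Reaction
from .sets import primary_metabolite_set

MASS_RANGE = (70.0, 600.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults mirror the intended study conditions: a 300-metabolite /
    220-reaction network, 200 candidate genes, 30 controls, 40 patients,
    an implanted effect of beta = 5 control standard deviations at the
    primary reaction decaying by delta = 0.6 per step out to
    ``signal_depth`` steps, and 20% relative lognormal control noise.
    """

    n_metabolites: int = 300
    n_reactions: int = 220
    min_side: int = 1
    max_side: int = 2
    hub_fraction: float = 0.02
    hub_participation: int = 25
    n_genes: int = 200
    unmapped_gene_fraction: float = 0.1
    multi_reaction_gene_fraction: float = 0.1
    isomer_fraction: float = 0.05
    measured_fraction: float = 0.6  # metabolites visible to the assay
    n_controls: int = 30
    n_patients: int = 40
    n_samples_per_patient: int = 1
    n_replicates: int = 3
    effect_size: float = 5.0  # beta: target |Z| at distance 0
    decay: float = 0.6  # delta: shift is beta * delta**distance
    signal_depth: int = 1  # steps from the primary reaction carrying signal
    signal_hub_cap: int = 19  # perturbation never propagates through hubs
    alternate_sign: bool = True
    noise_sigma: float = 0.2  # lognormal sigma of control intensities
    replicate_cv: float = 0.02  # technical triplicate jitter
    treated_fraction: float = 0.0  # patients with the signal nulled
    seed: int = 0

    def __post_init__(self):
        if min(self.n_metabolites, self.n_reactions, self.n_genes, self.n_patients) < 1:
            raise ConfigurationError("all counts must be positive")
        if self.n_controls < 2:
            raise ConfigurationError("need at least 2 controls")
        if not (0 < self.decay <= 1):
            raise ConfigurationError("decay must be in (0, 1]")
        if not (1 <= self.min_side <= self.max_side):
            raise ConfigurationError("invalid reaction side sizes")


def generate_network(
    spec: SyntheticSpec,
) -> tuple[MetaboliteNetwork, GeneReactionMap, dict[str, float]]:
    """Deterministically generate network, gene map and mass table.

    The network is connected: a backbone of chained reactions (each
    sharing one metabolite with the next) covers every metabolite, then
    extra random reactions are layered on top.  Hub metabolites are
    injected into additional reactions until their participation exceeds
    ``hub_participation`` (above the largest studied stringency of 19).
    Masses are unique per isomer group, spread over 70-600 Da with spacing
    far wider than the 2 ppm annotation window.
    """
    rng = np.random.default_rng(spec.seed)
    mets = [f"M{i:04d}" for i in range(spec.n_metabolites)]
    order = list(rng.permutation(spec.n_metabolites))

    # connected backbone: consecutive windows overlapping by one metabolite
    reactions: list[tuple[set[str], set[str]]] = []
    pos = 0
    while pos < spec.n_metabolites - 1:
        n_sub = int(rng.integers(spec.min_side, spec.max_side + 1))
        n_prod = int(rng.integers(spec.min_side, spec.max_side + 1))
        window = [mets[order[i % spec.n_metabolites]] for i in range(pos, pos + n_sub + n_prod)]
        reactions.append((set(window[:n_sub]), set(window[n_sub:])))
        pos += n_sub + n_prod - 1  # overlap one metabolite with the next reaction
    if len(reactions) > spec.n_reactions:
        raise ConfigurationError(
            f"n_reactions={spec.n_reactions} too small to connect "
            f"{spec.n_metabolites} metabolites (need >= {len(reactions)})"
        )

    while len(reactions) < spec.n_reactions:
        n_sub = int(rng.integers(spec.min_side, spec.max_side + 1))
        n_prod = int(rng.integers(spec.min_side, spec.max_side + 1))
        picks = rng.choice(spec.n_metabolites, size=n_sub + n_prod, replace=False)
        reactions.append(({mets[i] for i in picks[:n_sub]}, {mets[i] for i in picks[n_sub:]}))

    # promote hubs: inject into random reactions until participation target
    n_hubs = int(round(spec.hub_fraction * spec.n_metabolites))
    hubs = [mets[i] for i in rng.choice(spec.n_metabolites, size=n_hubs, replace=False)]
    for hub in hubs:
        present = {i for i, (s, p) in enumerate(reactions) if hub in s or hub in p}
        want = min(spec.hub_participation, len(reactions))
        candidates = [i for i in range(len(reactions)) if i not in present]
        extra = rng.choice(len(candidates), size=max(0, want - len(present)), replace=False)
        for j in extra:
            side = reactions[candidates[j]][int(rng.integers(2))]
            side.add(hub)

    network = MetaboliteNetwork(
        Reaction(f"R{i:04d}", frozenset(s), frozenset(p))
        for i, (s, p) in enumerate(reactions)
    )

    # gene map: a fraction unmapped, a fraction with two primary reactions
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    n_unmapped = int(round(spec.unmapped_gene_fraction * spec.n_genes))
    entries: dict[str, frozenset[str]] = {}
    rids = sorted(network.reactions)
    for gi, gene in enumerate(genes):
        if gi < n_unmapped:
            entries[gene] = frozenset()
            continue
        k = 2 if rng.random() < spec.multi_reaction_gene_fraction else 1
        entries[gene] = frozenset(rids[i] for i in rng.choice(len(rids), size=k, replace=False))
    gene_map = GeneReactionMap(entries)

    # masses: only a fraction of metabolites is visible to the assay
    # (emulating limited database/ionization coverage — e.g. reactive CoA
    # esters are never seen by direct infusion); one mass per isomer group,
    # well separated; isomer pairs share one mass
    n_measured = int(round(spec.measured_fraction * spec.n_metabolites))
    shuffled = list(rng.permutation(spec.n_metabolites))
    measured = [mets[i] for i in shuffled[:n_measured]]
    n_pairs = int(spec.isomer_fraction * n_measured / 2)
    n_groups = n_measured - n_pairs
    lo, hi = MASS_RANGE
    base = np.linspace(lo + 0.5, hi - 0.5, n_groups)
    base = base + rng.uniform(-0.1, 0.1, size=n_groups)  # spacing >> 2 ppm window
    masses: dict[str, float] = {}
    gi = 0
    for pair in range(n_pairs):
        masses[measured[2 * pair]] = masses[measured[2 * pair + 1]] = float(base[gi])
        gi += 1
    for i in range(2 * n_pairs, n_measured):
        masses[measured[i]] = float(base[gi])
        gi += 1
    return network, gene_map, masses


def _signal_distances(
    network: MetaboliteNetwork,
    gene_map: GeneReactionMap,
    gene: str,
    depth: int,
    hub_cap: int = 19,
) -> dict[str, int]:
    """Metabolite -> distance from the gene's primary reaction: the
    ground-truth perturbation footprint.  A metabolic block perturbs its
    pathway neighborhood but not the neighborhoods of promiscuous hub
    metabolites it happens to share, so the breadth-first walk never
    extends *through* a metabolite participating in more than ``hub_cap``
    reactions (hubs at the boundary still receive signal)."""
    primary = primary_metabolite_set(gene, gene_map, network)
    dist = {m: 0 for m in primary.members}
    frontier = set(dist)
    for d in range(depth):
        nxt = set()
        for m in frontier:
            if network.participation.get(m, 0) > hub_cap:
                continue
            for rid in network.reactions_of(m):
                for nb in network.reactions[rid].metabolites:
                    if nb not in dist:
                        dist[nb] = d + 1
                        nxt.add(nb)
        frontier = nxt
    return dist


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces."""

    spec: SyntheticSpec
    network: MetaboliteNetwork
    gene_map: GeneReactionMap
    masses: dict[str, float]
    peaks: PeakTable
    manifest: pd.DataFrame
    disease_genes: dict[str, str]  # patient id -> causal gene
    mass_of_peak: list[float] = field(default_factory=list)


def generate_cohort(
    spec: SyntheticSpec,
    network: MetaboliteNetwork,
    gene_map: GeneReactionMap,
    masses: dict[str, float],
) -> tuple[PeakTable, pd.DataFrame, dict[str, str]]:
    """Generate control and patient intensities with implanted signal.

    Controls are i.i.d. lognormal per metabolite.  Each patient draws a
    disease gene (from genes whose primary set is non-empty), and every
    metabolite at distance d <= signal_depth from that gene's primary
    reaction has its intensity multiplied so its expected Z-score is about
    ``±effect_size * decay**d`` (sign alternating with distance parity).
    Isomers sharing a mass contribute additively to one peak; replicate
    injections carry small multiplicative jitter.
    """
    rng = np.random.default_rng(spec.seed + 1)
    mets = sorted(network.metabolites | set(masses))
    m_idx = {m: i for i, m in enumerate(mets)}
    n_m = len(mets)
    base = rng.lognormal(mean=math.log(1e5), sigma=0.5, size=n_m)
    sigma = spec.noise_sigma
    rel_sd = math.sqrt(math.exp(sigma**2) - 1.0)  # relative sd of lognormal noise

    eligible = [
        g
        for g in gene_map.genes
        if primary_metabolite_set(g, gene_map, network).members
    ]
    if not eligible:
        raise ConfigurationError("no gene has a non-empty primary metabolite set")

    sample_cols: list[tuple[str, int]] = []
    sample_values: list[np.ndarray] = []
    manifest_rows = []
    disease_genes: dict[str, str] = {}

    def draw_sample(z_target: np.ndarray) -> np.ndarray:
        x = base * np.exp(rng.normal(0.0, sigma, size=n_m))
        factor = np.clip(1.0 + z_target * rel_sd, 0.02, None)
        return x * factor

    zero = np.zeros(n_m)
    for ci in range(spec.n_controls):
        sid = f"C{ci + 1:03d}"
        manifest_rows.append({"sample": sid, "role": "control", "patient_id": ""})
        sample_cols.append(sid)
        sample_values.append(draw_sample(zero))

    n_treated = int(round(spec.treated_fraction * spec.n_patients))
    for pi in range(spec.n_patients):
        pid = f"P{pi + 1:03d}"
        gene = eligible[int(rng.integers(len(eligible)))]
        disease_genes[pid] = gene
        z_target = np.zeros(n_m)
        if pi >= n_treated:  # treated patients carry no signal
            footprint = _signal_distances(
                network, gene_map, gene, spec.signal_depth, spec.signal_hub_cap
            )
            for m, d in footprint.items():
                sign = -1.0 if (spec.alternate_sign and d % 2 == 1) else 1.0
                z_target[m_idx[m]] = sign * spec.effect_size * spec.decay**d
        for si in range(spec.n_samples_per_patient):
            sid = f"{pid}-S{si + 1}"
            manifest_rows.append({"sample": sid, "role": "patient", "patient_id": pid})
            sample_cols.append(sid)
            sample_values.append(draw_sample(z_target))

    # collapse isomer groups (shared mass) into one peak, additively;
    # metabolites without a mass entry are invisible to the assay
    mass_groups: dict[float, list[int]] = {}
    for m in sorted(masses):
        mass_groups.setdefault(masses[m], []).append(m_idx[m])
    peak_masses = sorted(mass_groups)
    n_peaks = len(peak_masses)

    values = np.column_stack(sample_values)  # (n_m, n_samples)
    peak_mat = np.zeros((n_peaks, values.shape[1]))
    for r, mass in enumerate(peak_masses):
        peak_mat[r] = values[mass_groups[mass]].sum(axis=0)

    cols, data = [], []
    for j, sid in enumerate(sample_cols):
        for rep in range(1, spec.n_replicates + 1):
            cols.append((sid, rep))
            data.append(peak_mat[:, j] * np.exp(rng.normal(0.0, spec.replicate_cv, size=n_peaks)))
    intensities = pd.DataFrame(
        np.column_stack(data), columns=pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
    )
    roles = {
        row["sample"]: ("control" if row["role"] == "control" else row["patient_id"])
        for row in manifest_rows
    }
    peaks = PeakTable(np.array(peak_masses, dtype=float), intensities, roles)
    manifest = pd.DataFrame(manifest_rows, columns=["sample", "role", "patient_id"])
    return peaks, manifest, disease_genes


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Full synthetic study: network + gene map + masses + cohort."""
    spec = spec if spec is not None else SyntheticSpec()
    network, gene_map, masses = generate_network(spec)
    peaks, manifest, disease_genes = generate_cohort(spec, network, gene_map, masses)
    return SyntheticDataset(
        spec, network, gene_map, masses, peaks, manifest, disease_genes, list(peaks.mz)
    )


def cohort_profiles(dataset: SyntheticDataset, ppm: float = 2.0) -> list[CohortPatient]:
    """Run the metabolomics pipeline on a synthetic dataset.

    Annotates peaks against the dataset's mass table, computes Z-scores,
    averages per patient and pairs each profile with the ground-truth
    disease gene.
    """
    annotated = annotate_peaks(dataset.peaks, dataset.masses, ppm_window=ppm)
    per_patient = profiles_by_patient(dataset.peaks, annotated)
    return [
        CohortPatient(pid, dataset.disease_genes[pid], per_patient[pid])
        for pid in sorted(dataset.disease_genes)
    ]
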