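"""Gene-specific metabolite sets: primary sets and bounded extension.

A gene's *primary metabolite set* is the union of substrates and products
of its primary reaction(s) (distance 0).  The set is then extended
breadth-first over the reaction network: at each step d -> d+1, every
member at distance d whose participation count does not exceed the
*extension stringency* threshold T pulls in all metabolites of every
reaction it takes part in, at distance d+1.  Metabolites more promiscuous
than T stay in the set but are never expanded *through* — this is what
keeps currency-adjacent hubs from flooding the set.  Extension stops after
``max_distance`` steps (0 to 5 in the studied grid).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .network import DEFAULT_BLACKLIST, GeneReactionMap, MetaboliteNetwork

logger = logging.getLogger(__name__)

#: The studied grids for the two set-construction parameters.
MAX_DISTANCE_GRID = (0, 1, 2, 3, 4, 5)
STRINGENCY_GRID = (8, 10, 12, 15, 17, 19)


@dataclass(frozen=True)
class ExtensionParams:
    """Parameters controlling how a primary set is extended.

    Parameters
    ----------
    max_distance
        Maximum number of reaction steps away from the primary reaction
        (0 means the primary set only).
    extension_stringency
        A member is expanded through only if it participates in at most
        this many reactions.
    blacklist
        Non-specific metabolites removed from the network before anything
        is computed.
    exempt_primary
        If true, distance-0 members are expanded from regardless of their
        participation count.  Off by default: the stringency gate applies
        uniformly.
    """

    max_distance: int = 4
    extension_stringency: int = 15
    blacklist: frozenset[str] = DEFAULT_BLACKLIST
    exempt_primary: bool = False

    def __post_init__(self):
        if self.max_distance < 0:
            raise ConfigurationError("max_distance must be >= 0")
        if self.max_distance > max(MAX_DISTANCE_GRID):
            raise ConfigurationError(
                f"max_distance {self.max_distance} outside the studied grid "
                f"{MAX_DISTANCE_GRID}"
            )
        if self.extension_stringency < 1:
            raise ConfigurationError("extension_stringency must be >= 1")
        if self.extension_stringency not in STRINGENCY_GRID:
            warnings.warn(
                f"extension_stringency {self.extension_stringency} is outside "
                f"the studied grid {STRINGENCY_GRID}",
                stacklevel=2,
            )


@dataclass
class GeneMetaboliteSet:
    """A gene's metabolite set with per-metabolite distances.

    ``members`` maps metabolite id -> distance, the minimal number of
    extension steps at which the metabolite entered the set (0 for the
    primary set).  ``has_primary_reaction`` distinguishes a gene whose
    reactions happen to contribute no metabolites from a gene that has no
    mapped primary reaction at all.
    """

    gene: str
    members: dict[str, int] = field(default_factory=dict)
    has_primary_reaction: bool = True

    def metabolites(self) -> frozenset[str]:
        return frozenset(self.members)

    def at_distance(self, d: int) -> frozenset[str]:
        return frozenset(m for m, dist in self.members.items() if dist == d)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self.members


def primary_metabolite_set(
    gene: str, gene_map: GeneReactionMap, network: MetaboliteNetwork
) -> GeneMetaboliteSet:
    """Union of substrates and products over the gene's primary reaction(s).

    The network is expected to have had non-specific metabolites removed
    already.  A gene absent from the map yields an empty set with
    ``has_primary_reaction=False`` rather than an exception.  Reaction ids
    in the map that are not present in the network are skipped with a
    warning.
    """
    reaction_ids = gene_map.reactions_for(gene)
    if reaction_ids is None:
        return GeneMetaboliteSet(gene, {}, has_primary_reaction=False)
    members: dict[str, int] = {}
    for rid in reaction_ids:
        rxn = network.reactions.get(rid)
        if rxn is None:
            logger.warning("gene %s: reaction %s not in network; skipped", gene, rid)
            continue
        for m in rxn.metabolites:
            members[m] = 0
    return GeneMetaboliteSet(gene, members)


def extend_metabolite_set(
    primary: GeneMetaboliteSet,
    network: MetaboliteNetwork,
    params: ExtensionParams,
) -> GeneMetaboliteSet:
    """Breadth-first, stringency-gated extension of a primary set.

    Distances recorded are minimal entry steps; members whose participation
    exceeds ``params.extension_stringency`` remain in the set but the set
    is never extended through them.  Participation counts are the network's
    global counts (computed on the full blacklist-filtered network), not
    counts on any subgraph.
    """
    members = dict(primary.members)
    if any(d != 0 for d in members.values()):
        raise ConfigurationError("extend_metabolite_set expects a primary (distance-0) set")
    threshold = params.extension_stringency
    frontier = set(members)
    for depth in range(params.max_distance):
        next_frontier: set[str] = set()
        for m in frontier:
            gate_applies = depth > 0 or not params.exempt_primary
            if gate_applies and network.participation.get(m, 0) > threshold:
                continue
            for rid in network.reactions_of(m):
                for neighbor in network.reactions[rid].metabolites:
                    if neighbor not in members:
                        members[neighbor] = depth + 1
                        next_frontier.add(neighbor)
        if not next_frontier:
            break
        frontier = next_frontier
    return GeneMetaboliteSet(primary.gene, members, primary.has_primary_reaction)


def build_gene_set(
    gene: str,
    gene_map: GeneReactionMap,
    network: MetaboliteNetwork,
    params: ExtensionParams,
) -> GeneMetaboliteSet:
    """Primary set construction followed by extension, for one gene."""
    return extend_metabolite_set(primary_metabolite_set(gene, gene_map, network), network, params)


def build_all_sets(
    gene_map: GeneReactionMap,
    network: MetaboliteNetwork,
    params: ExtensionParams,
) -> dict[str, GeneMetaboliteSet]:
    """Build the gene-specific metabolite set for every gene in the map.

    This is the one-time part of the pipeline: for a fixed network and
    (max_distance, stringency) pair the result is deterministic and can be
    exported with :func:`save_sets` and reused across patients and across
    biochemical thresholds.
    """
    out: dict[str, GeneMetaboliteSet] = {}
    for gene in gene_map.genes:
        try:
            out[gene] = build_gene_set(gene, gene_map, network, params)
        except Exception:  # per-gene failures never abort the batch
            logger.warning("failed to build set for gene %s", gene, exc_info=True)
            out[gene] = GeneMetaboliteSet(gene, {}, has_primary_reaction=False)
    return out


def save_sets(sets: dict[str, GeneMetaboliteSet], params: ExtensionParams, path) -> None:
    """Export gene sets as JSON: {gene: {metabolite: distance}} plus a params header."""
    doc = {
        "params": {
            "max_distance": params.max_distance,
            "extension_stringency": params.extension_stringency,
            "blacklist": sorted(params.blacklist),
            "exempt_primary": params.exempt_primary,
        },
        "sets": {
            g: {m: d for m, d in sorted(s.members.items())} for g, s in sorted(sets.items())
        },
        "unmapped_genes": sorted(g for g, s in sets.items() if not s.has_primary_reaction),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_sets(path) -> tuple[dict[str, GeneMetaboliteSet], ExtensionParams]:
    """Read gene sets exported by :func:`save_sets`."""
    with open(path) as fh:
        doc = json.load(fh)
    p = doc["params"]
    params = ExtensionParams(
        max_distance=int(p["max_distance"]),
        extension_stringency=int(p["extension_stringency"]),
        blacklist=frozenset(p.get("blacklist", ())),
        exempt_primary=bool(p.get("exempt_primary", False)),
    )
    unmapped = set(doc.get("unmapped_genes", ()))
    sets = {
        g: GeneMetaboliteSet(g, {m: int(d) for m, d in members.items()}, g not in unmapped)
        for g, members in doc["sets"].items()
    }
    return sets, params
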