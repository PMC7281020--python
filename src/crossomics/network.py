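"""Bipartite metabolite-reaction network and gene-to-reaction mapping.

The network is the in-memory stand-in for a genome-scale metabolite-reaction
database: every reaction lists its substrate and product metabolites, and
each metabolite carries a *participation count* -- the number of distinct
reactions it takes part in, a proxy for currency-metabolite promiscuity.
Reaction direction is deliberately ignored downstream: set extension treats
a reaction as an undirected grouping of its metabolites, because diagnostic
biomarkers frequently sit upstream of the metabolic block.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

#: Default set of non-specific ("currency") metabolites removed from the
#: network before any extension or enrichment.  Users working with a real
#: reaction database should substitute the identifiers of their own curated
#: blacklist; these names only match networks that use them verbatim.
DEFAULT_BLACKLIST = frozenset(
    {
        "h2o", "h+", "atp", "adp", "amp", "pi", "ppi",
        "nad+", "nadh", "nadp+", "nadph", "fad", "fadh2",
        "coa", "co2", "o2", "h2o2", "nh3", "na+", "k+",
    }
)


@dataclass(frozen=True)
class Reaction:
    """One reaction: its identifier and the metabolites on each side."""

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


class MetaboliteNetwork:
    """Bipartite metabolite <-> reaction structure.

    Parameters
    ----------
    reactions
        Iterable of :class:`Reaction`.  Duplicate reaction ids are rejected.

    Attributes
    ----------
    reactions : dict[str, Reaction]
        Reaction id -> reaction.
    metabolites : frozenset[str]
        All metabolites appearing in any reaction.
    participation : dict[str, int]
        Metabolite -> number of distinct reactions containing it (as
        substrate or product).  Always >= 1 for present metabolites.
    """

    def __init__(self, reactions: Iterable[Reaction]):
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.reaction_id in self.reactions:
                raise InputError(f"duplicate reaction id: {rxn.reaction_id!r}")
            self.reactions[rxn.reaction_id] = rxn
        self._index: dict[str, frozenset[str]] = {}
        self.participation: dict[str, int] = {}
        self._reindex()

    def _reindex(self) -> None:
        index: dict[str, set[str]] = {}
        for rid, rxn in self.reactions.items():
            for m in rxn.metabolites:
                index.setdefault(m, set()).add(rid)
        self._index = {m: frozenset(rids) for m, rids in index.items()}
        self.participation = {m: len(rids) for m, rids in self._index.items()}

    @property
    def metabolites(self) -> frozenset[str]:
        return frozenset(self._index)

    def reactions_of(self, metabolite: str) -> frozenset[str]:
        """Ids of the reactions in which ``metabolite`` participates."""
        return self._index.get(metabolite, frozenset())

    def remove_metabolites(self, blacklist: Iterable[str]) -> "MetaboliteNetwork":
        """Return a copy of the network with ``blacklist`` metabolites removed.

        Removal strips the metabolites from every reaction's substrate and
        product sets; participation counts are recomputed.  Reactions whose
        metabolite sets become empty are retained (with empty sets) so the
        reaction universe is unchanged, but they can never be traversed.
        The original network is not modified.
        """
        bl = frozenset(blacklist)
        return MetaboliteNetwork(
            Reaction(rid, rxn.substrates - bl, rxn.products - bl)
            for rid, rxn in self.reactions.items()
        )

    def __len__(self) -> int:
        return len(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetaboliteNetwork: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


@dataclass
class GeneReactionMap:
    """Map gene name -> set of primary reaction ids.

    A gene may map to zero reactions, in which case its metabolite set is
    empty and the gene can never be prioritized ("missed" by construction).
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def reactions_for(self, gene: str) -> frozenset[str] | None:
        """Reaction ids for ``gene``; ``None`` if the gene is unmapped."""
        return self.entries.get(gene)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _split_ids(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


def load_network(path_or_records) -> MetaboliteNetwork:
    """Build a :class:`MetaboliteNetwork` from a reaction table.

    Accepts a path to a tab-separated file with columns ``reaction_id``,
    ``substrates``, ``products`` (ids semicolon-joined), a path to an
    equivalent JSON document ``{reaction_id: {"substrates": [...],
    "products": [...]}}``, or an in-memory ``pandas.DataFrame`` with the
    TSV columns.  A record must have a reaction id and at least one
    substrate or product.
    """
    if isinstance(path_or_records, pd.DataFrame):
        df = path_or_records
    else:
        path = str(path_or_records)
        if path.endswith(".json"):
            with open(path) as fh:
                doc = json.load(fh)
            reactions = []
            for rid, rec in doc.items():
                rxn = Reaction(
                    str(rid),
                    frozenset(map(str, rec.get("substrates", []))),
                    frozenset(map(str, rec.get("products", []))),
                )
                if not rxn.metabolites:
                    raise InputError(f"reaction {rid!r} has no metabolites")
                reactions.append(rxn)
            return MetaboliteNetwork(reactions)
        df = pd.read_csv(path, sep="\t", dtype=str)

    required = {"reaction_id", "substrates", "products"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"reaction table missing columns: {sorted(missing)}")

    reactions = []
    for i, row in enumerate(df.itertuples(index=False)):
        rid = row.reaction_id
        if rid is None or (isinstance(rid, float) and pd.isna(rid)) or not str(rid).strip():
            raise InputError(f"row {i}: missing reaction id")
        rxn = Reaction(str(rid).strip(), _split_ids(row.substrates), _split_ids(row.products))
        if not rxn.metabolites:
            raise InputError(f"row {i} (reaction {rid!r}): no substrates or products")
        reactions.append(rxn)
    return MetaboliteNetwork(reactions)


def load_gene_map(path_or_df) -> GeneReactionMap:
    """Read a gene map: tab-separated ``gene``, ``reaction_ids`` (semicolon-joined)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(str(path_or_df), sep="\t", dtype=str)
    required = {"gene", "reaction_ids"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"gene map missing columns: {sorted(missing)}")
    entries: dict[str, frozenset[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        gene = str(row.gene).strip()
        if not gene or gene == "nan":
            raise InputError(f"row {i}: missing gene name")
        if gene in entries:
            raise InputError(f"duplicate gene name: {gene!r}")
        entries[gene] = _split_ids(row.reaction_ids)
    return GeneReactionMap(entries)


def load_blacklist(path) -> frozenset[str]:
    """Read a blacklist file: one metabolite id per line, '#' comments allowed."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            tok = line.split("#", 1)[0].strip()
            if tok:
                ids.add(tok)
    return frozenset(ids)


def remove_nonspecific(
    network: MetaboliteNetwork, blacklist: Iterable[str] = DEFAULT_BLACKLIST
) -> MetaboliteNetwork:
    """Remove non-specific (currency) metabolites from the network.

    This is applied once, before any extension or enrichment, so that
    ubiquitous metabolites such as water or ATP can never stitch unrelated
    pathways together.  Blacklist ids absent from the network are ignored.
    """
    return network.remove_metabolites(blacklist)


def network_to_frame(network: MetaboliteNetwork) -> pd.DataFrame:
    """Serialize a network back to the reaction-table layout."""
    rows = [
        {
            "reaction_id": rid,
            "substrates": ";".join(sorted(rxn.substrates)),
            "products": ";".join(sorted(rxn.products)),
        }
        for rid, rxn in network.reactions.items()
    ]
    return pd.DataFrame(rows, columns=["reaction_id", "substrates", "products"])
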