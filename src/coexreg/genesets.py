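"""Gene-set (pathway) enrichment against GMT collections.

Hypergeometric over-representation of a query gene list in each set of
a collection, Bonferroni-corrected across the sets tested, with the
conventional minimum-overlap and enrichment-factor filters. The
p-value kernel is shared with the cluster-enrichment stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

from coexreg.prioritize import hypergeom_upper_tail


@dataclass
class GeneSetCollection:
    sets: Dict[str, Set[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)
    universe: Optional[Set[str]] = None

    def restrict_to_universe(self, universe: Set[str]) -> "GeneSetCollection":
        """Intersect every set with the universe; reports dropped genes."""
        restricted, n_dropped = {}, 0
        for name, members in self.sets.items():
            kept = members & universe
            n_dropped += len(members) - len(kept)
            restricted[name] = kept
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} gene(s) outside the universe", stacklevel=2
            )
        return GeneSetCollection(restricted, dict(self.descriptions), set(universe))


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated members."""
    sets: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicated members in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    enrichment_factor: float


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Set[str],
    min_count: int = 3,
    min_enrichment: float = 1.5,
    alpha: float = 0.05,
) -> List[EnrichmentRow]:
    """Hypergeometric over-representation with Bonferroni correction.

    Sets passing the ``min_count`` overlap filter form the family for
    the Bonferroni divisor; rows additionally require enrichment factor
    > ``min_enrichment`` and adjusted p < ``alpha``. Sorted by adjusted
    then raw p.
    """
    if not universe:
        raise ValueError("empty universe")
    restricted = collection.restrict_to_universe(universe)
    q = set(query) & universe
    n_q = len(q)
    tested = []
    for name, members in restricted.sets.items():
        overlap = len(q & members)
        if overlap < min_count:
            continue
        tested.append((name, members, overlap))
    n_tests = len(tested)
    rows = []
    for name, members, overlap in tested:
        n_set = len(members)
        p = hypergeom_upper_tail(overlap, len(universe), n_set, n_q)
        p_adj = min(1.0, p * n_tests)
        factor = (overlap / n_q) / (n_set / len(universe)) if n_q and n_set else 0.0
        if factor > min_enrichment and p_adj < alpha:
            rows.append(
                EnrichmentRow(name, overlap, n_set, n_q, len(universe), p, p_adj, factor)
            )
    rows.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_name))
    return rows
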