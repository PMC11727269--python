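"""Hypergeometric pathway over-representation and cross-dataset integration.

Per-dataset DEG lists are tested against a gene-set collection with the
upper-tail hypergeometric test; pathways significant in every dataset form
the shared set; their members that are consensus DEGs in at least one dataset
form the candidate gene pool fed to recursive feature elimination.  A
repetition-count ranking (genes appearing in at least 30% of the maximum
number of significant pathways) highlights the dominant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "CandidatePool",
    "hypergeom_enrich",
    "shared_pathways",
    "candidate_pool",
    "repetition_counts",
]


@dataclass
class GeneSetCollection:
    """Named pathways -> member gene IDs, with a gene universe.

    ``sets`` maps pathway ID to (description, members).  Members must be a
    subset of ``universe`` and no pathway may be empty.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"pathway {name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    # -- GMT I/O (name <TAB> description <TAB> member...) -------------------
    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (desc, members) in self.sets.items():
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")

    @classmethod
    def read_gmt(
        cls, path: str | Path, universe: frozenset[str] | None = None
    ) -> "GeneSetCollection":
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        seen: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, desc, *members = line.split("\t")
                sets[name] = (desc, frozenset(members))
                seen.update(members)
        return cls(sets, universe if universe is not None else frozenset(seen))


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation table for one query gene list.

    One row per pathway: overlap ``k``, pathway size ``K``, query size ``n``,
    universe size ``N``, upper-tail p, plus the overlapping gene IDs.
    """

    table: pd.DataFrame  # index pathway: k, K, n, N, pvalue
    overlaps: dict[str, frozenset[str]]
    dataset: str = "query"

    def significant(self, alpha: float = 0.05) -> set[str]:
        return set(self.table.index[self.table["pvalue"] < alpha])


@dataclass
class CandidatePool:
    """Shared-pathway gene pool with per-gene provenance."""

    shared_pathway_ids: list[str]
    genes: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def hypergeom_enrich(
    query_genes: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    dataset: str = "query",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the query against every pathway.

    p = P[X >= k] with X ~ Hypergeom(N, K, n) where N is the universe size,
    K the pathway size, n the query size, k the overlap.  Query genes outside
    the universe are dropped (with a logged count).
    """
    uni = set(universe) if universe is not None else set(collection.universe)
    query = set(query_genes)
    dropped = len(query - uni)
    if dropped:
        logger.info("%s: dropped %d query genes outside universe", dataset, dropped)
    query &= uni
    if not query:
        raise ValueError("empty query after restriction to the universe")
    n = len(query)
    big_n = len(uni)
    rows = []
    overlaps: dict[str, frozenset[str]] = {}
    for name in collection.sets:
        members = collection.members(name) & uni
        big_k = len(members)
        hit = frozenset(members & query)
        k = len(hit)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append((name, k, big_k, n, big_n, min(p, 1.0)))
        overlaps[name] = hit
    table = pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "pvalue"]
    ).set_index("pathway")
    table = table.sort_values("pvalue", kind="mergesort")
    return EnrichmentResult(table, overlaps, dataset)


def shared_pathways(
    per_dataset: list[EnrichmentResult],
    alpha: float = 0.05,
    min_datasets: int | None = None,
) -> set[str]:
    """Pathways significant (p < alpha) in every dataset.

    ``min_datasets`` relaxes the quorum from all datasets to at least that
    many.
    """
    if len(per_dataset) < 2:
        raise ValueError("need enrichment results from at least two datasets")
    quorum = len(per_dataset) if min_datasets is None else min_datasets
    counts: dict[str, int] = {}
    for res in per_dataset:
        for pw in res.significant(alpha):
            counts[pw] = counts.get(pw, 0) + 1
    return {pw for pw, c in counts.items() if c >= quorum}


def candidate_pool(
    shared_pathway_ids: set[str] | list[str],
    collection: GeneSetCollection,
    per_dataset_degs: dict[str, set[str]],
    require_all_datasets: bool = False,
) -> CandidatePool:
    """Pool = union over shared pathways of (members ∩ DEG union).

    ``require_all_datasets`` switches the DEG side from the union to the
    intersection across datasets.
    """
    shared = sorted(shared_pathway_ids)
    if not shared:
        raise ValueError("no shared pathways; pipeline cannot proceed")
    deg_sets = list(per_dataset_degs.values())
    degs = set.intersection(*deg_sets) if require_all_datasets else set.union(*deg_sets)
    rows = []
    pool: set[str] = set()
    for pw in shared:
        hit = collection.members(pw) & degs
        pool |= hit
        for gene in hit:
            in_ds = [ds for ds, s in per_dataset_degs.items() if gene in s]
            rows.append((gene, pw, ",".join(sorted(in_ds))))
    if not pool:
        raise ValueError("candidate pool is empty: DEGs disjoint from shared pathways")
    all_members = set.union(*[set(collection.members(pw)) for pw in shared])
    assert pool <= all_members
    prov = pd.DataFrame(rows, columns=["gene", "pathway", "deg_in_datasets"])
    return CandidatePool(shared, sorted(pool), prov)


def repetition_counts(
    gene_sets: dict[str, set[str]],
    enrichment_tables: list[EnrichmentResult],
    fraction: float = 0.30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank genes by how often they recur in significant pathways.

    Counts, for each gene in the union of ``gene_sets``, the number of
    significant pathways (p < alpha, across all tables) whose overlap contains
    it; keeps genes with count >= fraction * max count.  Ties are broken by
    gene ID.  Returns a DataFrame (gene, count, in_sets) sorted by descending
    count; the attrs carry the threshold.
    """
    genes = set.union(*gene_sets.values()) if gene_sets else set()
    counts: dict[str, int] = {g: 0 for g in genes}
    n_sig = 0
    for res in enrichment_tables:
        for pw in res.significant(alpha):
            n_sig += 1
            for g in res.overlaps[pw] & genes:
                counts[g] += 1
    if n_sig == 0:
        logger.warning("repetition_counts: no significant pathways")
        out = pd.DataFrame(columns=["gene", "count", "in_sets"])
        out.attrs["threshold"] = 0.0
        return out
    max_count = max(counts.values(), default=0)
    threshold = fraction * max_count
    kept = [
        (g, c, ",".join(sorted(k for k, s in gene_sets.items() if g in s)))
        for g, c in counts.items()
        if c >= threshold and c > 0
    ]
    kept.sort(key=lambda t: (-t[1], t[0]))
    out = pd.DataFrame(kept, columns=["gene", "count", "in_sets"])
    out.attrs["threshold"] = threshold
    out.attrs["max_count"] = max_count
    return out
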