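"""Gene-set over-representation, candidate ranking, and subgroup scoring.

"Enrichment" here is the hypergeometric overlap computation applied to a DEG
list against a named gene-set collection within a fixed universe, with BH
correction across sets.  Enriched-set genes are intersected with a
cancer-gene list and ranked by differential-expression significance to
nominate candidate genes; tumor samples are assigned to molecular subgroups
by the mean expression of subgroup signature genes relative to a reference
gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import EPSILON

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "SubgroupSignature",
    "hypergeom_enrich",
    "overlap_matrix",
    "cancer_intersect_rank",
    "subgroup_score",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they live in.

    Sets are harmonized on construction: duplicate members collapse and
    genes outside the universe are dropped.
    """

    sets: dict
    universe: frozenset

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.sets = {
            name: frozenset(members) & self.universe for name, members in self.sets.items()
        }

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        if universe is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets=sets, universe=frozenset(universe))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\tna\t{members}\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # universe size
    p: float
    q: float
    enriched: bool


@dataclass
class SubgroupSignature:
    """Subgroup -> signature gene list, scored against a reference gene."""

    signatures: dict
    reference_gene: str

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if self.reference_gene in genes:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} appears in signature {name!r}"
                )


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    q_max: float = 0.05,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric over-representation per set.

    p = P(X >= k) for overlap k between the query and a set of size K drawn
    within a universe of size N given a query of size n; BH correction
    across all sets; records sorted by (p, set name).  Query genes outside
    the universe are dropped with a warning.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped")
        query = query & collection.universe
    if not query:
        raise ValueError("empty query after harmonization")

    N, n = len(collection.universe), len(query)
    names = sorted(collection.sets)
    ks = np.array([len(query & collection.sets[s]) for s in names])
    Ks = np.array([len(collection.sets[s]) for s in names])
    ps = hypergeom.sf(ks - 1, N, Ks, n)
    ps = np.clip(ps, 0.0, 1.0)
    qs = multipletests(ps, method="fdr_bh")[1] if len(names) else np.array([])

    records = [
        EnrichmentRecord(s, int(k), int(K), n, N, float(p), float(qv), bool(qv <= q_max))
        for s, k, K, p, qv in zip(names, ks, Ks, ps, qs)
    ]
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "enriched": [r.enriched for r in records],
        }
    )


def overlap_matrix(
    genes,
    enriched: list[EnrichmentRecord],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Binary gene x enriched-set membership matrix.

    Rows are restricted to genes belonging to at least one enriched set;
    column sums equal the per-set overlap counts when ``genes`` is the
    enrichment query.
    """
    sets = [r.set_name for r in enriched if r.enriched]
    for s in sets:
        if s not in collection.sets:
            raise KeyError(f"enriched set {s!r} not in collection")
    genes = sorted(set(genes))
    data = {
        s: [1 if g in collection.sets[s] else 0 for g in genes] for s in sets
    }
    mat = pd.DataFrame(data, index=genes, dtype=int)
    if sets:
        mat = mat.loc[mat.sum(axis=1) > 0]
    else:
        mat = mat.iloc[0:0]
    return mat


def cancer_intersect_rank(
    matrix_genes,
    cancer_list,
    deg: pd.DataFrame,
) -> pd.DataFrame:
    """Rank enriched-set genes that are also cancer-annotated.

    ``deg`` is the per-gene stats table (columns p, log2fc) covering the
    matrix genes.  Candidates = matrix_genes intersect cancer_list, ranked
    by DEG p ascending, then |log2fc| descending, then gene name; rank 1 is
    the top candidate.  An empty intersection yields an empty table.
    """
    cancer = set(cancer_list)
    candidates = sorted(set(matrix_genes) & cancer)
    if not candidates:
        return pd.DataFrame(columns=["gene", "p", "log2fc", "rank"])
    missing = [g for g in candidates if g not in deg.index]
    if missing:
        raise KeyError(f"DEG stats missing for {missing}")
    tab = pd.DataFrame(
        {
            "gene": candidates,
            "p": deg.loc[candidates, "p"].to_numpy(),
            "log2fc": deg.loc[candidates, "log2fc"].to_numpy(),
        }
    )
    tab["abs_lfc"] = tab["log2fc"].abs()
    tab = tab.sort_values(
        ["p", "abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="abs_lfc")
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab.reset_index(drop=True)


def subgroup_score(
    rpkm: pd.DataFrame,
    sample: str,
    sig: SubgroupSignature,
    eps: float = EPSILON,
) -> tuple[str, dict]:
    """Reference-relative subgroup score and label for one sample.

    score(subgroup) = mean over its signature genes of
    log2((rpkm(g) + eps) / (rpkm(reference) + eps)); the label is the
    argmax, or UNCLASSIFIED on a tie for the maximum.  The reference gene
    must be present and expressed in the sample.
    """
    if sig.reference_gene not in rpkm.index:
        raise KeyError(f"reference gene {sig.reference_gene!r} absent")
    ref = float(rpkm.at[sig.reference_gene, sample])
    if ref <= 0:
        raise ValueError(f"reference gene not expressed in {sample!r}")
    scores = {}
    for name, genes in sig.signatures.items():
        genes = [g for g in genes if g in rpkm.index]
        if not genes:
            raise KeyError(f"signature {name!r} has no genes in the matrix")
        vals = rpkm.loc[genes, sample].to_numpy(dtype=float)
        scores[name] = float(np.mean(np.log2((vals + eps) / (ref + eps))))
    best = max(scores.values())
    winners = [s for s, v in scores.items() if v == best]
    label = winners[0] if len(winners) == 1 else UNCLASSIFIED
    return label, scores
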