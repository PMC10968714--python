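"""Gene-set enrichment: hypergeometric ORA and permutation GSEA.

Gene-set content (GO/KEGG/MSigDB or any other collection) is supplied
by the user as a GMT file; this module only provides the statistics.

ORA tests over-representation of a query list within each set via the
hypergeometric upper tail, with Benjamini-Hochberg correction across
sets.  GSEA computes the weighted Kolmogorov-Smirnov running sum over a
ranked gene list; the null is generated by gene-label permutation
(random sets of the same size), which is the appropriate null when the
input is a ranked list rather than raw expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name}")

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene...)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line has < 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in parts[2:] if g)
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    query_genes,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list per gene set.

    p = P[X >= k] with X ~ Hypergeom(N universe, K set, n query); BH
    q-values across sets.  Query genes outside the universe are dropped
    with a warning.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside universe dropped", len(outside))
        query &= universe
    if not query:
        raise ValueError("empty query after universe filtering")

    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        overlap = sorted(query & in_universe)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["q", "p", "set"]).reset_index(drop=True)


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    running_sum: pd.DataFrame  # columns: gene, score, in_set, running


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    w = np.abs(scores) ** weight
    nr = w[hits].sum()
    n_miss = len(scores) - hits.sum()
    steps = np.where(hits, w / nr, -1.0 / n_miss)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> float:
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_scores: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    set_name: str = "gene_set",
) -> GSEAResult:
    """Weighted KS enrichment of one gene set in a ranked list.

    ``ranked_scores`` maps gene -> ranking score (e.g. Spearman rho from
    the correlation step); genes are ordered by descending score.  Hits
    step the running sum up by |score|^weight (normalized over the set),
    misses step down by 1/(N-K); ES is the extremum by absolute value.
    The permutation null shuffles gene labels; NES divides ES by the
    mean |permuted ES| of matching sign, and p gets a +1 pseudo-count.
    """
    if ranked_scores.index.has_duplicates:
        raise ValueError("ranked gene list contains duplicate genes")
    if not np.isfinite(ranked_scores.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    order = ranked_scores.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    scores = order.to_numpy(dtype=float)
    members = set(gene_set)
    hits = np.isin(genes, list(members))
    K = int(hits.sum())
    if K < 2:
        raise ValueError("gene set shares < 2 genes with the ranking")
    if K == len(genes):
        raise ValueError("gene set covers the whole ranking")

    running = _running_sum(scores, hits, weight)
    es = _es_from_running(running)

    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm_hits = np.zeros(len(genes), dtype=bool)
        perm_hits[rng.choice(len(genes), size=K, replace=False)] = True
        es_perm[i] = _es_from_running(_running_sum(scores, perm_hits, weight))

    same_sign = es_perm * np.sign(es) > 0
    if same_sign.any():
        nes = es / np.abs(es_perm[same_sign]).mean()
    else:
        nes = np.sign(es) * np.inf
    p = (1.0 + (np.abs(es_perm[same_sign]) >= abs(es)).sum()) / (1.0 + same_sign.sum())

    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hits[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hits[peak:]) if h]

    trace = pd.DataFrame(
        {"gene": genes, "score": scores, "in_set": hits, "running": running}
    )
    return GSEAResult(set_name, es, float(nes), float(p), leading, trace)
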