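"""Weighted protein functional-network statistics.

Two views of the same functional-association network are used.  For
neighbourhood ("matrix similarity") statistics the full weighted adjacency
acts as a similarity matrix: S(i, j) is the association confidence in (0, 1]
when the pair is linked and 0 otherwise, and the matrix similarity of a
protein set is the mean (or median) of S over all unordered pairs in the
set.  For centrality and localization the network is thresholded at a high
confidence cutoff (0.8 by default) and treated as an unweighted graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import DrugProfile, FamilyTable, ParseError, _read_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalNetwork",
    "CentralityResult",
    "NeighbourhoodScore",
    "LocalizationScore",
    "read_network",
    "write_network",
    "matrix_similarity",
    "betweenness_analysis",
    "drug_neighbourhood_table",
    "family_neighbourhood",
    "localization",
]


class FunctionalNetwork:
    """Weighted undirected protein association network.

    Scores live in (0, 1]; zero-score edges are dropped at read time.  The
    ``graph`` attribute is the full weighted networkx graph; ``thresholded``
    returns the high-confidence unweighted view.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                continue  # no self-loops
            if not 0.0 < w <= 1.0:
                raise ValueError(f"edge ({u}, {v}) score {w} outside (0, 1]")
            if g.has_edge(u, v) and not math.isclose(g[u][v]["weight"], w, rel_tol=1e-9):
                raise ValueError(
                    f"conflicting duplicate edge ({u}, {v}): {g[u][v]['weight']} vs {w}"
                )
            g.add_edge(u, v, weight=w)
        self.graph = g
        self._thresholded: dict[float, nx.Graph] = {}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def score(self, u: str, v: str) -> float:
        """Similarity-matrix accessor: edge score, or 0 for absent pairs."""
        if self.graph.has_edge(u, v):
            return self.graph[u][v]["weight"]
        return 0.0

    def thresholded(self, cutoff: float = 0.8) -> nx.Graph:
        """Unweighted graph keeping edges with score >= cutoff (cached).

        All nodes are retained so that size-matched random draws come from
        the same universe regardless of cutoff.
        """
        if cutoff not in self._thresholded:
            g = nx.Graph()
            g.add_nodes_from(self.graph.nodes)
            g.add_edges_from(
                (u, v) for u, v, w in self.graph.edges(data="weight") if w >= cutoff
            )
            self._thresholded[cutoff] = g
        return self._thresholded[cutoff]


def read_network(path: str | Path, score_scale: str = "unit") -> FunctionalNetwork:
    """Read a 3-column weighted edge list (protein1, protein2, combined_score).

    score_scale "unit" expects scores already in [0, 1]; "string1000"
    divides integer scores in [0, 1000] by 1000 (the STRING convention).
    Zero-score edges are dropped with a logged count; duplicate rows must
    agree on the score.
    """
    if score_scale not in ("unit", "string1000"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = _read_tsv(path, ["protein1", "protein2", "combined_score"])
    edges = []
    n_zero = 0
    for idx, row in df.iterrows():
        try:
            w = float(row["combined_score"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: line {int(idx) + 2}: non-numeric combined_score "
                f"{row['combined_score']!r}"
            ) from None
        if score_scale == "string1000":
            w = w / 1000.0
        if w == 0.0:
            n_zero += 1
            continue
        edges.append((str(row["protein1"]), str(row["protein2"]), w))
    if n_zero:
        logger.info("read_network: dropped %d zero-score edges", n_zero)
    try:
        return FunctionalNetwork(edges)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_network(network: FunctionalNetwork, path: str | Path) -> None:
    rows = [
        {"protein1": u, "protein2": v, "combined_score": w}
        for u, v, w in sorted(network.graph.edges(data="weight"))
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class NeighbourhoodScore:
    """Matrix similarity of a protein set: mean (or median) pairwise
    association score, absent pairs contributing 0.  Missing (None value)
    for sets with fewer than two network-mapped proteins."""

    set_id: str
    kind: str  # "mean_pairwise" | "median_pairwise"
    value: float | None
    n_proteins: int


def _pairwise_scores(members: Sequence[str], network: FunctionalNetwork) -> np.ndarray:
    k = len(members)
    out = np.empty(k * (k - 1) // 2)
    t = 0
    for i in range(k):
        for j in range(i + 1, k):
            out[t] = network.score(members[i], members[j])
            t += 1
    return out


def matrix_similarity(
    protein_set: Iterable[str],
    network: FunctionalNetwork,
    kind: str = "mean_pairwise",
    set_id: str = "",
    restrict_to_network: bool = True,
) -> NeighbourhoodScore:
    """Matrix similarity of a protein set on the weighted network.

    The statistic is the mean (or median) of S(i, j) over all C(k, 2)
    unordered distinct pairs; the diagonal is never included and absent
    pairs score 0.  Sets with < 2 proteins on the network yield a missing
    value.
    """
    if kind not in ("mean_pairwise", "median_pairwise"):
        raise ValueError(f"unknown kind {kind!r}")
    members = sorted(set(protein_set))
    if restrict_to_network:
        members = [m for m in members if m in network.nodes]
    if len(members) < 2:
        logger.info("matrix_similarity(%s): fewer than 2 network proteins; missing", set_id)
        return NeighbourhoodScore(set_id=set_id, kind=kind, value=None, n_proteins=len(members))
    scores = _pairwise_scores(members, network)
    value = float(np.mean(scores)) if kind == "mean_pairwise" else float(np.median(scores))
    return NeighbourhoodScore(set_id=set_id, kind=kind, value=value, n_proteins=len(members))


@dataclass
class CentralityResult:
    """Mean betweenness of a query set against size-matched random sets."""

    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    empirical_p: float
    n_random: int


def betweenness_analysis(
    query_set: Iterable[str],
    network: FunctionalNetwork,
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
    cutoff: float = 0.8,
) -> CentralityResult:
    """Compare the mean betweenness centrality of a protein set with
    size-matched uniform random sets on the thresholded graph.

    Betweenness is normalized by (n-1)(n-2)/2.  The empirical p-value uses
    the add-one rule (1 + #{null >= observed}) / (n_random + 1), so it can
    never be 0.
    """
    g = network.thresholded(cutoff)
    query = sorted(set(query_set))
    missing = [q for q in query if q not in g]
    if missing:
        raise ValueError(f"query proteins not in network: {missing[:5]}...")
    if not query:
        raise ValueError("empty query set")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    bc = nx.betweenness_centrality(g, normalized=True)
    observed = float(np.mean([bc[q] for q in query]))
    all_nodes = sorted(g.nodes)
    k = len(query)
    null = np.empty(n_random)
    for i in range(n_random):
        draw = rng.choice(len(all_nodes), size=k, replace=False)
        null[i] = np.mean([bc[all_nodes[j]] for j in draw])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_random > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    emp_p = (1 + int(np.sum(null >= observed))) / (n_random + 1)
    return CentralityResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        empirical_p=emp_p,
        n_random=n_random,
    )


def drug_neighbourhood_table(
    profiles: Mapping[str, DrugProfile],
    network: FunctionalNetwork,
    n_random: int = 1,
    seed: int | np.random.Generator = 0,
    kind: str = "mean_pairwise",
) -> pd.DataFrame:
    """Per-drug matrix similarity of targets, off-targets, and size-matched
    random protein sets (one table row per drug).

    The three columns are directly comparable as CDFs: targets of drugs that
    concentrate in a network module score high, off-targets lower, random
    sets lowest.  Drugs without two network-mapped targets (or off-targets)
    get missing values.  *n_random* random sets per drug are averaged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    all_nodes = sorted(network.nodes)
    rows = []
    for drug in sorted(profiles):
        prof = profiles[drug]
        t_score = matrix_similarity(prof.targets, network, kind, set_id=drug).value
        o_score = matrix_similarity(prof.off_targets, network, kind, set_id=drug).value
        k = len([p for p in prof.targets if p in network.nodes])
        r_score = None
        if k >= 2:
            vals = []
            for _ in range(n_random):
                draw = rng.choice(len(all_nodes), size=k, replace=False)
                vals.append(
                    matrix_similarity([all_nodes[j] for j in draw], network, kind,
                                      restrict_to_network=False).value
                )
            r_score = float(np.mean(vals))
        rows.append(
            {
                "drug_id": drug,
                "n_targets": len(prof.targets),
                "n_off_targets": len(prof.off_targets),
                "target_score": t_score,
                "off_target_score": o_score,
                "random_score": r_score,
            }
        )
    return pd.DataFrame(rows)


def family_neighbourhood(
    family_table: FamilyTable,
    network: FunctionalNetwork,
    druggable: Iterable[str] | None = None,
    kind: str = "median_pairwise",
) -> tuple[pd.DataFrame, dict | None]:
    """Per-family matrix similarity, with an optional druggable-vs-rest
    comparison.

    Families need >= 2 network-mapped relatives to receive a score.  When a
    druggable family set is given, the two score groups are compared with a
    two-sided Mann-Whitney-Wilcoxon rank-sum test and the group medians are
    reported.
    """
    rows = []
    for fam in sorted(family_table.families):
        score = matrix_similarity(family_table.families[fam], network, kind, set_id=fam)
        rows.append(
            {
                "family_id": fam,
                "n_relatives": len(family_table.families[fam]),
                "n_on_network": score.n_proteins,
                "score": score.value,
            }
        )
    df = pd.DataFrame(rows)
    comparison = None
    if druggable is not None:
        druggable = set(druggable)
        scored = df.dropna(subset=["score"])
        a = scored.loc[scored["family_id"].isin(druggable), "score"].to_numpy()
        b = scored.loc[~scored["family_id"].isin(druggable), "score"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both druggable and non-druggable groups must be non-empty")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        comparison = {
            "median_druggable": float(np.median(a)),
            "median_rest": float(np.median(b)),
            "n_druggable": int(len(a)),
            "n_rest": int(len(b)),
            "mannwhitney_u": float(stat),
            "p_value": float(p),
        }
    return df, comparison


@dataclass
class LocalizationScore:
    """Shortest-path localization of a protein set on the thresholded graph.

    d_obs is the mean over members of the distance to the nearest other
    member; members unreachable from every other member are assigned
    diameter + 1 (finite penalty) and counted in n_disconnected.  The
    z-score compares d_obs with size-matched uniform random sets (negative z
    = more localized than chance).
    """

    set_id: str
    d_observed: float
    null_mean: float
    null_sd: float
    z_score: float
    n_proteins: int
    n_disconnected: int


def _mean_nearest_member_distance(
    members: Sequence[str], g: nx.Graph, penalty: float
) -> tuple[float, int]:
    dists = []
    n_disc = 0
    mset = set(members)
    for m in members:
        lengths = nx.single_source_shortest_path_length(g, m)
        best = min((d for n, d in lengths.items() if n in mset and n != m), default=None)
        if best is None:
            n_disc += 1
            best = penalty
        dists.append(best)
    return float(np.mean(dists)), n_disc


def localization(
    query_set: Iterable[str],
    network: FunctionalNetwork,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    cutoff: float = 0.8,
    set_id: str = "",
) -> LocalizationScore:
    """Network-distance localization of a protein set versus random sets."""
    g = network.thresholded(cutoff)
    members = sorted(set(query_set) & set(g.nodes))
    if len(members) < 2:
        raise ValueError("localization needs >= 2 network-mapped proteins")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # penalty for unreachable members: largest component diameter + 1
    comps = [g.subgraph(c) for c in nx.connected_components(g)]
    diam = max((nx.diameter(c) for c in comps if c.number_of_nodes() > 1), default=1)
    penalty = diam + 1

    d_obs, n_disc = _mean_nearest_member_distance(members, g, penalty)
    all_nodes = sorted(g.nodes)
    k = len(members)
    null = np.empty(n_random)
    for i in range(n_random):
        draw = rng.choice(len(all_nodes), size=k, replace=False)
        null[i], _ = _mean_nearest_member_distance([all_nodes[j] for j in draw], g, penalty)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_random > 1 else float("nan")
    z = (d_obs - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    return LocalizationScore(
        set_id=set_id,
        d_observed=d_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        n_proteins=k,
        n_disconnected=n_disc,
    )
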