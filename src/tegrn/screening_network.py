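"""All-pairs transfer entropy, the edge-screening cascade, and network export.

For n genes there are m = n·(n−1) ordered pairs, each carrying a transfer
entropy and a permutation p-value. The cascade then narrows candidates:

1. one_way_screen      — keep, per unordered pair, only the stronger
                         direction (n·(n−1)/2 edges survive);
2. pvalue_screen       — keep edges with p < alpha (strict; default 0.001);
3. te_threshold_screen — keep edges with TE >= min_te (inclusive; default
                         0.5 bits);
4. strongest_per_source / strongest_per_target — keep each gene's single
                         strongest outgoing (resp. incoming) edge.

All tie-breaks are lexicographic on gene names so reruns are reproducible.
The final edge lists export to Cytoscape-loadable SIF and TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tegrn.significance import derive_pair_seed, permutation_pvalue
from tegrn.te_core import DEFAULT_N_BINS

__all__ = [
    "TEMatrix",
    "EdgeList",
    "pair_count",
    "all_pairs_te",
    "one_way_screen",
    "pvalue_screen",
    "te_threshold_screen",
    "strongest_per_source",
    "strongest_per_target",
    "build_network",
    "write_sif",
    "write_edge_tsv",
    "read_edge_tsv",
    "read_sif",
]

_EDGE_COLUMNS = ["source", "target", "te", "p_value"]


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)


@dataclass
class TEMatrix:
    """TE and p-value for every ordered gene pair (diagonal absent)."""

    entries: pd.DataFrame  # columns: source, target, te, p_value
    genes: list[str]

    def __post_init__(self):
        self.entries = _canonical(self.entries[_EDGE_COLUMNS].copy())
        n = len(self.genes)
        if len(self.entries) != pair_count(n):
            raise ValueError(
                f"expected {pair_count(n)} ordered pairs for {n} genes, "
                f"got {len(self.entries)}"
            )
        if (self.entries["source"] == self.entries["target"]).any():
            raise ValueError("self-pairs are not allowed")

    def to_edge_list(self, stage: str = "all_pairs") -> "EdgeList":
        return EdgeList(self.entries.copy(), stage=stage)


@dataclass
class EdgeList:
    """Directed scored edges surviving some screening stage."""

    edges: pd.DataFrame  # columns: source, target, te, p_value
    stage: str = "unscreened"

    def __post_init__(self):
        self.edges = _canonical(self.edges[_EDGE_COLUMNS].copy())
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("self-loops are not allowed")
        if self.edges.duplicated(["source", "target"]).any():
            raise ValueError("duplicate (source, target) pairs")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))


def pair_count(n_genes: int) -> int:
    """Number of ordered gene pairs, m = n·(n−1)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return n_genes * (n_genes - 1)


def all_pairs_te(
    matrix: pd.DataFrame,
    k: int = 1,
    l: int = 1,
    n_bins: int = DEFAULT_N_BINS,
    n_permutations: int = 1000,
    master_seed: int = 0,
    log_base: float = 2.0,
) -> TEMatrix:
    """TE + permutation p-value for every ordered pair of gene rows.

    Each pair's permutation seed derives from (master_seed, source, target),
    so any pair's entry can be reproduced standalone and results do not
    depend on evaluation order.
    """
    genes = list(matrix.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    series = {g: matrix.loc[g].to_numpy(dtype=float) for g in genes}
    rows = []
    for src in genes:
        for tgt in genes:
            if src == tgt:
                continue
            seed = derive_pair_seed(master_seed, src, tgt)
            try:
                res = permutation_pvalue(
                    series[src],
                    series[tgt],
                    n_permutations=n_permutations,
                    seed=seed,
                    k=k,
                    l=l,
                    n_bins=n_bins,
                    log_base=log_base,
                )
            except ValueError as exc:
                raise ValueError(f"pair {src}->{tgt}: {exc}") from exc
            rows.append((src, tgt, res.observed_te, res.p_value))
    entries = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    return TEMatrix(entries, genes)


def one_way_screen(te_matrix: TEMatrix) -> EdgeList:
    """Keep the stronger direction of each unordered pair.

    On an exact TE tie the lexicographically smaller (source, target)
    ordering is kept. Output size is exactly n·(n−1)/2.
    """
    df = te_matrix.entries
    lookup = df.set_index(["source", "target"])
    rows = []
    genes = sorted(te_matrix.genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            fwd = lookup.loc[(a, b)]
            rev = lookup.loc[(b, a)]
            if fwd["te"] >= rev["te"]:  # tie -> lexicographic (a, b)
                rows.append((a, b, fwd["te"], fwd["p_value"]))
            else:
                rows.append((b, a, rev["te"], rev["p_value"]))
    return EdgeList(pd.DataFrame(rows, columns=_EDGE_COLUMNS), stage="one_way")


def pvalue_screen(edges: EdgeList, alpha: float = 0.001) -> EdgeList:
    """Keep edges with p-value strictly below alpha."""
    kept = edges.edges[edges.edges["p_value"] < alpha]
    return EdgeList(kept, stage="p_value")


def te_threshold_screen(edges: EdgeList, min_te: float = 0.5) -> EdgeList:
    """Keep edges with TE at or above min_te (inclusive bound, in bits)."""
    kept = edges.edges[edges.edges["te"] >= min_te]
    return EdgeList(kept, stage="te_threshold")


def _strongest_by(edges: EdgeList, group_col: str, tie_col: str, stage: str) -> EdgeList:
    df = edges.edges
    if df.empty:
        return EdgeList(df, stage=stage)
    # sort so the max-TE row (ties: lexicographically smallest partner) is first
    ordered = df.sort_values(
        [group_col, "te", tie_col], ascending=[True, False, True], kind="mergesort"
    )
    kept = ordered.groupby(group_col, sort=True).head(1)
    return EdgeList(kept, stage=stage)


def strongest_per_source(edges: EdgeList) -> EdgeList:
    """Each source gene's single maximum-TE outgoing edge."""
    return _strongest_by(edges, "source", "target", "strongest_outgoing")


def strongest_per_target(edges: EdgeList) -> EdgeList:
    """Each target gene's single maximum-TE incoming edge."""
    return _strongest_by(edges, "target", "source", "strongest_incoming")


def build_network(
    edges: EdgeList,
    sif_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> nx.DiGraph:
    """Directed graph over an edge list, optionally exported for Cytoscape.

    Nodes are exactly the genes incident to at least one edge. SIF lines are
    ``source<TAB>TE<TAB>target``; the TSV carries the full scored edges.
    """
    graph = nx.DiGraph()
    for row in edges.edges.itertuples(index=False):
        graph.add_edge(row.source, row.target, te=row.te, p_value=row.p_value)
    if sif_path is not None:
        write_sif(edges, sif_path)
    if tsv_path is not None:
        write_edge_tsv(edges, tsv_path)
    return graph


def write_sif(edges: EdgeList, path: str | Path) -> None:
    path = Path(path)
    try:
        with path.open("w") as fh:
            for row in edges.edges.itertuples(index=False):
                fh.write(f"{row.source}\tTE\t{row.target}\n")
    except OSError as exc:
        raise OSError(f"failed writing SIF to {path}: {exc}") from exc


def read_sif(path: str | Path) -> set[tuple[str, str]]:
    pairs = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            src, _rel, tgt = line.split("\t")
            pairs.add((src, tgt))
    return pairs


def write_edge_tsv(edges: EdgeList, path: str | Path) -> None:
    path = Path(path)
    out = edges.edges.copy()
    out["stage"] = edges.stage
    out.rename(columns={"te": "te_bits"}).to_csv(path, sep="\t", index=False)


def read_edge_tsv(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t")
    stage = df["stage"].iloc[0] if len(df) else "unscreened"
    df = df.rename(columns={"te_bits": "te"})
    return EdgeList(df[_EDGE_COLUMNS], stage=str(stage))
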