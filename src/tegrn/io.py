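"""File I/O, run configuration, and the end-to-end pipeline driver.

Expression matrices are plain TSV: first column gene identifiers, remaining
columns ordered time points. The run configuration is a flat ``key=value``
text file collecting every tunable default (bins, lags, smoothing window,
screening thresholds, permutation count, master seed) so a whole run is
reproducible from one small file plus the input matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from tegrn import preprocessing, screening_network, target_selection
from tegrn.preprocessing import SmoothingConfig

logger = logging.getLogger("tegrn")

__all__ = [
    "RunConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "PipelineResult",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Every tunable pipeline default, serializable to key=value text."""

    n_bins: int = 4
    k: int = 1
    l: int = 1
    log_base: float = 2.0
    window: int = 5
    boundary_policy: str = "shrink"
    min_std: float = 0.0
    n_clusters: int = 12
    fuzzifier: float = 2.0
    alpha: float = 0.001
    min_te: float = 0.5
    n_permutations: int = 1000
    seed: int = 0
    union_networks: bool = False

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: malformed config line {lineno}: {line!r}")
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in types:
                    raise ValueError(f"{path}: unknown config key {key!r} (line {lineno})")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(raw)
                elif isinstance(current, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × time-points TSV; rejects duplicates and non-numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene names {dup}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, column {col!r}"
            )
        numeric[col] = converted
    numeric.index.name = df.index.name or "gene"
    return numeric


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


@dataclass
class PipelineResult:
    """End-to-end run outputs plus per-stage edge counts."""

    config: RunConfig
    selected_genes: list[str]
    te_matrix: screening_network.TEMatrix
    one_way: screening_network.EdgeList
    significant: screening_network.EdgeList
    strong: screening_network.EdgeList
    strongest_outgoing: screening_network.EdgeList
    strongest_incoming: screening_network.EdgeList
    stage_counts: dict[str, int]


def _select_candidates(matrix, reference_gene, cfg) -> list[str]:
    fuzzy = target_selection.fuzzy_cmeans_cluster(
        matrix, n_clusters=cfg.n_clusters, fuzzifier=cfg.fuzzifier, seed=cfg.seed
    )
    cosine = target_selection.cosine_cluster(matrix, n_clusters=cfg.n_clusters)
    selected = target_selection.select_by_reference(fuzzy, cosine, reference_gene)
    return sorted(selected)


def run_pipeline(
    config: RunConfig,
    matrix: pd.DataFrame | str | Path,
    reference_gene: str | None = None,
    out_dir: str | Path | None = None,
    include_genes: set[str] | None = None,
    exclude_genes: set[str] | None = None,
) -> PipelineResult:
    """Smooth → filter → (select) → all-pairs TE → screening cascade → networks.

    When ``reference_gene`` is given, candidate genes are the intersection of
    the two pattern clusterings' reference clusters; otherwise every gene
    surviving the variability filter is analyzed. ``include_genes`` /
    ``exclude_genes`` are explicit curation lists applied after selection
    (genes are never dropped silently). With ``out_dir`` set, every
    intermediate edge list, both networks, the stage-count log and the
    effective configuration are written there.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = read_expression_matrix(matrix)
    cfg = config
    counts: dict[str, int] = {"input_genes": len(matrix)}

    smoothed = preprocessing.smooth_matrix(
        matrix, SmoothingConfig(window=cfg.window, boundary_policy=cfg.boundary_policy)
    )
    filtered, removed = preprocessing.filter_uninformative_genes(smoothed, min_std=cfg.min_std)
    counts["after_variability_filter"] = len(filtered)
    logger.info("variability filter removed %d genes", len(removed))

    if reference_gene is not None:
        if reference_gene not in filtered.index:
            raise ValueError(f"selection stage: reference gene {reference_gene!r} not in matrix")
        genes = _select_candidates(filtered, reference_gene, cfg)
    else:
        genes = sorted(filtered.index)
    if include_genes:
        genes = sorted(set(genes) | (include_genes & set(filtered.index)))
    if exclude_genes:
        genes = sorted(set(genes) - exclude_genes)
    counts["selected_genes"] = len(genes)
    logger.info("selected %d candidate genes", len(genes))
    selected = filtered.loc[genes]

    te_matrix = screening_network.all_pairs_te(
        selected,
        k=cfg.k,
        l=cfg.l,
        n_bins=cfg.n_bins,
        n_permutations=cfg.n_permutations,
        master_seed=cfg.seed,
        log_base=cfg.log_base,
    )
    counts["ordered_pairs"] = len(te_matrix.entries)

    one_way = screening_network.one_way_screen(te_matrix)
    counts["one_way"] = len(one_way)
    significant = screening_network.pvalue_screen(one_way, alpha=cfg.alpha)
    counts["p_value"] = len(significant)
    strong = screening_network.te_threshold_screen(significant, min_te=cfg.min_te)
    counts["te_threshold"] = len(strong)
    outgoing = screening_network.strongest_per_source(strong)
    counts["strongest_outgoing"] = len(outgoing)
    incoming = screening_network.strongest_per_target(strong)
    counts["strongest_incoming"] = len(incoming)
    for stage, value in counts.items():
        logger.info("stage %s: %d", stage, value)

    result = PipelineResult(
        config=cfg,
        selected_genes=genes,
        te_matrix=te_matrix,
        one_way=one_way,
        significant=significant,
        strong=strong,
        strongest_outgoing=outgoing,
        strongest_incoming=incoming,
        stage_counts=counts,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.save(out_dir / "run_config.txt")
    stages = {
        "all_pairs": result.te_matrix.to_edge_list(),
        "one_way": result.one_way,
        "p_value": result.significant,
        "te_threshold": result.strong,
        "strongest_outgoing": result.strongest_outgoing,
        "strongest_incoming": result.strongest_incoming,
    }
    for name, edge_list in stages.items():
        screening_network.write_edge_tsv(edge_list, out_dir / f"edges_{name}.tsv")
    for name in ("strongest_outgoing", "strongest_incoming"):
        screening_network.write_sif(stages[name], out_dir / f"network_{name}.sif")
    if result.config.union_networks:
        union = screening_network.EdgeList(
            pd.concat(
                [result.strongest_outgoing.edges, result.strongest_incoming.edges]
            ).drop_duplicates(["source", "target"]),
            stage="union",
        )
        screening_network.write_sif(union, out_dir / "network_union.sif")
        screening_network.write_edge_tsv(union, out_dir / "edges_union.tsv")
    with (out_dir / "stage_counts.tsv").open("w") as fh:
        fh.write("stage\tcount\n")
        for stage, value in result.stage_counts.items():
            fh.write(f"{stage}\t{value}\n")
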