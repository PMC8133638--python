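"""Config-driven orchestration: filter -> GCC -> candidates -> enrichment ->
network -> seed connectivity -> ortholog comparison -> exports.

Every stage writes its table under the output directory, the expensive GCC
profile is cached between runs (keyed by a hash of the upstream inputs and
parameters, so changing only the edge cutoff re-uses it), and a run report
echoes every effective parameter. Outputs are deterministic: identical
inputs and config give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeometric_enrichment, top_terms
from .gcc import GCCProfile, gcc_pairwise, gcc_seed_profile
from .io import (
    ExpressionMatrix,
    GOAnnotationMap,
    OrthologTable,
    SeedGeneSet,
    drop_constant_genes,
    filter_expressed,
    read_expression,
    read_go_map,
    read_ortholog_table,
    read_seed_list,
)
from .network import build_network, compute_kphq, export_network, collapse_orthologs

logger = logging.getLogger("seedcoex")

__all__ = ["RunConfig", "RunReport", "run_single_species", "run_comparison"]


@dataclass
class RunConfig:
    """Parameters of one species' analysis; defaults are the standard ones
    (FPKM >= 2 in >= 2 samples, top-500 or GCC >= 0.8 candidates, edge
    cutoff 0.6, top 10 enrichment terms)."""

    expression_path: str | None = None
    seeds_path: str | None = None
    go_map_path: str | None = None
    out_dir: str = "seedcoex_out"
    species: str = "species"
    min_fpkm: float = 2.0
    min_samples: int = 2
    candidate_mode: str = "top_k"  # or "threshold"
    top_k: int = 500
    min_gcc: float = 0.8
    edge_cutoff: float = 0.6
    log_transform: bool = False
    permissive_seeds: bool = False
    top_terms_n: int = 10
    network_formats: tuple[str, ...] = ("graphml", "edge_tsv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "network_formats" in d:
            d["network_formats"] = tuple(d["network_formats"])
        return cls(**d)

    def params_dict(self) -> dict:
        d = asdict(self)
        d["network_formats"] = list(self.network_formats)
        return d


@dataclass
class RunReport:
    """Summary of one run: effective parameters plus stage outcomes."""

    species: str
    params: dict
    n_genes_input: int
    n_genes_filtered: int
    n_constant_dropped: int
    seeds_used: list[str]
    union_size: int
    n_network_nodes: int
    n_network_edges: int
    kphq_summary: pd.DataFrame
    enrichment_top: pd.DataFrame | None
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        # out_dir is excluded so reports from identical inputs compare equal
        params = {k: v for k, v in self.params.items() if k != "out_dir"}
        d = {
            "tool": "seedcoex",
            "version": __version__,
            "species": self.species,
            "params": params,
            "n_genes_input": self.n_genes_input,
            "n_genes_filtered": self.n_genes_filtered,
            "n_constant_dropped": self.n_constant_dropped,
            "seeds_used": self.seeds_used,
            "union_size": self.union_size,
            "n_network_nodes": self.n_network_nodes,
            "n_network_edges": self.n_network_edges,
            "kphq_summary": self.kphq_summary.to_dict(orient="records"),
            "enrichment_top": (
                None if self.enrichment_top is None else self.enrichment_top.to_dict(orient="records")
            ),
            "files": self.files,
        }
        return json.dumps(d, indent=2, sort_keys=True)


# parameters echoed into each stage's table header: only those that can
# change the stage's content, so downstream-only parameter changes leave
# upstream tables byte-identical
_STAGE_PARAMS = {
    "candidates": ("species", "min_fpkm", "min_samples", "log_transform",
                   "candidate_mode", "top_k", "min_gcc"),
    "enrichment": ("species", "min_fpkm", "min_samples", "log_transform",
                   "candidate_mode", "top_k", "min_gcc", "top_terms_n"),
    "kphq": ("species", "min_fpkm", "min_samples", "log_transform",
             "candidate_mode", "top_k", "min_gcc", "edge_cutoff"),
}


def _metadata_header(params: dict, stage: str) -> str:
    keys = _STAGE_PARAMS[stage]
    items = " ".join(f"{k}={params[k]}" for k in keys)
    return f"# seedcoex {__version__} {items}\n"


def _write_table(df: pd.DataFrame, path: Path, params: dict, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(params, stage))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _profile_cache_key(matrix: ExpressionMatrix, seeds: SeedGeneSet, params: dict) -> str:
    """Hash of everything upstream of the GCC stage."""
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(matrix.df, index=True).to_numpy().tobytes())
    h.update(",".join(matrix.sample_ids).encode())
    h.update(",".join(seeds.seeds).encode())
    upstream = {k: params[k] for k in ("min_fpkm", "min_samples", "log_transform")}
    h.update(json.dumps(upstream, sort_keys=True).encode())
    return h.hexdigest()


def run_single_species(
    config: RunConfig,
    matrix: ExpressionMatrix | None = None,
    seeds: SeedGeneSet | None = None,
    annotations: GOAnnotationMap | None = None,
) -> RunReport:
    """Run the full single-species analysis.

    Inputs may be passed in memory or read from the paths in ``config``.
    Any stage error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params_dict()
    files: dict[str, str] = {}

    stage = "read_inputs"
    try:
        if matrix is None:
            matrix = read_expression(config.expression_path)
        if seeds is None:
            seeds = read_seed_list(config.seeds_path)
        if annotations is None and config.go_map_path:
            annotations = read_go_map(config.go_map_path)

        stage = "filter"
        n_input = matrix.n_genes
        filtered = filter_expressed(matrix, config.min_fpkm, config.min_samples)
        if config.log_transform:
            filtered = filtered.log2_transform()
        n_filtered = filtered.n_genes
        nonconstant = drop_constant_genes(filtered)
        n_constant = n_filtered - nonconstant.n_genes
        seeds_used = seeds.reconcile(nonconstant, permissive=config.permissive_seeds)

        stage = "gcc_profile"
        cache_key = _profile_cache_key(nonconstant, seeds_used, params)
        profile_path = out / "gcc_profile.tsv"
        key_path = out / "gcc_profile.key"
        profile = None
        if profile_path.exists() and key_path.exists() and key_path.read_text().strip() == cache_key:
            logger.info("INFO gcc_profile_cache_hit key=%s", cache_key[:12])
            profile = GCCProfile.read_tsv(profile_path)
        if profile is None:
            profile = gcc_seed_profile(nonconstant, seeds_used)
            profile.write_tsv(profile_path)
            key_path.write_text(cache_key + "\n")
        files["gcc_profile"] = str(profile_path)

        stage = "candidates"
        from .network import extract_candidates

        candidates = extract_candidates(
            profile, mode=config.candidate_mode, k=config.top_k, min_gcc=config.min_gcc
        )
        cand_path = out / "candidates.tsv"
        _write_table(candidates.to_frame(), cand_path, params, "candidates")
        files["candidates"] = str(cand_path)
        union = sorted(candidates.union)
        union_path = out / "union_set.txt"
        union_path.write_text("".join(g + "\n" for g in union))
        files["union_set"] = str(union_path)

        stage = "enrichment"
        enr_top = None
        if annotations is not None:
            background = set(nonconstant.gene_ids) & annotations.annotated_genes
            annotated_candidates = set(union) & annotations.annotated_genes
            if annotated_candidates:
                rows = hypergeometric_enrichment(annotated_candidates, annotations, background)
                enr_all = top_terms(rows, n=len(rows))
                enr_path = out / "enrichment.tsv"
                _write_table(enr_all, enr_path, params, "enrichment")
                files["enrichment"] = str(enr_path)
                enr_top = top_terms(rows, n=config.top_terms_n)

        stage = "network"
        node_set = sorted(set(union) | set(seeds_used.seeds))
        pairwise = gcc_pairwise(nonconstant, node_set)
        net = build_network(
            nonconstant, node_set, seeds=seeds_used, cutoff=config.edge_cutoff, pairwise=pairwise
        )
        for fmt in config.network_formats:
            ext = {"graphml": "graphml", "sif": "sif", "edge_tsv": "edges.tsv"}[fmt]
            net_path = out / f"network.{ext}"
            export_network(net, net_path, format=fmt)
            files[f"network_{fmt}"] = str(net_path)

        stage = "kphq"
        conn = compute_kphq(net, seeds_used)
        kphq_path = out / "kphq.tsv"
        _write_table(conn.table, kphq_path, params, "kphq")
        files["kphq"] = str(kphq_path)
        summary = conn.summary()
        summary_path = out / "kphq_summary.tsv"
        _write_table(summary, summary_path, params, "kphq")
        files["kphq_summary"] = str(summary_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        species=config.species,
        params=params,
        n_genes_input=n_input,
        n_genes_filtered=n_filtered,
        n_constant_dropped=n_constant,
        seeds_used=seeds_used.seeds,
        union_size=len(union),
        n_network_nodes=net.number_of_nodes(),
        n_network_edges=net.number_of_edges(),
        kphq_summary=summary,
        enrichment_top=enr_top,
        files={k: Path(v).name for k, v in files.items()},
    )
    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report


@dataclass
class ComparisonReport:
    """Side-by-side cross-species comparison."""

    nonredundant_sizes: dict[str, int]
    kphq_table: pd.DataFrame  # threshold grid x species fractions
    presence: pd.DataFrame


def run_comparison(
    reports: dict[str, RunReport],
    connectivity: dict[str, "pd.DataFrame"],
    union_sets: dict[str, set[str]],
    orthologs: OrthologTable,
    transcriptomes: dict[str, set[str]] | None = None,
    out_dir: str | None = None,
    thresholds=None,
) -> ComparisonReport:
    """Compare >= 2 completed species runs on a shared k_PhQ threshold grid.

    ``connectivity`` maps species -> the per-node k_phq table of its run;
    ``union_sets`` maps species -> the gene set to collapse across species.
    Species without any seed are excluded with a warning.
    """
    from .network import ConnectivityTable

    usable = {}
    for sp, rep in reports.items():
        if not rep.seeds_used:
            logger.warning("WARN species_excluded no seeds species=%s", sp)
            continue
        usable[sp] = rep
    nonredundant, presence = collapse_orthologs(
        {sp: union_sets[sp] for sp in usable}, orthologs, transcriptomes
    )
    max_seeds = max(len(rep.seeds_used) for rep in usable.values())
    grid = list(thresholds) if thresholds is not None else list(range(1, max_seeds + 1))
    cols = {"k_phq_min": grid}
    for sp, rep in usable.items():
        ct = ConnectivityTable(connectivity[sp], n_seeds=len(rep.seeds_used))
        cols[f"{sp}_fraction_all"] = [ct.fraction_at_least(t, "all") for t in grid]
        cols[f"{sp}_fraction_nonseed"] = [ct.fraction_at_least(t, "nonseed") for t in grid]
    table = pd.DataFrame(cols)
    sizes = {sp: len(s) for sp, s in nonredundant.items()}
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        table.to_csv(outp / "kphq_comparison.tsv", sep="\t", index=False, float_format="%.10g")
        presence.to_csv(outp / "orthogroup_presence.tsv", sep="\t")
        pd.Series(sizes, name="nonredundant_size").rename_axis("species").to_csv(
            outp / "nonredundant_sizes.tsv", sep="\t"
        )
    return ComparisonReport(sizes, table, presence)
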