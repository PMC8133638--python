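"""End-to-end benchmarks on synthetic data with planted truth.

Two study-condition benchmarks are provided:

* :func:`planted_partner_recovery` — can top-k candidate extraction recover
  each seed's planted module partners from a realistic transcriptome
  (5,000 background genes by default)?
* :func:`architecture_discrimination` — does the seed-connectivity fraction
  at majority threshold separate a single dense seed module
  (holoparasite-like) from seeds split across two modules
  (hemiparasite-like)? Run over seeded replicates at a reduced
  1,000-background-gene scale.
"""

from __future__ import annotations

import pandas as pd

from .gcc import gcc_seed_profile
from .io import SeedGeneSet, drop_constant_genes, filter_expressed
from .network import build_network, compute_kphq, extract_candidates
from .simulate import SpeciesData, SyntheticConfig, generate_expression, generate_multispecies

__all__ = [
    "planted_partner_recovery",
    "majority_fraction",
    "architecture_discrimination",
]


def planted_partner_recovery(
    config: SyntheticConfig | None = None, k: int = 500
) -> dict[str, float]:
    """Per-seed recall of planted module partners by top-k extraction.

    Returns seed id -> fraction of the seed's same-module partners present
    in its top-k candidate list.
    """
    if config is None:
        config = SyntheticConfig()
    matrix, truth = generate_expression(config)
    filtered = drop_constant_genes(filter_expressed(matrix))
    seeds = SeedGeneSet(truth.seeds).reconcile(filtered)
    profile = gcc_seed_profile(filtered, seeds)
    candidates = extract_candidates(profile, mode="top_k", k=k)
    recovery = {}
    for s in seeds.seeds:
        partners = truth.partners_of(s)
        hits = {g for g, _ in candidates.per_seed[s]}
        recovery[s] = len(partners & hits) / len(partners)
    return recovery


def majority_fraction(
    species_data: SpeciesData, k: int = 500, cutoff: float = 0.6
) -> tuple[float, int, int]:
    """Fraction of network nodes with k_PhQ >= majority of the seed count.

    Majority means strictly more than half: floor(n_seeds / 2) + 1.
    Returns (fraction over all retained nodes, node count, majority used).
    """
    filtered = drop_constant_genes(filter_expressed(species_data.matrix))
    seeds = species_data.seeds.reconcile(filtered)
    profile = gcc_seed_profile(filtered, seeds)
    candidates = extract_candidates(profile, mode="top_k", k=k)
    nodes = sorted(candidates.union | set(seeds.seeds))
    net = build_network(filtered, nodes, seeds=seeds, cutoff=cutoff)
    conn = compute_kphq(net, seeds)
    majority = len(seeds.seeds) // 2 + 1
    return conn.fraction_at_least(majority), net.number_of_nodes(), majority


def architecture_discrimination(
    n_replicates: int = 100,
    n_background: int = 1000,
    base_seed: int = 0,
    k: int = 500,
    cutoff: float = 0.6,
) -> pd.DataFrame:
    """Dense vs split seed-module scenarios over seeded replicates.

    Each replicate generates matched holoparasite-like ("dense": all seeds
    in one module) and hemiparasite-like ("split": seeds divided between two
    modules) datasets with identical gene counts, noise and seed number,
    runs the full candidate -> network -> k_PhQ pipeline on both, and
    records the majority-connectivity fractions. Columns: replicate,
    fraction_dense, fraction_split, dense_wins.
    """
    rows = []
    for rep in range(n_replicates):
        config = SyntheticConfig(n_background=n_background, rng_seed=base_seed + rep)
        data = generate_multispecies(config, scenarios={"dense_sp": "dense", "split_sp": "split"})
        f_dense, _, _ = majority_fraction(data.species["dense_sp"], k=k, cutoff=cutoff)
        f_split, _, _ = majority_fraction(data.species["split_sp"], k=k, cutoff=cutoff)
        rows.append((rep, f_dense, f_split, f_dense > f_split))
    return pd.DataFrame(rows, columns=["replicate", "fraction_dense", "fraction_split", "dense_wins"])
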