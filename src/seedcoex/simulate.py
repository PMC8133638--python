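"""Synthetic expression data with planted coexpression structure.

Emulates a stage-structured developmental RNA-seq design (by default 7
stages — imbibed seed through established parasite — with 3 replicates
each) in which groups of genes share a latent stage profile. A module gene
g sampled at stage t has

    value(g, s) = exp(a_g + b_g * L_m(t(s)) + eps),   eps ~ Normal(0, sd^2)

with b_g > 0, i.e. multiplicative log-normal noise around a gene-specific
scaling of the module's latent profile L_m (standardized to mean 0,
variance 1 across stages). The log-normal form mimics FPKM positivity and
right skew and keeps the within-module correlation analytic:

    corr(log g1, log g2) = b1*b2 / sqrt((b1^2 + sd^2) * (b2^2 + sd^2))

Background genes are independent log-normal draws; below-filter genes have
fewer than two samples >= 2 by construction; optional outliers multiply
random cells by a large factor. Seed (pathway) genes are ordinary module
members, so their coexpression neighborhood is the module — the ground
truth every pipeline stage is tested against.

All randomness flows from one integer seed through a single generator
stream in a fixed draw order: identical (config, seed) gives byte-identical
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GOAnnotationMap, OrthologTable, SeedGeneSet

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SpeciesData",
    "MultiSpeciesData",
    "generate_expression",
    "generate_multispecies",
    "inject_outliers",
    "expected_log_correlation",
]


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    ``profile`` selects the latent stage curve (an integer; distinct
    integers give distinct, weakly-correlated curves). ``n_seeds`` of the
    module's genes are designated seed (pathway) genes.
    """

    size: int = 50
    profile: int = 0
    noise_sd: float = 0.33
    n_seeds: int = 0

    def validate(self):
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.n_seeds <= self.size:
            raise ValueError("n_seeds must lie in [0, size]")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the desk-scale study conditions.

    7 stages x 3 replicates, three 50-gene modules (the first carrying the
    7 seed genes), 5,000 background genes, 25 below-filter genes, log-noise
    sd 0.33 (within-module latent correlation ~0.9).
    """

    n_stages: int = 7
    replicates_per_stage: int = 3
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(size=50, profile=0, n_seeds=7),
            ModuleSpec(size=50, profile=1),
            ModuleSpec(size=50, profile=2),
        ]
    )
    n_background: int = 5000
    n_below_filter: int = 25
    outlier_rate: float = 0.0
    outlier_magnitude: float = 20.0
    baseline_mean: float = 2.5
    baseline_sd: float = 0.5
    slope_low: float = 0.8
    slope_high: float = 1.2
    background_sd: float = 0.5
    species: str = "SP"
    rng_seed: int = 0

    def validate(self):
        if self.n_stages < 2 or self.replicates_per_stage < 1:
            raise ValueError("need >= 2 stages and >= 1 replicate per stage")
        if self.n_background < 0 or self.n_below_filter < 0:
            raise ValueError("gene counts must be nonnegative")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier rate must lie in [0, 1)")
        if not self.modules:
            raise ValueError("at least one module required")
        for m in self.modules:
            m.validate()
        if not 0 < self.slope_low <= self.slope_high:
            raise ValueError("slopes must satisfy 0 < low <= high")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "modules" in d:
            d["modules"] = [ModuleSpec(**m) for m in d["modules"]]
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Everything needed to predict the generated correlation structure."""

    module_of: dict[str, int | str]  # gene -> module index, "background", "below_filter"
    seeds: list[str]
    latent_profiles: np.ndarray  # modules x stages, standardized
    baseline: dict[str, float]  # a_g
    slope: dict[str, float]  # b_g (module genes only)
    below_filter: list[str]
    stage_of_sample: list[int]
    outlier_positions: list[tuple[str, str]] = field(default_factory=list)
    config: SyntheticConfig | None = None

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def partners_of(self, seed: str) -> set[str]:
        """Planted coexpression partners: same-module genes, seed excluded."""
        m = self.module_of[seed]
        return {g for g in self.module_members(m) if g != seed}

    def write_tsv(self, path) -> None:
        rows = [
            (
                g,
                str(m),
                int(g in set(self.seeds)),
                self.baseline.get(g, float("nan")),
                self.slope.get(g, float("nan")),
            )
            for g, m in self.module_of.items()
        ]
        pd.DataFrame(
            rows, columns=["gene_id", "module", "is_seed", "baseline", "slope"]
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _latent_profile(profile: int, n_stages: int) -> np.ndarray:
    """Deterministic standardized stage curve; distinct ids -> distinct shapes."""
    t = np.linspace(0.0, 1.0, n_stages)
    k = profile % 6
    if k == 0:
        curve = t  # rising (e.g. haustorium program)
    elif k == 1:
        curve = np.exp(-((t - 0.5) ** 2) / 0.045)  # mid peak
    elif k == 2:
        curve = 1.0 - t  # falling (e.g. seed program)
    elif k == 3:
        curve = np.sin(2 * np.pi * t)
    elif k == 4:
        curve = np.exp(-((t - 0.15) ** 2) / 0.03)  # early peak
    else:
        curve = np.exp(-((t - 0.85) ** 2) / 0.03)  # late peak
    curve = curve - curve.mean()
    sd = curve.std()
    if sd == 0:
        raise ValueError("degenerate latent profile")
    return curve / sd


def expected_log_correlation(b1: float, b2: float, noise_sd: float) -> float:
    """Analytic within-module Pearson correlation of log-values."""
    return b1 * b2 / np.sqrt((b1**2 + noise_sd**2) * (b2**2 + noise_sd**2))


def generate_expression(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one species' matrix plus its ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sp = config.species
    n_stages, reps = config.n_stages, config.replicates_per_stage
    stage_of_sample = [t for t in range(n_stages) for _ in range(reps)]
    sample_ids = [f"stage{t}_rep{r}" for t in range(n_stages) for r in range(reps)]
    n_samples = len(sample_ids)

    profiles = np.vstack([_latent_profile(m.profile, n_stages) for m in config.modules])

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    module_of: dict[str, int | str] = {}
    baseline: dict[str, float] = {}
    slope: dict[str, float] = {}
    seeds: list[str] = []

    stage_idx = np.array(stage_of_sample)
    for mi, mod in enumerate(config.modules):
        latent = profiles[mi][stage_idx]
        a = rng.normal(config.baseline_mean, config.baseline_sd, size=mod.size)
        b = rng.uniform(config.slope_low, config.slope_high, size=mod.size)
        eps = rng.normal(0.0, mod.noise_sd, size=(mod.size, n_samples))
        log_vals = a[:, None] + b[:, None] * latent[None, :] + eps
        blocks.append(np.exp(log_vals))
        for gi in range(mod.size):
            if gi < mod.n_seeds:
                gid = f"{sp}_SEED_M{mi}_{gi:02d}"
                seeds.append(gid)
            else:
                gid = f"{sp}_M{mi}_{gi:03d}"
            gene_ids.append(gid)
            module_of[gid] = mi
            baseline[gid] = float(a[gi])
            slope[gid] = float(b[gi])

    if config.n_background:
        a = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_background)
        eps = rng.normal(0.0, config.background_sd, size=(config.n_background, n_samples))
        blocks.append(np.exp(a[:, None] + eps))
        for gi in range(config.n_background):
            gid = f"{sp}_BG{gi:05d}"
            gene_ids.append(gid)
            module_of[gid] = "background"
            baseline[gid] = float(a[gi])

    below: list[str] = []
    if config.n_below_filter:
        low = rng.uniform(0.0, 1.9, size=(config.n_below_filter, n_samples))
        spike_col = rng.integers(0, n_samples, size=config.n_below_filter)
        spike_val = rng.uniform(2.0, 6.0, size=config.n_below_filter)
        for gi in range(config.n_below_filter):
            if gi % 2 == 0:  # half get exactly one sample >= 2: still below filter
                low[gi, spike_col[gi]] = spike_val[gi]
            gid = f"{sp}_LOW{gi:03d}"
            gene_ids.append(gid)
            module_of[gid] = "below_filter"
            below.append(gid)
        blocks.append(low)

    values = np.vstack(blocks)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = SyntheticTruth(
        module_of=module_of,
        seeds=seeds,
        latent_profiles=profiles,
        baseline=baseline,
        slope=slope,
        below_filter=below,
        stage_of_sample=stage_of_sample,
        config=config,
    )
    if config.outlier_rate > 0:
        matrix, truth = inject_outliers(
            matrix, truth, config.outlier_rate, config.outlier_magnitude, rng=rng
        )
    return matrix, truth


def inject_outliers(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    rate: float,
    magnitude: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multiply a Bernoulli(rate) selection of cells by ``magnitude``.

    Positions are recorded in the returned truth (the inputs are not
    mutated). Rate 0 returns the inputs unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return matrix, truth
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(matrix.values.shape) < rate
    values = matrix.values.copy()
    values[mask] *= magnitude
    out = ExpressionMatrix(pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids))
    positions = [
        (matrix.gene_ids[i], matrix.sample_ids[j]) for i, j in np.argwhere(mask)
    ]
    new_truth = SyntheticTruth(
        module_of=truth.module_of,
        seeds=truth.seeds,
        latent_profiles=truth.latent_profiles,
        baseline=truth.baseline,
        slope=truth.slope,
        below_filter=truth.below_filter,
        stage_of_sample=truth.stage_of_sample,
        outlier_positions=list(truth.outlier_positions) + positions,
        config=truth.config,
    )
    return out, new_truth


# ---------------------------------------------------------------------------
# multi-species scenarios


@dataclass
class SpeciesData:
    matrix: ExpressionMatrix
    truth: SyntheticTruth
    seeds: SeedGeneSet
    annotations: GOAnnotationMap
    scenario: str


@dataclass
class MultiSpeciesData:
    species: dict[str, SpeciesData]
    orthologs: OrthologTable


PHOTOSYNTHESIS_TERM = "GO:0015979"
_GENERIC_TERMS = [f"GO:GEN{i:02d}" for i in range(12)]


def _scenario_modules(base: SyntheticConfig, scenario: str) -> list[ModuleSpec]:
    """Module layout per architecture scenario, same totals either way.

    ``dense``: every seed in module 0 (holoparasite-like single dense
    module). ``split``: seeds divided between modules 0 and 1, module 1
    standing in for a photosynthesis module (hemiparasite-like).
    """
    mods = [ModuleSpec(m.size, m.profile, m.noise_sd, 0) for m in base.modules]
    n_seeds = sum(m.n_seeds for m in base.modules)
    if scenario == "dense":
        mods[0].n_seeds = n_seeds
    elif scenario == "split":
        if len(mods) < 2:
            raise ValueError("split scenario needs >= 2 modules")
        mods[0].n_seeds = (n_seeds + 1) // 2
        mods[1].n_seeds = n_seeds - mods[0].n_seeds
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return mods


def _annotate(truth: SyntheticTruth, rng: np.random.Generator, scenario: str) -> GOAnnotationMap:
    """Module-specific terms plus generic background terms.

    Module 0 carries a redox-flavored term block; in the split scenario the
    second seed module carries the photosynthesis term, so enrichment of
    candidate sets can discriminate the architectures.
    """
    gene_to_terms: dict[str, set[str]] = {}
    labels = {
        "GO:MOD0": "oxidation-reduction process",
        "GO:MOD1": "photosynthesis" if scenario == "split" else "defense response",
        "GO:MOD2": "protein phosphorylation",
        PHOTOSYNTHESIS_TERM: "photosynthesis",
    }
    for gene, m in truth.module_of.items():
        terms: set[str] = set()
        if isinstance(m, int):
            terms.add(f"GO:MOD{m}")
            if scenario == "split" and m == 1:
                terms.add(PHOTOSYNTHESIS_TERM)
        # generic terms keep the universe realistic; ~60% of genes annotated
        if rng.random() < 0.6:
            n_extra = int(rng.integers(1, 4))
            terms.update(rng.choice(_GENERIC_TERMS, size=n_extra, replace=False))
        if terms:
            gene_to_terms[gene] = terms
    return GOAnnotationMap(gene_to_terms, labels)


def generate_multispecies(
    config: SyntheticConfig,
    scenarios: dict[str, str] | None = None,
) -> MultiSpeciesData:
    """Generate linked per-species datasets plus the ortholog table.

    ``scenarios`` maps species id -> "dense" | "split"; the default is one
    holoparasite-like and two hemiparasite-like species. Counterpart genes
    (same module slot, or same background index) share an orthogroup across
    species.
    """
    config.validate()
    if scenarios is None:
        scenarios = {"holo": "dense", "hemiA": "split", "hemiB": "split"}
    rng = np.random.default_rng(config.rng_seed)
    species_out: dict[str, SpeciesData] = {}
    ortho_rows: list[tuple[str, str, str]] = []
    for sp, scenario in scenarios.items():
        sp_conf = SyntheticConfig.from_dict(config.to_dict())
        sp_conf.species = sp
        sp_conf.modules = _scenario_modules(config, scenario)
        matrix, truth = generate_expression(sp_conf, rng=rng)
        annotations = _annotate(truth, rng, scenario)
        seed_set = SeedGeneSet(truth.seeds)
        species_out[sp] = SpeciesData(matrix, truth, seed_set, annotations, scenario)
        # orthogroups by structural slot: module index x within-module rank,
        # independent of which slots are seeds in this species
        for gid, m in truth.module_of.items():
            if isinstance(m, int):
                rank = sorted(truth.module_members(m)).index(gid)
                ortho_rows.append((sp, gid, f"OG_M{m}_{rank:03d}"))
            elif m == "background":
                ortho_rows.append((sp, gid, f"OG_BG{gid.split('BG')[-1]}"))
    orthologs = OrthologTable(pd.DataFrame(ortho_rows, columns=["species", "gene", "orthogroup"]))
    return MultiSpeciesData(species_out, orthologs)
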