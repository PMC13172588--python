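"""Synthetic study generator.

Produces every input the analysis pipeline consumes, with planted ground
truth and full determinism under a single seed:

* a proteome whose proteins carry known numbers of polyproline (PP)
  motifs, planted as proline runs inserted into proline-free background
  sequence so that a rescan always reproduces the planted count;
* paired RNA-seq / Ribo-seq negative-binomial count matrices for a
  control and a treated condition, where the treated ribosome-footprint
  mean of a responsive gene is repressed by 2^(-beta * PP-count) —
  emulating motif-dependent translational inhibition under prolyl-tRNA
  synthetase blockade;
* metabolite trajectory panels for several ordered-group cohorts with
  planted shapes and a shared progressively-increasing subset;
* gene-set collections with a metastasis-style set over-represented among
  responsive genes and one pathway planted as enriched among the true
  translationally repressed genes.

One global seed expands into fixed per-component child seeds, so each
sub-generator is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import GeneSetCollection
from .trajectory_cluster import MetabolitePanel
from .translation_efficiency import CountsExperiment

__all__ = [
    "SimConfig",
    "ProteomeRecord",
    "SyntheticStudy",
    "nb_counts",
    "generate_proteome",
    "simulate_counts",
    "simulate_panels",
    "generate_gene_sets",
    "generate_study",
]

_AA_NO_P = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # background excludes proline

# fixed child-seed offsets: proteome, counts, panels, gene sets
_CHILD = {"proteome": 0, "counts": 1, "panels": 2, "gene_sets": 3}

SHAPES = ("increasing", "decreasing", "peaked", "valley", "flat")

#: cross-cohort progressively increasing metabolites planted by default
DEFAULT_SHARED = (
    "proline", "serine", "alanine", "histidine", "threonine",
    "methionine", "isoleucine", "glycine", "valine", "leucine",
)


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _CHILD[component]]))


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration (defaults define the study conditions)."""

    # proteome + counts
    n_genes: int = 2000
    mean_length: int = 400
    pp_bin_probs: tuple[float, ...] = (0.66, 0.15, 0.08, 0.05, 0.06)
    n_reps: int = 3
    baseline_mu: float = 500.0
    dispersion: float = 0.1
    beta: float = 1.0
    frac_responsive: float = 0.3
    lib_size: float | None = None  # defaults to n_genes * baseline_mu

    # trajectory panels
    cohorts: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "cohort1": ("control", "NM", "EHM"),
            "mouse": ("week2", "week3", "week4", "week5"),
        }
    )
    n_metabolites: int = 70
    shared_increasing: tuple[str, ...] = DEFAULT_SHARED
    shape_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "increasing": 0.25, "decreasing": 0.25, "peaked": 0.25, "valley": 0.25,
        }
    )
    amplitude: float = 1.2
    noise_sd: float = 0.3
    n_panel_reps: int = 6

    # gene sets
    metastasis_size: int = 300
    metastasis_weight: float = 5.0
    n_pathways: int = 5
    pathway_size: int = 50
    planted_fraction: float = 0.7

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.mean_length <= 0 or self.n_reps <= 0:
            raise ValueError("counts and sizes must be strictly positive")
        if self.n_metabolites <= 0 or self.n_panel_reps <= 0 or self.baseline_mu <= 0:
            raise ValueError("counts and sizes must be strictly positive")
        probs = np.asarray(self.pp_bin_probs, dtype=float)
        if probs.size != 5 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("pp_bin_probs must be 5 non-negative values summing to 1")
        if self.dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise sd must be non-negative")
        if not 0 <= self.frac_responsive <= 1:
            raise ValueError("frac_responsive must lie in [0, 1]")
        for shape in self.shape_probs:
            if shape not in SHAPES:
                raise ValueError(f"unknown trajectory shape {shape!r}")

    @property
    def effective_lib_size(self) -> float:
        return self.lib_size if self.lib_size is not None else self.n_genes * self.baseline_mu

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ProteomeRecord:
    gene: str
    sequence: str
    pp_count: int
    responsive: bool


@dataclass
class SyntheticStudy:
    config: SimConfig
    proteome: list[ProteomeRecord]
    counts: CountsExperiment
    panels: dict[str, MetabolitePanel]
    gene_sets: GeneSetCollection
    truth: dict


def nb_counts(
    rng: np.random.Generator, mu, dispersion: float, size=None
) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu(1 + dispersion*mu).

    ``dispersion`` is the NB dispersion phi >= 0; phi = 0 degenerates to
    Poisson.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    mu = np.asarray(mu, dtype=float)
    if (mu < 0).any():
        raise ValueError("mean must be non-negative")
    if dispersion == 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mu)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# proteome


def _planted_sequence(
    rng: np.random.Generator, length: int, pp_count: int
) -> str:
    """Random proline-free sequence with proline runs planting pp_count PP motifs.

    Runs of length r contribute r-1 overlapping PP each; runs are inserted
    at distinct cut points of the background so they never merge, keeping
    the rescanned count equal to the planted one.
    """
    runs: list[int] = []
    remaining = pp_count
    while remaining > 0:
        contrib = int(rng.integers(1, min(remaining, 3) + 1))
        runs.append(contrib + 1)
        remaining -= contrib
    bg_len = max(length - sum(runs), len(runs) + 1)
    bg = rng.choice(_AA_NO_P, size=bg_len)
    if not runs:
        return "".join(bg)
    cuts = np.sort(rng.choice(np.arange(1, bg_len), size=len(runs), replace=False))
    parts: list[str] = []
    prev = 0
    for cut, run in zip(cuts, runs):
        parts.append("".join(bg[prev:cut]))
        parts.append("P" * run)
        prev = cut
    parts.append("".join(bg[prev:]))
    return "".join(parts)


def generate_proteome(config: SimConfig) -> list[ProteomeRecord]:
    """Proteome with planted PP-motif content and responsiveness flags.

    Each gene draws a PP bin from ``pp_bin_probs`` (bin ">=4" spreads over
    4-8 motifs); PP-containing genes are responsive with probability
    ``frac_responsive``.
    """
    rng = _rng(config.seed, "proteome")
    records: list[ProteomeRecord] = []
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        bin_idx = int(rng.choice(5, p=config.pp_bin_probs))
        if bin_idx < 4:
            pp = bin_idx
        else:
            pp = 4 + min(int(rng.geometric(0.5)) - 1, 4)
        length = max(50, int(round(rng.normal(config.mean_length, 0.2 * config.mean_length))))
        seq = _planted_sequence(rng, length, pp)
        responsive = pp >= 1 and rng.random() < config.frac_responsive
        records.append(
            ProteomeRecord(gene=f"g{i + 1:0{width}d}", sequence=seq, pp_count=pp,
                           responsive=responsive)
        )
    return records


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimConfig, proteome: Sequence[ProteomeRecord]) -> CountsExperiment:
    """Paired RNA/RPF NB counts for control and treated conditions.

    Per-gene expected expression mu_g is lognormal, rescaled so every
    library's expected total equals ``lib_size``; RNA counts are
    identically distributed across conditions, while the treated RPF mean
    of a responsive gene is multiplied by t_g = 2^(-beta * PP-count).
    The treated RPF library is deliberately not renormalized, so its total
    reflects the repressed mass (within 10% of lib_size at the default
    configuration).
    """
    rng = _rng(config.seed, "counts")
    genes = [r.gene for r in proteome]
    n = len(genes)
    w = rng.lognormal(mean=0.0, sigma=0.8, size=n)
    mu = w / w.sum() * config.effective_lib_size
    t = np.array(
        [2.0 ** (-config.beta * r.pp_count) if r.responsive else 1.0 for r in proteome]
    )

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for assay in ("rna", "rpf"):
        for cond in ("control", "treated"):
            for rep in range(1, config.n_reps + 1):
                mean = mu * t if (assay == "rpf" and cond == "treated") else mu
                sample = f"{assay}_{cond}_{rep}"
                counts[sample] = nb_counts(rng, mean, config.dispersion)
                meta_rows.append((sample, assay, cond, rep))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "assay", "condition", "replicate"]
    ).set_index("sample")
    return CountsExperiment(counts=counts_df, metadata=meta)


# ---------------------------------------------------------------------------
# trajectory panels


def shape_template(shape: str, groups: int, amplitude: float) -> np.ndarray:
    """Noise-free group-mean trajectory on the z-like scale [-amplitude, amplitude]."""
    if groups < 3:
        raise ValueError("monotone trajectory shapes need at least 3 ordered groups")
    t = np.linspace(0.0, 1.0, groups)
    if shape == "increasing":
        return amplitude * (2 * t - 1)
    if shape == "decreasing":
        return amplitude * (1 - 2 * t)
    if shape == "peaked":
        return amplitude * (1 - 2 * np.abs(2 * t - 1))
    if shape == "valley":
        return -amplitude * (1 - 2 * np.abs(2 * t - 1))
    if shape == "flat":
        return np.zeros(groups)
    raise ValueError(f"unknown trajectory shape {shape!r}")


def simulate_panels(config: SimConfig) -> dict[str, MetabolitePanel]:
    """One metabolite panel per cohort with planted trajectory shapes.

    The configured shared metabolites appear in every cohort with the
    "increasing" shape; remaining metabolites are cohort-specific with
    shapes drawn from ``shape_probs``. Group means follow the shape
    template plus Gaussian noise (sd ``noise_sd``); per-group replicate
    values (for PERMANOVA) add independent noise around the means.
    """
    rng = _rng(config.seed, "panels")
    shapes = list(config.shape_probs)
    probs = np.array([config.shape_probs[s] for s in shapes], dtype=float)
    probs = probs / probs.sum()

    panels: dict[str, MetabolitePanel] = {}
    for cohort, groups in config.cohorts.items():
        if len(groups) < 3:
            raise ValueError(f"cohort {cohort!r} needs at least 3 ordered groups")
        n_shared = len(config.shared_increasing)
        if n_shared > config.n_metabolites:
            raise ValueError("shared subset larger than the panel")
        names = list(config.shared_increasing) + [
            f"{cohort}_met{j + 1:03d}" for j in range(config.n_metabolites - n_shared)
        ]
        true_shapes = ["increasing"] * n_shared + [
            shapes[int(i)] for i in rng.choice(len(shapes), size=len(names) - n_shared, p=probs)
        ]
        g = len(groups)
        means = np.vstack(
            [
                shape_template(s, g, config.amplitude) + rng.normal(0, config.noise_sd, g)
                for s in true_shapes
            ]
        )
        values = pd.DataFrame(means, index=pd.Index(names, name="metabolite"), columns=groups)

        sample_ids, sample_groups, rows = [], [], []
        for gi, group in enumerate(groups):
            for rep in range(1, config.n_panel_reps + 1):
                sample_ids.append(f"{cohort}_{group}_r{rep}")
                sample_groups.append(group)
                rows.append(means[:, gi] + rng.normal(0, config.noise_sd, len(names)))
        replicate_values = pd.DataFrame(
            rows, index=pd.Index(sample_ids, name="sample"), columns=names
        )
        panels[cohort] = MetabolitePanel(
            cohort=cohort,
            groups=tuple(groups),
            values=values,
            replicate_values=replicate_values,
            replicate_groups=pd.Series(sample_groups, index=sample_ids, name="group"),
            true_shapes=pd.Series(true_shapes, index=names, name="shape"),
        )
    return panels


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    config: SimConfig, proteome: Sequence[ProteomeRecord]
) -> tuple[GeneSetCollection, dict]:
    """Metastasis-style set plus pathway sets with one planted enrichment.

    The "metastasis" set is sampled without replacement with weight
    ``metastasis_weight`` on responsive genes (weight 1 elsewhere); weight 1
    makes membership independent of responsiveness. One pathway draws
    ``planted_fraction`` of its members from responsive (truly repressed)
    genes; the others are uniform.
    """
    rng = _rng(config.seed, "gene_sets")
    genes = np.array([r.gene for r in proteome])
    responsive = np.array([r.responsive for r in proteome])
    if config.metastasis_size > genes.size or config.pathway_size > genes.size:
        raise ValueError("requested set size exceeds the number of genes")
    if config.pathway_size <= 0 or config.metastasis_size <= 0:
        raise ValueError("empty gene-set request")
    if config.n_pathways < 3:
        raise ValueError("need at least 3 pathway sets")

    weights = np.where(responsive, config.metastasis_weight, 1.0)
    weights = weights / weights.sum()
    metastasis = rng.choice(genes, size=config.metastasis_size, replace=False, p=weights)

    planted_idx = int(rng.integers(config.n_pathways))
    collection = GeneSetCollection({"metastasis": metastasis})
    responsive_pool = genes[responsive]
    other_pool = genes[~responsive]
    planted_name = None
    for j in range(config.n_pathways):
        name = f"pathway_{j + 1}"
        if j == planted_idx:
            n_resp = min(int(round(config.planted_fraction * config.pathway_size)),
                         responsive_pool.size)
            members = np.concatenate(
                [
                    rng.choice(responsive_pool, size=n_resp, replace=False),
                    rng.choice(other_pool, size=config.pathway_size - n_resp, replace=False),
                ]
            )
            planted_name = name
        else:
            members = rng.choice(genes, size=config.pathway_size, replace=False)
        collection[name] = frozenset(members)

    truth = {"planted_pathway": planted_name, "metastasis_size": int(config.metastasis_size)}
    return collection, truth


# ---------------------------------------------------------------------------
# whole study


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate the complete synthetic study (deterministic under config.seed)."""
    proteome = generate_proteome(config)
    counts = simulate_counts(config, proteome)
    panels = simulate_panels(config)
    gene_sets, set_truth = generate_gene_sets(config, proteome)
    truth = {
        "seed": config.seed,
        "beta": config.beta,
        "pp_counts": {r.gene: r.pp_count for r in proteome},
        "responsive_genes": sorted(r.gene for r in proteome if r.responsive),
        "shared_increasing": list(config.shared_increasing),
        "shapes": {
            cohort: panel.true_shapes.to_dict() for cohort, panel in panels.items()
        },
        **set_truth,
    }
    return SyntheticStudy(
        config=config, proteome=proteome, counts=counts, panels=panels,
        gene_sets=gene_sets, truth=truth,
    )
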