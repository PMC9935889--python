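"""Parametric simulation of fullness data and cohort-level helpers.

The parametric generator is the exact mirror of the per-module binomial
GLM: satisfied-step counts are drawn as
``k ~ Binomial(S_m, invlogit(alpha_m + beta_mp * c))`` with completeness c
as a proportion, so slope recovery and correction behaviour are testable
against a known truth. The mechanistic route (contig dropout on generated
genomes) lives in :mod:`magbias.genomes`; :func:`simulate_cohort` combines
the two into an annotated training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .catalog import ModuleCatalog
from .distill import FullnessMatrix
from .genomes import (
    DEFAULT_PHYLA,
    GenomeRecord,
    default_sccg_ids,
    estimate_completeness,
    generate_complete_genome,
    subsample_contigs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParametricModel",
    "DEFAULT_PHYLUM_SLOPE_OFFSETS",
    "sample_parametric_model",
    "generate_parametric_dataset",
    "simulate_cohort",
]

#: Phylum offsets added to each module's base slope. The ordering
#: (Proteobacteria strongest, then Firmicutes, Actinobacteriota,
#: Bacteroidota) reflects the strength ranking of the fullness-completeness
#: relationship reported across the four dominant bacterial phyla.
DEFAULT_PHYLUM_SLOPE_OFFSETS: dict[str, float] = {
    "Actinobacteriota": -0.1,
    "Bacteroidota": -0.4,
    "Firmicutes": 0.1,
    "Proteobacteria": 0.4,
}


@dataclass
class ParametricModel:
    """Known logit-linear truth: per-module intercepts, per-(module, phylum) slopes.

    On the logit scale, with completeness expressed as a proportion:
    ``logit E[f_mg] = intercepts[m] + slopes[m][p] * c_g``.
    """

    intercepts: dict[str, float]
    slopes: dict[str, dict[str, float]] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.intercepts) != set(self.slopes):
            raise ValueError("intercepts and slopes must cover the same modules")
        phyla = None
        for m, per_phylum in self.slopes.items():
            if not per_phylum:
                raise ValueError(f"module {m!r} has no phylum slopes")
            if phyla is None:
                phyla = set(per_phylum)
            elif set(per_phylum) != phyla:
                raise ValueError("every module must carry a slope for each phylum")

    @property
    def module_ids(self) -> list[str]:
        return sorted(self.intercepts)

    @property
    def phyla(self) -> list[str]:
        first = next(iter(self.slopes.values()))
        return sorted(first)


def sample_parametric_model(
    catalog: ModuleCatalog,
    phyla: Sequence[str] = DEFAULT_PHYLA,
    intercept_mean: float = -1.5,
    intercept_sd: float = 1.0,
    slope_mean: float = 4.0,
    slope_sd: float = 1.0,
    phylum_offsets: Mapping[str, float] | None = None,
    steps_coef: float = -0.05,
    seed: int | np.random.Generator = 0,
) -> ParametricModel:
    """Draw a realistic generative model over a catalog.

    Module base slopes are Gaussian around ``slope_mean`` and shifted by a
    phylum offset and by ``steps_coef * (S_m - mean S)`` so that more
    complex modules have systematically weaker completeness dependence.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if phylum_offsets is None:
        phylum_offsets = {p: DEFAULT_PHYLUM_SLOPE_OFFSETS.get(p, 0.0) for p in phyla}
    steps = np.array([m.n_steps for m in catalog], dtype=float)
    mean_steps = steps.mean()
    intercepts: dict[str, float] = {}
    slopes: dict[str, dict[str, float]] = {}
    for i, module in enumerate(catalog):
        base = rng.normal(slope_mean, slope_sd) + steps_coef * (steps[i] - mean_steps)
        intercepts[module.module_id] = rng.normal(intercept_mean, intercept_sd)
        slopes[module.module_id] = {p: base + phylum_offsets[p] for p in phyla}
    return ParametricModel(intercepts=intercepts, slopes=slopes)


def generate_parametric_dataset(
    model: ParametricModel,
    catalog: ModuleCatalog,
    n_genomes: int,
    completeness_range: tuple[float, float] = (0.70, 1.00),
    phylum_mix: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> FullnessMatrix:
    """Simulate a fullness matrix from a known logit-linear model.

    Completeness is uniform on ``completeness_range`` (default the 70-100%
    window typical of MAG cohorts); satisfied-step counts are binomial with
    the model's success probability. The drawn completeness doubles as the
    estimated completeness in the genome metadata.
    """
    lo, hi = completeness_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("completeness_range must be within (0, 1]")
    if hi == lo and n_genomes > 1:
        logger.warning(
            "degenerate completeness range [%g, %g]: slope unidentifiable", lo, hi
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phyla = model.phyla
    if phylum_mix is None:
        probs = np.full(len(phyla), 1.0 / len(phyla))
    else:
        probs = np.array([phylum_mix[p] for p in phyla], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("phylum_mix must sum to 1")

    module_ids = [m.module_id for m in catalog if m.module_id in model.intercepts]
    if not module_ids:
        raise ValueError("model covers no module of the catalog")
    steps = np.array([catalog[m].n_steps for m in module_ids], dtype=int)

    genome_ids = [f"g{i + 1:05d}" for i in range(n_genomes)]
    phylum = rng.choice(phyla, size=n_genomes, p=probs)
    completeness = rng.uniform(lo, hi, size=n_genomes)

    alpha = np.array([model.intercepts[m] for m in module_ids])
    beta = np.array(
        [[model.slopes[m][p] for m in module_ids] for p in phyla]
    )  # phyla x modules
    phylum_idx = np.array([phyla.index(p) for p in phylum])
    eta = alpha[np.newaxis, :] + beta[phylum_idx, :] * completeness[:, np.newaxis]
    counts = rng.binomial(steps[np.newaxis, :], expit(eta))

    genome_meta = pd.DataFrame(
        {
            "phylum": phylum,
            "completeness": completeness,
            "true_completeness": completeness,
            "contamination": 0.0,
        },
        index=pd.Index(genome_ids, name="genome_id"),
    )
    module_meta = pd.DataFrame(
        {"domain": [catalog[m].domain for m in module_ids], "n_steps": steps},
        index=pd.Index(module_ids, name="module_id"),
    )
    return FullnessMatrix(
        values=pd.DataFrame(
            counts / steps[np.newaxis, :], index=genome_meta.index, columns=module_meta.index
        ),
        counts=pd.DataFrame(counts, index=genome_meta.index, columns=module_meta.index),
        genome_meta=genome_meta,
        module_meta=module_meta,
    )


def simulate_cohort(
    catalog: ModuleCatalog,
    n_genomes: int,
    phyla: Sequence[str] = DEFAULT_PHYLA,
    completeness_range: tuple[float, float] = (0.70, 1.00),
    module_presence_prob: float = 0.7,
    n_contigs: int = 200,
    n_sccg: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[GenomeRecord]:
    """Mechanistic training cohort: complete genomes degraded by contig dropout.

    Each genome is generated complete, then contigs are dropped so that the
    retained fraction is uniform on ``completeness_range``, and completeness
    is re-estimated from the SCCG fraction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sccg = default_sccg_ids(n_sccg)
    genomes: list[GenomeRecord] = []
    for i in range(n_genomes):
        phylum = phyla[i % len(phyla)]
        complete = generate_complete_genome(
            f"g{i + 1:05d}",
            phylum,
            catalog,
            module_presence_prob=module_presence_prob,
            n_contigs=n_contigs,
            n_sccg=n_sccg,
            seed=rng,
        )
        retention = rng.uniform(*completeness_range)
        genome = subsample_contigs(complete, retention, seed=rng) if retention < 1 else complete
        estimate_completeness(genome, sccg)
        genomes.append(genome)
    return genomes
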