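"""Distillation of gene content into module fullness.

Fullness of a module in a genome is the proportion of the module's steps
for which at least one of the step's alternative genes is present — the
step-level summary a DRAM-style distillation produces from per-gene
annotations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import ModuleCatalog, ModuleDefinition
from .genomes import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FullnessMatrix",
    "compute_fullness",
    "build_matrix",
    "prevalence_threshold",
    "filter_modules",
]


@dataclass
class FullnessMatrix:
    """Genomes x modules fullness values with the underlying step counts.

    ``values`` holds fullness f = k / S in [0, 1]; ``counts`` the integer
    satisfied-step counts k; ``genome_meta`` (indexed by genome_id) carries
    phylum, completeness and contamination; ``module_meta`` (indexed by
    module_id) carries the functional domain and the step count S.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    genome_meta: pd.DataFrame
    module_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.counts.index) or not self.values.columns.equals(
            self.counts.columns
        ):
            raise ValueError("values and counts must share index and columns")
        if not self.values.index.equals(self.genome_meta.index):
            raise ValueError("genome_meta index must match the value rows")
        if not self.values.columns.equals(self.module_meta.index):
            raise ValueError("module_meta index must match the value columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate genome_id")
        steps = self.module_meta["n_steps"].to_numpy()
        if (steps < 1).any():
            raise ValueError("module step counts must be >= 1")
        expected = self.counts.to_numpy() / steps[np.newaxis, :]
        if not np.allclose(self.values.to_numpy(), expected, atol=1e-9):
            raise ValueError("fullness must equal counts / n_steps")

    @property
    def n_genomes(self) -> int:
        return self.values.shape[0]

    @property
    def n_modules(self) -> int:
        return self.values.shape[1]

    @property
    def module_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)


def compute_fullness(genome: GenomeRecord, module: ModuleDefinition) -> tuple[int, float]:
    """Count satisfied steps of ``module`` in ``genome`` and the fullness.

    A step is satisfied when the genome carries at least one of its
    alternative genes (pure OR semantics).
    """
    genes = genome.gene_to_contig
    k = sum(1 for step in module.steps if any(g in genes for g in step))
    return k, k / module.n_steps


def build_matrix(genomes: Sequence[GenomeRecord], catalog: ModuleCatalog) -> FullnessMatrix:
    """Distill a cohort of genomes against a catalog, cell by cell."""
    ids = [g.genome_id for g in genomes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome_id in cohort")
    module_ids = catalog.module_ids
    counts = np.zeros((len(genomes), len(module_ids)), dtype=int)
    for i, genome in enumerate(genomes):
        gene_set = genome.gene_to_contig
        for j, module in enumerate(catalog):
            counts[i, j] = sum(
                1 for step in module.steps if any(g in gene_set for g in step)
            )
    steps = np.array([m.n_steps for m in catalog], dtype=int)
    values = counts / steps[np.newaxis, :]
    genome_meta = pd.DataFrame(
        {
            "phylum": [g.phylum for g in genomes],
            "completeness": [g.est_completeness for g in genomes],
            "true_completeness": [g.true_completeness for g in genomes],
            "contamination": [g.contamination for g in genomes],
        },
        index=pd.Index(ids, name="genome_id"),
    )
    module_meta = pd.DataFrame(
        {"domain": [m.domain for m in catalog], "n_steps": steps},
        index=pd.Index(module_ids, name="module_id"),
    )
    return FullnessMatrix(
        values=pd.DataFrame(values, index=genome_meta.index, columns=module_meta.index),
        counts=pd.DataFrame(counts, index=genome_meta.index, columns=module_meta.index),
        genome_meta=genome_meta,
        module_meta=module_meta,
    )


def prevalence_threshold(n_genomes: int, min_prevalence: float = 0.05) -> int:
    """Minimum presence count implied by a prevalence fraction (floor rule)."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    return int(math.floor(min_prevalence * n_genomes))


def filter_modules(matrix: FullnessMatrix, min_prevalence: float = 0.05) -> FullnessMatrix:
    """Keep only widespread modules.

    A module is present in a genome when its fullness is > 0 (any step
    satisfied); modules present in fewer than
    ``floor(min_prevalence * n_genomes)`` genomes are dropped.
    """
    threshold = prevalence_threshold(matrix.n_genomes, min_prevalence)
    presence = (matrix.values > 0).sum(axis=0)
    keep = presence[presence >= threshold].index
    logger.info(
        "prevalence filter: threshold %d genomes; %d of %d modules kept",
        threshold,
        len(keep),
        matrix.n_modules,
    )
    if len(keep) == 0:
        logger.warning("prevalence filter removed every module")
    return FullnessMatrix(
        values=matrix.values[keep],
        counts=matrix.counts[keep],
        genome_meta=matrix.genome_meta,
        module_meta=matrix.module_meta.loc[keep],
    )
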