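"""Synthetic genomes and mechanistic incompleteness.

Complete genomes are built from a module catalog by placing one enabling
gene per step of each included module, plus a set of single-copy core
genes (SCCGs), uniformly at random on a fixed number of contigs.
Incompleteness is simulated by dropping whole contigs, which is how real
metagenome-assembled genomes lose content; completeness is then
re-estimated from the surviving SCCG fraction, emulating a CheckM-style
marker estimate (noisy by construction, since SCCGs are ordinary genes
subject to the same dropout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import ModuleCatalog

__all__ = [
    "GenomeRecord",
    "DEFAULT_PHYLA",
    "default_sccg_ids",
    "generate_complete_genome",
    "subsample_contigs",
    "estimate_completeness",
    "add_contamination",
]

#: Default phylum universe: the four most genome-rich bacterial phyla.
DEFAULT_PHYLA: tuple[str, ...] = (
    "Actinobacteriota",
    "Bacteroidota",
    "Firmicutes",
    "Proteobacteria",
)


def default_sccg_ids(n_sccg: int) -> frozenset[str]:
    """Identifiers of the simulated single-copy core gene set."""
    if n_sccg < 1:
        raise ValueError("n_sccg must be >= 1")
    return frozenset(f"SCCG{i:04d}" for i in range(n_sccg))


@dataclass
class GenomeRecord:
    """A (possibly incomplete) genome: contigs, gene content, quality metadata.

    ``true_completeness`` is the fraction of the parent complete genome's
    genes retained; ``est_completeness`` is the SCCG-based estimate (NaN
    until :func:`estimate_completeness` has run).
    """

    genome_id: str
    phylum: str
    contigs: list[str]
    gene_to_contig: dict[str, str]
    true_completeness: float = 1.0
    est_completeness: float = float("nan")
    contamination: float = 0.0
    #: gene count of the ancestral complete genome (for true_completeness).
    n_genes_complete: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for c in (self.true_completeness, self.est_completeness):
            if not math.isnan(c) and not 0.0 <= c <= 1.0:
                raise ValueError(f"completeness {c} outside [0, 1]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")
        contig_set = set(self.contigs)
        for gene, contig in self.gene_to_contig.items():
            if contig not in contig_set:
                raise ValueError(f"gene {gene!r} maps to unknown contig {contig!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_contig)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


def generate_complete_genome(
    genome_id: str,
    phylum: str,
    catalog: ModuleCatalog,
    module_presence_prob: float = 0.7,
    n_contigs: int = 42,
    n_sccg: int = 100,
    seed: int | np.random.Generator = 0,
) -> GenomeRecord:
    """Build a complete genome from a catalog.

    Each module is included with probability ``module_presence_prob``; an
    included module contributes one gene per step (chosen uniformly among
    the step's alternatives), so every included module starts at fullness 1.
    ``n_sccg`` single-copy marker genes are always present. All genes are
    assigned to ``n_contigs`` contigs uniformly at random.
    """
    if not 0.0 <= module_presence_prob <= 1.0:
        raise ValueError("module_presence_prob must be in [0, 1]")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    genes: list[str] = []
    for module in catalog:
        if rng.random() < module_presence_prob:
            for step in module.steps:
                alts = sorted(step)
                genes.append(alts[rng.integers(len(alts))])
    genes.extend(sorted(default_sccg_ids(n_sccg)))

    contigs = [f"{genome_id}_c{i + 1:04d}" for i in range(n_contigs)]
    placement = rng.integers(n_contigs, size=len(genes))
    gene_to_contig = {g: contigs[placement[i]] for i, g in enumerate(genes)}
    return GenomeRecord(
        genome_id=genome_id,
        phylum=phylum,
        contigs=contigs,
        gene_to_contig=gene_to_contig,
        true_completeness=1.0,
        est_completeness=1.0,
        contamination=0.0,
        n_genes_complete=len(gene_to_contig),
    )


def subsample_contigs(
    genome: GenomeRecord,
    retention: float,
    seed: int | np.random.Generator = 0,
) -> GenomeRecord:
    """Drop contigs uniformly at random, keeping a fraction ``retention``.

    Keeps ``round(retention * n_contigs)`` contigs (round half up, floor of
    one contig), chosen without replacement. Genes on dropped contigs are
    lost; ``true_completeness`` is recomputed as the retained-gene fraction
    and ``est_completeness`` is reset to NaN pending re-estimation.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    if genome.n_contigs < 1:
        raise ValueError("genome has no contigs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_keep = max(1, int(math.floor(retention * genome.n_contigs + 0.5)))
    keep_idx = rng.choice(genome.n_contigs, size=n_keep, replace=False)
    kept = set(genome.contigs[i] for i in keep_idx)
    contigs = [c for c in genome.contigs if c in kept]
    gene_to_contig = {g: c for g, c in genome.gene_to_contig.items() if c in kept}
    n_complete = genome.n_genes_complete or len(genome.gene_to_contig)
    return replace(
        genome,
        contigs=contigs,
        gene_to_contig=gene_to_contig,
        true_completeness=len(gene_to_contig) / n_complete if n_complete else 0.0,
        est_completeness=float("nan"),
        n_genes_complete=n_complete,
    )


def estimate_completeness(genome: GenomeRecord, sccg_ids: frozenset[str] | set[str]) -> float:
    """SCCG-fraction completeness estimate (CheckM-style emulation).

    Returns the fraction of the marker set present in the genome and writes
    it into ``genome.est_completeness``.
    """
    if not sccg_ids:
        raise ValueError("sccg_ids must be non-empty")
    present = sum(1 for g in sccg_ids if g in genome.gene_to_contig)
    est = present / len(sccg_ids)
    genome.est_completeness = est
    return est


def add_contamination(
    genome: GenomeRecord,
    fraction: float,
    sccg_ids: frozenset[str] | set[str],
    seed: int | np.random.Generator = 0,
) -> GenomeRecord:
    """Inject redundancy by duplicating a fraction of the SCCG set.

    Duplicated markers get ``_dup`` identifiers on random existing contigs
    and ``contamination`` is set to the duplicated fraction. Exists only to
    exercise contamination-based cohort filtering.
    """
    if not 0.0 <= fraction:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    markers = sorted(g for g in sccg_ids if g in genome.gene_to_contig)
    n_dup = min(len(markers), int(round(fraction * len(sccg_ids))))
    gene_to_contig = dict(genome.gene_to_contig)
    for g in rng.choice(markers, size=n_dup, replace=False) if n_dup else []:
        contig = genome.contigs[rng.integers(genome.n_contigs)]
        gene_to_contig[f"{g}_dup"] = contig
    return replace(
        genome,
        gene_to_contig=gene_to_contig,
        contamination=n_dup / len(sccg_ids),
    )
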