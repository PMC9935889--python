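"""Readers, writers, pipeline configuration and cohort filtering.

All on-disk formats are plain text: the module catalog travels as JSON
(or a flat TSV), genome annotations as a DRAM-like TSV of
(genome_id, phylum, contig_id, gene_id) rows, fullness matrices as a
directory of TSVs, and fitted GLM bundles as JSON. Completeness is stored
as a proportion in [0, 1] internally; TSV metadata may be read/written on
the percent scale with an explicit flag.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import ModuleCatalog, ModuleDefinition
from .distill import FullnessMatrix
from .genomes import DEFAULT_PHYLA, GenomeRecord
from .glm import ModuleGlmFit

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_catalog",
    "write_catalog",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "read_fullness",
    "write_fullness",
    "read_fits",
    "write_fits",
    "write_slopes",
    "read_slopes",
    "filter_cohort",
    "write_manifest",
]

_EMPTY_GENE = "."  # placeholder row that records a contig with no genes


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    Defaults encode the cohort definition of the analysis: modules present
    in at least 5% of genomes, genomes with completeness >= 70% (inclusive)
    and contamination < 10% (strict), retention tiers 70/80/90% with ten
    replicates, and 999 bootstrap simulations.
    """

    min_prevalence: float = 0.05
    contamination_max: float = 0.10
    completeness_min: float = 0.70
    hq_completeness: float = 0.90
    tiers: tuple[float, ...] = (0.7, 0.8, 0.9)
    replicates: int = 10
    n_sim: int = 999
    seed: int = 1337
    percent: bool = False
    allow_extra_phyla: bool = False

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "contamination_max", "completeness_min", "hq_completeness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 < t <= 1.0 for t in self.tiers):
            raise ValueError("tiers must lie in (0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "tiers" in data:
            data["tiers"] = tuple(data["tiers"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiers"] = list(d["tiers"])
        return d


# ---------------------------------------------------------------------------
# catalog

def write_catalog(catalog: ModuleCatalog, path: str | Path) -> None:
    data = [
        {
            "module_id": m.module_id,
            "domain": m.domain,
            "steps": [sorted(step) for step in m.steps],
        }
        for m in catalog
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_catalog(path: str | Path) -> ModuleCatalog:
    data = json.loads(Path(path).read_text())
    modules = []
    for i, entry in enumerate(data):
        try:
            modules.append(
                ModuleDefinition(
                    module_id=entry["module_id"],
                    domain=entry["domain"],
                    steps=tuple(frozenset(step) for step in entry["steps"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: catalog entry {i}: {exc}") from exc
    return ModuleCatalog(modules)


def write_catalog_tsv(catalog: ModuleCatalog, path: str | Path) -> None:
    """Flat long-form catalog: one row per (module, step, alternative gene)."""
    rows = [
        {"module_id": m.module_id, "domain": m.domain, "step_index": i, "gene_id": g}
        for m in catalog
        for i, step in enumerate(m.steps)
        for g in sorted(step)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> ModuleCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"module_id", "domain", "step_index", "gene_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    modules = []
    for module_id, grp in df.groupby("module_id", sort=False):
        domain = grp["domain"].iloc[0]
        steps = []
        for _, step_grp in grp.groupby(grp["step_index"].astype(int), sort=True):
            steps.append(frozenset(step_grp["gene_id"]))
        modules.append(ModuleDefinition(module_id=module_id, domain=domain, steps=tuple(steps)))
    return ModuleCatalog(modules)


# ---------------------------------------------------------------------------
# genomes

def write_annotations(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    """DRAM-like annotation table: genome_id, phylum, contig_id, gene_id.

    Contigs without genes are preserved as placeholder rows so reading the
    table back reproduces the genome exactly.
    """
    rows = []
    for g in genomes:
        by_contig: dict[str, list[str]] = {c: [] for c in g.contigs}
        for gene, contig in g.gene_to_contig.items():
            by_contig[contig].append(gene)
        for contig in g.contigs:  # contig order is part of the record
            genes = by_contig[contig]
            if not genes:
                rows.append((g.genome_id, g.phylum, contig, _EMPTY_GENE))
            for gene in genes:
                rows.append((g.genome_id, g.phylum, contig, gene))
    pd.DataFrame(rows, columns=["genome_id", "phylum", "contig_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_metadata(
    genomes: Sequence[GenomeRecord], path: str | Path, percent: bool = False
) -> None:
    scale = 100.0 if percent else 1.0
    rows = [
        {
            "genome_id": g.genome_id,
            "phylum": g.phylum,
            "completeness": g.est_completeness * scale,
            "contamination": g.contamination * scale,
            "true_completeness": g.true_completeness * scale,
            "n_genes_complete": g.n_genes_complete if g.n_genes_complete is not None else "",
        }
        for g in genomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path, percent: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "phylum", "completeness", "contamination"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    scale = 0.01 if percent else 1.0
    for col in ("completeness", "contamination", "true_completeness"):
        if col in df.columns:
            df[col] = df[col].astype(float) * scale
    bad = df[(df["completeness"] < 0) | (df["completeness"] > 1)]
    if len(bad):
        raise ValueError(
            f"{path}: completeness outside [0, 1] for {list(bad['genome_id'])[:5]} "
            "(use percent=True for percent-scale files)"
        )
    return df.set_index("genome_id")


def read_annotations(
    path: str | Path,
    metadata: pd.DataFrame | str | Path | None = None,
    percent: bool = False,
    allow_extra_phyla: bool = False,
) -> list[GenomeRecord]:
    """Read an annotation TSV (optionally joined with quality metadata)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "phylum", "contig_id", "gene_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not allow_extra_phyla:
        unknown = set(df["phylum"].unique()) - set(DEFAULT_PHYLA)
        if unknown:
            raise ValueError(
                f"{path}: unknown phylum labels {sorted(unknown)}; allowed: "
                f"{list(DEFAULT_PHYLA)} (pass allow_extra_phyla=True to accept)"
            )
    meta = None
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata, percent)

    genomes = []
    for genome_id, grp in df.groupby("genome_id", sort=False):
        contigs = list(dict.fromkeys(grp["contig_id"]))
        gene_rows = grp[grp["gene_id"] != _EMPTY_GENE]
        gene_to_contig = dict(zip(gene_rows["gene_id"], gene_rows["contig_id"]))
        kwargs: dict = {
            "phylum": grp["phylum"].iloc[0],
            "true_completeness": float("nan"),
            "est_completeness": float("nan"),
        }
        if meta is not None:
            if genome_id not in meta.index:
                raise ValueError(f"{path}: genome {genome_id!r} absent from metadata")
            row = meta.loc[genome_id]
            kwargs["est_completeness"] = float(row["completeness"])
            kwargs["contamination"] = float(row["contamination"])
            if "true_completeness" in row and pd.notna(row["true_completeness"]):
                kwargs["true_completeness"] = float(row["true_completeness"])
            if "n_genes_complete" in row and pd.notna(row["n_genes_complete"]) and row["n_genes_complete"] != "":
                kwargs["n_genes_complete"] = int(row["n_genes_complete"])
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                contigs=contigs,
                gene_to_contig=gene_to_contig,
                **kwargs,
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# fullness matrices

def write_fullness(matrix: FullnessMatrix, outdir: str | Path) -> None:
    """Write a fullness matrix as four TSVs (values, counts, genome/module metadata)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(out / "fullness.tsv", sep="\t")
    matrix.counts.to_csv(out / "counts.tsv", sep="\t")
    matrix.genome_meta.to_csv(out / "genomes.tsv", sep="\t")
    matrix.module_meta.to_csv(out / "modules.tsv", sep="\t")


def read_fullness(indir: str | Path) -> FullnessMatrix:
    ind = Path(indir)
    values = pd.read_csv(ind / "fullness.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(ind / "counts.tsv", sep="\t", index_col=0)
    genome_meta = pd.read_csv(ind / "genomes.tsv", sep="\t", index_col=0)
    module_meta = pd.read_csv(ind / "modules.tsv", sep="\t", index_col=0)
    for df in (values, counts, genome_meta):
        df.index.name = "genome_id"
    for cols in (values.columns, counts.columns):
        cols.name = "module_id"
    module_meta.index.name = "module_id"
    if ((values < 0) | (values > 1)).any().any():
        raise ValueError(f"{ind / 'fullness.tsv'}: fullness values outside [0, 1]")
    return FullnessMatrix(
        values=values, counts=counts, genome_meta=genome_meta, module_meta=module_meta
    )


# ---------------------------------------------------------------------------
# fitted models

def write_fits(fits: Mapping[str, ModuleGlmFit], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({m: f.to_dict() for m, f in fits.items()}, indent=1)
    )


def read_fits(path: str | Path) -> dict[str, ModuleGlmFit]:
    data = json.loads(Path(path).read_text())
    return {m: ModuleGlmFit.from_dict(d) for m, d in data.items()}


def write_slopes(fits: Iterable[ModuleGlmFit], path: str | Path) -> None:
    """Flat per-(module, phylum) summary: slope, s.e., intercept, convergence."""
    rows = []
    for f in fits:
        for p in f.phyla:
            rows.append(
                {
                    "module_id": f.module_id,
                    "phylum": p,
                    "slope": f.slopes.get(p, float("nan")),
                    "se": f.slope_se.get(p, float("nan")),
                    "intercept": f.intercepts.get(p, float("nan")),
                    "converged": f.converged,
                    "domain": f.domain,
                    "n_steps": f.n_steps,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_slopes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"module_id", "phylum", "slope"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort filtering

def filter_cohort(
    genome_meta: pd.DataFrame,
    config: PipelineConfig | None = None,
    per_window_target: int | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Apply the cohort quality filters.

    Drops genomes below the completeness floor (inclusive bound: a genome
    at exactly the floor is kept) or at/above the contamination ceiling
    (strict bound: exactly 10% is dropped). With ``per_window_target``,
    additionally subsamples each half-open 1%-completeness window
    [lower, upper) down to at most that many genomes per phylum.
    """
    config = config or PipelineConfig()
    kept = genome_meta[
        (genome_meta["completeness"] >= config.completeness_min)
        & (genome_meta["contamination"] < config.contamination_max)
    ]
    logger.info("cohort filter: %d of %d genomes kept", len(kept), len(genome_meta))
    if len(kept) == 0:
        logger.warning("cohort filter removed every genome")
    if per_window_target is not None:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        windows = np.floor(kept["completeness"].to_numpy() * 100).astype(int)
        pieces = []
        for (_, _), grp in kept.groupby([windows, kept["phylum"]], sort=True):
            if len(grp) > per_window_target:
                idx = rng.choice(len(grp), size=per_window_target, replace=False)
                grp = grp.iloc[np.sort(idx)]
            pieces.append(grp)
        kept = pd.concat(pieces).loc[lambda d: d.index]
        kept = kept.loc[[i for i in genome_meta.index if i in kept.index]]
    return kept


def write_manifest(outdir: str | Path, config: PipelineConfig, seed: int, stage: str,
                   extra: Mapping | None = None) -> None:
    """Record everything needed to reproduce a pipeline stage bit-for-bit."""
    manifest = {
        "stage": stage,
        "magbias_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    Path(outdir, "manifest.json").write_text(json.dumps(manifest, indent=1))
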