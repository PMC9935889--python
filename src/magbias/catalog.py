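"""Metabolic module catalogs.

A module is an ordered series of enzymatic steps; a step is satisfied by
any one of a set of alternative orthologous genes (OR semantics, as in
KEGG module definitions summarised at the step level). The catalog is the
functional universe against which genome gene content is distilled into
fullness values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ModuleDefinition",
    "ModuleCatalog",
    "DEFAULT_DOMAINS",
    "generate_catalog",
    "poisson_steps",
    "constant_steps",
]

#: Functional-domain labels used by default (up to ten categorical levels,
#: patterned after top-level KEGG metabolism categories).
DEFAULT_DOMAINS: tuple[str, ...] = (
    "Amino acid metabolism",
    "Biosynthesis of other secondary metabolites",
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Glycan metabolism",
    "Lipid metabolism",
    "Metabolism of cofactors and vitamins",
    "Nucleotide metabolism",
    "Terpenoid and polyketide metabolism",
    "Xenobiotics biodegradation",
)


@dataclass(frozen=True)
class ModuleDefinition:
    """One metabolic module: ordered steps, each a set of alternative genes."""

    module_id: str
    domain: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError(f"module {self.module_id!r} has no steps")
        for i, step in enumerate(self.steps):
            if len(step) == 0:
                raise ValueError(f"module {self.module_id!r} step {i} is empty")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def genes(self) -> frozenset[str]:
        """All gene identifiers referenced by any step."""
        out: set[str] = set()
        for step in self.steps:
            out |= step
        return frozenset(out)


@dataclass
class ModuleCatalog:
    """An ordered collection of modules with unique identifiers."""

    modules: list[ModuleDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(ids) != len(set(ids)):
            raise ValueError("module_ids are not unique")
        self._by_id = {m.module_id: m for m in self.modules}

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[ModuleDefinition]:
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> ModuleDefinition:
        return self._by_id[module_id]

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._by_id

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def subset(self, module_ids: Sequence[str]) -> "ModuleCatalog":
        return ModuleCatalog([self._by_id[m] for m in module_ids])


def poisson_steps(mean: float = 6.0) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Step-count distribution ``1 + Poisson(mean)`` (support >= 1)."""
    if mean < 0:
        raise ValueError("Poisson mean must be non-negative")

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return 1 + rng.poisson(mean, size=n)

    return draw


def constant_steps(k: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Degenerate step-count distribution: every module has ``k`` steps."""
    if k < 1:
        raise ValueError("step count must be a positive integer")

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, k, dtype=int)

    return draw


def generate_catalog(
    n_modules: int,
    step_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    n_domains: int = 10,
    alt_genes_per_step: int = 2,
    seed: int | np.random.Generator = 0,
) -> ModuleCatalog:
    """Generate a synthetic module catalog.

    Module step counts are drawn from ``step_dist`` (default ``1+Poisson(6)``),
    domains are assigned round-robin from :data:`DEFAULT_DOMAINS`, and every
    step receives ``alt_genes_per_step`` globally unique alternative gene
    identifiers in KO-like style. Deterministic given ``seed``.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if not 1 <= n_domains <= len(DEFAULT_DOMAINS):
        raise ValueError(f"n_domains must be in 1..{len(DEFAULT_DOMAINS)}")
    if alt_genes_per_step < 1:
        raise ValueError("alt_genes_per_step must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if step_dist is None:
        step_dist = poisson_steps(6.0)
    counts = np.asarray(step_dist(rng, n_modules), dtype=int)
    if counts.shape != (n_modules,) or (counts < 1).any():
        raise ValueError("step_dist must return positive integer counts")

    domains = DEFAULT_DOMAINS[:n_domains]
    modules = []
    gene_counter = 0
    for i in range(n_modules):
        steps = []
        for _ in range(int(counts[i])):
            alts = frozenset(
                f"K{gene_counter + j:05d}" for j in range(alt_genes_per_step)
            )
            gene_counter += alt_genes_per_step
            steps.append(alts)
        modules.append(
            ModuleDefinition(
                module_id=f"M{i + 1:05d}",
                domain=domains[i % len(domains)],
                steps=tuple(steps),
            )
        )
    return ModuleCatalog(modules)
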