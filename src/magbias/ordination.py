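"""Ordination and the contig-subsampling validation experiment.

Functional profiles (fullness vectors) are compared by pairwise distance
and embedded with classical principal coordinates analysis (PCoA). The
validation experiment degrades complete genomes at fixed contig-retention
tiers, corrects the resulting profiles with GLMs trained on an
independent cohort, and quantifies how far raw and corrected profiles sit
from the complete genome — jointly visualised in one PCoA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .catalog import ModuleCatalog
from .correct import correct_matrix
from .distill import FullnessMatrix, build_matrix
from .genomes import GenomeRecord, default_sccg_ids, estimate_completeness, subsample_contigs
from .glm import ModuleGlmFit

logger = logging.getLogger(__name__)

__all__ = [
    "PcoaResult",
    "ValidationReport",
    "profile_distance",
    "pcoa",
    "confidence_ellipse",
    "run_validation",
    "plot_validation",
]

_METRICS = {"euclidean", "braycurtis"}


@dataclass
class PcoaResult:
    """Classical-MDS embedding of a distance matrix.

    ``coordinates`` columns are ordered by decreasing eigenvalue; axes
    with non-positive eigenvalues are dropped and their absolute mass is
    reported in ``negative_mass``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_mass: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def profile_distance(values: pd.DataFrame, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between genome fullness profiles (rows)."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genomes")
    d = squareform(pdist(values.to_numpy(dtype=float), metric=metric))
    return DistanceMatrix(d, ids=[str(i) for i in values.index])


def pcoa(dist: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; axes belonging to negative eigenvalues (possible for
    non-Euclidean metrics) are discarded and their absolute mass recorded.
    """
    if not isinstance(dist, DistanceMatrix):
        arr = np.asarray(dist, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be square and symmetric")
        dist = DistanceMatrix(arr, ids=[str(i) for i in (ids or range(arr.shape[0]))])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dist, method="eigh")
    eig = res.eigvals.to_numpy(dtype=float)
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    coords = res.samples.to_numpy(dtype=float)[:, order]
    pos = eig > max(1e-12 * max(eig.max(), 0.0), 0.0)
    negative_mass = float(np.abs(eig[eig < 0]).sum())
    eig_pos = eig[pos]
    coords = coords[:, pos]
    total = eig_pos.sum()
    prop = eig_pos / total if total > 0 else np.zeros_like(eig_pos)
    coordinates = pd.DataFrame(
        coords,
        index=pd.Index(list(dist.ids), name="sample_id"),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(
        coordinates=coordinates,
        eigenvalues=eig_pos,
        proportion_explained=prop,
        negative_mass=negative_mass,
    )


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> dict[str, float]:
    """Normal-approximation confidence ellipse of 2-D replicate scatter.

    Axis half-lengths are ``sqrt(chi2_2(coverage) * lambda_i)`` of the
    sample covariance; the angle is the first principal axis direction in
    degrees.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    q = chi2.ppf(coverage, df=2)
    angle = float(np.degrees(np.arctan2(vecs[1, 0], vecs[0, 0])))
    return {
        "center_x": float(mean[0]),
        "center_y": float(mean[1]),
        "semi_major": float(np.sqrt(q * vals[0])),
        "semi_minor": float(np.sqrt(q * vals[1])),
        "angle_deg": angle,
    }


@dataclass
class ValidationReport:
    """Outputs of the contig-subsampling validation experiment."""

    samples: pd.DataFrame  # sample_id, genome_id, kind, tier, replicate, completeness
    report: pd.DataFrame  # per-subsample distances to the complete genome
    ordination: PcoaResult
    ellipses: pd.DataFrame
    n_subsamples: int


def run_validation(
    complete_genomes: Sequence[GenomeRecord],
    catalog: ModuleCatalog,
    fits: Mapping[str, ModuleGlmFit],
    sccg_ids: frozenset[str] | set[str] | None = None,
    tiers: Sequence[float] = (0.7, 0.8, 0.9),
    replicates: int = 10,
    seed: int | np.random.Generator = 0,
    completeness_source: str = "estimated",
    metric: str = "euclidean",
) -> ValidationReport:
    """Subsample -> distill -> correct -> ordinate, end to end.

    Every complete genome is degraded ``replicates`` times at each
    retention tier; raw and corrected profiles of all subsamples join the
    complete profiles in one PCoA. ``completeness_source`` picks what
    drives the correction: the SCCG estimate ("estimated", default), the
    true retained-gene fraction ("true"), or the nominal tier ("tier").
    """
    if len(complete_genomes) < 2:
        raise ValueError("need >= 2 complete genomes")
    if completeness_source not in {"estimated", "true", "tier"}:
        raise ValueError("completeness_source must be 'estimated', 'true' or 'tier'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sccg_ids is None:
        sccg_ids = default_sccg_ids(100)

    subs: list[GenomeRecord] = []
    labels: list[dict] = []
    for genome in complete_genomes:
        for tier in tiers:
            for rep in range(1, replicates + 1):
                sub = subsample_contigs(genome, tier, seed=rng)
                sub.genome_id = f"{genome.genome_id}|r{int(round(tier * 100))}|{rep:02d}"
                estimate_completeness(sub, sccg_ids)
                subs.append(sub)
                labels.append(
                    {
                        "parent": genome.genome_id,
                        "tier": tier,
                        "replicate": rep,
                        "est_completeness": sub.est_completeness,
                        "true_completeness": sub.true_completeness,
                    }
                )
    n_expected = len(complete_genomes) * len(tiers) * replicates
    assert len(subs) == n_expected, "subsample bookkeeping is inconsistent"

    complete_matrix = build_matrix(complete_genomes, catalog)
    raw_matrix = build_matrix(subs, catalog)
    if completeness_source == "tier":
        raw_for_correction = FullnessMatrix(
            values=raw_matrix.values,
            counts=raw_matrix.counts,
            genome_meta=raw_matrix.genome_meta.assign(
                completeness=[l["tier"] for l in labels]
            ),
            module_meta=raw_matrix.module_meta,
        )
        corrected_values, _ = correct_matrix(raw_for_correction, fits, "estimated")
    else:
        corrected_values, _ = correct_matrix(raw_matrix, fits, completeness_source)

    # joint ordination of complete + raw + corrected profiles
    frames, rows = [], []
    for gid in complete_matrix.genome_ids:
        rows.append(
            {
                "sample_id": f"{gid}|complete",
                "genome_id": gid,
                "kind": "complete",
                "tier": 1.0,
                "replicate": 0,
                "est_completeness": 1.0,
                "true_completeness": 1.0,
            }
        )
    frames.append(
        complete_matrix.values.set_index(
            complete_matrix.values.index.map(lambda g: f"{g}|complete")
        )
    )
    for kind, values in (("raw", raw_matrix.values), ("corrected", corrected_values)):
        for lab, sid in zip(labels, values.index):
            rows.append(
                {
                    "sample_id": f"{sid}|{kind}",
                    "genome_id": lab["parent"],
                    "kind": kind,
                    "tier": lab["tier"],
                    "replicate": lab["replicate"],
                    "est_completeness": lab["est_completeness"],
                    "true_completeness": lab["true_completeness"],
                }
            )
        frames.append(values.set_index(values.index.map(lambda g: f"{g}|{kind}")))
    joint = pd.concat(frames, axis=0)
    samples = pd.DataFrame(rows).set_index("sample_id")
    ordination = pcoa(profile_distance(joint, metric=metric))

    # per-subsample distance to the parent complete genome
    report_rows = []
    for lab, sid in zip(labels, raw_matrix.values.index):
        truth = complete_matrix.values.loc[lab["parent"]].to_numpy()
        raw = raw_matrix.values.loc[sid].to_numpy()
        cor = corrected_values.loc[sid].to_numpy()
        d_raw = float(np.linalg.norm(raw - truth))
        d_cor = float(np.linalg.norm(cor - truth))
        dir_vec = raw - truth
        norm = np.linalg.norm(dir_vec)
        overshoot = float((cor - truth) @ dir_vec / norm) if norm > 0 else 0.0
        report_rows.append(
            {
                "sample_id": sid,
                "genome_id": lab["parent"],
                "tier": lab["tier"],
                "replicate": lab["replicate"],
                "est_completeness": lab["est_completeness"],
                "true_completeness": lab["true_completeness"],
                "d_raw": d_raw,
                "d_corrected": d_cor,
                "gain": d_raw - d_cor,
                "overshoot_projection": overshoot,
            }
        )
    report = pd.DataFrame(report_rows).set_index("sample_id")

    # 95% ellipses of replicate scatter on the first two PCoA axes
    ellipse_rows = []
    coords = ordination.coordinates
    if coords.shape[1] >= 2:
        meta = samples.join(coords.iloc[:, :2])
        for (gid, kind, tier), grp in meta[meta["kind"] != "complete"].groupby(
            ["genome_id", "kind", "tier"]
        ):
            if len(grp) < 3:
                continue
            ell = confidence_ellipse(grp.iloc[:, -2:].to_numpy())
            ell.update({"genome_id": gid, "kind": kind, "tier": tier, "n": len(grp)})
            ellipse_rows.append(ell)
    ellipses = pd.DataFrame(ellipse_rows)

    return ValidationReport(
        samples=samples,
        report=report,
        ordination=ordination,
        ellipses=ellipses,
        n_subsamples=n_expected,
    )


def plot_validation(report: ValidationReport, path: str, dpi: int = 150) -> None:
    """Scatter of the joint PCoA, coloured by genome, shaped by profile kind."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = report.ordination.coordinates
    if coords.shape[1] < 2:
        raise ValueError("ordination has fewer than 2 axes")
    meta = report.samples.join(coords.iloc[:, :2])
    genomes = sorted(meta["genome_id"].unique())
    cmap = plt.get_cmap("tab10")
    markers = {"complete": "s", "raw": "o", "corrected": "^"}
    fig, ax = plt.subplots(figsize=(7, 6))
    for i, gid in enumerate(genomes):
        for kind, marker in markers.items():
            sel = meta[(meta["genome_id"] == gid) & (meta["kind"] == kind)]
            if sel.empty:
                continue
            ax.scatter(
                sel.iloc[:, -2],
                sel.iloc[:, -1],
                c=[cmap(i % 10)],
                marker=marker,
                s=60 if kind == "complete" else 25,
                alpha=1.0 if kind == "complete" else 0.6,
                label=f"{gid} ({kind})" if kind == "complete" else None,
            )
    var = report.ordination.proportion_explained
    ax.set_xlabel(f"PCo1 ({var[0]:.1%})")
    ax.set_ylabel(f"PCo2 ({var[1]:.1%})")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
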