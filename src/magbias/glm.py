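"""Per-module binomial regression of fullness on completeness x phylum.

Each module gets its own weighted binomial GLM with logit link: the
response is the satisfied-step count out of the module's S steps (so S
acts as the binomial weight), and the linear predictor is completeness,
phylum (treatment coding) and their interaction — one completeness slope
per phylum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .catalog import ModuleCatalog
from .distill import FullnessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleGlmFit",
    "fit_module_glm",
    "fit_all_modules",
    "predict_fullness",
    "extract_slopes",
    "fullness_change",
]


@dataclass
class ModuleGlmFit:
    """Fitted coefficients of one module's completeness model.

    Coefficients are on the logit scale with completeness as a proportion.
    ``intercepts[p]`` and ``slopes[p]`` are the per-phylum derived
    intercept/slope (reference phylum's slope is the main completeness
    coefficient; other phyla add their interaction term).
    """

    module_id: str
    reference: str
    phyla: list[str]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    intercepts: dict[str, float]
    slopes: dict[str, float]
    slope_se: dict[str, float]
    converged: bool
    n_obs: int
    n_steps: int
    domain: str | None = None

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "reference": self.reference,
            "phyla": list(self.phyla),
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "intercepts": dict(self.intercepts),
            "slopes": dict(self.slopes),
            "slope_se": dict(self.slope_se),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_steps": int(self.n_steps),
            "domain": self.domain,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModuleGlmFit":
        return cls(**dict(d))


def _design(
    phylum: np.ndarray, completeness: np.ndarray, reference: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design matrix for completeness x phylum."""
    levels = sorted(np.unique(phylum))
    if reference not in levels:
        raise ValueError(f"reference phylum {reference!r} absent from data")
    others = [p for p in levels if p != reference]
    cols = [np.ones_like(completeness), ]
    names = ["Intercept"]
    for p in others:
        cols.append((phylum == p).astype(float))
        names.append(f"phylum[{p}]")
    cols.append(completeness)
    names.append("completeness")
    for p in others:
        cols.append(completeness * (phylum == p))
        names.append(f"completeness:phylum[{p}]")
    return np.column_stack(cols), names, levels


def _failed_fit(
    module_id: str, reference: str, levels: Sequence[str], n_obs: int, n_steps: int,
    domain: str | None,
) -> ModuleGlmFit:
    nan = float("nan")
    return ModuleGlmFit(
        module_id=module_id,
        reference=reference,
        phyla=list(levels),
        coefficients={},
        standard_errors={},
        intercepts={p: nan for p in levels},
        slopes={p: nan for p in levels},
        slope_se={p: nan for p in levels},
        converged=False,
        n_obs=n_obs,
        n_steps=n_steps,
        domain=domain,
    )


def fit_module_glm(
    matrix: FullnessMatrix,
    module_id: str,
    max_iter: int = 100,
    tol: float = 1e-8,
    reference: str | None = None,
) -> ModuleGlmFit:
    """Fit one module's weighted binomial GLM by IRLS.

    The endogenous variable is the two-column (successes, failures) form of
    the satisfied-step counts, which makes the module's step count the
    binomial weight. Non-convergence or a numerically singular design
    yields a fit flagged ``converged=False`` with NaN coefficients; such
    fits are excluded downstream rather than patched.
    """
    if module_id not in matrix.values.columns:
        raise KeyError(f"unknown module {module_id!r}")
    k = matrix.counts[module_id].to_numpy(dtype=float)
    n_steps = int(matrix.module_meta.loc[module_id, "n_steps"])
    domain = matrix.module_meta.loc[module_id].get("domain")
    phylum = matrix.genome_meta["phylum"].to_numpy()
    completeness = matrix.genome_meta["completeness"].to_numpy(dtype=float)
    if np.unique(completeness).size < 2:
        raise ValueError("need >= 2 distinct completeness values to fit a slope")

    levels = sorted(np.unique(phylum))
    ref = reference if reference is not None else levels[0]
    X, names, levels = _design(phylum, completeness, ref)
    endog = np.column_stack([k, n_steps - k])

    try:
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit(maxiter=max_iter, tol=tol, tol_criterion="deviance")
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        ok = bool(getattr(res, "converged", True)) and np.all(np.isfinite(params)) and np.all(
            np.isfinite(bse)
        )
    except Exception as exc:  # separation, singular design, ...
        logger.warning("module %s: GLM fit failed (%s)", module_id, exc)
        return _failed_fit(module_id, ref, levels, len(k), n_steps, domain)
    if not ok:
        logger.warning("module %s: GLM did not converge", module_id)
        return _failed_fit(module_id, ref, levels, len(k), n_steps, domain)

    coef = dict(zip(names, params))
    se = dict(zip(names, bse))
    idx = {n: i for i, n in enumerate(names)}
    intercepts, slopes, slope_se = {}, {}, {}
    for p in levels:
        if p == ref:
            intercepts[p] = coef["Intercept"]
            slopes[p] = coef["completeness"]
            slope_se[p] = se["completeness"]
        else:
            intercepts[p] = coef["Intercept"] + coef[f"phylum[{p}]"]
            slopes[p] = coef["completeness"] + coef[f"completeness:phylum[{p}]"]
            i, j = idx["completeness"], idx[f"completeness:phylum[{p}]"]
            slope_se[p] = float(np.sqrt(cov[i, i] + cov[j, j] + 2 * cov[i, j]))
    return ModuleGlmFit(
        module_id=module_id,
        reference=ref,
        phyla=list(levels),
        coefficients=coef,
        standard_errors=se,
        intercepts=intercepts,
        slopes=slopes,
        slope_se=slope_se,
        converged=True,
        n_obs=len(k),
        n_steps=n_steps,
        domain=domain,
    )


def fit_all_modules(
    matrix: FullnessMatrix,
    max_iter: int = 100,
    tol: float = 1e-8,
    reference: str | None = None,
) -> dict[str, ModuleGlmFit]:
    """Fit every module of the matrix; returns module_id -> fit."""
    fits = {
        m: fit_module_glm(matrix, m, max_iter=max_iter, tol=tol, reference=reference)
        for m in matrix.module_ids
    }
    n_bad = sum(1 for f in fits.values() if not f.converged)
    if n_bad:
        logger.info("%d of %d module fits did not converge", n_bad, len(fits))
    return fits


def predict_fullness(fit: ModuleGlmFit, phylum: str, completeness: float) -> float:
    """Predicted fullness at a given completeness for one phylum."""
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    if phylum not in fit.intercepts:
        raise ValueError(
            f"phylum {phylum!r} not in fit for module {fit.module_id} "
            f"(known: {fit.phyla})"
        )
    return float(expit(fit.intercepts[phylum] + fit.slopes[phylum] * completeness))


def extract_slopes(
    fits: Iterable[ModuleGlmFit],
    catalog: ModuleCatalog | None = None,
) -> pd.DataFrame:
    """Long table of per-(module, phylum) slope estimates.

    Rows from non-converged fits are excluded (and counted in the log);
    functional domain and step count come from the fit itself or, when
    given, the catalog.
    """
    rows = []
    n_dropped = 0
    for fit in fits:
        if not fit.converged:
            n_dropped += 1
            continue
        domain = fit.domain
        n_steps = fit.n_steps
        if catalog is not None and fit.module_id in catalog:
            module = catalog[fit.module_id]
            domain, n_steps = module.domain, module.n_steps
        for p in fit.phyla:
            rows.append(
                {
                    "module_id": fit.module_id,
                    "phylum": p,
                    "slope": fit.slopes[p],
                    "se": fit.slope_se[p],
                    "domain": domain,
                    "n_steps": n_steps,
                }
            )
    if n_dropped:
        logger.info("extract_slopes: %d non-converged fits excluded", n_dropped)
    return pd.DataFrame(
        rows, columns=["module_id", "phylum", "slope", "se", "domain", "n_steps"]
    )


def fullness_change(
    fit: ModuleGlmFit, phylum: str, c_lo: float = 0.70, c_hi: float = 1.00
) -> float:
    """Percentage-point fullness change between two completeness values."""
    if not fit.converged:
        raise ValueError(f"module {fit.module_id}: fit did not converge")
    return 100.0 * (
        predict_fullness(fit, phylum, c_hi) - predict_fullness(fit, phylum, c_lo)
    )
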