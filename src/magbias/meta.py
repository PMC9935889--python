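"""Meta-analysis of fullness-completeness slopes across modules.

The per-(module, phylum) slopes from the binomial GLMs become the
response of a linear mixed model with phylum, functional domain and
module step count as fixed effects and a module-level random intercept
(each module contributes one slope per phylum, so slopes of the same
module are correlated). Confidence intervals for the marginal predictions
and for the steps coefficient come from a percentile parametric
bootstrap: simulate new responses from the fitted model, refit, repeat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "MetaFit",
    "fit_slope_lmm",
    "bootstrap_cis",
    "marginal_predictions",
    "evaluate_hypotheses",
    "format_findings",
]

_REQUIRED = ("module_id", "phylum", "slope", "domain", "n_steps")


@dataclass
class MetaFit:
    """REML fit of slope ~ phylum + domain + steps + (1 | module)."""

    fe_params: pd.Series
    fe_se: pd.Series
    sigma2_module: float
    sigma2_resid: float
    singular: bool
    converged: bool
    phylum_levels: list[str]
    domain_levels: list[str]
    ref_phylum: str
    ref_domain: str | None
    steps_mean: float
    n_obs: int
    n_modules: int
    design_columns: list[str] = field(repr=False, default_factory=list)


def _build_design(
    table: pd.DataFrame,
    ref_phylum: str,
    ref_domain: str | None,
    phylum_levels: Sequence[str],
    domain_levels: Sequence[str],
    include_steps: bool = True,
) -> tuple[np.ndarray, list[str]]:
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for p in phylum_levels:
        if p == ref_phylum:
            continue
        cols.append((table["phylum"] == p).to_numpy(dtype=float))
        names.append(f"phylum[{p}]")
    if ref_domain is not None:
        for d in domain_levels:
            if d == ref_domain:
                continue
            cols.append((table["domain"] == d).to_numpy(dtype=float))
            names.append(f"domain[{d}]")
    if include_steps:
        cols.append(table["n_steps"].to_numpy(dtype=float))
        names.append("n_steps")
    return np.column_stack(cols), names


def _fit_mixed(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, names: list[str]
) -> tuple[pd.Series, pd.Series, float, float, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        last_exc: Exception | None = None
        # bfgs struggles near the variance boundary; fall back to slower
        # derivative-free optimizers before giving up
        for method in (None, "powell", "cg"):
            try:
                cand = model.fit(reml=True) if method is None else model.fit(
                    reml=True, method=method
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if res is None or (cand.converged and not res.converged):
                res = cand
            if res.converged:
                break
        if res is None:
            raise RuntimeError(f"mixed-model fit failed: {last_exc}")
    fe = pd.Series(np.asarray(res.fe_params, dtype=float), index=names)
    se = pd.Series(np.asarray(res.bse_fe, dtype=float), index=names)
    s2b = float(np.asarray(res.cov_re)[0, 0])
    s2e = float(res.scale)
    return fe, se, s2b, s2e, bool(res.converged)


def fit_slope_lmm(
    table: pd.DataFrame,
    ref_phylum: str | None = None,
    ref_domain: str | None = None,
) -> MetaFit:
    """Fit the random-intercept mixed model to a slope table.

    ``table`` needs columns module_id, phylum, slope, domain, n_steps.
    Reference levels default to the alphabetically first level of each
    factor; a factor with a single observed level is dropped from the
    design. A fit whose module-level variance collapses to (near) zero is
    flagged singular but still returned.
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"slope table lacks columns {missing}")
    if table["module_id"].nunique() < 2:
        raise ValueError("need >= 2 modules")
    table = table.reset_index(drop=True)

    phylum_levels = sorted(table["phylum"].unique())
    domain_levels = sorted(table["domain"].unique())
    ref_p = ref_phylum if ref_phylum is not None else phylum_levels[0]
    if ref_p not in phylum_levels:
        raise ValueError(f"unknown reference phylum {ref_p!r}")
    if len(domain_levels) < 2:
        ref_d = None  # constant factor: drop from the design
    else:
        ref_d = ref_domain if ref_domain is not None else domain_levels[0]
        if ref_d not in domain_levels:
            raise ValueError(f"unknown reference domain {ref_d!r}")

    include_steps = table["n_steps"].nunique() > 1  # constant column would alias the intercept
    X, names = _build_design(
        table, ref_p, ref_d, phylum_levels, domain_levels, include_steps
    )
    y = table["slope"].to_numpy(dtype=float)
    groups = table["module_id"].to_numpy()
    fe, se, s2b, s2e, converged = _fit_mixed(y, X, groups, names)
    total = s2b + s2e
    scale = max(float(np.var(y)), 1e-12)
    singular = total <= 1e-10 * scale or s2b / max(total, 1e-300) < 1e-6
    if singular:
        logger.info("mixed model is singular (module variance ~ 0)")
    return MetaFit(
        fe_params=fe,
        fe_se=se,
        sigma2_module=max(s2b, 0.0),
        sigma2_resid=max(s2e, 0.0),
        singular=singular,
        converged=converged,
        phylum_levels=phylum_levels,
        domain_levels=domain_levels,
        ref_phylum=ref_p,
        ref_domain=ref_d,
        steps_mean=float(table["n_steps"].mean()),
        n_obs=len(table),
        n_modules=int(table["module_id"].nunique()),
        design_columns=names,
    )


def _marginal_row(fit: MetaFit, focal: str, level: str) -> np.ndarray:
    """Design row for one focal level: non-focal factors at reference, steps at mean."""
    x = np.zeros(len(fit.design_columns))
    x[fit.design_columns.index("Intercept")] = 1.0
    if "n_steps" in fit.design_columns:
        x[fit.design_columns.index("n_steps")] = fit.steps_mean
    name = f"{focal}[{level}]"
    if name in fit.design_columns:
        x[fit.design_columns.index(name)] = 1.0
    return x


def marginal_predictions(fit: MetaFit, focal: str) -> pd.Series:
    """Predicted mean slope per level of the focal factor.

    The non-focal factor sits at its reference level and step count at its
    mean, so levels are compared on equal footing.
    """
    if focal == "phylum":
        levels = fit.phylum_levels
    elif focal == "domain":
        if fit.ref_domain is None:
            raise ValueError("domain had a single level and was dropped from the model")
        levels = fit.domain_levels
    else:
        raise ValueError(f"focal must be 'phylum' or 'domain', got {focal!r}")
    if len(levels) < 2:
        raise ValueError(f"focal factor {focal!r} has fewer than 2 levels")
    beta = fit.fe_params.to_numpy()
    return pd.Series(
        {lev: float(_marginal_row(fit, focal, lev) @ beta) for lev in levels},
        name=f"marginal_slope[{focal}]",
    )


def bootstrap_cis(
    fit: MetaFit,
    table: pd.DataFrame,
    n_sim: int = 999,
    seed: int | np.random.Generator = 0,
    max_fail_frac: float = 0.05,
) -> pd.DataFrame:
    """Percentile parametric-bootstrap 95% CIs for the reported quantities.

    Each simulation draws new module intercepts ~ N(0, sigma2_module) and
    residuals ~ N(0, sigma2_resid), rebuilds the response around the fixed
    effects, refits, and records the marginal predictions per phylum/domain
    level plus the steps coefficient. Failed refits are dropped and
    counted; more than ``max_fail_frac`` failures aborts.

    Returns a table with columns factor, level, estimate, lo, hi, n_boot.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = table.reset_index(drop=True)
    X, names = _build_design(
        table,
        fit.ref_phylum,
        fit.ref_domain,
        fit.phylum_levels,
        fit.domain_levels,
        include_steps="n_steps" in fit.design_columns,
    )
    if names != fit.design_columns:
        raise ValueError("slope table does not match the fitted design")
    groups = table["module_id"].to_numpy()
    codes, _ = pd.factorize(groups)
    n_groups = codes.max() + 1
    mu = X @ fit.fe_params.to_numpy()
    sd_b = np.sqrt(fit.sigma2_module)
    sd_e = np.sqrt(fit.sigma2_resid)

    quantities: list[tuple[str, str]] = [("phylum", p) for p in fit.phylum_levels]
    if fit.ref_domain is not None:
        quantities += [("domain", d) for d in fit.domain_levels]
    if "n_steps" in fit.design_columns:
        quantities.append(("steps", "n_steps"))

    sims: list[dict[tuple[str, str], float]] = []
    n_fail = 0
    for _ in range(n_sim):
        b = rng.normal(0.0, sd_b, size=n_groups)
        e = rng.normal(0.0, sd_e, size=len(table))
        y_star = mu + b[codes] + e
        try:
            fe, _, s2b, s2e, ok = _fit_mixed(y_star, X, groups, names)
            if not (ok and np.all(np.isfinite(fe.to_numpy()))):
                raise RuntimeError("refit did not converge")
        except Exception:
            n_fail += 1
            continue
        boot_fit = MetaFit(
            fe_params=fe,
            fe_se=fe * np.nan,
            sigma2_module=max(s2b, 0.0),
            sigma2_resid=max(s2e, 0.0),
            singular=False,
            converged=True,
            phylum_levels=fit.phylum_levels,
            domain_levels=fit.domain_levels,
            ref_phylum=fit.ref_phylum,
            ref_domain=fit.ref_domain,
            steps_mean=fit.steps_mean,
            n_obs=len(table),
            n_modules=n_groups,
            design_columns=names,
        )
        record: dict[tuple[str, str], float] = {}
        for factor, level in quantities:
            if factor == "steps":
                record[(factor, level)] = float(fe["n_steps"])
            else:
                record[(factor, level)] = float(
                    _marginal_row(boot_fit, factor, level) @ fe.to_numpy()
                )
        sims.append(record)

    if n_fail > max_fail_frac * n_sim:
        raise RuntimeError(
            f"{n_fail}/{n_sim} bootstrap refits failed (> {max_fail_frac:.0%})"
        )
    if n_fail:
        logger.info("bootstrap: %d of %d refits failed and were dropped", n_fail, n_sim)

    rows = []
    for factor, level in quantities:
        draws = np.array([s[(factor, level)] for s in sims])
        if factor == "steps":
            est = float(fit.fe_params["n_steps"])
        else:
            est = float(_marginal_row(fit, factor, level) @ fit.fe_params.to_numpy())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "factor": factor,
                "level": level,
                "estimate": est,
                "lo": float(lo),
                "hi": float(hi),
                "n_boot": len(draws),
            }
        )
    return pd.DataFrame(rows)


def evaluate_hypotheses(ci_table: pd.DataFrame) -> dict:
    """Read off the evidence from a bootstrap CI table.

    Non-overlapping 95% CIs between two levels of a categorical factor are
    treated as evidence of a difference; a steps-coefficient CI excluding
    zero as evidence of an association with module complexity.
    """
    findings: dict = {"phylum": [], "domain": [], "steps": None}
    for factor in ("phylum", "domain"):
        sub = ci_table[ci_table["factor"] == factor]
        levels = list(sub["level"])
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                ra = sub[sub["level"] == a].iloc[0]
                rb = sub[sub["level"] == b].iloc[0]
                disjoint = ra["hi"] < rb["lo"] or rb["hi"] < ra["lo"]
                if disjoint:
                    findings[factor].append((a, b))
    steps = ci_table[ci_table["factor"] == "steps"]
    if len(steps):
        lo, hi = float(steps.iloc[0]["lo"]), float(steps.iloc[0]["hi"])
        if hi < 0:
            direction = "negative"
        elif lo > 0:
            direction = "positive"
        else:
            direction = None
        findings["steps"] = {"lo": lo, "hi": hi, "direction": direction}
    return findings


def format_findings(findings: dict) -> str:
    """Human-readable summary of :func:`evaluate_hypotheses` output."""
    lines = []
    for factor in ("phylum", "domain"):
        pairs = findings.get(factor, [])
        if pairs:
            for a, b in pairs:
                lines.append(
                    f"{factor}: 95% CIs of {a} and {b} do not overlap "
                    "(evidence of a difference)"
                )
        else:
            lines.append(f"{factor}: no pair of levels with non-overlapping 95% CIs")
    steps = findings.get("steps")
    if steps is not None:
        if steps["direction"]:
            lines.append(
                f"steps: coefficient CI [{steps['lo']:.4g}, {steps['hi']:.4g}] "
                f"excludes zero ({steps['direction']} association with module complexity)"
            )
        else:
            lines.append(
                f"steps: coefficient CI [{steps['lo']:.4g}, {steps['hi']:.4g}] overlaps zero"
            )
    return "\n".join(lines)
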