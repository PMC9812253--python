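"""Statistical layer: hemispheric mixed model, age correlations, summaries.

The central model is the linear mixed-effects model

    ITPC ~ 1 + Hemisphere / ERF + (1 | subject)

with the intercept corresponding to the right hemisphere, a left-
hemisphere main effect, and the sustained-field amplitude (ERF) slope
nested within each hemisphere.  The nested coding is expanded
explicitly to avoid formula-dialect ambiguity::

    [1, 1{left}, ERF * 1{left}, ERF * 1{right}]

The model is fit by REML (statsmodels ``MixedLM``) with a random
intercept per subject.  t-based p-values use the residual-df
approximation ``df = n_obs - n_fixed`` (documented; Satterthwaite is
not available on this backend).  The intraclass correlation is
``tau^2 / (tau^2 + sigma^2)``; marginal/conditional R^2 follow the
Nakagawa variance decomposition.

Age associations are two-sided Pearson correlations, Bonferroni-
corrected within a declared family (the coordinate family is 6 tests:
X, Y, Z in each hemisphere; the ITPC/ERF age correlations are reported
uncorrected, family size 1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "MixedModelResult",
    "CorrelationResult",
    "build_design",
    "fit_itpc_model",
    "correlate_with_age",
    "hemispheric_summary",
    "report",
]

FIXED_TERMS = ("Intercept", "Hemisphere_Left", "Hemisphere_Left:Amplitude",
               "Hemisphere_Right:Amplitude")


@dataclass(frozen=True)
class MixedModelResult:
    """REML fit of the hemisphere / nested-amplitude mixed model."""

    fixed_effects: dict  # term -> {estimate, standard_error, t_value, p_value}
    random_intercept_variance: float  # tau^2
    residual_variance: float  # sigma^2
    icc: float
    n_subjects: int
    n_observations: int
    r2_marginal: float
    r2_conditional: float
    converged: bool
    df_method: str = "residual"


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson correlation with its Bonferroni-adjusted p-value."""

    variable: str
    hemisphere: str
    r: float
    p_raw: float
    p_adjusted: float
    family_size: int
    n: int
    method: str = "pearson"


def build_design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Response, fixed-effects design matrix and group labels from the
    long-format analysis table (columns subject, hemisphere, itpc, erf)."""
    hemi = table["hemisphere"].to_numpy()
    unknown = set(hemi) - {"left", "right"}
    if unknown:
        raise ValueError(f"unknown hemisphere labels {sorted(unknown)}")
    left = (hemi == "left").astype(float)
    erf = table["erf"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table)), left, erf * left, erf * (1.0 - left)])
    return table["itpc"].to_numpy(dtype=float), X, table["subject"].to_numpy()


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: aliased columns have ~0 diagonal in R
        _, R, piv = scipy.linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        aliased = [FIXED_TERMS[piv[i]] for i in range(X.shape[1]) if i >= rank or diag[i] <= tol]
        raise ValueError(f"rank-deficient fixed-effects design; aliased terms: {sorted(set(aliased))}")


def _gls_standard_errors(
    X: np.ndarray, groups: np.ndarray, tau2: float, sigma2: float
) -> np.ndarray:
    """Model-based SEs of the fixed effects at the fitted variance
    components: sqrt(diag((X' V^-1 X)^-1)) with V = sigma^2 I + tau^2 J
    per subject.  Well defined on the tau^2 = 0 boundary, where the
    numerical Hessian is not."""
    A = np.zeros((X.shape[1], X.shape[1]))
    for g in pd.unique(groups):
        Xg = X[groups == g]
        n_g = len(Xg)
        shrink = tau2 / (sigma2 + n_g * tau2)
        col = Xg.sum(axis=0)
        A += (Xg.T @ Xg - shrink * np.outer(col, col)) / sigma2
    return np.sqrt(np.diag(np.linalg.inv(A)))


def fit_itpc_model(table: pd.DataFrame) -> MixedModelResult:
    """Fit ITPC ~ 1 + Hemisphere/ERF + (1|subject) by REML.

    Requires both hemispheres to be present; raises on a rank-deficient
    design (e.g. an all-zero ERF column aliases the nested slopes).
    """
    if set(table["hemisphere"]) != {"left", "right"}:
        raise ValueError("analysis table must contain both hemispheres")
    y, X, groups = build_design(table)
    _check_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        fit = model.fit(reml=True)
        # gradient optimizers can stall (or falsely report convergence)
        # when tau^2 sits on the 0 boundary; cross-check with
        # derivative-free Powell and keep the better REML criterion
        refit = model.fit(reml=True, method="powell")
        if not np.isfinite(fit.llf) or (np.isfinite(refit.llf) and refit.llf > fit.llf + 1e-10):
            fit = refit
    tau2 = float(np.squeeze(fit.cov_re))
    sigma2 = float(fit.scale)
    k = X.shape[1]
    df = len(y) - k
    bse = _gls_standard_errors(X, groups, tau2, sigma2)
    fixed = {}
    for i, term in enumerate(FIXED_TERMS):
        est = float(fit.fe_params[i])
        se = float(bse[i])
        t = est / se
        fixed[term] = {
            "estimate": est,
            "standard_error": se,
            "t_value": t,
            "p_value": float(2 * sps.t.sf(abs(t), df)),
        }
    var_fixed = float(np.var(X @ fit.fe_params))
    total = var_fixed + tau2 + sigma2
    return MixedModelResult(
        fixed_effects=fixed,
        random_intercept_variance=tau2,
        residual_variance=sigma2,
        icc=tau2 / (tau2 + sigma2),
        n_subjects=int(pd.unique(groups).size),
        n_observations=len(y),
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + tau2) / total,
        converged=bool(fit.converged),
    )


def correlate_with_age(
    table: pd.DataFrame,
    variables: tuple[str, ...] = ("itpc", "erf"),
    family_size: int | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations of each variable with age, per hemisphere.

    ``family_size`` sets the Bonferroni family
    (``p_adj = min(1, p * family)``); by default it is the number of
    tests actually run.
    """
    results = []
    pairs = [(v, h) for v in variables for h in ("left", "right")]
    family = family_size if family_size is not None else len(pairs)
    for var, hemi in pairs:
        sub = table[table["hemisphere"] == hemi]
        age = sub["age"].to_numpy(dtype=float)
        vals = sub[var].to_numpy(dtype=float)
        ok = np.isfinite(age) & np.isfinite(vals)
        age, vals = age[ok], vals[ok]
        if len(age) < 3:
            raise ValueError(f"need >= 3 complete pairs for {var}/{hemi}, got {len(age)}")
        if np.std(age) == 0 or np.std(vals) == 0:
            raise ValueError(f"zero variance in {var}/{hemi}; correlation undefined")
        r, p = sps.pearsonr(age, vals)
        results.append(
            CorrelationResult(
                variable=var,
                hemisphere=hemi,
                r=float(r),
                p_raw=float(p),
                p_adjusted=float(min(1.0, p * family)),
                family_size=family,
                n=len(age),
            )
        )
    return results


def hemispheric_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-hemisphere mean and sample SD (n-1) of ITPC and ERF amplitude.

    SD is reported as missing (NaN) for a single observation.
    """
    for hemi in ("left", "right"):
        if (table["hemisphere"] == hemi).sum() < 1:
            raise ValueError(f"no rows for hemisphere {hemi!r}")
    return (
        table.groupby("hemisphere")[["itpc", "erf"]]
        .agg(["mean", lambda x: x.std(ddof=1)])
        .rename(columns={"<lambda_0>": "sd"}, level=1)
    )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping (reproducibility tag)."""
    payload = json.dumps(_to_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def report(results: dict, out_dir, *, config=None, seed: int | None = None) -> dict:
    """Write a machine-readable (JSON) and human-readable (markdown) report.

    ``results`` maps section names to result objects (mixed model,
    correlation lists, summary frames).  The run config and seed, when
    given, are embedded together with a config hash so any report can
    be traced to the exact run that produced it.
    """
    if not results:
        raise ValueError("refusing to write a report of empty results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"results": _to_jsonable(results)}
    if config is not None:
        payload["config"] = _to_jsonable(config)
        payload["config_hash"] = config_hash(config)
    if seed is not None:
        payload["seed"] = int(seed)
    (out_dir / "stats_report.json").write_text(json.dumps(payload, indent=2))

    lines = ["# ASSR analysis report", ""]
    if seed is not None:
        lines.append(f"- seed: {seed}")
    if config is not None:
        lines.append(f"- config hash: `{payload['config_hash']}`")
    lines.append("")
    for section, value in results.items():
        lines.append(f"## {section}")
        lines.append("")
        if isinstance(value, MixedModelResult):
            lines.append("| term | estimate | SE | t | p |")
            lines.append("|---|---|---|---|---|")
            for term, row in value.fixed_effects.items():
                lines.append(
                    f"| {term} | {row['estimate']:.3f} | {row['standard_error']:.3f} "
                    f"| {row['t_value']:.2f} | {row['p_value']:.3g} |"
                )
            lines += [
                "",
                f"sigma^2 = {value.residual_variance:.2f}, "
                f"tau00 = {value.random_intercept_variance:.2f}, ICC = {value.icc:.2f}",
                f"N = {value.n_subjects} subjects, {value.n_observations} observations",
                f"Marginal R2 / Conditional R2 = {value.r2_marginal:.3f} / {value.r2_conditional:.3f}",
            ]
        elif isinstance(value, list) and value and isinstance(value[0], CorrelationResult):
            lines.append("| variable | hemisphere | r | p | p (Bonferroni) | n |")
            lines.append("|---|---|---|---|---|---|")
            for c in value:
                lines.append(
                    f"| {c.variable} | {c.hemisphere} | {c.r:.3f} | {c.p_raw:.3g} "
                    f"| {c.p_adjusted:.3g} | {c.n} |"
                )
        elif isinstance(value, pd.DataFrame):
            lines.append("```\n" + value.to_string() + "\n```")
        else:
            lines.append(f"```\n{json.dumps(_to_jsonable(value), indent=2)}\n```")
        lines.append("")
    (out_dir / "stats_report.md").write_text("\n".join(lines))
    return payload
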