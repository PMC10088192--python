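"""Marginal (GEE) inference for clustered pixel observations.

The parametric-map values are analysed with a Gaussian-identity
generalized linear model estimated by generalized estimating
equations: pixels are the observations, the animal is the cluster, and
the mean structure is the full factorial state × condition × region
with treatment (reference-cell) coding — control / fed / cortex as the
reference levels. The working correlation is exchangeable by default
(pixels within an animal share a constant pairwise correlation);
independence is available. Standard errors come from the cluster-robust
sandwich estimator, and effects are tested with multi-degree-of-freedom
Wald chi-square statistics.

Estimation alternates a β update by weighted least squares under the
current working covariance with moment re-estimation of the dispersion
φ and the exchangeable parameter α from Pearson residuals, until the
coefficients stabilize.

Covariance use: pairwise contrasts are reported with cluster-robust
(sandwich) standard errors. The omnibus multi-degree-of-freedom effect
tests default to the model-based (working) covariance, because the
unadjusted sandwich is markedly anticonservative in multi-df Wald
tests at the cohort sizes this design uses (~24 animals), while the
model-based covariance is exactly valid when the exchangeable working
correlation is correctly specified — which the phantom's
animal-intercept-plus-independent-pixel-noise generative model
guarantees. ``wald_cov="robust"`` switches the effect tests to the
sandwich.

The module also provides pairwise cell contrasts with robust SEs, the
step-down Holm–Šídák multiplicity adjustment, and unpaired t-tests for
physiology endpoints (body weight, glucose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import CONDITIONS, REGIONS, STATES

SIGNIFICANCE_LEVEL = 0.05


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# factorial design with treatment coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorialDesign:
    """Treatment-coded state × condition × region design description."""

    states: tuple[str, ...]
    conditions: tuple[str, ...]
    regions: tuple[str, ...]
    column_names: tuple[str, ...]

    def cell_vector(self, state: str, condition: str, region: str) -> np.ndarray:
        """Row vector mapping coefficients to the (s, c, r) cell mean."""
        for level, levels, factor in (
            (state, self.states, "state"),
            (condition, self.conditions, "condition"),
            (region, self.regions, "region"),
        ):
            if level not in levels:
                raise InferenceError(f"unknown {factor} level {level!r}")
        s = np.array([state == lev for lev in self.states[1:]], dtype=float)
        c = np.array([condition == lev for lev in self.conditions[1:]], dtype=float)
        r = np.array([region == lev for lev in self.regions[1:]], dtype=float)
        return np.concatenate(
            [
                [1.0],
                s,
                c,
                r,
                np.outer(s, c).ravel(),
                np.outer(s, r).ravel(),
                np.outer(c, r).ravel(),
                np.einsum("i,j,k->ijk", s, c, r).ravel(),
            ]
        )

    def effect_groups(self) -> dict[str, np.ndarray]:
        """Column indices of each effect term, for Wald tests."""
        ns, nc, nr = len(self.states) - 1, len(self.conditions) - 1, len(self.regions) - 1
        sizes = {
            "state": ns,
            "condition": nc,
            "region": nr,
            "state:condition": ns * nc,
            "state:region": ns * nr,
            "condition:region": nc * nr,
            "state:condition:region": ns * nc * nr,
        }
        groups, start = {}, 1
        for name, size in sizes.items():
            groups[name] = np.arange(start, start + size)
            start += size
        return groups


def build_design(table: pd.DataFrame) -> tuple[np.ndarray, FactorialDesign]:
    """Design matrix for the observations in ``table``.

    Factor levels are taken in the canonical order (control/tumor,
    fed/fasted, cortex/hippocampus/hypothalamus/thalamus) restricted
    to the levels present.
    """
    states = tuple(s for s in STATES if s in set(table["state"]))
    conditions = tuple(c for c in CONDITIONS if c in set(table["condition"]))
    regions = tuple(r for r in REGIONS if r in set(table["region"]))
    extra = set(table["region"]) - set(REGIONS)
    if extra:
        regions = regions + tuple(sorted(extra))
    design = FactorialDesign(states, conditions, regions, _column_names(states, conditions, regions))
    x = np.stack(
        [
            design.cell_vector(s, c, r)
            for s, c, r in zip(table["state"], table["condition"], table["region"])
        ]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise InferenceError(
            "rank-deficient factorial design: not every state x condition x region cell is observed"
        )
    return x, design


def _column_names(states, conditions, regions) -> tuple[str, ...]:
    s = [f"state[{v}]" for v in states[1:]]
    c = [f"condition[{v}]" for v in conditions[1:]]
    r = [f"region[{v}]" for v in regions[1:]]
    names = ["intercept", *s, *c, *r]
    names += [f"{a}:{b}" for a in s for b in c]
    names += [f"{a}:{b}" for a in s for b in r]
    names += [f"{a}:{b}" for a in c for b in r]
    names += [f"{a}:{b}:{d}" for a in s for b in c for d in r]
    return tuple(names)


# ---------------------------------------------------------------------------
# GEE estimation
# ---------------------------------------------------------------------------


@dataclass
class GEEResult:
    params: pd.Series
    cov_robust: np.ndarray
    cov_naive: np.ndarray
    alpha: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    working_correlation: str
    wald_covariance: str
    design: FactorialDesign
    wald_tests: pd.DataFrame = field(repr=False)

    def wald_pvalue(self, effect: str) -> float:
        row = self.wald_tests.loc[self.wald_tests["effect"] == effect]
        if row.empty:
            raise InferenceError(f"no Wald test for effect {effect!r}")
        return float(row["p"].iloc[0])


def _exchangeable_inverse(n: int, alpha: float) -> np.ndarray:
    """Closed-form inverse of the n×n exchangeable correlation matrix."""
    eye = np.eye(n)
    if n == 1 or alpha == 0.0:
        return eye
    denom = 1.0 + (n - 1) * alpha
    return (eye - (alpha / denom) * np.ones((n, n))) / (1.0 - alpha)


def fit_gee(
    table: pd.DataFrame,
    parameter: str | None = None,
    working_correlation: str = "exchangeable",
    max_iter: int = 100,
    tol: float = 1e-8,
    wald_cov: str = "naive",
) -> GEEResult:
    """Fit the factorial GEE to pixel observations clustered by animal.

    ``table`` needs columns value / animal_id / state / condition /
    region (and parameter, if ``parameter`` is given to select one
    dependent variable). ``wald_cov`` chooses the covariance behind
    the omnibus effect tests ("naive" model-based by default, see
    module docstring; "robust" for the sandwich). Non-convergence is
    flagged in the result, not raised.
    """
    if working_correlation not in ("independence", "exchangeable"):
        raise InferenceError(f"unknown working correlation {working_correlation!r}")
    if wald_cov not in ("naive", "robust"):
        raise InferenceError(f"wald_cov must be 'naive' or 'robust', got {wald_cov!r}")
    data = table if parameter is None else table.loc[table["parameter"] == parameter]
    if data.empty:
        raise InferenceError("no observations to fit")
    if data["animal_id"].nunique() < 2:
        raise InferenceError("need at least 2 clusters (animals)")

    x, design = build_design(data)
    y = data["value"].to_numpy(dtype=float)
    n_obs, p = x.shape

    cluster_ids, cluster_index = np.unique(data["animal_id"].to_numpy(), return_inverse=True)
    clusters = [np.flatnonzero(cluster_index == i) for i in range(len(cluster_ids))]

    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    alpha = 0.0
    scale = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - x @ beta
        scale = float(resid @ resid) / max(n_obs - p, 1)
        if working_correlation == "exchangeable":
            e = resid / np.sqrt(scale)
            num, denom_pairs = 0.0, 0.0
            for idx in clusters:
                ei = e[idx]
                m = ei.size
                if m > 1:
                    num += (ei.sum() ** 2 - ei @ ei) / 2.0
                    denom_pairs += m * (m - 1) / 2.0
            alpha = num / max(denom_pairs - p, 1.0)
            max_n = max(len(idx) for idx in clusters)
            alpha = float(np.clip(alpha, -1.0 / max(max_n - 1, 1) + 1e-6, 0.999))
        a = np.zeros((p, p))
        b = np.zeros(p)
        for idx in clusters:
            xi, yi = x[idx], y[idx]
            rinv = _exchangeable_inverse(len(idx), alpha)
            xr = xi.T @ rinv
            a += xr @ xi
            b += xr @ yi
        new_beta = np.linalg.solve(a, b)
        delta = np.max(np.abs(new_beta - beta)) / max(1.0, np.max(np.abs(beta)))
        beta = new_beta
        if delta < tol:
            converged = True
            break

    # covariance: naive A^{-1} (with the scale) and the cluster-robust sandwich
    resid = y - x @ beta
    a = np.zeros((p, p))
    meat = np.zeros((p, p))
    for idx in clusters:
        xi, ri = x[idx], resid[idx]
        rinv = _exchangeable_inverse(len(idx), alpha) / scale
        xr = xi.T @ rinv
        a += xr @ xi
        u = xr @ ri
        meat += np.outer(u, u)
    a_inv = np.linalg.inv(a)
    cov_robust = a_inv @ meat @ a_inv
    cov_robust = (cov_robust + cov_robust.T) / 2.0

    params = pd.Series(beta, index=list(design.column_names))
    wald = _wald_table(beta, a_inv if wald_cov == "naive" else cov_robust, design)
    return GEEResult(
        params=params,
        cov_robust=cov_robust,
        cov_naive=a_inv,
        alpha=float(alpha),
        scale=scale,
        n_clusters=len(clusters),
        n_obs=n_obs,
        converged=converged,
        n_iter=it,
        working_correlation=working_correlation,
        wald_covariance=wald_cov,
        design=design,
        wald_tests=wald,
    )


def _wald_table(beta: np.ndarray, cov: np.ndarray, design: FactorialDesign) -> pd.DataFrame:
    rows = []
    for effect, idx in design.effect_groups().items():
        if idx.size == 0:
            continue
        bg = beta[idx]
        cg = cov[np.ix_(idx, idx)]
        try:
            stat = float(bg @ np.linalg.solve(cg, bg))
        except np.linalg.LinAlgError:
            stat = float("nan")
        df = int(idx.size)
        rows.append({"effect": effect, "statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    description: str
    estimate: float
    se: float
    z: float
    p: float
    p_adjusted: float | None = None
    adjust_method: str | None = None


def pairwise_contrast(
    result: GEEResult,
    factor: str,
    level_a: str,
    level_b: str,
    **fixed: str,
) -> ContrastResult:
    """Robust Wald contrast of two cell means: level_b − level_a of
    ``factor``, with the other two factors held at the levels given in
    ``fixed`` (e.g. ``condition="fed", region="cortex"``)."""
    cells = {}
    for level in (level_a, level_b):
        kw = dict(fixed)
        kw[factor] = level
        cells[level] = result.design.cell_vector(kw["state"], kw["condition"], kw["region"])
    contrast = cells[level_b] - cells[level_a]
    estimate = float(contrast @ result.params.to_numpy())
    var = float(contrast @ result.cov_robust @ contrast)
    se = float(np.sqrt(max(var, 0.0)))
    if np.allclose(contrast, 0.0):
        return ContrastResult(f"{factor}: {level_b} - {level_a} | {fixed}", 0.0, 0.0, 0.0, 1.0)
    z = estimate / se if se > 0 else np.inf * np.sign(estimate)
    pval = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    desc = f"{factor}: {level_b} - {level_a} | " + ", ".join(f"{k}={v}" for k, v in sorted(fixed.items()))
    return ContrastResult(desc, estimate, se, float(z), pval)


# ---------------------------------------------------------------------------
# multiplicity adjustment and physiology t-tests
# ---------------------------------------------------------------------------


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm–Šídák adjustment, returned in the input order.

    Sort ascending; adjusted_(i) = max_{j<=i} [1 − (1 − p_(j))^(m−j+1)]
    (1-based ranks), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepwise = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def unpaired_ttest(group_a, group_b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; Welch (unequal variances) by default.

    Returns (t, df, p). Degenerate zero-variance inputs: two constant
    equal groups give (0, df, 1); constant but different groups give
    p = 0 with an infinite statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def physiology_ttests(
    measurements: pd.DataFrame,
    value_column: str,
    comparisons: list[tuple[dict, dict, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Holm–Šídák-corrected family of unpaired t-tests on per-animal
    endpoints (body weight, glucose).

    Default family: fed vs fasted within each state, and control vs
    tumor within each condition. ``measurements`` needs columns state,
    condition and ``value_column``.
    """
    if comparisons is None:
        comparisons = [
            ({"state": s, "condition": "fed"}, {"state": s, "condition": "fasted"}, f"{s}: fed vs fasted")
            for s in STATES
        ] + [
            ({"state": "control", "condition": c}, {"state": "tumor", "condition": c}, f"{c}: control vs tumor")
            for c in CONDITIONS
        ]
    rows = []
    for sel_a, sel_b, label in comparisons:
        mask_a = np.logical_and.reduce([measurements[k] == v for k, v in sel_a.items()])
        mask_b = np.logical_and.reduce([measurements[k] == v for k, v in sel_b.items()])
        t, df, p = unpaired_ttest(
            measurements.loc[mask_a, value_column],
            measurements.loc[mask_b, value_column],
            equal_var=equal_var,
        )
        rows.append({"comparison": label, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak_adjust(out["p"].to_numpy())
    out["method"] = "holm-sidak"
    return out
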