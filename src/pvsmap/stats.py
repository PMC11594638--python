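"""Statistical analysis layer: correlations, the nine-transformation
normality ladder, linear regressions, and quartile group tests.

The ladder tries nine power-type transformations of a positive outcome
(cubic, square, identity, square root, logarithmic, 1/square root, inverse,
1/square, 1/cubic), scores each by the Shapiro-Wilk W statistic on every
regional outcome vector, aggregates by the minimum W across regions (the
worst region decides), and keeps the candidate with the largest aggregate.
Regression models are ordinary least squares on the transformed outcome:
one unadjusted fit per regressor, and an adjusted fit adding age, sex and
hypertension; when the regressor of interest is itself one of the
covariates, its adjusted row is read off the covariates-only model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TRANSFORMS",
    "LADDER_ORDER",
    "TransformLadder",
    "ModelResult",
    "correlations",
    "select_transformation",
    "fit_models",
    "quartile_assign",
    "quartile_tests",
    "DEFAULT_COVARIATES",
]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "female", "hypertension")

# candidate name -> (function, domain guard)
TRANSFORMS: dict = {
    "cubic": (lambda x: x**3, lambda x: np.ones_like(x, dtype=bool)),
    "square": (lambda x: x**2, lambda x: np.ones_like(x, dtype=bool)),
    "identity": (lambda x: x, lambda x: np.ones_like(x, dtype=bool)),
    "square root": (np.sqrt, lambda x: x >= 0),
    "logarithmic": (np.log, lambda x: x > 0),
    "1/square root": (lambda x: 1 / np.sqrt(x), lambda x: x > 0),
    "inverse": (lambda x: 1 / x, lambda x: x != 0),
    "1/square": (lambda x: 1 / x**2, lambda x: x != 0),
    "1/cubic": (lambda x: 1 / x**3, lambda x: x != 0),
}
LADDER_ORDER = tuple(TRANSFORMS)


@dataclass
class TransformLadder:
    """Result of the normality ladder: per-candidate scores and the winner."""

    scores: dict[str, float]
    per_region_w: dict[str, dict[str, float]]
    chosen: str

    def apply(self, x: np.ndarray) -> np.ndarray:
        return TRANSFORMS[self.chosen][0](np.asarray(x, dtype=float))


@dataclass
class ModelResult:
    """One regressor's row of a regression table."""

    outcome: str
    regressor: str
    beta: float
    p_value: float
    r2_pct: float
    adjusted: bool
    n: int
    se: float
    covariates: tuple[str, ...] = ()
    degenerate: bool = False

    def as_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "regressor": self.regressor,
            "model": "adjusted" if self.adjusted else "unadjusted",
            "beta": self.beta,
            "p": self.p_value,
            "r2_pct": self.r2_pct,
            "n": self.n,
            "se": self.se,
            "degenerate": self.degenerate,
        }
        return d


def correlations(vectors: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    """Pearson r, its square (R^2) and Spearman rho for every pair.

    Missing pairs are dropped pairwise (logged). A zero-variance vector
    makes its correlations NaN, flagged with a warning.
    """
    names = list(vectors)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            x = np.asarray(vectors[names[i]], dtype=float)
            y = np.asarray(vectors[names[j]], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < len(x):
                log.info("dropping %d incomplete pairs for (%s, %s)",
                         int(len(x) - ok.sum()), names[i], names[j])
            x, y = x[ok], y[ok]
            if len(x) < 3:
                raise ValueError(f"fewer than 3 paired observations for ({names[i]}, {names[j]})")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"zero variance in pair ({names[i]}, {names[j]}); correlation undefined",
                    stacklevel=2,
                )
                pr = srho = np.nan
            else:
                pr = sps.pearsonr(x, y).statistic
                srho = sps.spearmanr(x, y).statistic
            r.iloc[i, j] = r.iloc[j, i] = pr
            rho.iloc[i, j] = rho.iloc[j, i] = srho
    return {"pearson_r": r, "r_squared": r**2, "spearman_rho": rho}


def select_transformation(region_vectors: dict[str, np.ndarray]) -> TransformLadder:
    """Run the nine-candidate ladder over the regional outcome vectors.

    A candidate is disqualified if it maps any observation of any region to
    a non-finite value. Scores are Shapiro-Wilk W aggregated by the minimum
    over regions; the maximizing candidate wins, with exact ties broken by
    ladder order.
    """
    scores: dict[str, float] = {}
    per_region: dict[str, dict[str, float]] = {}
    for name in LADDER_ORDER:
        fn, guard = TRANSFORMS[name]
        ws: dict[str, float] = {}
        valid = True
        for region, vec in region_vectors.items():
            x = np.asarray(vec, dtype=float)
            if len(x) < 3:
                raise ValueError("need at least 3 observations per region")
            if not np.all(guard(x)):
                valid = False
                break
            with np.errstate(all="ignore"):
                t = fn(x)
            if not np.all(np.isfinite(t)):
                valid = False
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ws[region] = float(sps.shapiro(t).statistic)
        if valid:
            per_region[name] = ws
            scores[name] = min(ws.values())
    if not scores:
        raise ValueError("all ladder candidates disqualified on this data")
    chosen = max(scores, key=lambda k: (scores[k], -LADDER_ORDER.index(k)))
    return TransformLadder(scores=scores, per_region_w=per_region, chosen=chosen)


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_models(
    table: pd.DataFrame,
    outcome: str,
    regressors: list[str],
    adjust: bool = False,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    transform: TransformLadder | str | None = None,
) -> list[ModelResult]:
    """One OLS fit per regressor on the (optionally transformed) outcome.

    Unadjusted: outcome ~ regressor. Adjusted: outcome ~ regressor +
    covariates; a regressor that *is* a covariate is reported from the
    covariates-only model. Complete-case per model; a regressor collinear
    with a covariate is flagged degenerate instead of raising.
    """
    y_raw = np.asarray(table[outcome], dtype=float)
    if transform is None:
        y_all = y_raw
    elif isinstance(transform, str):
        y_all = TRANSFORMS[transform][0](y_raw)
    else:
        y_all = transform.apply(y_raw)

    results = []
    for reg in regressors:
        cols = [reg] + [c for c in covariates if adjust and c != reg]
        X_all = table[cols].astype(float)
        ok = np.isfinite(y_all) & np.isfinite(X_all).all(axis=1).to_numpy()
        n_drop = int(len(ok) - ok.sum())
        if n_drop:
            log.info("outcome %s ~ %s: dropping %d incomplete cases", outcome, reg, n_drop)
        y = y_all[ok]
        X = X_all.loc[ok]
        degenerate = False
        if adjust and reg not in covariates:
            for c in covariates:
                if np.ptp(X[reg] - X[c]) == 0 or np.ptp(X[reg] + X[c]) == 0:
                    degenerate = True
        if np.ptp(X[reg].to_numpy()) == 0:
            degenerate = True
        if degenerate:
            log.warning("regressor %s collinear/constant for outcome %s", reg, outcome)
            results.append(ModelResult(outcome, reg, np.nan, np.nan, np.nan,
                                       adjust, len(y), np.nan,
                                       tuple(covariates) if adjust else (), True))
            continue
        if len(y) <= len(cols) + 1:
            raise ValueError(f"n = {len(y)} too small for {len(cols)}-predictor model")
        fit = _ols(y, X)
        results.append(ModelResult(
            outcome=outcome,
            regressor=reg,
            beta=float(fit.params[reg]),
            p_value=float(fit.pvalues[reg]),
            r2_pct=100.0 * float(fit.rsquared),
            adjusted=adjust,
            n=int(fit.nobs),
            se=float(fit.bse[reg]),
            covariates=tuple(covariates) if adjust else (),
        ))
    return results


def quartile_assign(x: np.ndarray) -> np.ndarray:
    """Quartile bin index 0..3 by type-7 quantiles, ties to the lower bin.

    Degenerate (empty) bins produced by heavy ties are merged downward with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, [0.25, 0.5, 0.75])  # numpy default = type-7 (linear)
    bins = np.searchsorted(qs, x, side="left")
    present = np.unique(bins)
    if len(present) < 4:
        warnings.warn("empty quartile bin after ties; merging with neighbor", stacklevel=2)
        remap = {b: i for i, b in enumerate(present)}
        bins = np.vectorize(remap.get)(bins)
    return bins


def quartile_tests(
    table: pd.DataFrame,
    pvs_measure: str,
    continuous_vars: list[str] = (),
    ordinal_vars: list[str] = (),
) -> pd.DataFrame:
    """One-way ANOVA (continuous) and Kruskal-Wallis (ordinal/skewed) across
    quartiles of a PVS measure. Returns a long-format table of statistics."""
    x = np.asarray(table[pvs_measure], dtype=float)
    if len(x) < 8:
        raise ValueError("need n >= 8 for non-degenerate quartiles")
    bins = quartile_assign(x)
    rows = []
    for var, test in [(v, "anova") for v in continuous_vars] + [
        (v, "kruskal") for v in ordinal_vars
    ]:
        groups = [np.asarray(table[var], dtype=float)[bins == b] for b in np.unique(bins)]
        groups = [g[np.isfinite(g)] for g in groups]
        groups = [g for g in groups if len(g) > 0]
        if test == "anova":
            res = sps.f_oneway(*groups)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            try:
                res = sps.kruskal(*groups)
                stat, p = float(res.statistic), float(res.pvalue)
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
        rows.append({"measure": pvs_measure, "variable": var, "test": test,
                     "statistic": stat, "p": p})
    return pd.DataFrame(rows)
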