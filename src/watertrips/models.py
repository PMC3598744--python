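"""Linear mixed models of trip statistics and within-trip speed.

Two model families are fitted, both with individual identity as the
grouping factor to absorb intra-individual correlation:

* trip-level models — distance traveled, maximum distance to the start/end
  waterhole, or mean speed regressed on trip type (looping vs commuting),
  trip duration and their interaction, with a random intercept and random
  slopes by individual;
* within-trip speed models — step speed regressed on either distance to
  water or progression through the trip (linear or quadratic), fully
  crossed with trip type and trip duration, with a random intercept by
  individual.  The four candidates are ranked by AIC.

All models are estimated by maximum likelihood (not REML) so that AICs are
comparable across fixed-effect structures.  Confidence intervals come from
a parametric bootstrap: simulate new responses from the fitted model
(fresh random effects and residual noise), refit, take percentile
intervals; a term is significant when its interval excludes zero.

Random-intercept models are fitted by an exact profiled-likelihood solver
(the variance ratio is the only free parameter after profiling out the
fixed effects and the residual variance), which makes the thousands of
bootstrap refits cheap; it is validated against statsmodels' MixedLM.
Random-slope models go through statsmodels directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import DURATION_BIN_EDGES, DURATION_BIN_LABELS


# ---------------------------------------------------------------------------
# Profiled ML solver for the random-intercept model
# ---------------------------------------------------------------------------

def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    return codes, len(uniques)


def _profile_nll(log_lam: float, y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 counts: np.ndarray) -> float:
    beta, sigma2, llf = _profile_fit_at(np.exp(log_lam), y, X, codes, counts)
    return -llf


def _profile_fit_at(lam: float, y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                    counts: np.ndarray) -> tuple[np.ndarray, float, float]:
    """GLS fit at a fixed variance ratio lam = sigma_b^2 / sigma_e^2.

    Whitening: V_i^{-1/2} acts on group i as x -> x - gamma_i * mean_i(x)
    with gamma_i = 1 - (1 + lam * n_i)^{-1/2}, turning GLS into OLS.
    """
    n = y.size
    gamma = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)
    gmean_y = np.bincount(codes, weights=y) / counts
    yw = y - gamma[codes] * gmean_y[codes]
    Xw = np.empty_like(X)
    for j in range(X.shape[1]):
        gm = np.bincount(codes, weights=X[:, j]) / counts
        Xw[:, j] = X[:, j] - gamma[codes] * gm[codes]
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    logdet = float(np.sum(np.log1p(lam * counts)))
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return beta, sigma2, llf


def _fit_random_intercept_ml(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, float, float, float]:
    """Exact ML for y = X beta + b_g + e.  Returns (beta, sigma_b2, sigma_e2,
    llf), maximising over the profiled variance ratio (boundary at 0
    included)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    res = optimize.minimize_scalar(
        _profile_nll,
        bounds=(-12.0, 12.0),
        args=(y, X, codes, counts),
        method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [np.exp(res.x), 0.0]
    best = None
    for lam in candidates:
        beta, sigma2, llf = _profile_fit_at(lam, y, X, codes, counts)
        if best is None or llf > best[3]:
            best = (beta, lam * sigma2, sigma2, llf)
    return best


# ---------------------------------------------------------------------------
# Model specs and fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect design plus random-effect structure.

    ``random`` is "intercept" or "slopes"; for "slopes", ``slope_terms``
    names the design columns that also get by-individual random slopes.
    """

    name: str
    response: str
    terms: tuple[str, ...]
    random: str = "intercept"
    slope_terms: tuple[str, ...] = ()

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=df.index)
        for term in self.terms:
            if term == "intercept":
                X[term] = 1.0
            else:
                cols = term.split(":")
                v = np.ones(len(df))
                for c in cols:
                    v = v * df[c].to_numpy(float)
                X[term] = v
        return X


@dataclass
class ModelFit:
    """A fitted mixed model with everything needed to simulate from it."""

    spec: ModelSpec
    params: pd.Series
    cov_re: np.ndarray  # random-effect covariance (q x q)
    scale: float  # residual variance
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    engine: str  # "profile" | "statsmodels"
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    group_codes: np.ndarray = field(repr=False)
    exog_re: np.ndarray = field(repr=False)  # n x q random-effect design
    notes: list[str] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        q = self.cov_re.shape[0]
        return len(self.params) + q * (q + 1) // 2 + 1


def _aic(llf: float, k: int) -> float:
    return -2.0 * llf + 2.0 * k


def fit_lmm(spec: ModelSpec, df: pd.DataFrame, allow_fallback: bool = True) -> ModelFit:
    """Fit a mixed model by ML.

    Random-intercept specs use the exact profiled solver; random-slope
    specs use statsmodels MixedLM.  A non-converged random-slope fit falls
    back to the intercept-only structure (noted on the fit) when
    ``allow_fallback`` is set.
    """
    X = spec.design(df)
    y = df[spec.response].to_numpy(float)
    codes, n_groups = _group_codes(df["individual_id"])
    notes: list[str] = []

    if spec.random == "intercept":
        beta, sigma_b2, sigma_e2, llf = _fit_random_intercept_ml(
            y, X.to_numpy(float), codes, n_groups
        )
        if sigma_e2 <= 1e-12:
            notes.append("zero residual variance")
        params = pd.Series(beta, index=X.columns)
        cov_re = np.array([[sigma_b2]])
        fit = ModelFit(
            spec=spec,
            params=params,
            cov_re=cov_re,
            scale=sigma_e2,
            llf=llf,
            aic=np.nan,
            n_obs=len(y),
            n_groups=n_groups,
            converged=bool(np.isfinite(beta).all()),
            engine="profile",
            X=X,
            y=y,
            group_codes=codes,
            exog_re=np.ones((len(y), 1)),
            notes=notes,
        )
        fit.aic = _aic(llf, fit.k_params)
        return fit

    if spec.random != "slopes":
        raise ValueError(f"unknown random structure {spec.random!r}")

    import statsmodels.api as sm

    exog_re = np.column_stack(
        [np.ones(len(df))] + [X[t].to_numpy(float) for t in spec.slope_terms]
    )
    ok = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X.to_numpy(float), groups=codes, exog_re=exog_re)
            res = model.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=500)
            ok = bool(res.converged) and np.isfinite(res.fe_params).all()
        except (np.linalg.LinAlgError, ValueError):
            ok = False
    if ok:
        params = pd.Series(res.fe_params, index=X.columns)
        fit = ModelFit(
            spec=spec,
            params=params,
            cov_re=np.asarray(res.cov_re) * 1.0,
            scale=float(res.scale),
            llf=float(res.llf),
            aic=np.nan,
            n_obs=len(y),
            n_groups=n_groups,
            converged=True,
            engine="statsmodels",
            X=X,
            y=y,
            group_codes=codes,
            exog_re=exog_re,
            notes=notes,
        )
        fit.aic = _aic(fit.llf, fit.k_params)
        return fit

    if not allow_fallback:
        raise RuntimeError(f"model {spec.name} did not converge")
    notes.append("random-slope fit did not converge; fell back to random intercept")
    fallback = ModelSpec(
        name=spec.name,
        response=spec.response,
        terms=spec.terms,
        random="intercept",
    )
    fit = fit_lmm(fallback, df)
    fit.notes = notes + fit.notes
    fit.converged = False  # records that the requested structure failed
    return fit


# ---------------------------------------------------------------------------
# The concrete model families
# ---------------------------------------------------------------------------

TRIP_RESPONSES = ("distance_km", "max_dist_startend_km", "mean_speed_kmh")

#: Fixed effects of every trip-level model: looping intercept, commuting
#: offset, duration slope, commuting-by-duration interaction.
TRIP_TERMS = ("intercept", "commuting", "duration_h", "commuting:duration_h")


def trip_model_spec(response: str, random: str = "slopes") -> ModelSpec:
    if response not in TRIP_RESPONSES:
        raise ValueError(f"unknown trip response {response!r}")
    return ModelSpec(
        name=f"trip_{response}",
        response=response,
        terms=TRIP_TERMS,
        random=random,
        slope_terms=("commuting", "duration_h") if random == "slopes" else (),
    )


def fit_trip_model(
    trip_stats: pd.DataFrame, response: str, random: str = "slopes"
) -> ModelFit:
    """Fit one trip-level model (random intercept + slopes by individual)."""
    if trip_stats["individual_id"].nunique() < 2:
        raise ValueError("trip-level models need at least 2 individuals")
    if len(trip_stats) < 10:
        raise ValueError("trip-level models need at least 10 trips")
    return fit_lmm(trip_model_spec(response, random), trip_stats)


def _crossed_terms(focal: tuple[str, ...]) -> tuple[str, ...]:
    """Full crossing of the focal polynomial terms with trip type and
    duration, plus the shared base terms."""
    terms = ["intercept", "commuting", "duration_h", "commuting:duration_h"]
    for f in focal:
        terms.extend([f, f"{f}:commuting", f"{f}:duration_h", f"{f}:commuting:duration_h"])
    return tuple(terms)


SPEED_MODEL_SPECS: dict[str, ModelSpec] = {
    name: ModelSpec(
        name=name,
        response="speed_kmh",
        terms=_crossed_terms(focal),
        random="intercept",
    )
    for name, focal in {
        "dist_linear": ("dist_water_km",),
        "dist_quadratic": ("dist_water_km", "dist_water_km_sq"),
        "prog_linear": ("progression_pct",),
        "prog_quadratic": ("progression_pct", "progression_pct_sq"),
    }.items()
}


def _with_squares(step_table: pd.DataFrame) -> pd.DataFrame:
    df = step_table.copy()
    df["progression_pct_sq"] = df["progression_pct"] ** 2
    df["dist_water_km_sq"] = df["dist_water_km"] ** 2
    return df


def fit_speed_models(step_table: pd.DataFrame) -> list[ModelFit]:
    """Fit the four candidate within-trip speed models and rank by AIC.

    Candidates: distance-to-water linear/quadratic, progression
    linear/quadratic, each fully crossed with trip type and duration, all
    by ML on the identical step table, random intercept by individual.
    Non-convergent candidates are reported (converged=False) but excluded
    from the ranking order.
    """
    if step_table.empty:
        raise ValueError("empty step table")
    if step_table["individual_id"].nunique() < 2:
        raise ValueError("speed models need at least 2 individuals")
    df = _with_squares(step_table)
    fits = [fit_lmm(spec, df) for spec in SPEED_MODEL_SPECS.values()]
    return sorted(fits, key=lambda f: (not f.converged, f.aic))


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap confidence intervals for a fit's fixed effects."""

    table: pd.DataFrame  # term, estimate, ci_lo, ci_hi, significant
    n_boot: int
    n_failed: int
    seed: int
    level: float

    def significant_terms(self) -> list[str]:
        return self.table.loc[self.table["significant"], "term"].tolist()


def simulate_response(fit: ModelFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a new response vector from the fitted model: fixed effects +
    fresh group-level random effects + residual noise."""
    mu = fit.X.to_numpy(float) @ fit.params.to_numpy()
    q = fit.cov_re.shape[0]
    b = rng.multivariate_normal(np.zeros(q), fit.cov_re, size=fit.n_groups)
    re_contrib = np.einsum("ij,ij->i", fit.exog_re, b[fit.group_codes])
    eps = rng.normal(0.0, np.sqrt(fit.scale), size=fit.n_obs)
    return mu + re_contrib + eps


def _refit_params(fit: ModelFit, y_new: np.ndarray) -> np.ndarray | None:
    """Refit the same spec on a simulated response; None on failure."""
    if fit.engine == "profile":
        counts = np.bincount(fit.group_codes, minlength=fit.n_groups).astype(float)
        Xa = fit.X.to_numpy(float)
        res = optimize.minimize_scalar(
            _profile_nll,
            bounds=(-12.0, 12.0),
            args=(y_new, Xa, fit.group_codes, counts),
            method="bounded",
            options={"xatol": 1e-6},
        )
        beta, _, llf = _profile_fit_at(np.exp(res.x), y_new, Xa, fit.group_codes, counts)
        beta0, _, llf0 = _profile_fit_at(0.0, y_new, Xa, fit.group_codes, counts)
        return beta if llf >= llf0 else beta0
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(
                y_new, fit.X.to_numpy(float), groups=fit.group_codes, exog_re=fit.exog_re
            )
            res = model.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=200)
            if np.isfinite(res.fe_params).all():
                return np.asarray(res.fe_params)
        except (np.linalg.LinAlgError, ValueError):
            pass
    return None


def parametric_bootstrap(
    fit: ModelFit,
    n_boot: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile parametric-bootstrap CIs for the fixed effects.

    Each replicate simulates a response from the fitted model and refits
    the same specification.  Replicates whose refit fails are redrawn once,
    then dropped; more than 5% dropped is an error (the data are too small
    or the random structure too rich for a stable bootstrap).
    """
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(fit.params)))
    n_failed = 0
    for i in range(n_boot):
        beta = _refit_params(fit, simulate_response(fit, rng))
        if beta is None:  # one redraw, then give up on this replicate
            beta = _refit_params(fit, simulate_response(fit, rng))
        if beta is None:
            n_failed += 1
            draws[i] = np.nan
        else:
            draws[i] = beta
    if n_failed > 0.05 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed; use more data or a "
            "simpler random structure"
        )
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(draws, 100 * alpha, axis=0)
    hi = np.nanpercentile(draws, 100 * (1 - alpha), axis=0)
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )
    table["significant"] = (table["ci_lo"] > 0) | (table["ci_hi"] < 0)
    return BootstrapResult(
        table=table, n_boot=n_boot, n_failed=n_failed, seed=seed, level=level
    )


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def compare_duration_distributions(
    looping_durations_h: Sequence[float], commuting_durations_h: Sequence[float]
) -> dict:
    """Chi-square test of homogeneity of the five-bin trip-duration
    distribution between looping and commuting trips.  Bins whose expected
    count falls below 1 are merged with their left neighbor (or right
    neighbor for the first bin) and the merge is reported."""
    loop = np.asarray(list(looping_durations_h), float)
    comm = np.asarray(list(commuting_durations_h), float)
    if loop.size == 0 or comm.size == 0:
        raise ValueError("both trip-type groups must be non-empty")
    bins = list(DURATION_BIN_EDGES)
    counts = np.vstack(
        [np.histogram(g, bins=bins)[0] for g in (loop, comm)]
    ).astype(float)
    labels = list(DURATION_BIN_LABELS)
    nonzero = counts.sum(axis=0) > 0
    counts = counts[:, nonzero]
    labels = [l for l, keep in zip(labels, nonzero) if keep]

    merged: list[str] = []
    while counts.shape[1] > 1:
        colsum = counts.sum(axis=0)
        expected = np.outer(counts.sum(axis=1), colsum) / counts.sum()
        bad = np.flatnonzero(expected.min(axis=0) < 1.0)
        if bad.size == 0:
            break
        j = int(bad[0])
        k = j - 1 if j > 0 else j + 1
        merged.append(f"{labels[j]}+{labels[k]}")
        counts[:, k] += counts[:, j]
        counts = np.delete(counts, j, axis=1)
        labels[k] = f"{labels[min(j,k)]}|{labels[max(j,k)]}"
        del labels[j]
    if counts.shape[1] < 2:
        raise ValueError("all trips fall in a single duration bin")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return {
        "statistic": float(stat),
        "p": float(p),
        "dof": int(dof),
        "merged_bins": merged,
        "table": counts.tolist(),
        "bin_labels": labels,
    }


def dry_wet_speed_test(
    dry_speeds_kmh: Sequence[float],
    wet_speeds_kmh: Sequence[float],
    exceedance_thresholds_kmh: Sequence[float] = (0.8, 1.0, 1.2),
) -> dict:
    """Welch two-sample t-test of dry- vs wet-season speeds, plus the
    fraction of wet-season speeds exceeding each reference threshold."""
    dry = np.asarray(list(dry_speeds_kmh), float)
    wet = np.asarray(list(wet_speeds_kmh), float)
    if dry.size < 2 or wet.size < 2:
        raise ValueError("both samples need at least 2 observations")
    t, p = stats.ttest_ind(dry, wet, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "mean_dry": float(dry.mean()),
        "mean_wet": float(wet.mean()),
        "sd_dry": float(dry.std(ddof=1)),
        "sd_wet": float(wet.std(ddof=1)),
        "wet_exceedance": {
            float(thr): float(np.mean(wet > thr)) for thr in exceedance_thresholds_kmh
        },
    }
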