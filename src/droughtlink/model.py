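"""Varying-intercept Bayesian logistic regression of a recent binary
outcome on drought exposure, plus survey-weighted prevalence estimation.

One model is fitted per exposure category, with a single binary exposure
indicator whose implicit reference group is everyone not carrying that
flag:

    logit P(y_i = 1) = a_{c[i]} + beta * exposure_i
                       + g1*age_i + g2*school_i + g3*partnered_i + g4*poor_i
    a_c ~ Normal(mu, sigma^2);  beta, g, mu ~ Normal(0, 1);
    sigma ~ Half-Normal(1)

The outcome follows the survey skip pattern: the 12-month question is only
asked of respondents reporting lifetime violence, so ``not_applicable``
(lifetime = no) recodes to 0; ``missing`` stays missing and is dropped
under the complete-case policy with explicit accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SamplerSettings
from .diagnostics import ESS_GATE, RHAT_GATE, compute_ess, compute_rhat
from .sampler import HierLogisticPosterior, sample_posterior

CATEGORIES = ["slight_to_moderate", "very_dry", "recent_and_long", "prolonged_extreme"]
COVARIATES = ["age", "in_school", "ever_partnered", "poor_household"]


def derive_outcome(sv_lifetime: bool, sv_recent_raw: str) -> float:
    """Recode the skip-patterned 12-month response to a 0/1 outcome.

    yes -> 1; no -> 0; not_applicable (only valid when lifetime is no)
    -> 0; missing -> NaN (dropped later under complete-case analysis).
    """
    raw = str(sv_recent_raw).strip().lower()
    if raw == "yes":
        return 1.0
    if raw == "no":
        return 0.0
    if raw == "not_applicable":
        if sv_lifetime:
            raise ValueError(
                "inconsistent record: sv_recent_raw=not_applicable with "
                "sv_lifetime=yes (skip pattern only skips lifetime-negative "
                "respondents)"
            )
        return 0.0
    if raw == "missing":
        return float("nan")
    raise ValueError(f"unknown sv_recent_raw code {sv_recent_raw!r}")


@dataclass
class ModelInput:
    """Design assembled for one focal exposure category."""

    y: np.ndarray  # (n,) 0/1
    X: np.ndarray  # (n, 5): exposure then the four covariates
    country: np.ndarray  # (n,) 0-based country codes
    country_labels: list[str]
    category: str
    prior_sd: float = 1.0
    n_dropped: dict = field(default_factory=dict)
    colnames: tuple = ("exposure", "age", "in_school", "ever_partnered",
                       "poor_household")


def build_model_input(
    cohort: pd.DataFrame, category: str, standardize_age: bool = False
) -> ModelInput:
    """Complete-case design matrix for the focal category.

    Rows with a missing outcome or covariate are dropped and counted.
    Raises if the exposure column is constant (non-identifiable) or fewer
    than two countries remain.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown exposure category {category!r}")
    df = cohort.copy()
    if "sv_recent" not in df.columns:
        df["sv_recent"] = [
            derive_outcome(l, r)
            for l, r in zip(df["sv_lifetime"], df["sv_recent_raw"])
        ]
    n0 = len(df)
    missing_outcome = df["sv_recent"].isna()
    df = df.loc[~missing_outcome]
    missing_cov = df[COVARIATES].isna().any(axis=1)
    df = df.loc[~missing_cov]
    dropped = {
        "missing_outcome": int(missing_outcome.sum()),
        "missing_covariate": int(missing_cov.sum()),
        "input_rows": len(df),
        "cohort_rows": n0,
    }
    x = df[category].astype(float).to_numpy()
    if x.min() == x.max():
        raise ValueError(
            f"category {category}: all respondents {'exposed' if x.max() else 'unexposed'}; "
            "the exposure effect is not identifiable"
        )
    age = df["age"].astype(float).to_numpy()
    if standardize_age:
        age = (age - age.mean()) / age.std()
    X = np.column_stack(
        [x, age]
        + [df[c].astype(float).to_numpy() for c in COVARIATES[1:]]
    )
    labels = sorted(df["country_id"].astype(str).unique())
    if len(labels) < 2:
        raise ValueError("varying intercepts require >= 2 countries")
    code = {c: i for i, c in enumerate(labels)}
    country = df["country_id"].astype(str).map(code).to_numpy()
    return ModelInput(
        y=df["sv_recent"].to_numpy(dtype=float),
        X=X,
        country=country,
        country_labels=labels,
        category=category,
        n_dropped=dropped,
    )


@dataclass
class PosteriorDraws:
    """Named posterior draws, shaped (chains, draws) per scalar parameter."""

    params: dict
    meta: dict

    def chains(self, name: str) -> np.ndarray:
        return self.params[name]

    def stacked(self, group: str) -> np.ndarray:
        """Flattened draws for a parameter block: 'beta' -> (S, p) including
        the exposure column first; 'a_country' -> (S, C)."""
        if group == "beta":
            names = [n for n in self.params if n.startswith("b_")]
            return np.column_stack([self.params[n].ravel() for n in names])
        if group == "a_country":
            names = [n for n in self.params if n.startswith("a[")]
            return np.column_stack([self.params[n].ravel() for n in names])
        return self.params[group].ravel()[:, None]


def fit_model(
    model_input: ModelInput,
    sampler: SamplerSettings | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the hierarchical logistic posterior with HMC.

    Raises RuntimeError (carrying the offending diagnostics) when any
    reported parameter fails the convergence gates or sampling diverges
    heavily.
    """
    settings = sampler or SamplerSettings()
    settings.validate()
    post = HierLogisticPosterior(
        model_input.X, model_input.y, model_input.country, model_input.prior_sd
    )
    res = sample_posterior(
        post, chains=settings.chains, draws=settings.draws,
        warmup=settings.warmup, seed=seed,
    )
    if res.n_divergent > 0.02 * settings.chains * settings.draws:
        # a rare warmup pathology (a chain adapting in a bad region) is
        # retried once with stricter adaptation, as with Stan's adapt_delta
        res = sample_posterior(
            post, chains=settings.chains, draws=settings.draws,
            warmup=2 * settings.warmup, seed=seed + 997, target_accept=0.98,
        )
    p = model_input.X.shape[1]
    C = post.n_countries
    theta = res.theta  # (chains, draws, dim)
    names = [f"b_{c}" for c in model_input.colnames]
    params: dict = {}
    for j, name in enumerate(names):
        params[name] = theta[:, :, j]
    mu, sigma, a = post.intercept_draws(theta)
    params["mu"] = mu
    params["sigma"] = sigma
    for c in range(C):
        params[f"a[{model_input.country_labels[c]}]"] = a[:, :, c]

    draws = PosteriorDraws(
        params=params,
        meta={
            **res.meta,
            "category": model_input.category,
            "parameterization": post.parameterization,
            "accept_rate": res.accept_rate.tolist(),
            "step_size": res.step_size.tolist(),
            "n_divergent": res.n_divergent,
        },
    )
    if res.n_divergent > 0.02 * settings.chains * settings.draws:
        raise RuntimeError(
            f"sampling unstable: {res.n_divergent} divergent transitions; "
            f"meta={draws.meta}"
        )
    return draws


REPORTED = ["b_exposure", "b_age", "b_in_school", "b_ever_partnered",
            "b_poor_household", "mu", "sigma"]


def convergence_table(draws: PosteriorDraws) -> dict:
    """Split-Rhat and bulk ESS for every reported parameter."""
    out = {}
    for name in REPORTED:
        if name not in draws.params:
            continue
        x = draws.chains(name)
        out[name] = {"rhat": compute_rhat(x), "ess_bulk": compute_ess(x)}
    return out


def check_convergence(diag: dict) -> list[str]:
    """Names of parameters failing the Rhat/ESS gates."""
    bad = []
    for name, d in diag.items():
        if not np.isfinite(d["rhat"]) or d["rhat"] > RHAT_GATE:
            bad.append(name)
        elif not np.isfinite(d["ess_bulk"]) or d["ess_bulk"] < ESS_GATE:
            bad.append(name)
    return bad


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Coefficient table: Estimate (posterior mean of the log-odds), SE
    (posterior SD), OR = exp(Estimate), 95% credible interval on the OR
    scale from the 2.5/97.5 posterior quantiles, plus the posterior median
    and the convergence diagnostics."""
    diag = convergence_table(draws)
    rows = []
    for name, x in draws.params.items():
        flat = x.ravel()
        mean = float(flat.mean())
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": mean,
                "median": float(np.median(flat)),
                "sd": float(flat.std(ddof=1)),
                "or": float(np.exp(mean)),
                "or_ci_low": float(np.exp(lo)),
                "or_ci_high": float(np.exp(hi)),
                "rhat": diag.get(name, {}).get("rhat", float("nan")),
                "ess_bulk": diag.get(name, {}).get("ess_bulk", float("nan")),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def summary_dict(draws: PosteriorDraws) -> dict:
    """JSON-ready per-category summary (parameters + sampler metadata)."""
    table = summarize_posterior(draws)
    params = {
        ("exposure" if name == "b_exposure" else name): row.to_dict()
        for name, row in table.iterrows()
    }
    return {"parameters": params, "sampler": draws.meta}


def weighted_prevalence(
    cohort: pd.DataFrame, outcome: str = "recent", group_by: str = "country_id"
) -> pd.DataFrame:
    """Survey-weighted prevalence with linearised SE and a 95% normal CI.

    ``outcome`` selects lifetime (sv_lifetime) or recent (derived sv_recent).
    Unit weights are assumed (with a warning) when no weight column exists.
    The Taylor-linearised SE of the weighted ratio mean is
    sqrt(sum(w_i^2 (y_i - p)^2)) / sum(w_i); the CI is truncated to [0, 1]
    and flagged degenerate at p in {0, 1}.
    """
    df = cohort.copy()
    if outcome == "lifetime":
        y = df["sv_lifetime"].astype(float)
    elif outcome == "recent":
        if "sv_recent" not in df.columns:
            df["sv_recent"] = [
                derive_outcome(l, r)
                for l, r in zip(df["sv_lifetime"], df["sv_recent_raw"])
            ]
        y = df["sv_recent"].astype(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if "weight" in df.columns:
        w = df["weight"].astype(float)
    else:
        import warnings

        warnings.warn("no survey weights present; using unit weights")
        w = pd.Series(1.0, index=df.index)
    df = df.assign(_y=y, _w=w).dropna(subset=["_y"])
    rows = []
    for g, sub in df.groupby(group_by):
        if sub.empty:  # pragma: no cover
            continue
        wv, yv = sub["_w"].to_numpy(), sub["_y"].to_numpy()
        p = float(wv @ yv / wv.sum())
        se = float(np.sqrt(np.sum(wv**2 * (yv - p) ** 2)) / wv.sum())
        z = norm.ppf(0.975)
        rows.append(
            {
                group_by: g,
                "n": len(sub),
                "prevalence_pct": 100 * p,
                "se_pct": 100 * se,
                "ci_low_pct": 100 * max(0.0, p - z * se),
                "ci_high_pct": 100 * min(1.0, p + z * se),
                "degenerate": p in (0.0, 1.0),
            }
        )
    return pd.DataFrame(rows).set_index(group_by)
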