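"""Synthetic SPEI grids and survey cohorts with known ground truth.

The SPEI generator emulates a standardized drought index: a stationary
AR(1) Gaussian baseline with unit marginal variance (SPEI is standardized
against the local climatology, so non-drought months are ~ N(0, 1)), with
drought episodes injected as blocks of months drawn around a prescribed
mean depth. The cohort generator mirrors the association model exactly —
a varying-intercept logistic regression with known coefficients — and
emits the survey skip-pattern coding so the outcome-recode path is
exercised end to end.

Default cohort conditions emulate the multi-country study sample:
~35,000 respondents aged 13-24 in 14 countries, school attendance 50%,
ever-partnered 64%, poor household 40%, recent-outcome prevalence near
9.9% and lifetime near 21%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import PipelineConfig
from .drought import SpeiSeries
from .io import write_spei_csv

#: Exposure-category effect presets on the log-odds scale (association
#: magnitudes the reported study context makes interesting to recover).
EFFECT_PRESETS = {
    "slight_to_moderate": -0.008,
    "recent_and_long": -0.156,
    "very_dry": 0.046,
    "prolonged_extreme": 0.197,
}

CATEGORIES = list(EFFECT_PRESETS)


@dataclass
class Episode:
    cell_id: str
    start: int  # absolute month index
    duration: int
    mean_depth: float

    def months(self) -> range:
        return range(self.start, self.start + self.duration)


@dataclass
class SpeiSimParams:
    n_cells: int = 10
    n_months: int = 120
    start_month: int = 2010 * 12  # January 2010
    ar1: float = 0.3
    episodes: list = field(default_factory=list)  # list[Episode]
    episode_depth_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ar1 <= 0.95:
            raise ValueError("ar1 must lie in [0, 0.95]")
        if self.episode_depth_sd < 0:
            raise ValueError("episode_depth_sd must be >= 0")
        per_cell: dict[str, list[Episode]] = {}
        for ep in self.episodes:
            per_cell.setdefault(ep.cell_id, []).append(ep)
            if ep.duration < 1:
                raise ValueError("episode duration must be >= 1")
        for cell, eps in per_cell.items():
            eps = sorted(eps, key=lambda e: e.start)
            for a, b in zip(eps, eps[1:]):
                if a.start + a.duration > b.start:
                    raise ValueError(f"overlapping episodes in cell {cell}")


def simulate_spei(params: SpeiSimParams) -> tuple[dict[str, SpeiSeries], dict]:
    """AR(1) SPEI-like series with injected drought episodes.

    Baseline: x_t = rho x_{t-1} + sqrt(1 - rho^2) e_t, e_t ~ N(0,1), so the
    marginal distribution stays standard normal for any rho. Episode months
    are overwritten with draws N(mean_depth, episode_depth_sd), clipped to
    >= -6 (well inside the valid SPEI range). The returned ground-truth
    ledger records the exact episode months and realized depths.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    series: dict[str, SpeiSeries] = {}
    ledger = []
    cells = [f"cell{str(i).zfill(3)}" for i in range(params.n_cells)]
    eps_by_cell: dict[str, list[Episode]] = {}
    for ep in params.episodes:
        eps_by_cell.setdefault(ep.cell_id, []).append(ep)
    for cell in cells:
        innov = rng.standard_normal(params.n_months)
        x = np.empty(params.n_months)
        x[0] = innov[0]
        scale = np.sqrt(1.0 - params.ar1**2)
        for t in range(1, params.n_months):
            x[t] = params.ar1 * x[t - 1] + scale * innov[t]
        for ep in eps_by_cell.get(cell, []):
            lo = ep.start - params.start_month
            if lo < 0 or lo + ep.duration > params.n_months:
                raise ValueError(f"episode outside series for cell {cell}")
            depths = np.clip(
                rng.normal(ep.mean_depth, params.episode_depth_sd, ep.duration),
                -6.0,
                None,
            )
            x[lo : lo + ep.duration] = depths
            ledger.append(
                {
                    "cell_id": cell,
                    "months": list(ep.months()),
                    "mean_depth": ep.mean_depth,
                    "realized_depths": depths.tolist(),
                }
            )
        series[cell] = SpeiSeries(
            unit_id=cell, start_month=params.start_month, values=x
        )
    truth = {"episodes": ledger, "params": {**asdict(params), "episodes": len(params.episodes)}}
    return series, truth


@dataclass
class CohortSimParams:
    """Generative conditions for the multi-country synthetic cohort."""

    n_respondents: int = 35_309
    n_countries: int = 14
    districts_per_country: int = 10
    beta: dict = field(default_factory=lambda: dict(EFFECT_PRESETS))
    gamma: dict = field(
        default_factory=lambda: {
            "age": 0.03,
            "in_school": -0.2,
            "ever_partnered": 0.7,
            "poor_household": 0.15,
        }
    )
    mu: float = -3.27  # calibrated: expected marginal outcome prevalence ~9.9%
    sigma: float = 0.5  # country-intercept SD
    covariate_rates: dict = field(
        default_factory=lambda: {
            "in_school": 0.50,
            "ever_partnered": 0.64,
            "poor_household": 0.40,
        }
    )
    age_range: tuple = (13, 24)
    exposure_prevalence: dict = field(
        default_factory=lambda: {
            "slight_to_moderate": 0.80,
            "very_dry": 0.15,
            "recent_and_long": 0.22,
            "prolonged_extreme": 0.13,
        }
    )
    extra_lifetime_rate: float = 0.123  # lifts lifetime prevalence to ~21%
    outcome_missing_rate: float = 0.0016
    weight_log_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 2:
            raise ValueError("n_countries must be >= 2")
        for k, v in {**self.covariate_rates, **self.exposure_prevalence}.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"rate {k}={v} must lie in (0, 1)")
        if not 0.0 <= self.extra_lifetime_rate < 1.0:
            raise ValueError("extra_lifetime_rate must lie in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def make_district_flags(params: CohortSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli district exposure flags at the target prevalences."""
    rows = []
    for c in range(params.n_countries):
        for d in range(params.districts_per_country):
            row = {
                "country_id": f"C{str(c).zfill(2)}",
                "district_id": f"C{str(c).zfill(2)}D{str(d).zfill(2)}",
            }
            for cat, p in params.exposure_prevalence.items():
                row[cat] = bool(rng.uniform() < p)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    params: CohortSimParams, district_flags: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Respondent records drawn from the varying-intercept logistic model.

    Each respondent is assigned a district (uniformly), inherits its four
    exposure flags, and the recent outcome is Bernoulli with
    logit = a_c + sum_cat beta_cat * flag_cat + gamma' z. The lifetime
    indicator is recent OR an independent Bernoulli(extra_lifetime_rate) —
    a minimal construction whose only purpose is to exercise the survey
    skip pattern (not_applicable when lifetime is no).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if district_flags is None:
        district_flags = make_district_flags(params, rng)
    flags = district_flags.reset_index(drop=True)
    n = params.n_respondents
    pick = rng.integers(0, len(flags), size=n)
    dist = flags.iloc[pick].reset_index(drop=True)

    countries = sorted(flags["country_id"].unique())
    a_by_country = {
        c: params.mu + params.sigma * z
        for c, z in zip(countries, rng.standard_normal(len(countries)))
    }
    age = rng.integers(params.age_range[0], params.age_range[1] + 1, size=n)
    cov = {"age": age.astype(float)}
    for name, rate in params.covariate_rates.items():
        cov[name] = (rng.uniform(size=n) < rate).astype(float)

    logit = np.array([a_by_country[c] for c in dist["country_id"]])
    for cat in CATEGORIES:
        logit += params.beta.get(cat, 0.0) * dist[cat].to_numpy(dtype=float)
    for name, g in params.gamma.items():
        logit += g * cov[name]
    prob = expit(logit)
    n_clipped = int(((prob <= 0) | (prob >= 1)).sum())
    if n_clipped:  # pragma: no cover - only under extreme parameters
        import warnings

        warnings.warn(f"{n_clipped} respondents had degenerate probabilities")
        prob = np.clip(prob, 1e-12, 1 - 1e-12)

    recent = rng.uniform(size=n) < prob
    lifetime = recent | (rng.uniform(size=n) < params.extra_lifetime_rate)
    raw = np.where(lifetime, np.where(recent, "yes", "no"), "not_applicable")
    miss = rng.uniform(size=n) < params.outcome_missing_rate
    raw = np.where(miss, "missing", raw)

    df = pd.DataFrame(
        {
            "respondent_id": [f"R{str(i).zfill(6)}" for i in range(n)],
            "country_id": dist["country_id"],
            "district_id": dist["district_id"],
            "interview_year": 2018,
            "interview_month": 6,
            "age": cov["age"].astype(int),
            "in_school": cov["in_school"].astype(int),
            "ever_partnered": cov["ever_partnered"].astype(int),
            "poor_household": cov["poor_household"].astype(int),
            "sv_lifetime": lifetime.astype(int),
            "sv_recent_raw": raw,
            "weight": np.exp(rng.normal(0.0, params.weight_log_sd, size=n)),
        }
    )
    for cat in CATEGORIES:
        df[cat] = dist[cat].to_numpy()
    truth = {
        "parameters": {
            "beta": params.beta,
            "gamma": params.gamma,
            "mu": params.mu,
            "sigma": params.sigma,
            "country_intercepts": a_by_country,
        },
        "realized_flags": flags.to_dict(orient="records"),
        "true_recent": recent.astype(int).tolist(),
    }
    return df, truth


def make_fixture_suite(
    seed: int,
    out_dir: str | Path,
    n_respondents: int = 6000,
    n_countries: int = 6,
    districts_per_country: int = 4,
    cells_per_district: int = 2,
    config: PipelineConfig | None = None,
) -> dict:
    """Write a small end-to-end bundle: SPEI CSV, weights, cohort, truth.

    Districts whose cells carry injected episodes develop real drought
    signal, so the exposure flags the cohort is generated from are the
    flags the pipeline itself recomputes from the written SPEI grid.
    """
    from .linkage import link_exposure, load_cell_weights

    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_districts = n_countries * districts_per_country
    n_cells = n_districts * cells_per_district
    start = 2013 * 12
    n_months = 72
    interview = (2018, 6)

    weights = []
    for d in range(n_districts):
        c = d // districts_per_country
        did = f"C{str(c).zfill(2)}D{str(d % districts_per_country).zfill(2)}"
        for j in range(cells_per_district):
            weights.append(
                {
                    "district_id": did,
                    "cell_id": f"cell{str(d * cells_per_district + j).zfill(3)}",
                    "weight": 1.0 / cells_per_district,
                }
            )
    weights_df = pd.DataFrame(weights)
    weights_path = out / "weights.csv"
    weights_df.to_csv(weights_path, index=False)
    probe = pd.DataFrame(
        {
            "respondent_id": [f"P{d}" for d in range(n_districts)],
            "country_id": [w["district_id"][:3] for w in weights[::cells_per_district]],
            "district_id": [w["district_id"] for w in weights[::cells_per_district]],
            "interview_year": interview[0],
            "interview_month": interview[1],
        }
    )

    # Draw climates until every category varies across districts (a flag
    # constant in-sample would make its association model non-identifiable);
    # the retry loop is deterministic in the bundle seed.
    for _attempt in range(10):
        # Persistently wet districts: a standardized index gives every
        # location the same marginal, so without them every district would
        # record at least one mildly dry month in 48 and the
        # slight-to-moderate flag would be constant.
        wet_districts = {
            int(d) for d in rng.choice(n_districts, size=max(2, n_districts // 6),
                                       replace=False)
        }
        wet_cells = {
            d * cells_per_district + j
            for d in wet_districts
            for j in range(cells_per_district)
        }
        episodes = []
        for i in range(n_cells):
            cell = f"cell{str(i).zfill(3)}"
            r = rng.uniform()
            if i in wet_cells:
                continue
            # mix of episode severities so every category occurs in-sample
            if r < 0.25:
                episodes.append(
                    Episode(cell, start + int(rng.integers(24, 40)),
                            int(rng.integers(14, 24)), -2.2)
                )
            elif r < 0.5:
                episodes.append(
                    Episode(cell, start + int(rng.integers(30, 50)),
                            int(rng.integers(6, 10)), -3.0)
                )
            elif r < 0.7:
                episodes.append(
                    Episode(cell, start + int(rng.integers(20, 60)),
                            int(rng.integers(3, 5)), -1.6)
                )
        spei_params = SpeiSimParams(
            n_cells=n_cells, n_months=n_months, start_month=start,
            ar1=0.3, episodes=episodes, seed=int(rng.integers(2**31 - 1)),
        )
        series, spei_truth = simulate_spei(spei_params)
        cells_sorted = sorted(series)
        for i in sorted(wet_cells):
            s = series[cells_sorted[i]]
            s.values[:] = np.abs(rng.normal(0.8, 0.4, size=len(s))) + 0.05
        spei_truth["wet_cells"] = [cells_sorted[i] for i in sorted(wet_cells)]

        # realized district flags from the engine itself
        linked, _, _ = link_exposure(
            probe, series, load_cell_weights(weights_path), cfg
        )
        flags = linked[
            ["country_id", "district_id"] + CATEGORIES
        ].reset_index(drop=True)
        if all(flags[cat].nunique() == 2 for cat in CATEGORIES):
            break
    else:
        raise RuntimeError(
            "could not realize in-sample variation for all exposure categories"
        )

    cohort_params = CohortSimParams(
        n_respondents=n_respondents,
        n_countries=n_countries,
        districts_per_country=districts_per_country,
        seed=int(rng.integers(2**31 - 1)),
    )
    cohort, cohort_truth = simulate_cohort(cohort_params, flags)
    cohort["interview_year"] = interview[0]
    cohort["interview_month"] = interview[1]

    spei_path = out / "spei.csv"
    cohort_path = out / "cohort.csv"
    write_spei_csv(series, spei_path)
    cohort.drop(columns=CATEGORIES).to_csv(cohort_path, index=False)
    truth = {
        "seed": seed,
        "spei": spei_truth,
        "cohort": cohort_truth,
        "designed_flags": flags.to_dict(orient="records"),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return {
        "spei": spei_path,
        "weights": weights_path,
        "cohort": cohort_path,
        "truth": out / "truth.json",
    }
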