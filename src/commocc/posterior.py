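"""Posterior summaries: richness, community probabilities, effects.

All credible intervals are central percentile intervals of the
retained draws (2.5% and 97.5% quantiles), and "significance" of an
effect means its 95% interval excludes zero. Summaries are plain
pandas DataFrames so they can be written to CSV and recomputed
bit-exactly from the raw draw store.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import PosteriorDraws

__all__ = [
    "summary_row",
    "richness_summary",
    "community_prob_summary",
    "effect_summary",
    "species_vs_hyper",
    "region_mass_summary",
    "write_summary_tables",
]

_HYPER_EFFECTS = {
    "alpha_mass": "log body mass on detection",
    "mu_alpha_dSettl": "distance to settlements on detection",
    "beta_mass": "log body mass on occupancy",
    "mu_beta_dRiv": "distance to rivers on occupancy",
    "mu_beta_dSettl": "distance to settlements on occupancy",
    "mu_beta_forCover": "moist-forest cover on occupancy",
}


def summary_row(name: str, x: np.ndarray) -> dict:
    """Mean, median, central 95% interval and zero-exclusion flag."""
    x = np.asarray(x, dtype=float)
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return {
        "quantity": name,
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(med),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "excludes_zero": bool(lo > 0.0 or hi < 0.0),
    }


def richness_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-region posterior median and 95% BCI of richness N_r.

    Richness draws are integer counts; quantiles use the
    nearest-observation rule so the summaries stay integers and are
    never below the observed species count.
    """
    rows = []
    regions = draws.meta.get("regions")
    if regions is None:
        regions = [n[2:-1] for n in draws.names if n.startswith("N[")]
    n_obs = draws.meta.get("n_obs", [None] * len(regions))
    for region, n_r in zip(regions, n_obs):
        x = draws.flat(f"N[{region}]")
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5], method="nearest")
        rows.append(
            {
                "region": region,
                "n_observed": n_r,
                "median": int(med),
                "q2.5": int(lo),
                "q97.5": int(hi),
            }
        )
    return pd.DataFrame(rows)


def community_prob_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Meta-community occupancy and per-day detection probability.

    Summarizes the inverse-logit of the community hyper-mean
    intercepts (covariates standing at their standardized mean of
    zero), the conventional reading of an "average community"
    probability.
    """
    rows = [
        summary_row("occupancy", expit(draws.flat("mu_beta0"))),
        summary_row("detection", expit(draws.flat("mu_alpha0"))),
    ]
    return pd.DataFrame(rows)


def effect_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Community-level covariate effects with significance flags.

    One row per hyper-level effect: posterior mean, 95% BCI, whether
    the interval excludes zero, and the posterior probability that the
    effect has the sign of its mean.
    """
    rows = []
    for name, desc in _HYPER_EFFECTS.items():
        if name not in draws.names:
            continue
        x = draws.flat(name)
        row = summary_row(name, x)
        row["description"] = desc
        sign = np.sign(row["mean"]) or 1.0
        row["prob_sign"] = float((np.sign(x) == sign).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def species_vs_hyper(draws: PosteriorDraws) -> pd.DataFrame:
    """Flag species-region effects that diverge from the community mean.

    For every monitored species-level slope, the species is flagged
    when its 95% BCI and the 95% BCI of the corresponding hyper-mean
    are disjoint intervals (the species response differs significantly
    from the community average).
    """
    pairs = {
        "beta_": "mu_beta_",
        "alpha_": "mu_alpha_",
    }
    hyper_cache: dict[str, tuple[float, float]] = {}
    rows = []
    for name in draws.names:
        if "[" not in name or ":" not in name:
            continue
        base, rest = name.split("[", 1)
        region, species = rest[:-1].split(":", 1)
        hyper = None
        for prefix, hp in pairs.items():
            if base.startswith(prefix) and not base.startswith("beta0"):
                cand = hp + base[len(prefix):]
                if cand in draws.names:
                    hyper = cand
        if base == "beta0":
            hyper = "mu_beta0"
        if base == "alpha0":
            hyper = "mu_alpha0"
        if hyper is None:
            continue
        if hyper not in hyper_cache:
            h = draws.flat(hyper)
            hyper_cache[hyper] = tuple(np.percentile(h, [2.5, 97.5]))
        h_lo, h_hi = hyper_cache[hyper]
        x = draws.flat(name)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {
                "effect": base,
                "region": region,
                "species": species,
                "q2.5": float(lo),
                "q97.5": float(hi),
                "hyper": hyper,
                "hyper_q2.5": float(h_lo),
                "hyper_q97.5": float(h_hi),
                "diverges": bool(hi < h_lo or lo > h_hi),
            }
        )
    return pd.DataFrame(rows)


def region_mass_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior of the average community body mass per region
    (standardized log scale)."""
    regions = draws.meta.get("regions")
    if regions is None:
        regions = [n[8:-1] for n in draws.names if n.startswith("mu_mass[")]
    rows = []
    for region in regions:
        row = summary_row(f"mu_mass[{region}]", draws.flat(f"mu_mass[{region}]"))
        row["region"] = region
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_tables(draws: PosteriorDraws, out_dir: str | Path) -> dict[str, Path]:
    """Write the richness/mass, effect and species-divergence tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    tables = {
        "richness.csv": richness_summary(draws),
        "community_probabilities.csv": community_prob_summary(draws),
        "effects.csv": effect_summary(draws),
        "region_mass.csv": region_mass_summary(draws),
    }
    sp = species_vs_hyper(draws)
    if len(sp):
        tables["species_effects.csv"] = sp
    for fname, df in tables.items():
        path = out / fname
        df.to_csv(path, index=False)
        written[fname] = path
    return written
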