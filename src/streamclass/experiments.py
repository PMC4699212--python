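"""Reference computational experiments.

High-level drivers that reproduce the package's reference experiments:
a long stochastic run with phase statistics, the gamma x eta parameter
sweep of within-run lag correlations, the delta x sigma grid of
deterministic segregation proportions and initial-integration durations,
and stochastic build-up curves.  Each driver is pure given (config, seed)
and returns plain pandas/JSON-serializable results; the CLI is a thin
wrapper around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import engine, phase_stats
from .simulate import INTEGRATION, SEGREGATION

__all__ = [
    "PERIODIC_REFERENCE",
    "STOCHASTIC_REFERENCE",
    "SEPARATION_REFERENCE",
    "long_stochastic_run",
    "run_summary",
    "sweep_gamma_eta",
    "sweep_delta_sigma",
]

# Reference parameter sets for the package's standard experiments.
PERIODIC_REFERENCE = dict(gamma=0.1, eta=0.5, delta=5.0, sigma=1.0, beta=1.5, pi2_init=0.001)
STOCHASTIC_REFERENCE = dict(gamma=0.03, eta=0.1, delta=0.6, sigma=1.0, beta=0.5, K=6, pi2_init=1e-4)
SEPARATION_REFERENCE = dict(gamma=0.1, eta_tilde=0.05, beta=0.5, pi2_init=0.001)

MIN_SWITCHES = 10  # a run "switches" when it completes at least this many phases


def long_stochastic_run(
    *,
    n_phases: int,
    seed: int,
    max_elements: int = 2_000_000,
    update_source: str = "percept",
    **params,
) -> engine.RunPhases:
    """One long stochastic run; returns its interior phases."""
    cfg = {**STOCHASTIC_REFERENCE, **params}
    rng = np.random.default_rng(seed)
    res = engine.run_batch(
        gamma=cfg["gamma"], eta=cfg["eta"], delta=cfg["delta"], sigma=cfg["sigma"],
        beta=cfg["beta"], pi2_init=cfg["pi2_init"], mode="stochastic", K=cfg["K"],
        update_source=update_source, n_phases=n_phases, max_elements=max_elements,
        rng=rng,
    )
    return res.phases[0].interior()


def run_summary(phases: engine.RunPhases) -> dict:
    """Phase-statistics summary of one run: mean durations per percept,
    evidence-vs-duration correlations, and lag-1/2/3 duration correlations
    by transition type."""
    out: dict = {}
    d = phases.durations.astype(float)
    p = phases.percepts
    for ptype, name in ((INTEGRATION, "integration"), (SEGREGATION, "segregation")):
        m = p == ptype
        out[f"n_{name}"] = int(m.sum())
        out[f"mean_duration_{name}"] = float(d[m].mean()) if m.any() else np.nan
        ev = phases.evidence[m]
        ok = np.isfinite(ev)
        if ok.sum() >= 3 and np.std(d[m][ok]) > 0:
            r, pval = stats.pearsonr(ev[ok], d[m][ok])
            out[f"evidence_corr_{name}"] = float(r)
            out[f"evidence_corr_{name}_p"] = float(pval)
        else:
            out[f"evidence_corr_{name}"] = np.nan
    for lag in (1, 2, 3):
        for transition in phase_stats.TRANSITIONS[lag]:
            f, to = transition.split("->")
            want_f = INTEGRATION if f == "I" else SEGREGATION
            want_t = INTEGRATION if to == "I" else SEGREGATION
            m = (p[:-lag] == want_f) & (p[lag:] == want_t)
            key = f"lag{lag}_{f}{to}"
            if m.sum() >= 3:
                r, pval = stats.pearsonr(d[:-lag][m], d[lag:][m])
                out[key] = float(r)
                out[key + "_p"] = float(pval)
                out[key + "_n"] = int(m.sum())
            else:
                out[key] = np.nan
    return out


def _per_run_lag_corr(rp: engine.RunPhases, lag: int, want_from: int, want_to: int):
    d = rp.durations.astype(float)
    p = rp.percepts
    if len(d) <= lag:
        return np.nan
    m = (p[:-lag] == want_from) & (p[lag:] == want_to)
    if m.sum() < 3 or np.std(d[:-lag][m]) == 0 or np.std(d[lag:][m]) == 0:
        return np.nan
    return float(stats.pearsonr(d[:-lag][m], d[lag:][m])[0])


def sweep_gamma_eta(
    *,
    grid_size: int = 30,
    gamma_range: tuple[float, float] = (0.001, 0.3),
    eta_range: tuple[float, float] = (0.001, 0.3),
    n_phases: int = 500,
    max_elements: int = 120_000,
    seed: int = 0,
    spacing: str = "linear",
    update_source: str = "percept",
    **fixed,
) -> pd.DataFrame:
    """Within-run lag correlations across a gamma x eta grid.

    Runs ``grid_size**2`` stochastic simulations (one per grid cell, other
    parameters as in the reference long run), computes per-run lag-1 and
    lag-2 duration correlations by transition type, and flags runs in which
    switching occurred (at least ``MIN_SWITCHES`` completed phases).
    """
    cfg = {**STOCHASTIC_REFERENCE, **fixed}
    space = np.linspace if spacing == "linear" else (
        lambda lo, hi, n: np.geomspace(lo, hi, n))
    gammas = space(gamma_range[0], gamma_range[1], grid_size)
    etas = space(eta_range[0], eta_range[1], grid_size)
    gg, ee = np.meshgrid(gammas, etas, indexing="ij")
    rng = np.random.default_rng(seed)
    res = engine.run_batch(
        gamma=gg.ravel(), eta=ee.ravel(), delta=cfg["delta"], sigma=cfg["sigma"],
        beta=cfg["beta"], pi2_init=cfg["pi2_init"], mode="stochastic", K=cfg["K"],
        update_source=update_source, n_phases=n_phases, max_elements=max_elements,
        rng=rng,
    )
    rows = []
    for i in range(gg.size):
        rp = res.phases[i]
        interior = rp.interior()
        row = {
            "gamma": gg.ravel()[i],
            "eta": ee.ravel()[i],
            "n_switches": int(rp.n_switches),
            "switching": rp.n_switches >= MIN_SWITCHES,
            "n_elements": int(res.n_elements[i]),
        }
        for lag, transition in [(1, "I->S"), (1, "S->I"), (2, "I->I"), (2, "S->S")]:
            f, to = transition.split("->")
            wf = INTEGRATION if f == "I" else SEGREGATION
            wt = INTEGRATION if to == "I" else SEGREGATION
            row[f"lag{lag}_{f}{to}"] = _per_run_lag_corr(interior, lag, wf, wt)
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_aggregates(table: pd.DataFrame) -> dict:
    """Mean/std/range/positive-count of per-run correlations over switching runs."""
    sw = table[table["switching"]]
    out = {"n_runs": int(len(table)), "n_switching": int(len(sw))}
    for col in ("lag1_IS", "lag1_SI", "lag2_II", "lag2_SS"):
        vals = sw[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        out[col] = {
            "mean": float(np.mean(vals[ok])),
            "std": float(np.std(vals[ok])),
            "min": float(np.min(vals[ok])),
            "max": float(np.max(vals[ok])),
            "n_positive": int(np.sum(vals[ok] > 0)),
            "n": int(ok.sum()),
        }
    return out


def sweep_delta_sigma(
    *,
    delta_values: Sequence[float] = tuple(np.arange(1.0, 10.0)),
    sigma_values: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    horizon: int = 60_000,
    buildup_sigma: float = 4.0,
    buildup_deltas: Sequence[float] | None = None,
    buildup_runs: int = 100,
    buildup_horizon: int = 600,
    buildup_K: int = 6,
    seed: int = 0,
    **fixed,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic (delta, sigma) grid plus stochastic build-up curves.

    Returns the grid table from :func:`phase_stats.deterministic_grid` and,
    for ``sigma = buildup_sigma``, build-up curves (probability of
    segregation vs element index over ``buildup_runs`` stochastic runs per
    delta).
    """
    cfg = {**SEPARATION_REFERENCE, **fixed}
    grid = phase_stats.deterministic_grid(
        delta_values, sigma_values,
        gamma=cfg["gamma"], eta_tilde=cfg["eta_tilde"], beta=cfg["beta"],
        pi2_init=cfg["pi2_init"], horizon=horizon,
    )
    if buildup_deltas is None:
        buildup_deltas = [d for d in delta_values if 1.0 <= d / buildup_sigma <= 2.5]
    rng = np.random.default_rng(seed)
    curves = phase_stats.buildup_curve(
        buildup_deltas, sigma=buildup_sigma, gamma=cfg["gamma"],
        eta=cfg["eta_tilde"] * buildup_sigma, beta=cfg["beta"], K=buildup_K,
        pi2_init=cfg["pi2_init"], n_runs=buildup_runs, horizon=buildup_horizon,
        rng=rng,
    )
    return grid, curves
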