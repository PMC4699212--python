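"""Phase-duration statistics for bistable perception reports.

Implements the analysis pipeline applied to subject reports and to model
simulations alike: extraction of interior phase durations from switch-time
sequences, per-trial normalization (each duration divided by the mean
duration of its percept type within its trial, which removes spurious
pooled correlations driven by between-subject rate differences), pooled and
per-trial lag correlations split by transition type, a random-intercept
mixed-effects test of the mean per-trial correlation, and the build-up /
segregation-proportion summaries of the model as a function of the
normalized feature separation.

Lag conventions: lag 1 pairs adjacent phases (transitions I→S and S→I);
lag 2 pairs same-type phases separated by one opposite phase (I→I, S→S);
lag 3 pairs opposite-type phases two apart (I→S, S→I).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simulate import INTEGRATION, SEGREGATION
from . import engine

__all__ = [
    "Trial",
    "ReportData",
    "Phase",
    "CorrelationResult",
    "trial_phases",
    "normalize_durations",
    "lag_pairs",
    "pooled_lag_correlation",
    "per_trial_correlations",
    "buildup_curve",
    "deterministic_grid",
]

logger = logging.getLogger(__name__)

TRANSITIONS = {
    1: ("I->S", "S->I"),
    2: ("I->I", "S->S"),
    3: ("I->S", "S->I"),
}

_LABEL = {INTEGRATION: "I", SEGREGATION: "S"}


@dataclass
class Trial:
    """One trial's report: switch times (seconds or element counts) and the
    percept entered at each switch (1=integration, 2=segregation)."""

    switch_times: np.ndarray
    percepts: np.ndarray
    subject: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.percepts = np.asarray(self.percepts, dtype=int)
        if len(self.switch_times) != len(self.percepts):
            raise ValueError("switch_times and percepts must have equal length")
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError(
                f"switch times must be strictly increasing "
                f"(subject={self.subject!r}, trial={self.trial})"
            )
        if np.any((self.percepts != INTEGRATION) & (self.percepts != SEGREGATION)):
            raise ValueError("percept labels must be 1 (integration) or 2 (segregation)")
        dup = np.flatnonzero(np.diff(self.percepts) == 0)
        if len(dup):
            logger.warning(
                "merging %d repeated percept label(s) in subject=%r trial=%d",
                len(dup), self.subject, self.trial,
            )
            keep = np.concatenate([[True], np.diff(self.percepts) != 0])
            self.switch_times = self.switch_times[keep]
            self.percepts = self.percepts[keep]


@dataclass
class ReportData:
    """Subjects x trials of switch-time reports."""

    trials: list[Trial]
    units: str = "seconds"
    source: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject)
        return list(seen)


@dataclass(frozen=True)
class Phase:
    percept: int
    duration: float
    normalized: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    transition: str
    lag: int
    rho: float
    p: float | None
    n: int


def trial_phases(trial: Trial) -> list[Phase]:
    """Interior phase durations of one trial.

    Durations are successive differences of switch times; the phase entered
    at switch i has percept ``percepts[i]`` and lasts until switch i+1.  The
    interval before the first switch and the phase after the last switch are
    unbounded and dropped; the first and last *measured* phases are also
    dropped as boundary phases.  Fewer than 3 switch events yield an empty
    result.
    """
    if len(trial.switch_times) < 3:
        return []
    durations = np.diff(trial.switch_times)
    percepts = trial.percepts[:-1]
    return [Phase(int(p), float(d)) for p, d in zip(percepts[1:-1], durations[1:-1])]


def normalize_durations(phases: Sequence[Phase]) -> list[Phase]:
    """Divide each duration by the mean duration of its percept type.

    Applied within one trial; the per-type mean of the normalized values is
    1, so pooled scatters from trials with different switching rates
    concentrate around (1, 1).  Idempotent.
    """
    out: list[Phase] = []
    means = {}
    for ptype in (INTEGRATION, SEGREGATION):
        d = [ph.duration for ph in phases if ph.percept == ptype]
        means[ptype] = float(np.mean(d)) if d else np.nan
    for ph in phases:
        out.append(Phase(ph.percept, ph.duration, ph.duration / means[ph.percept]))
    return out


def lag_pairs(phases: Sequence[Phase], lag: int, transition: str,
              normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(d_i, d_{i+lag}) pairs within one trial restricted to a transition type."""
    want_from, want_to = transition.split("->")
    vals = np.array(
        [ph.normalized if normalized else ph.duration for ph in phases], dtype=float
    )
    kinds = np.array([_LABEL[ph.percept] for ph in phases])
    if len(phases) <= lag:
        return np.empty(0), np.empty(0)
    m = (kinds[:-lag] == want_from) & (kinds[lag:] == want_to)
    return vals[:-lag][m], vals[lag:][m]


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float | None]:
    if len(x) < 3:
        return (float(np.corrcoef(x, y)[0, 1]) if len(x) == 2 else np.nan, None)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pooled_lag_correlation(
    reports: ReportData | Iterable[list[Phase]],
    lag: int,
    transition: str,
    min_switches: int | None = None,
) -> CorrelationResult:
    """Pearson correlation of normalized duration pairs pooled over trials.

    Pairs are formed within each trial (never across trial boundaries) from
    per-trial normalized interior durations, restricted to ``transition``,
    then pooled unweighted across all trials and subjects.  ``min_switches``
    optionally excludes trials with fewer switch events.
    """
    xs, ys = [], []
    for phases in _iter_phase_lists(reports, min_switches):
        x, y = lag_pairs(normalize_durations(phases), lag, transition)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    rho, p = _pearson(x, y)
    return CorrelationResult(transition, lag, rho, p, len(x))


def per_trial_correlations(
    reports: ReportData | Iterable[list[Phase]],
    lag: int,
    transition: str,
    min_pairs: int = 3,
    min_switches: int | None = None,
    subjects: Sequence[str] | None = None,
) -> tuple[list[tuple[str, int, float]], int]:
    """One Pearson rho per trial (raw durations; normalization is not needed
    within a trial).  Trials with fewer than ``min_pairs`` pairs are skipped;
    the count of skipped trials is returned alongside."""
    out: list[tuple[str, int, float]] = []
    skipped = 0
    if isinstance(reports, ReportData):
        items = [(t.subject, t.trial, trial_phases(t))
                 for t in reports.trials
                 if min_switches is None or len(t.switch_times) >= min_switches]
    else:
        items = [(subjects[i] if subjects else str(i), i, phases)
                 for i, phases in enumerate(reports)]
    for subject, idx, phases in items:
        x, y = lag_pairs(phases, lag, transition, normalized=False)
        if len(x) < min_pairs or np.std(x) == 0 or np.std(y) == 0:
            skipped += 1
            continue
        out.append((subject, idx, float(stats.pearsonr(x, y)[0])))
    return out, skipped


def _iter_phase_lists(reports, min_switches):
    if isinstance(reports, ReportData):
        for t in reports.trials:
            if min_switches is not None and len(t.switch_times) < min_switches:
                continue
            yield trial_phases(t)
    else:
        yield from reports


def buildup_curve(
    delta_values: Sequence[float],
    *,
    sigma: float,
    gamma: float,
    eta: float,
    beta: float,
    K: int,
    pi2_init: float,
    n_runs: int,
    horizon: int,
    rng: np.random.Generator,
) -> dict[float, dict[str, np.ndarray]]:
    """Build-up of segregation: P(segregation) vs element index.

    For each feature separation, runs ``n_runs`` stochastic simulations and
    returns the mean segregation indicator per element with its standard
    error of the mean.
    """
    out = {}
    for d in delta_values:
        mat = engine.percept_matrix(
            gamma=gamma, eta=eta, delta=float(d), sigma=sigma, beta=beta,
            pi2_init=pi2_init, K=K, n_runs=n_runs, horizon=horizon, rng=rng,
        )
        prob = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        out[float(d)] = {"p_seg": prob, "sem": sem}
    return out


def deterministic_grid(
    delta_values: Sequence[float],
    sigma_values: Sequence[float],
    *,
    gamma: float,
    eta_tilde: float,
    beta: float,
    pi2_init: float,
    horizon: int,
) -> "pd.DataFrame":
    """Deterministic long-run summaries over a (delta, sigma) grid.

    For each cell: the long-run proportion of elements in segregation
    (measured between the first and last switch, i.e. over complete
    cycles), the initial-integration duration in elements (0 when the first
    percept is segregation; >= horizon, flagged, when no switch to
    segregation occurs), and whether on-going switching occurred.  The
    mixing update rate is ``eta_tilde * sigma``, keeping the normalized
    rate constant across sigma as in rate-vs-separation experiments.
    """
    import pandas as pd

    dv = np.asarray(delta_values, float)
    sv = np.asarray(sigma_values, float)
    dd, ss = np.meshgrid(dv, sv, indexing="ij")
    dd, ss = dd.ravel(), ss.ravel()
    res = engine.run_batch(
        gamma=gamma, eta=eta_tilde * ss, delta=dd, sigma=ss, beta=beta,
        pi2_init=pi2_init, mode="deterministic", n_phases=10 ** 9,
        max_elements=horizon,
    )
    rows = []
    for i in range(len(dd)):
        rp = res.phases[i]
        first_seg = res.first_b_percept[i] == SEGREGATION
        if first_seg:
            init_integration = 0
        elif rp.n_switches >= 1:
            # the first closed phase is the initial integration phase
            init_integration = int(rp.durations[0])
        else:
            init_integration = horizon
        if rp.n_switches >= 2:
            interior = rp.interior()
            seg_time = interior.durations[interior.percepts == SEGREGATION].sum()
            seg_prop = float(seg_time / interior.durations.sum())
        else:
            # no complete cycle: proportion held at the standing percept
            seg_prop = 1.0 if res.final_percept[i] == SEGREGATION else 0.0
        rows.append(
            {
                "delta": dd[i],
                "sigma": ss[i],
                "delta_tilde": dd[i] / ss[i],
                "seg_proportion": seg_prop,
                "init_integration": init_integration,
                "init_integration_censored": (not first_seg) and init_integration >= horizon,
                "switching": rp.n_switches >= 10,
                "n_switches": int(rp.n_switches),
            }
        )
    return pd.DataFrame(rows)
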