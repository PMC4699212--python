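"""Vectorized two-class simulation engine.

The package-scale experiments (parameter sweeps, long stochastic runs,
build-up curves) all use the two-class mixture initialized at A and B with
no class creation.  This module runs many such simulations in lockstep as
numpy array operations — one array slot per run — which is what makes a
900-run sweep with hundreds of phases per run take seconds instead of hours.

The per-element arithmetic is the same as the scalar reference path in
:mod:`streamclass.simulate` (creation check is moot at theta=0, then
classification, centroid update, mixing update with the moved centroid);
equivalence between the two paths is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gnmix import FACTOR_FLOOR, GNShape
from .simulate import INTEGRATION, SEGREGATION

__all__ = ["BatchResult", "RunPhases", "run_batch", "percept_matrix"]

_PATTERNS = {"ABA-": ("A", "B", "A"), "ABAB": ("A", "B")}


@dataclass
class RunPhases:
    """Completed phases of one run, in order.

    ``percepts``/``durations``/``evidence`` cover every *closed* phase
    (each switch closes one).  The first closed phase is a boundary phase
    (truncated by the run start); the final, never-closed phase is not
    recorded.  ``interior()`` drops the first closed phase, giving the
    analyzable set.
    """

    percepts: np.ndarray
    durations: np.ndarray
    evidence: np.ndarray

    def interior(self) -> "RunPhases":
        return RunPhases(self.percepts[1:], self.durations[1:], self.evidence[1:])

    @property
    def n_switches(self) -> int:
        return len(self.durations)


@dataclass
class BatchResult:
    phases: list[RunPhases]
    n_elements: np.ndarray      # elements simulated per run
    completed: np.ndarray       # reached the requested phase count
    final_percept: np.ndarray
    first_b_percept: np.ndarray  # percept implied by the first B classification


def run_batch(
    *,
    gamma,
    eta,
    delta,
    sigma=1.0,
    beta: float,
    pi2_init: float,
    pattern: str = "ABA-",
    mode: str = "stochastic",
    K: int = 1,
    update_source: str = "percept",
    n_phases: int = 500,
    max_elements: int = 200_000,
    rng: np.random.Generator | None = None,
) -> BatchResult:
    """Run a batch of two-class simulations in lockstep.

    ``gamma``, ``eta``, ``delta`` and ``sigma`` broadcast to a common run
    count.  Each run proceeds until it has closed ``n_phases + 1`` phases
    (``n_phases`` analyzable interior phases) or ``max_elements`` elements.

    In stochastic mode each element's class is drawn from its posterior, the
    percept flips after ``K`` opposite-percept B classifications (cumulative
    within the phase, switch taking effect at the triggering element), and
    the parameter updates attribute the element either to the stream implied
    by the current percept (``update_source="percept"``, the default:
    integration sends everything to class 1, segregation sends B to class 2)
    or to the drawn class (``update_source="drawn"``).  In deterministic
    mode the class is the posterior argmax and the percept follows the most
    recent B.
    """
    gamma, eta, delta, sigma = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (gamma, eta, delta, sigma))
    )
    n_runs = gamma.shape[0]
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    unit = _PATTERNS[pattern]

    # per-run density constants (sigma may vary across runs)
    shapes = GNShape(beta=beta, sigma=1.0)
    alpha = sigma * shapes.alpha            # alpha scales linearly with sigma
    cnorm = shapes.norm_const / sigma       # norm const scales as 1/sigma

    mu1 = np.zeros(n_runs)
    mu2 = delta.astype(float).copy()
    pi1 = np.full(n_runs, 1.0 - pi2_init)
    pi2 = np.full(n_runs, float(pi2_init))

    percept = np.full(n_runs, INTEGRATION, dtype=np.int8)
    counter = np.zeros(n_runs, dtype=np.int64)
    phase_start = np.zeros(n_runs, dtype=np.int64)
    phase_evidence = np.full(n_runs, np.nan)
    switch_count = np.zeros(n_runs, dtype=np.int64)
    seen_b = np.zeros(n_runs, dtype=bool)
    first_b_percept = np.zeros(n_runs, dtype=np.int8)

    ph_percept: list[list[int]] = [[] for _ in range(n_runs)]
    ph_duration: list[list[int]] = [[] for _ in range(n_runs)]
    ph_evidence: list[list[float]] = [[] for _ in range(n_runs)]

    active = np.arange(n_runs)
    n_elements = np.zeros(n_runs, dtype=np.int64)
    target_switches = n_phases + 1

    t = 0
    while len(active) and t < max_elements:
        label = unit[t % len(unit)]
        a = active
        x = delta[a] if label == "B" else 0.0

        z1 = np.abs(x - mu1[a]) / alpha[a]
        z2 = np.abs(x - mu2[a]) / alpha[a]
        p1 = cnorm[a] * np.exp(-(z1 ** beta))
        p2 = cnorm[a] * np.exp(-(z2 ** beta))
        j1 = pi1[a] * p1
        j2 = pi2[a] * p2
        total = j1 + j2
        if np.any(total <= 1e-300):
            raise FloatingPointError("mixture density underflow in batch run")
        post2 = j2 / total

        if mode == "deterministic":
            k2 = post2 > 0.5
        else:
            u = rng.random(len(a))
            k2 = u >= (1.0 - post2)

        # percept bookkeeping first: a switch takes effect at the element
        # that triggers it, and the updates below see the new percept
        if label == "B":
            newly = ~seen_b[a]
            if np.any(newly):
                first_b_percept[a[newly]] = np.where(k2[newly], SEGREGATION, INTEGRATION)
                seen_b[a] = True
                fresh = np.isnan(phase_evidence[a])
                phase_evidence[a[fresh]] = post2[fresh]
            if mode == "deterministic":
                new_percept = np.where(k2, SEGREGATION, INTEGRATION).astype(np.int8)
                switched = new_percept != percept[a]
            else:
                opposite = ((percept[a] == INTEGRATION) & k2) | (
                    (percept[a] == SEGREGATION) & ~k2
                )
                counter[a] += opposite
                switched = counter[a] >= K
                new_percept = np.where(
                    switched,
                    np.where(percept[a] == INTEGRATION, SEGREGATION, INTEGRATION),
                    percept[a],
                ).astype(np.int8)
            if np.any(switched):
                for pos in np.flatnonzero(switched):
                    r = a[pos]
                    ph_percept[r].append(int(percept[r]))
                    ph_duration[r].append(t - int(phase_start[r]))
                    ph_evidence[r].append(float(phase_evidence[r]))
                    phase_start[r] = t
                    phase_evidence[r] = post2[pos]
                    counter[r] = 0
                    switch_count[r] += 1
            percept[a] = new_percept

        # centroid update for the attributed class
        if mode == "stochastic" and update_source == "percept":
            k2_upd = (percept[a] == SEGREGATION) if label == "B" else np.zeros(len(a), bool)
        else:
            k2_upd = k2
        g = gamma[a]
        mu2[a] = np.where(k2_upd, mu2[a] + g * post2 * (x - mu2[a]), mu2[a])
        mu1[a] = np.where(~k2_upd, mu1[a] + g * (1.0 - post2) * (x - mu1[a]), mu1[a])

        # mixing update with the moved centroid
        z1 = np.abs(x - mu1[a]) / alpha[a]
        z2 = np.abs(x - mu2[a]) / alpha[a]
        p1 = cnorm[a] * np.exp(-(z1 ** beta))
        p2 = cnorm[a] * np.exp(-(z2 ** beta))
        px = pi1[a] * p1 + pi2[a] * p2
        f1 = 1.0 + eta[a] * (p1 - px)
        f2 = 1.0 + eta[a] * (p2 - px)
        clamped = (f1 <= 0) | (f2 <= 0)
        if np.any(clamped):
            f1 = np.maximum(f1, FACTOR_FLOOR)
            f2 = np.maximum(f2, FACTOR_FLOOR)
        new1 = pi1[a] * f1
        new2 = pi2[a] * f2
        if np.any(clamped):
            s = new1 + new2
            new1 = np.where(clamped, new1 / s, new1)
            new2 = np.where(clamped, new2 / s, new2)
        pi1[a] = new1
        pi2[a] = new2

        t += 1
        done = switch_count[a] >= target_switches
        if np.any(done):
            n_elements[a[done]] = t
            active = a[~done]

    if len(active):
        n_elements[active] = t

    phases = [
        RunPhases(
            np.asarray(ph_percept[r], dtype=np.int8),
            np.asarray(ph_duration[r], dtype=np.int64),
            np.asarray(ph_evidence[r]),
        )
        for r in range(n_runs)
    ]
    return BatchResult(
        phases=phases,
        n_elements=n_elements,
        completed=switch_count >= target_switches,
        final_percept=percept.copy(),
        first_b_percept=first_b_percept.copy(),
    )


def percept_matrix(
    *,
    gamma: float,
    eta: float,
    delta: float,
    sigma: float,
    beta: float,
    pi2_init: float,
    K: int,
    n_runs: int,
    horizon: int,
    rng: np.random.Generator,
    pattern: str = "ABA-",
    update_source: str = "percept",
) -> np.ndarray:
    """Per-element segregation indicator for ``n_runs`` stochastic runs.

    Returns a boolean (n_runs, horizon) matrix used for build-up curves:
    entry [r, t] is True when run r's percept at element t is segregation.
    The latent percept starts at integration and flips by the K-counter
    rule, exactly as in :func:`run_batch`.
    """
    unit = _PATTERNS[pattern]
    shape = GNShape(beta=beta, sigma=1.0)
    alpha = sigma * shape.alpha
    cnorm = shape.norm_const / sigma

    mu1 = np.zeros(n_runs)
    mu2 = np.full(n_runs, float(delta))
    pi1 = np.full(n_runs, 1.0 - pi2_init)
    pi2 = np.full(n_runs, float(pi2_init))
    percept = np.full(n_runs, INTEGRATION, dtype=np.int8)
    counter = np.zeros(n_runs, dtype=np.int64)
    out = np.zeros((n_runs, horizon), dtype=bool)

    for t in range(horizon):
        label = unit[t % len(unit)]
        x = float(delta) if label == "B" else 0.0
        z1 = np.abs(x - mu1) / alpha
        z2 = np.abs(x - mu2) / alpha
        p1 = cnorm * np.exp(-(z1 ** beta))
        p2 = cnorm * np.exp(-(z2 ** beta))
        j1 = pi1 * p1
        j2 = pi2 * p2
        post2 = j2 / (j1 + j2)
        u = rng.random(n_runs)
        k2 = u >= (1.0 - post2)
        if label == "B":
            opposite = ((percept == INTEGRATION) & k2) | (
                (percept == SEGREGATION) & ~k2
            )
            counter += opposite
            flip = counter >= K
            percept = np.where(
                flip,
                np.where(percept == INTEGRATION, SEGREGATION, INTEGRATION),
                percept,
            ).astype(np.int8)
            counter[flip] = 0
        if update_source == "percept":
            k2_upd = (percept == SEGREGATION) if label == "B" else np.zeros(n_runs, bool)
        else:
            k2_upd = k2
        mu2 = np.where(k2_upd, mu2 + gamma * post2 * (x - mu2), mu2)
        mu1 = np.where(~k2_upd, mu1 + gamma * (1.0 - post2) * (x - mu1), mu1)
        z1 = np.abs(x - mu1) / alpha
        z2 = np.abs(x - mu2) / alpha
        p1 = cnorm * np.exp(-(z1 ** beta))
        p2 = cnorm * np.exp(-(z2 ** beta))
        px = pi1 * p1 + pi2 * p2
        f1 = np.maximum(1.0 + eta * (p1 - px), FACTOR_FLOOR)
        f2 = np.maximum(1.0 + eta * (p2 - px), FACTOR_FLOOR)
        n1 = pi1 * f1
        n2 = pi2 * f2
        s = n1 + n2
        pi1, pi2 = n1 / s, n2 / s
        out[:, t] = percept == SEGREGATION
    return out
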