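"""Tone-sequence simulation: stimulus generation, the online classification
loop, percept labeling, switch detection, and phase extraction.

Alternating two-tone sequences (ABAB or ABA-, where "-" is a silent gap that
contributes no input element) are fed to the online mixture classifier.  The
percept is *integration* while B elements are classified to the same class as
A, and *segregation* while B is captured by the second class.  In
deterministic mode the percept follows the most recent B classification and
switching is periodic; in stochastic mode classifications are drawn from the
posterior and the percept is a latent state that flips after ``K``
opposite-percept B classifications within the current phase.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .gnmix import (
    GNShape,
    MixtureState,
    ModelConfig,
    maybe_create_class,
    posterior,
    update_centroid,
    update_mixing,
)

__all__ = [
    "INTEGRATION",
    "SEGREGATION",
    "StimulusSequence",
    "StepRecord",
    "SimulationTrace",
    "PhaseRecord",
    "make_sequence",
    "init_mixture",
    "step",
    "run_deterministic",
    "run_stochastic",
    "extract_phases",
]

INTEGRATION = 1
SEGREGATION = 2


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered feature-valued elements with A/B labels.

    A sits at feature 0 and B at feature ``delta``; any affine placement is
    equivalent by the translation/scale invariance of the update rules.
    """

    features: np.ndarray
    labels: np.ndarray  # array of 'A'/'B'
    pattern: str
    delta: float

    def __len__(self) -> int:
        return len(self.features)


def make_sequence(pattern: str, delta: float, n_triplets: int) -> StimulusSequence:
    """Build an ABA- or ABAB stimulus.

    ABA- emits three elements per triplet (A, B, A; the silent gap adds
    nothing), ABAB emits two (A, B).  ``n_triplets`` counts repeats of the
    base unit.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if pattern == "ABA-":
        unit_labels = ["A", "B", "A"]
    elif pattern == "ABAB":
        unit_labels = ["A", "B"]
    else:
        raise ValueError(f"unknown pattern {pattern!r}; expected 'ABA-' or 'ABAB'")
    labels = np.array(unit_labels * n_triplets)
    features = np.where(labels == "B", float(delta), 0.0)
    return StimulusSequence(features=features, labels=labels, pattern=pattern, delta=delta)


def init_mixture(delta: float, shape: GNShape, pi2_init: float) -> MixtureState:
    """Two-class initial state: centroids at A (0) and B (``delta``),
    mixing ``(1 - pi2_init, pi2_init)``."""
    if not (0 < pi2_init < 1):
        raise ValueError("pi2_init must be in (0, 1)")
    return MixtureState(
        centroids=np.array([0.0, float(delta)]),
        mixing=np.array([1.0 - pi2_init, pi2_init]),
        shape=shape,
    )


@dataclass
class StepRecord:
    index: int
    label: str
    x: float
    k_star: int
    post: np.ndarray          # posterior used for classification (pre-update)
    mixing: np.ndarray        # state after the update
    centroids: np.ndarray


@dataclass
class SimulationTrace:
    """Per-element record of one simulation run."""

    records: list[StepRecord]
    percepts: np.ndarray          # per-element percept (INTEGRATION/SEGREGATION)
    switch_indices: np.ndarray    # element indices where the percept changes
    config: ModelConfig
    sequence: StimulusSequence

    def evidence_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(element indices of B inputs, P(c=2|B) at those inputs)."""
        idx = [r.index for r in self.records if r.label == "B"]
        ev = [float(r.post[1]) if len(r.post) > 1 else 0.0
              for r in self.records if r.label == "B"]
        return np.asarray(idx), np.asarray(ev)

    def to_frame(self):
        """Tidy per-element table (pandas imported lazily)."""
        import pandas as pd

        rows = []
        for r, percept in zip(self.records, self.percepts):
            rows.append(
                {
                    "element_index": r.index,
                    "label": r.label,
                    "k_star": r.k_star,
                    "pi_2": r.mixing[1] if len(r.mixing) > 1 else np.nan,
                    "mu_1": r.centroids[0],
                    "mu_2": r.centroids[1] if len(r.centroids) > 1 else np.nan,
                    "p_c2_given_B": r.post[1] if (r.label == "B" and len(r.post) > 1) else np.nan,
                    "percept": "integration" if percept == INTEGRATION else "segregation",
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseRecord:
    """One maximal run of a single percept.

    ``evidence_at_start`` is P(c=2|B) at the first B of the phase (for a
    phase entered by a switch, the B that triggered it).  ``boundary`` marks
    the first and last phases of a run, which downstream analysis excludes.
    """

    percept: int
    start: int
    duration: int
    evidence_at_start: float
    boundary: bool = False


def step(
    state: MixtureState,
    x: float,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MixtureState, int, np.ndarray]:
    """One update cycle: creation check, classification, centroid update,
    mixing update.  Returns (new state, k*, classification posterior)."""
    state = maybe_create_class(state, x, config.theta, config.p_init)
    post = posterior(state, x)
    if config.classification_mode == "deterministic":
        k_star = int(np.argmax(post))
    else:
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        u = rng.random()
        k_star = int(np.searchsorted(np.cumsum(post), u, side="right").clip(0, len(post) - 1))
    if config.mixing_update_uses_new_mu:
        state = update_centroid(state, k_star, x, config.gamma)
        state = update_mixing(state, x, config.eta)
    else:
        # mixing update sees the pre-move centroids
        mixed = update_mixing(state, x, config.eta)
        state = update_centroid(state, k_star, x, config.gamma)
        state.mixing = mixed.mixing
    return state, k_star, post


def run_deterministic(
    config: ModelConfig,
    sequence: StimulusSequence,
    state: MixtureState | None = None,
    pi2_init: float = 0.001,
    shape: GNShape | None = None,
) -> SimulationTrace:
    """Deterministic-classification run.

    The percept at each element is segregation iff the most recent B was
    classified to class 2 (index 1); before any B, integration.
    """
    if state is None:
        if shape is None:
            raise ValueError("provide either an initial state or a shape")
        state = init_mixture(sequence.delta, shape, pi2_init)
    records: list[StepRecord] = []
    percepts = np.empty(len(sequence), dtype=int)
    percept = INTEGRATION
    for i, (x, label) in enumerate(zip(sequence.features, sequence.labels)):
        state, k_star, post = step(state, float(x), config)
        if label == "B":
            percept = SEGREGATION if k_star == 1 else INTEGRATION
        percepts[i] = percept
        records.append(StepRecord(i, str(label), float(x), k_star,
                                  post.copy(), state.mixing.copy(), state.centroids.copy()))
    switches = np.flatnonzero(np.diff(percepts) != 0) + 1
    return SimulationTrace(records, percepts, switches, config, sequence)


def run_stochastic(
    config: ModelConfig,
    sequence: StimulusSequence,
    rng: np.random.Generator,
    state: MixtureState | None = None,
    pi2_init: float = 0.0001,
    shape: GNShape | None = None,
) -> tuple[SimulationTrace, list[PhaseRecord]]:
    """Stochastic-classification run with the K-counter percept rule.

    Each element's class is drawn from the posterior.  A per-phase counter
    counts B classifications opposite to the current percept; when it
    reaches K the percept flips, taking effect at the triggering element.
    A classifications never affect the percept.

    The parameter updates follow ``config.update_source``: with
    ``"percept"`` (default) each element is attributed to the stream the
    current percept implies (integration: class 1 for everything;
    segregation: class 2 for B), so the mixture tracks the active scene
    interpretation; with ``"drawn"`` the drawn class is updated.
    """
    if config.classification_mode != "stochastic":
        raise ValueError("run_stochastic requires classification_mode='stochastic'")
    if state is None:
        if shape is None:
            raise ValueError("provide either an initial state or a shape")
        state = init_mixture(sequence.delta, shape, pi2_init)
    if config.update_source == "percept" and state.n_classes != 2:
        raise ValueError("percept-attributed updates require a two-class mixture")
    records: list[StepRecord] = []
    percepts = np.empty(len(sequence), dtype=int)
    percept = INTEGRATION
    counter = 0
    for i, (x, label) in enumerate(zip(sequence.features, sequence.labels)):
        x = float(x)
        state = maybe_create_class(state, x, config.theta, config.p_init)
        post = posterior(state, x)
        u = rng.random()
        k_star = int(np.searchsorted(np.cumsum(post), u, side="right").clip(0, len(post) - 1))
        if label == "B":
            opposite = (percept == INTEGRATION and k_star == 1) or (
                percept == SEGREGATION and k_star == 0
            )
            if opposite:
                counter += 1
                if counter >= config.K:
                    percept = SEGREGATION if percept == INTEGRATION else INTEGRATION
                    counter = 0
            elif config.counter_mode == "consecutive":
                counter = 0
        if config.update_source == "percept":
            k_upd = 1 if (label == "B" and percept == SEGREGATION) else 0
        else:
            k_upd = k_star
        if config.mixing_update_uses_new_mu:
            state = update_centroid(state, k_upd, x, config.gamma)
            state = update_mixing(state, x, config.eta)
        else:
            mixed = update_mixing(state, x, config.eta)
            state = update_centroid(state, k_upd, x, config.gamma)
            state.mixing = mixed.mixing
        percepts[i] = percept
        records.append(StepRecord(i, str(label), float(x), k_star,
                                  post.copy(), state.mixing.copy(), state.centroids.copy()))
    switches = np.flatnonzero(np.diff(percepts) != 0) + 1
    trace = SimulationTrace(records, percepts, switches, config, sequence)
    return trace, extract_phases(trace)


def extract_phases(trace: SimulationTrace) -> list[PhaseRecord]:
    """Segment the percept stream into contiguous phases.

    Phases tile the trace; the first and last are flagged as boundary
    phases (truncated by the run edges) for downstream exclusion.
    ``evidence_at_start`` is P(c=2|B) at the first B at or after the phase
    start (NaN if the phase contains no B).
    """
    percepts = trace.percepts
    n = len(percepts)
    if n == 0:
        return []
    b_idx, b_ev = trace.evidence_series()
    starts = np.concatenate([[0], np.flatnonzero(np.diff(percepts) != 0) + 1])
    ends = np.concatenate([starts[1:], [n]])
    phases = []
    for j, (s, e) in enumerate(zip(starts, ends)):
        pos = np.searchsorted(b_idx, s)
        ev = float(b_ev[pos]) if pos < len(b_idx) and b_idx[pos] < e else float("nan")
        phases.append(
            PhaseRecord(
                percept=int(percepts[s]),
                start=int(s),
                duration=int(e - s),
                evidence_at_start=ev,
                boundary=(j == 0 or j == len(starts) - 1),
            )
        )
    return phases
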