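"""Synthetic subject reports and report-file I/O.

The generator emulates key-press experiments in which listeners report
switches between integration and segregation over a fixed-length trial:
alternating phase durations are drawn from a log-normal chain whose latent
Gaussian log-durations follow an AR(1) process with lag-1 correlation ``r``
(so lag-2 partial correlation vanishes by construction), scaled per subject
by a multiplicative rate factor to emulate fast and slow switchers.  The
induced correlation on the duration scale is smaller than ``r`` (the
log-normal transform shrinks it); tests recover it against a Monte-Carlo
oracle rather than assuming it equals ``r``.

File formats: a JSON format with per-trial arrays ``switch_times_s`` and
``percepts`` plus metadata, a flat CSV alternative (subject, trial, time_s,
percept), and an optional MATLAB import for files laid out as a
subjects x trials struct array with fields ``data`` (switch times) and
``percept``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phase_stats import ReportData, Trial
from .simulate import INTEGRATION, SEGREGATION

__all__ = [
    "SynthConfig",
    "generate_reports",
    "write_reports_json",
    "read_reports_json",
    "write_reports_csv",
    "read_reports_csv",
    "import_mat_reports",
]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic report generator.

    Defaults emulate a 21-subject experiment with 6 trials of 4 minutes and
    mean phase durations of 6.0 s (integration) and 8.1 s (segregation).
    ``subject_spread`` is the multiplicative between-subject spread of the
    switching rate: subject factors are log-normal with sd(log) =
    log(subject_spread), so 1.0 means identical subjects.  ``lognorm_sd``
    is the sd of the latent log-duration (0.9 gives a coefficient of
    variation close to the heavy spread seen in report data).  ``r`` is the
    lag-1 correlation of the latent AR(1) log-duration chain.
    """

    n_subjects: int = 21
    n_trials: int = 6
    trial_length_s: float = 240.0
    mean_integration_s: float = 6.0
    mean_segregation_s: float = 8.1
    subject_spread: float = 1.5
    r: float = 0.2
    lognorm_sd: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.mean_integration_s, self.mean_segregation_s) <= 0:
            raise ValueError("mean durations must be positive")
        if not (-1 < self.r < 1):
            raise ValueError("lag-1 correlation must be in (-1, 1)")
        if self.trial_length_s <= 0:
            raise ValueError("trial length must be positive")
        if self.subject_spread < 1:
            raise ValueError("subject_spread is multiplicative and must be >= 1")


def generate_reports(cfg: SynthConfig, rng: np.random.Generator) -> ReportData:
    """Draw a full subjects x trials report set.

    Within a trial, latent z_i ~ AR(1) with parameter ``cfg.r`` and unit
    marginal variance; duration_i = mean(type_i) * subject_factor *
    exp(sd * z_i - sd^2/2) so each percept type keeps its configured mean.
    Switch times are the cumulative sums, truncated at the trial length;
    the truncated final phase is emitted as-is (analysis drops boundary
    phases anyway).
    """
    means = {INTEGRATION: cfg.mean_integration_s, SEGREGATION: cfg.mean_segregation_s}
    sd = cfg.lognorm_sd
    trials = []
    for s in range(cfg.n_subjects):
        factor = float(np.exp(rng.normal(0.0, np.log(cfg.subject_spread))))
        for t in range(cfg.n_trials):
            percept = int(rng.integers(1, 3))
            z = rng.normal()
            times, percepts = [], []
            clock = 0.0
            while clock < cfg.trial_length_s:
                times.append(clock)
                percepts.append(percept)
                d = means[percept] * factor * float(np.exp(sd * z - 0.5 * sd ** 2))
                clock += d
                percept = SEGREGATION if percept == INTEGRATION else INTEGRATION
                z = cfg.r * z + np.sqrt(1.0 - cfg.r ** 2) * rng.normal()
            times.append(cfg.trial_length_s)
            percepts.append(percept)
            trials.append(
                Trial(np.asarray(times), np.asarray(percepts),
                      subject=f"S{s+1:02d}", trial=t + 1)
            )
    return ReportData(trials=trials, units="seconds", source="synthetic",
                      metadata={"config": cfg.__dict__.copy()})


def write_reports_json(reports: ReportData, path) -> None:
    payload = {
        "units": reports.units,
        "source": reports.source,
        "metadata": reports.metadata,
        "trials": [
            {
                "subject": t.subject,
                "trial": t.trial,
                "switch_times_s": t.switch_times.tolist(),
                "percepts": t.percepts.tolist(),
            }
            for t in reports.trials
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_reports_json(path) -> ReportData:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed report file {path}: {exc}") from exc
    trials = []
    for i, rec in enumerate(payload.get("trials", [])):
        try:
            trials.append(
                Trial(
                    np.asarray(rec["switch_times_s"], dtype=float),
                    np.asarray(rec["percepts"], dtype=int),
                    subject=str(rec.get("subject", "")),
                    trial=int(rec.get("trial", i)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"malformed trial record #{i} "
                f"(subject={rec.get('subject')!r}, trial={rec.get('trial')!r}): {exc}"
            ) from exc
    return ReportData(trials=trials, units=payload.get("units", "seconds"),
                      source=payload.get("source", "experimental"),
                      metadata=payload.get("metadata", {}))


def write_reports_csv(reports: ReportData, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "trial", "time_s", "percept"])
        for t in reports.trials:
            for time, percept in zip(t.switch_times, t.percepts):
                w.writerow([t.subject, t.trial, repr(float(time)), int(percept)])


def read_reports_csv(path) -> ReportData:
    rows: dict[tuple[str, int], list[tuple[float, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, rec in enumerate(reader):
            try:
                key = (rec["subject"], int(rec["trial"]))
                rows.setdefault(key, []).append((float(rec["time_s"]), int(rec["percept"])))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed CSV row #{i + 2}: {rec!r}: {exc}") from exc
    trials = []
    for (subject, trial), vals in rows.items():
        vals.sort(key=lambda v: v[0])
        times = np.asarray([v[0] for v in vals])
        percepts = np.asarray([v[1] for v in vals])
        trials.append(Trial(times, percepts, subject=subject, trial=trial))
    return ReportData(trials=trials, units="seconds", source="experimental")


def import_mat_reports(path) -> ReportData:
    """Read reports from a MAT file holding a subjects x trials struct array
    ``trial`` with fields ``data`` (switch times, seconds) and ``percept``
    (1=integration, 2=segregation); a ``freqL`` field, if present, is kept
    as per-trial metadata."""
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=False)
    if "trial" not in mat:
        raise ValueError(f"{path}: expected a struct array named 'trial'")
    arr = mat["trial"]
    names = arr.dtype.names or ()
    for field in ("data", "percept"):
        if field not in names:
            raise ValueError(f"{path}: struct 'trial' lacks required field {field!r}")
    n_subj, n_trials = arr.shape
    trials = []
    freqs = {}
    for s in range(n_subj):
        for t in range(n_trials):
            cell = arr[s, t]
            times = np.asarray(cell["data"], dtype=float).ravel()
            percepts = np.asarray(cell["percept"], dtype=float).ravel().astype(int)
            if len(times) == 0:
                continue
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"{path}: non-increasing switch times at subject {s+1}, trial {t+1}"
                )
            trials.append(Trial(times, percepts, subject=f"S{s+1:02d}", trial=t + 1))
            if "freqL" in names:
                freqs[f"S{s+1:02d}/{t+1}"] = float(np.asarray(cell["freqL"]).ravel()[0])
    meta = {"shape": [int(n_subj), int(n_trials)]}
    if freqs:
        meta["freqL"] = freqs
    return ReportData(trials=trials, units="seconds", source="experimental", metadata=meta)
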