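"""Trial-level domain types, trials-file I/O, spike counting and inclusion filters.

Spike times are in milliseconds relative to stimulus onset.  All counting
windows and bins are half-open ``[lo, hi)``.  The analysis window end ``T`` is
600 or 1000 ms; a 600 ms pre-onset baseline must be available on every trial.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

VALID_T = (600, 1000)
CONDITIONS = ("A", "B", "AB")

TRIALS_COLUMNS = [
    "session_id", "neuron_id", "trial_id", "condition",
    "locA_deg", "freqA_hz", "levelA_db",
    "locB_deg", "freqB_hz", "levelB_db",
    "T_ms", "correct", "first_saccade", "spike_times", "lfp_path",
]


@dataclass(frozen=True)
class StimParams:
    """One sound's parameters: azimuth (deg), band center (Hz), level (dB SPL)."""

    loc_deg: float
    freq_hz: float
    level_db: float

    def key(self) -> tuple[float, float, float]:
        return (round(self.loc_deg, 6), round(self.freq_hz, 6), round(self.level_db, 6))


@dataclass
class TrialRecord:
    """A single behavioral trial of one neuron.

    ``condition`` is ``A`` or ``B`` (one sound) or ``AB`` (both sounds
    simultaneously); ``stim_b`` is ``None`` on single-sound trials.
    """

    session_id: str
    neuron_id: str
    trial_id: int
    condition: str
    stim_a: StimParams
    stim_b: StimParams | None
    spike_times: np.ndarray
    t_end: int
    correct: bool = True
    first_saccade: str = "unknown"
    epoch: tuple[float, float] = None  # type: ignore[assignment]
    lfp: np.ndarray | None = None
    lfp_path: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "AB" and self.stim_b is None:
            raise ValueError("AB trial requires stim_b")
        if self.t_end not in VALID_T:
            raise ValueError(f"T must be one of {VALID_T}, got {self.t_end}")
        if self.first_saccade not in ("A", "B", "unknown"):
            raise ValueError(f"bad first_saccade {self.first_saccade!r}")
        if self.epoch is None:
            self.epoch = (-600.0, float(self.t_end))
        lo, hi = self.epoch
        if lo > -600.0 or hi < self.t_end:
            raise ValueError(f"epoch {self.epoch} must cover [-600, {self.t_end}]")
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if st.size and np.any(np.diff(st) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if st.size and (st[0] < lo or st[-1] > hi):
            raise ValueError("spike_times outside the recorded epoch")
        self.spike_times = st


@dataclass
class Triplet:
    """Matched A-alone, B-alone and AB trial sets for one neuron."""

    neuron_id: str
    stim_a: StimParams
    stim_b: StimParams
    trials_a: list[TrialRecord]
    trials_b: list[TrialRecord]
    trials_ab: list[TrialRecord]
    t_end: int

    @property
    def n_a(self) -> int:
        return len(self.trials_a)

    @property
    def n_b(self) -> int:
        return len(self.trials_b)

    @property
    def n_ab(self) -> int:
        return len(self.trials_ab)

    def counts(self, condition: str, window: tuple[float, float] | None = None) -> np.ndarray:
        """Spike counts per trial for one condition over ``window`` (default [0, T))."""
        if window is None:
            window = (0.0, float(self.t_end))
        trials = {"A": self.trials_a, "B": self.trials_b, "AB": self.trials_ab}[condition]
        return np.array([count_spikes(t, window) for t in trials], dtype=int)


@dataclass
class BinnedCounts:
    """Per-trial spike counts in C contiguous bins of width w over [0, T)."""

    counts: np.ndarray  # (n_trials, C) ints
    w: float
    t_end: float

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.w


def count_spikes(trial: TrialRecord, window: tuple[float, float]) -> int:
    """Number of spikes in the half-open window [lo, hi)."""
    lo, hi = window
    if lo < trial.epoch[0] or hi > trial.epoch[1]:
        raise ValueError(f"window {window} outside recorded epoch {trial.epoch}")
    st = trial.spike_times
    return int(np.count_nonzero((st >= lo) & (st < hi)))


def bin_spikes(trials: Sequence[TrialRecord], w: float, t_end: float) -> BinnedCounts:
    """Bin each trial's spikes over [0, T) into C = T/w half-open bins."""
    n_bins = t_end / w
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"T={t_end} is not divisible by w={w}")
    c = int(round(n_bins))
    edges = np.arange(c + 1) * w
    counts = np.zeros((len(trials), c), dtype=int)
    for j, tr in enumerate(trials):
        st = tr.spike_times
        st = st[(st >= 0) & (st < t_end)]
        counts[j] = np.histogram(st, bins=edges)[0]
    return BinnedCounts(counts=counts, w=float(w), t_end=float(t_end))


def responsiveness_filter(trials: Sequence[TrialRecord]) -> tuple[float, bool]:
    """One-tailed paired t-test of evoked vs baseline spike counts.

    Compares the count in the 600 ms after onset with the 600 ms before,
    per trial; keep = (p <= 0.05) for post > pre.  A degenerate comparison
    (zero-variance differences) is unresponsive by construction: p = 1.
    """
    if len(trials) < 2:
        raise ValueError("responsiveness test needs at least 2 trials")
    post = np.array([count_spikes(t, (0.0, 600.0)) for t in trials], dtype=float)
    pre = np.array([count_spikes(t, (-600.0, 0.0)) for t in trials], dtype=float)
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0, False
    p = float(stats.ttest_rel(post, pre, alternative="greater").pvalue)
    return p, p <= 0.05


def assemble_triplets(
    records: Iterable[TrialRecord], min_trials: int = 5
) -> list[Triplet]:
    """Group correct trials into matched (A, B, AB) triplets per neuron.

    An AB condition defines a triplet; its A and B components are matched to
    single-sound conditions with identical stimulus parameters.  Triplets
    with fewer than ``min_trials`` correct trials in any member are dropped.
    """
    by_neuron: dict[str, list[TrialRecord]] = {}
    for r in records:
        if not r.correct:
            continue  # all analyses use correctly performed trials only
        by_neuron.setdefault(r.neuron_id, []).append(r)

    out: list[Triplet] = []
    for neuron_id in sorted(by_neuron):
        recs = by_neuron[neuron_id]
        singles: dict[tuple, list[TrialRecord]] = {}
        duals: dict[tuple, list[TrialRecord]] = {}
        for r in recs:
            if r.condition == "AB":
                duals.setdefault((r.stim_a.key(), r.stim_b.key(), r.t_end), []).append(r)
            else:
                # single-sound trials carry their one stimulus in stim_a,
                # whichever label (A or B) it plays in the triplet
                singles.setdefault((r.condition, r.stim_a.key(), r.t_end), []).append(r)
        for (key_a, key_b, t_end), ab_trials in sorted(duals.items()):
            trials_a = singles.get(("A", key_a, t_end), [])
            trials_b = singles.get(("B", key_b, t_end), [])
            if min(len(trials_a), len(trials_b), len(ab_trials)) < min_trials:
                continue
            out.append(
                Triplet(
                    neuron_id=neuron_id,
                    stim_a=ab_trials[0].stim_a,
                    stim_b=ab_trials[0].stim_b,  # type: ignore[arg-type]
                    trials_a=trials_a,
                    trials_b=trials_b,
                    trials_ab=ab_trials,
                    t_end=t_end,
                )
            )
    return out


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials to the CSV dialect that :func:`load_trials` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIALS_COLUMNS)
        for r in records:
            b = r.stim_b
            writer.writerow([
                r.session_id, r.neuron_id, r.trial_id, r.condition,
                _fmt_float(r.stim_a.loc_deg), _fmt_float(r.stim_a.freq_hz),
                _fmt_float(r.stim_a.level_db),
                _fmt_float(b.loc_deg if b else None),
                _fmt_float(b.freq_hz if b else None),
                _fmt_float(b.level_db if b else None),
                r.t_end, int(r.correct), r.first_saccade,
                ";".join(repr(float(t)) for t in r.spike_times),
                r.lfp_path or "",
            ])


def load_trials(path: str | Path) -> list[TrialRecord]:
    """Parse a trials CSV; every row is validated into a :class:`TrialRecord`."""
    records: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIALS_COLUMNS) - set(reader.fieldnames or []) - {"lfp_path"}
        if missing:
            raise ValueError(f"trials file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except Exception as exc:  # noqa: BLE001 - re-raise with row context
                raise ValueError(f"malformed trial row {i} of {path}: {exc}") from exc
    return records


def _parse_row(row: dict[str, str]) -> TrialRecord:
    stim_a = StimParams(
        float(row["locA_deg"]), float(row["freqA_hz"]), float(row["levelA_db"])
    )
    stim_b = None
    if row["locB_deg"].strip() != "":
        stim_b = StimParams(
            float(row["locB_deg"]), float(row["freqB_hz"]), float(row["levelB_db"])
        )
    spikes_field = row["spike_times"].strip()
    spikes = (
        np.array([float(s) for s in spikes_field.split(";")])
        if spikes_field
        else np.empty(0)
    )
    lfp_path = (row.get("lfp_path") or "").strip() or None
    lfp = None
    if lfp_path and Path(lfp_path).exists():
        tbl = np.loadtxt(lfp_path, delimiter=",", skiprows=1)
        lfp = tbl[:, 1] if tbl.ndim == 2 else np.atleast_1d(tbl)
    return TrialRecord(
        session_id=row["session_id"],
        neuron_id=row["neuron_id"],
        trial_id=int(row["trial_id"]),
        condition=row["condition"].strip(),
        stim_a=stim_a,
        stim_b=stim_b,
        spike_times=spikes,
        t_end=int(float(row["T_ms"])),
        correct=bool(int(row["correct"])),
        first_saccade=row["first_saccade"].strip() or "unknown",
        lfp=lfp,
        lfp_path=lfp_path,
    )
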