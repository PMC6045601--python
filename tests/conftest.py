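import numpy as np
import pytest

from spikemux.trials import StimParams, TrialRecord, Triplet

STIM_A = StimParams(loc_deg=-24.0, freq_hz=742.0, level_db=55.0)
STIM_B = StimParams(loc_deg=24.0, freq_hz=500.0, level_db=55.0)


def record_with_counts(
    condition: str,
    resp_count: int,
    base_count: int = 0,
    trial_id: int = 0,
    t_end: int = 600,
    neuron_id: str = "n1",
    first_saccade: str = "unknown",
) -> TrialRecord:
    """A trial whose response/baseline windows hold exactly the given counts."""
    resp = np.linspace(1.0, 500.0, resp_count) if resp_count else np.empty(0)
    base = np.linspace(-500.0, -100.0, base_count) if base_count else np.empty(0)
    return TrialRecord(
        session_id="s1",
        neuron_id=neuron_id,
        trial_id=trial_id,
        condition=condition,
        stim_a=STIM_B if condition == "B" else STIM_A,
        stim_b=STIM_B if condition == "AB" else None,
        spike_times=np.sort(np.concatenate([base, resp])),
        t_end=t_end,
        first_saccade=first_saccade,
    )


def triplet_from_counts(
    counts_a, counts_b, counts_ab, base=0, t_end: int = 600
) -> Triplet:
    """Triplet whose per-trial window counts equal the given integer lists."""
    mk = record_with_counts
    return Triplet(
        neuron_id="n1",
        stim_a=STIM_A,
        stim_b=STIM_B,
        trials_a=[mk("A", c, base, i, t_end) for i, c in enumerate(counts_a)],
        trials_b=[mk("B", c, base, i, t_end) for i, c in enumerate(counts_b)],
        trials_ab=[mk("AB", c, base, i, t_end) for i, c in enumerate(counts_ab)],
        t_end=t_end,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
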