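import numpy as np
import pytest
from hypothesis import settings

import catrace as ct

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_session():
    """600 s session, 30% freezing-selective neurons at 5x rate modulation."""
    cfg = ct.SimConfig(n_neurons=200, duration_s=600.0,
                       frac_freezing_selective=0.3, modulation_factor=5.0,
                       seed=42)
    return ct.simulate_session(cfg)


@pytest.fixture(scope="session")
def recovery_standardized(recovery_session):
    return ct.process_traces(recovery_session.traces)["standardized"]


@pytest.fixture(scope="session")
def recovery_selectivity(recovery_session, recovery_standardized):
    return ct.classify_population(recovery_standardized,
                                  recovery_session.behavior,
                                  n_iter=1000, seed=42)


@pytest.fixture(scope="session")
def detection_session():
    """Session for event-recovery scoring: default (null) rate modulation."""
    cfg = ct.SimConfig(n_neurons=50, duration_s=600.0, seed=3)
    session = ct.simulate_session(cfg)
    std = ct.process_traces(session.traces)["standardized"]
    return session, std


def event_f1(session, std, tol_frames: int = 2):
    """Event-level F1 of detected onsets vs ground-truth event times."""
    events = ct.detect_transients(std)
    fs = std.frame_rate_hz
    by_neuron: dict[str, list] = {}
    for e in events:
        by_neuron.setdefault(e.neuron_id, []).append(e)
    tp = fp = n_truth = 0
    for j, nid in enumerate(std.neuron_ids):
        truth = list(session.truth.event_times[j])
        n_truth += len(truth)
        used: set[int] = set()
        for e in sorted(by_neuron.get(nid, []), key=lambda e: e.onset_frame):
            t_on = e.onset_frame / fs
            match = next((i for i, t0 in enumerate(truth)
                          if i not in used and abs(t0 - t_on) <= tol_frames / fs),
                         None)
            if match is None:
                fp += 1
            else:
                used.add(match)
                tp += 1
    precision = tp / max(tp + fp, 1)
    recall = tp / max(n_truth, 1)
    return 2 * precision * recall / max(precision + recall, 1e-12)
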