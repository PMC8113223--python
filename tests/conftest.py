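import numpy as np
import pytest

from rivalrykit.events import KeyEvent, KeyMap, Session, Trial

KM = KeyMap({"b": "happy", "n": "mixed", "m": "neutral"})


def make_trial(events, subject="s1", mimicry="free", block=1, trial=1,
               stimulus="s1", duration=15.0):
    return Trial(subject_id=subject, mimicry=mimicry, block=block, trial=trial,
                 stimulus_id=stimulus, key_map=KM, duration_s=duration,
                 events=list(events))


def hold(key, t_on, t_off):
    return KeyEvent(key, t_on, t_off)


def random_trial(rng: np.random.Generator, max_events: int = 12,
                 duration: float = 15.0) -> Trial:
    """Adversarial random trial: overlapping holds, unreleased keys, events
    beyond trial end.  Times are quantized to 1 ms so the rasterization
    oracle samples every regime unambiguously."""
    n = int(rng.integers(0, max_events + 1))
    events = []
    for _ in range(n):
        tp = round(float(rng.uniform(0, duration + 1.0)), 3)
        if rng.random() < 0.15:
            tr = None  # held to trial end
        else:
            tr = round(tp + max(0.001, float(rng.exponential(2.0))), 3)
            if tr <= tp:
                tr = tp + 0.001
        events.append(KeyEvent(str(rng.choice(["b", "n", "m"])), tp, tr))
    return make_trial(events)


def make_session(trials, subject="s1", order="free-first", tas=None, iri=None,
                 ratings=None):
    return Session(subject_id=subject, condition_order=order, trials=list(trials),
                   tas20_total=tas, iri_total=iri, ratings=ratings or {})


@pytest.fixture(scope="session")
def small_study():
    """A 10-subject simulated study shared by I/O and pipeline tests."""
    from rivalrykit.simulate import RivalryParams, StudyConfig, simulate_study

    sessions, truth = simulate_study(StudyConfig(n_subjects=10, seed=11),
                                     RivalryParams())
    return sessions, truth
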