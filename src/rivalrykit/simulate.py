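"""Synthetic continuous-report rivalry sessions.

The generator is a renewal-process model of binocular rivalry: after an
initial unresolved onset period (lognormal), dominance epochs of the two
monocular percepts alternate with gamma-distributed durations, optionally
passing through short mixed-percept interludes at switches.  The happy-face
predominance seen empirically is produced both by a first-percept bias
(``p_first_happy``) and a longer happy duration scale.  The experimental
manipulation of interest — mimicry blocking lengthening neutral dominance —
is injected as a target increment of the per-trial mean neutral cumulative
time in the blocked condition, realized by a Monte-Carlo-calibrated
multiplier on the neutral gamma scale.

Latent timelines are serialized to key press/release events with Gaussian
report-latency jitter, producing logs in exactly the format the reader
consumes, so the whole pipeline can be exercised end to end and used for
type-I-error calibration and effect-recovery studies.

Randomness uses numpy's PCG64 via ``default_rng``; streams are derived from
``(seed, subject, condition, block, trial)`` index tuples so every trial is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .events import KeyEvent, KeyMap, Rating, Session, Trial
from .metrics import TrialMetrics

IDENTITIES = ("id1", "id2")
STIMULI = ("s1", "s2", "s3", "s4")  # four rival pairs, two per identity
STIMULUS_IDENTITY = {"s1": "id1", "s2": "id1", "s3": "id2", "s4": "id2"}

# Monocular-image rating model (means/SDs on the -3..+3 valence and 1..7
# arousal scales): happy faces clearly positive and arousing, neutral close
# to zero valence and low arousal.
RATING_MODEL = {
    ("happy", "valence"): (2.15, 1.12),
    ("neutral", "valence"): (-0.63, 0.98),
    ("happy", "arousal"): (4.97, 1.63),
    ("neutral", "arousal"): (2.74, 1.54),
}


@dataclass(frozen=True)
class RivalryParams:
    """Generative parameters of the per-trial rivalry process.

    Defaults were calibrated once by Monte-Carlo so that a default
    free-condition trial yields mean cumulative times near the empirical
    benchmarks (happy ~ 7.7 s, neutral ~ 2.7 s of a 15-s trial), with the
    remainder split between mixed reports and unreported onset/gap time.
    """

    gamma_shape_happy: float = 3.5
    gamma_scale_happy: float = 0.78
    gamma_shape_neutral: float = 3.5
    gamma_scale_neutral: float = 0.28
    onset_mu: float = math.log(1.1)  # lognormal location of the unresolved onset (s)
    onset_sigma: float = 0.45
    p_first_happy: float = 0.72
    p_mixed_interlude: float = 0.60
    mixed_mu: float = math.log(0.9)
    mixed_sigma: float = 0.5
    report_latency_sd: float = 0.05
    blocked_neutral_ct_delta_s: float = 0.70
    subject_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_shape_happy", "gamma_scale_happy", "gamma_shape_neutral",
                     "gamma_scale_neutral", "onset_sigma", "mixed_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_first_happy", "p_mixed_interlude"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.blocked_neutral_ct_delta_s < 0:
            raise ValueError("blocked_neutral_ct_delta_s must be >= 0")
        if self.report_latency_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class StudyConfig:
    """Design constants of a simulated study.

    The default layout mirrors the continuous-report design the analysis
    expects: 28 subjects, two mimicry conditions (order counterbalanced)
    of two blocks x eight 15-s trials each, four rival stimuli presented
    twice per block, key maps counterbalanced across blocks with the middle
    key always coding the mixed percept.  Questionnaire totals follow the
    normal-range means/SDs (TAS-20 43.6 +- 11.5, IRI 98.75 +- 8), with TAS
    correlated at ``rho_tas_emotion`` with the subject-level
    happy-dominance latent factor.
    """

    n_subjects: int = 28
    n_blocks_per_condition: int = 2
    n_trials_per_block: int = 8
    duration_s: float = 15.0
    tas_mean: float = 43.6
    tas_sd: float = 11.5
    iri_mean: float = 98.75
    iri_sd: float = 8.0
    rho_tas_emotion: float = -0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_blocks_per_condition, self.n_trials_per_block) < 1:
            raise ValueError("counts must be positive")
        if abs(self.rho_tas_emotion) > 1:
            raise ValueError("|rho_tas_emotion| must be <= 1")


@dataclass
class SubjectState:
    """Per-subject latent state: a standard-normal happy-dominance factor.

    Positive ``dominance_z`` lengthens happy epochs (multiplicatively, with
    spread ``subject_sd``), creating stable between-subject differences that
    questionnaire scores can correlate with.
    """

    subject_id: str
    dominance_z: float = 0.0


def _key_map_for_block(block: int) -> KeyMap:
    # "n" always codes mixed; the outer keys swap across blocks
    if block % 2 == 1:
        return KeyMap({"b": "happy", "n": "mixed", "m": "neutral"})
    return KeyMap({"b": "neutral", "n": "mixed", "m": "happy"})


def _latent_timeline(params: RivalryParams, happy_scale: float, neutral_scale: float,
                     rng: np.random.Generator, duration: float) -> list[tuple[str, float, float]]:
    """Tile [onset, duration] with alternating dominance epochs (latent truth)."""
    tiles: list[tuple[str, float, float]] = []
    t = float(rng.lognormal(params.onset_mu, params.onset_sigma))
    if t >= duration:
        return tiles
    label = "happy" if rng.random() < params.p_first_happy else "neutral"
    while t < duration:
        if label == "happy":
            dur = rng.gamma(params.gamma_shape_happy, happy_scale)
        else:
            dur = rng.gamma(params.gamma_shape_neutral, neutral_scale)
        tiles.append((label, t, min(t + dur, duration)))
        t += dur
        if t >= duration:
            break
        if rng.random() < params.p_mixed_interlude:
            mdur = rng.lognormal(params.mixed_mu, params.mixed_sigma)
            tiles.append(("mixed", t, min(t + mdur, duration)))
            t += mdur
            if t >= duration:
                break
        label = "neutral" if label == "happy" else "happy"
    return tiles


def _subject_scales(params: RivalryParams, state: SubjectState) -> tuple[float, float]:
    mult = math.exp(params.subject_sd * state.dominance_z)
    return params.gamma_scale_happy * mult, params.gamma_scale_neutral / mult


def simulate_trial(params: RivalryParams, subject_state: SubjectState, mimicry: str,
                   rng: np.random.Generator, *, block: int = 1, trial: int = 1,
                   stimulus_id: str = "s1", duration_s: float = 15.0,
                   neutral_blocked_multiplier: float | None = None) -> Trial:
    """Draw one trial of the renewal process and serialize it to key events.

    In the blocked condition the neutral gamma scale is multiplied by the
    calibrated multiplier realizing the target neutral-CT increment.  Report
    latency jitter (truncated so press/release pairs never reorder) is then
    added when serializing the latent timeline.
    """
    happy_scale, neutral_scale = _subject_scales(params, subject_state)
    if mimicry == "blocked":
        if neutral_blocked_multiplier is None:
            neutral_blocked_multiplier = calibrate_neutral_multiplier(params)
        neutral_scale *= neutral_blocked_multiplier
    tiles = _latent_timeline(params, happy_scale, neutral_scale, rng, duration_s)

    key_map = _key_map_for_block(block)
    label_to_key = {v: k for k, v in key_map.mapping.items()}
    events: list[KeyEvent] = []
    prev_press = -math.inf
    for label, t_on, t_off in tiles:
        press = t_on + rng.normal(0.0, params.report_latency_sd) if params.report_latency_sd else t_on
        release = t_off + rng.normal(0.0, params.report_latency_sd) if params.report_latency_sd else t_off
        press = min(max(press, 0.0, prev_press + 1e-6), duration_s - 1e-6)
        release = min(max(release, press + 1e-4), duration_s)
        events.append(KeyEvent(label_to_key[label], press, release))
        prev_press = press
    return Trial(subject_id=subject_state.subject_id, mimicry=mimicry, block=block,
                 trial=trial, stimulus_id=stimulus_id, key_map=key_map,
                 duration_s=duration_s, events=events)


def _mean_neutral_ct(params: RivalryParams, multiplier: float, n_trials: int,
                     seed: int, duration: float = 15.0) -> float:
    """Marginal (over subjects) mean per-trial *measured* neutral CT at a
    given neutral-scale multiplier.

    Trials are serialized to key events and parsed back exactly as the
    analysis pipeline does, so the calibrated increment lands on the
    quantity the cumulative-time analysis actually estimates (report jitter
    and boundary clipping shift measured CT slightly relative to the latent
    timeline).  Common random numbers across multipliers (the stream depends
    only on the trial index) keep the calibration objective smooth.
    """
    from .metrics import trial_metrics

    total = 0.0
    for i in range(n_trials):
        rng = np.random.default_rng([seed, i])
        state = SubjectState("cal", float(rng.standard_normal()))
        trial = simulate_trial(params, state, "blocked", rng,
                               duration_s=duration,
                               neutral_blocked_multiplier=multiplier)
        total += trial_metrics(trial).ct_s["neutral"]
    return total / n_trials


@lru_cache(maxsize=32)
def _calibrate_cached(params: RivalryParams, delta: float, n_trials: int, seed: int) -> float:
    if delta <= 0:
        return 1.0
    base = _mean_neutral_ct(params, 1.0, n_trials, seed)

    def objective(m: float) -> float:
        return _mean_neutral_ct(params, m, n_trials, seed) - base - delta

    hi = 2.0
    while objective(hi) < 0 and hi < 32:
        hi *= 2
    return float(brentq(objective, 1.0, hi, xtol=1e-4))


def calibrate_neutral_multiplier(params: RivalryParams, delta: float | None = None,
                                 n_trials: int = 16000, seed: int = 987654321) -> float:
    """Neutral-scale multiplier whose blocked-condition effect on mean neutral
    CT equals ``delta`` seconds (default: the params' target increment).

    Solved by Monte-Carlo bisection with common random numbers; the
    calibration stream is fixed and independent of the study seed so the
    mapping is a deterministic function of the parameters.
    """
    if delta is None:
        delta = params.blocked_neutral_ct_delta_s
    return _calibrate_cached(params, float(delta), n_trials, seed)


def simulate_study(config: StudyConfig, params: RivalryParams | None = None
                   ) -> tuple[list[Session], dict]:
    """Simulate a full counterbalanced study; returns sessions + ground truth.

    Condition order alternates across subjects; stimuli are shuffled within
    block (each of the four rival pairs twice); questionnaires are drawn
    with TAS-20 tied to the dominance factor at ``rho_tas_emotion``.
    """
    params = params or RivalryParams()
    nb = config.n_blocks_per_condition
    n_blocks = 2 * nb
    mult = calibrate_neutral_multiplier(params) if params.blocked_neutral_ct_delta_s > 0 else 1.0
    rho = config.rho_tas_emotion

    sessions: list[Session] = []
    truth_subjects = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        order = "free-first" if i % 2 == 0 else "blocked-first"
        srng = np.random.default_rng([config.seed, params.seed, i, 0])
        z = float(srng.standard_normal())
        tas = config.tas_mean + config.tas_sd * (rho * z + math.sqrt(1 - rho ** 2)
                                                 * srng.standard_normal())
        iri = config.iri_mean + config.iri_sd * srng.standard_normal()
        state = SubjectState(subject_id=subject_id, dominance_z=z)

        trials: list[Trial] = []
        for block in range(1, n_blocks + 1):
            first = order.split("-")[0]
            mimicry = first if block <= nb else {"free": "blocked", "blocked": "free"}[first]
            brng = np.random.default_rng([config.seed, params.seed, i, block, 777])
            stim_pool = [STIMULI[j % 4] for j in range(config.n_trials_per_block)]
            stim_order = list(brng.permutation(stim_pool))
            for trial_idx in range(1, config.n_trials_per_block + 1):
                trng = np.random.default_rng([config.seed, params.seed, i, block, trial_idx])
                trials.append(simulate_trial(
                    params, state, mimicry, trng, block=block, trial=trial_idx,
                    stimulus_id=str(stim_order[trial_idx - 1]),
                    duration_s=config.duration_s,
                    neutral_blocked_multiplier=mult,
                ))

        ratings: dict[tuple[str, str, str], Rating] = {}
        rrng = np.random.default_rng([config.seed, params.seed, i, 1])
        for mim in ("free", "blocked"):
            for ident in IDENTITIES:
                for expr in ("happy", "neutral"):
                    vm, vs = RATING_MODEL[(expr, "valence")]
                    am, as_ = RATING_MODEL[(expr, "arousal")]
                    val = float(np.clip(rrng.normal(vm, vs), -3, 3))
                    aro = float(np.clip(rrng.normal(am, as_), 1, 7))
                    ratings[(mim, ident, expr)] = Rating(val, aro)

        sessions.append(Session(subject_id=subject_id, condition_order=order,
                                trials=trials, tas20_total=tas, iri_total=iri,
                                ratings=ratings))
        truth_subjects.append({"subject": subject_id, "dominance_z": z,
                               "tas20_total": tas, "iri_total": iri,
                               "condition_order": order})

    ground_truth = {
        "params": asdict(params),
        "config": asdict(config),
        "neutral_blocked_multiplier": mult,
        "subjects": truth_subjects,
        "rng": "numpy PCG64 (default_rng), streams keyed by "
               "(study seed, params seed, subject, block, trial)",
    }
    return sessions, ground_truth


# ---------------------------------------------------------------------------
# rasterization oracle (used by tests as the independent metrics route)

def grid_oracle_metrics(trial: Trial, step_ms: float = 1.0) -> TrialMetrics:
    """IP/ORT/CT by millisecond rasterization, independent of the sweep parser.

    At each grid-cell center the dominant label is the label of the most
    recent still-held press covering that time; painting events in press
    order realizes exactly that rule.  Intended as a test oracle: accuracy
    is one grid step per event boundary.
    """
    step = step_ms / 1000.0
    n = int(round(trial.duration_s / step))
    centers = (np.arange(n) + 0.5) * step
    labels = np.full(n, -1, dtype=np.int8)
    code = {"happy": 0, "neutral": 1, "mixed": 2}
    for ev in sorted(trial.events, key=lambda e: e.t_press):
        rel = ev.t_release if ev.t_release is not None else trial.duration_s
        mask = (centers >= ev.t_press) & (centers < rel)
        labels[mask] = code[trial.key_map.percept(ev.key)]
    ct = {lab: float(np.sum(labels == c) * step) for lab, c in code.items()}
    unreported = trial.duration_s - sum(ct.values())
    non_mixed = np.nonzero((labels == 0) | (labels == 1))[0]
    if non_mixed.size == 0:
        return TrialMetrics(ip="none", ort_s=None, ct_s=ct, unreported_s=unreported)
    first = int(non_mixed[0])
    ip = "happy" if labels[first] == 0 else "neutral"
    return TrialMetrics(ip=ip, ort_s=float(first * step), ct_s=ct, unreported_s=unreported)
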