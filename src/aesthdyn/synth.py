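"""Synthetic dial-rating experiment generator.

Generates event logs and overall judgments with the statistical structure the
downstream analyses assume:

* each stimulus carries a smooth *shared* latent value time course (plus a
  stimulus-specific mean level), common to all observers;
* each (observer, stimulus) pair carries a smooth *individual* latent time
  course plus observer-specific mean and category-affinity offsets;
* the momentary latent value is the ``w_shared``-weighted mixture of the two,
  plus a category mean shift and a smooth session-specific perturbation;
* the dial is a first-order lag tracking the latent value with time constant
  ``tau_integration``; an event is emitted only when the lagged target moves
  more than ``dead_zone`` away from the current dial position;
* the overall judgment is the time mean of the latent trace plus noise.

Shared and individual components are drawn once per stimulus and per
(observer, stimulus) respectively and reused across sessions; session noise is
the only cross-session difference.  All randomness is a pure function of the
configured seed: every random stream is keyed by (seed, stream tag, stable id
hashes), so regenerating any single trace in isolation gives the same values
as a full experiment run.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .config import Dist, SimulationConfig

__all__ = [
    "ParticipantProfile",
    "StimulusProfile",
    "EventLog",
    "generate_latent_trace",
    "simulate_dial_events",
    "simulate_experiment",
    "dial_responsiveness",
    "SESSIONS",
    "CATEGORIES",
    "GROUPS",
]

SESSIONS = ("test", "retest")
CATEGORIES = ("dance", "landscape")
GROUPS = ("rate", "view")

# random-stream tags (second entry of every seed key)
_T_PARTICIPANTS = 0
_T_STIMULI = 1
_T_SHARED = 2
_T_INDIV = 3
_T_SESSION = 4
_T_OVERALL = 5
_T_TRAITS = 6

# trait-covariate linear model: trait = loading * source + N(0, noise_sd).
# Loadings are stated here once; the trait-regression analyses must be able
# to recover them from simulated data.
TRAIT_MODEL = {
    "panas_pos": ("mean_bias", 1.0, 0.10),
    "panas_neg": (None, 0.0, 0.20),
    "stai": (None, 0.0, 0.20),
    "shaps": ("log_tau", 0.3, 0.12),  # anhedonia: slower, flatter dial use
    "area": ("w_shared_centered", 1.0, 0.10),
    "pref_dance": ("affinity_dance", 1.0, 0.08),
    "pref_landscape": ("affinity_landscape", 1.0, 0.08),
}


def _id_key(identifier: str | int) -> int:
    """Stable 31-bit hash of an identifier, for seed derivation."""
    digest = hashlib.blake2s(str(identifier).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _stream(seed: int, tag: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag), *map(int, keys)])


@dataclass
class ParticipantProfile:
    participant_id: str
    group: str
    w_shared: float
    tau_integration: float
    dead_zone: float
    session_noise_sd: float
    overall_noise_sd: float
    mean_bias: float = 0.0
    affinity_dance: float = 0.0
    affinity_landscape: float = 0.0
    trait_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0.0 <= self.w_shared <= 1.0:
            raise ValueError("w_shared must lie in [0, 1]")
        if not self.tau_integration > 0:
            raise ValueError("tau_integration must be positive")
        for name in ("dead_zone", "session_noise_sd", "overall_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("w_shared", "tau_integration", "dead_zone",
                     "session_noise_sd", "overall_noise_sd", "mean_bias",
                     "affinity_dance", "affinity_landscape"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def affinity(self, category: str) -> float:
        return {"dance": self.affinity_dance,
                "landscape": self.affinity_landscape}[category]


@dataclass
class StimulusProfile:
    stimulus_id: str
    category: str
    mean_level: float
    length_scale_s: float
    amplitude: float
    category_mean_shift: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.length_scale_s <= 0 or self.amplitude < 0:
            raise ValueError("length_scale_s must be > 0 and amplitude >= 0")


@dataclass
class EventLog:
    """Timestamped dial positions for one (participant, stimulus, session)."""

    participant_id: str
    group: str
    session: str
    category: str
    stimulus_id: str
    t_sec: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.t_sec = np.asarray(self.t_sec, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.t_sec.shape != self.position.shape:
            raise ValueError("t_sec and position must have equal length")
        if self.t_sec.size and np.any(np.diff(self.t_sec) <= 0):
            raise ValueError("event timestamps must be strictly increasing")
        if self.position.size and (np.any(self.position < -1) or np.any(self.position > 1)):
            raise ValueError("dial positions must lie in [-1, 1]")

    def __len__(self) -> int:
        return int(self.t_sec.size)


def _smooth_standard_noise(n: int, sample_rate_hz: float, length_scale_s: float,
                           rng: np.random.Generator,
                           demean: bool = True) -> np.ndarray:
    """Low-pass-filtered white noise scaled to SD 1.

    With ``demean`` the trace is also centered to time-mean 0 (used for the
    shared and individual components).  The session perturbation keeps its
    natural random mean so that session-to-session changes in liking shift
    the overall judgment as well as the momentary trace.
    """
    white = rng.standard_normal(n)
    sigma = length_scale_s * sample_rate_hz
    smooth = gaussian_filter1d(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(n)
    if demean:
        return (smooth - smooth.mean()) / sd
    return smooth / sd


def _shared_component(stimulus: StimulusProfile, config: SimulationConfig,
                      seed: int) -> np.ndarray:
    rng = _stream(seed, _T_SHARED, _id_key(stimulus.stimulus_id))
    z = _smooth_standard_noise(config.n_samples, config.sample_rate_hz,
                               stimulus.length_scale_s, rng)
    return stimulus.amplitude * z + stimulus.mean_level


def _individual_component(participant: ParticipantProfile,
                          stimulus: StimulusProfile,
                          config: SimulationConfig, seed: int) -> np.ndarray:
    rng = _stream(seed, _T_INDIV, _id_key(participant.participant_id),
                  _id_key(stimulus.stimulus_id))
    z = _smooth_standard_noise(config.n_samples, config.sample_rate_hz,
                               stimulus.length_scale_s, rng)
    offset = participant.mean_bias + participant.affinity(stimulus.category)
    return stimulus.amplitude * z + offset


def generate_latent_trace(participant: ParticipantProfile,
                          stimulus: StimulusProfile, session: str,
                          config: SimulationConfig, seed: int) -> np.ndarray:
    """Momentary latent value trace for one viewing, clipped to [-1, 1].

    The shared component (per stimulus) and individual component (per
    participant x stimulus) are reproducibly derived from ``seed`` and reused
    across sessions; the session adds an independent smooth perturbation with
    SD ``session_noise_sd``.
    """
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}, got {session!r}")
    shared = _shared_component(stimulus, config, seed)
    indiv = _individual_component(participant, stimulus, config, seed)
    w = participant.w_shared
    latent = w * shared + (1.0 - w) * indiv + stimulus.category_mean_shift
    if participant.session_noise_sd > 0:
        rng = _stream(seed, _T_SESSION, _id_key(participant.participant_id),
                      _id_key(stimulus.stimulus_id), SESSIONS.index(session))
        latent = latent + participant.session_noise_sd * _smooth_standard_noise(
            config.n_samples, config.sample_rate_hz,
            stimulus.length_scale_s, rng, demean=False)
    return np.clip(latent, -1.0, 1.0)


def dial_path(latent: np.ndarray, participant: ParticipantProfile,
              sample_rate_hz: float) -> np.ndarray:
    """Sample path of the dial at the sampling grid (lag + dead zone)."""
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise ValueError("latent trace is empty")
    dt = 1.0 / sample_rate_hz
    alpha = 1.0 - math.exp(-dt / participant.tau_integration)
    # first-order lag: l_i = (1 - alpha) l_{i-1} + alpha x_i, l_{-1} = 0
    lagged = lfilter([alpha], [1.0, -(1.0 - alpha)], latent)
    path = np.empty_like(lagged)
    pos = 0.0
    dz = participant.dead_zone
    for i, target in enumerate(lagged):
        if abs(target - pos) > dz:
            pos = min(1.0, max(-1.0, target))
        path[i] = pos
    return path


def simulate_dial_events(latent: np.ndarray, participant: ParticipantProfile,
                         sample_rate_hz: float, *, trial_keys: dict | None = None,
                         ) -> EventLog:
    """Emit dial events for one viewing.

    The dial starts at 0 (neutral).  An event (timestamp, new position) is
    recorded whenever the lagged target moves more than ``dead_zone`` away
    from the current dial position; the dial then jumps to the target.  The
    mechanism is deterministic given the latent trace.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise ValueError("latent trace is empty")
    path = dial_path(latent, participant, sample_rate_hz)
    times, positions = [], []
    pos = 0.0
    for i, p in enumerate(path):
        if p != pos:
            pos = p
            times.append(i / sample_rate_hz)
            positions.append(pos)
    keys = {
        "participant_id": participant.participant_id,
        "group": participant.group,
        "session": "test",
        "category": "dance",
        "stimulus_id": "",
    }
    if trial_keys:
        keys.update(trial_keys)
    return EventLog(t_sec=np.asarray(times), position=np.asarray(positions), **keys)


def dial_responsiveness(tau_integration: float, dead_zone: float,
                        config: SimulationConfig | None = None,
                        n_reference: int = 20) -> float:
    """Derived generating parameter: responsiveness of a dial configuration.

    The lag time constant and the dead zone jointly set how dynamically a
    dial tracks experience (a long lag smooths change away; a wide dead zone
    turns it into sparse jumps, which *raises* the root-mean-squared
    derivative for the same total travel).  Responsiveness is therefore
    defined mechanistically: the median rmsd the dial produces on
    standard-amplitude reference latent inputs, a deterministic function of
    (tau_integration, dead_zone) only.
    """
    config = config or SimulationConfig()
    probe = ParticipantProfile(
        participant_id="_probe", group="rate", w_shared=0.5,
        tau_integration=tau_integration, dead_zone=dead_zone,
        session_noise_sd=0.0, overall_noise_sd=0.0)
    vals = []
    for k in range(n_reference):
        rng = _stream(988_777, 0, k)  # fixed probe inputs, not the data seed
        latent = config.latent_amplitude * _smooth_standard_noise(
            config.n_samples, config.sample_rate_hz,
            config.latent_length_scale_s, rng)
        path = dial_path(latent, probe, config.sample_rate_hz)
        d = np.diff(path)
        vals.append(float(np.sqrt(np.mean(d * d))))
    return float(np.median(vals))


def _sample_participants(config: SimulationConfig) -> list[ParticipantProfile]:
    pop = config.population
    n = config.n_rate + config.n_view
    rng = _stream(config.rng_seed, _T_PARTICIPANTS)
    cols = {
        name: pop[name].sample(rng, n)
        for name in ("w_shared", "tau_integration", "dead_zone",
                     "session_noise_sd", "overall_noise_sd", "mean_bias")
    }
    aff_d = pop["affinity"].sample(rng, n)
    aff_l = pop["affinity"].sample(rng, n)
    cols["w_shared"] = np.clip(cols["w_shared"], 0.0, 1.0)
    cols["tau_integration"] = np.maximum(cols["tau_integration"], 1e-3)
    cols["dead_zone"] = np.maximum(cols["dead_zone"], 0.0)
    cols["session_noise_sd"] = np.maximum(cols["session_noise_sd"], 0.0)
    cols["overall_noise_sd"] = np.maximum(cols["overall_noise_sd"], 0.0)

    trng = _stream(config.rng_seed, _T_TRAITS)
    profiles = []
    for i in range(n):
        group = "rate" if i < config.n_rate else "view"
        pid = f"P{i:03d}"
        sources = {
            "mean_bias": cols["mean_bias"][i],
            "w_shared_centered": cols["w_shared"][i] - 0.5,
            "log_tau": float(np.log(cols["tau_integration"][i])),
            "affinity_dance": aff_d[i],
            "affinity_landscape": aff_l[i],
        }
        traits = {
            name: (0.0 if src is None else loading * sources[src])
            + trng.normal(0.0, noise_sd)
            for name, (src, loading, noise_sd) in TRAIT_MODEL.items()
        }
        profiles.append(ParticipantProfile(
            participant_id=pid, group=group,
            w_shared=float(cols["w_shared"][i]),
            tau_integration=float(cols["tau_integration"][i]),
            dead_zone=float(cols["dead_zone"][i]),
            session_noise_sd=float(cols["session_noise_sd"][i]),
            overall_noise_sd=float(cols["overall_noise_sd"][i]),
            mean_bias=float(cols["mean_bias"][i]),
            affinity_dance=float(aff_d[i]),
            affinity_landscape=float(aff_l[i]),
            trait_scores=traits,
        ))
    return profiles


def _sample_stimuli(config: SimulationConfig) -> list[StimulusProfile]:
    rng = _stream(config.rng_seed, _T_STIMULI)
    profiles = []
    half = config.category_shift / 2.0
    for cat, n_cat, prefix, shift in (
        ("dance", config.n_dance, "D", -half),
        ("landscape", config.n_landscape, "L", +half),
    ):
        levels = rng.normal(0.0, config.stim_level_sd, n_cat)
        for j in range(n_cat):
            profiles.append(StimulusProfile(
                stimulus_id=f"{prefix}{j:02d}", category=cat,
                mean_level=float(levels[j]),
                length_scale_s=config.latent_length_scale_s,
                amplitude=config.latent_amplitude,
                category_mean_shift=shift,
            ))
    return profiles


def has_continuous_rating(group: str, session: str) -> bool:
    """Design rule: the view group gives no continuous ratings at test."""
    return not (group == "view" and session == "test")


def simulate_experiment(config: SimulationConfig | None = None):
    """Simulate a full experiment and return a :class:`~aesthdyn.dataset.Dataset`.

    Continuous event logs exist for rate x {test, retest} and view x {retest}
    only; overall ratings exist for every (participant, stimulus, session).
    """
    from .dataset import Dataset  # local import to avoid a cycle

    config = config or SimulationConfig()
    participants = _sample_participants(config)
    stimuli = _sample_stimuli(config)
    seed = config.rng_seed

    ev_rows: list[pd.DataFrame] = []
    ov_rows: list[dict] = []
    for p in participants:
        pkey = _id_key(p.participant_id)
        for v in stimuli:
            vkey = _id_key(v.stimulus_id)
            for s_idx, session in enumerate(SESSIONS):
                latent = generate_latent_trace(p, v, session, config, seed)
                orng = _stream(seed, _T_OVERALL, pkey, vkey, s_idx)
                rating = float(np.clip(
                    latent.mean() + orng.normal(0.0, p.overall_noise_sd),
                    -1.0, 1.0))
                ov_rows.append({
                    "participant_id": p.participant_id, "group": p.group,
                    "session": session, "category": v.category,
                    "stimulus_id": v.stimulus_id, "rating": rating,
                })
                if has_continuous_rating(p.group, session):
                    log = simulate_dial_events(
                        latent, p, config.sample_rate_hz,
                        trial_keys={"session": session,
                                    "category": v.category,
                                    "stimulus_id": v.stimulus_id})
                    ev_rows.append(pd.DataFrame({
                        "participant_id": log.participant_id,
                        "group": log.group, "session": log.session,
                        "category": log.category,
                        "stimulus_id": log.stimulus_id,
                        "t_sec": log.t_sec, "position": log.position,
                    }))

    events = (pd.concat(ev_rows, ignore_index=True) if ev_rows
              else pd.DataFrame(columns=["participant_id", "group", "session",
                                         "category", "stimulus_id", "t_sec",
                                         "position"]))
    overall = pd.DataFrame(ov_rows)
    participants_df = pd.DataFrame([
        {
            "participant_id": p.participant_id, "group": p.group,
            "w_shared": p.w_shared, "tau_integration": p.tau_integration,
            "dead_zone": p.dead_zone, "session_noise_sd": p.session_noise_sd,
            "overall_noise_sd": p.overall_noise_sd, "mean_bias": p.mean_bias,
            "affinity_dance": p.affinity_dance,
            "affinity_landscape": p.affinity_landscape,
            **{f"trait_{k}": v for k, v in p.trait_scores.items()},
        }
        for p in participants
    ])
    stimuli_df = pd.DataFrame([
        {
            "stimulus_id": v.stimulus_id, "category": v.category,
            "mean_level": v.mean_level, "length_scale_s": v.length_scale_s,
            "amplitude": v.amplitude,
            "category_mean_shift": v.category_mean_shift,
        }
        for v in stimuli
    ])
    return Dataset(events=events, overall=overall,
                   participants=participants_df, stimuli=stimuli_df,
                   config=config)
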