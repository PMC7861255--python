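"""Messages and agent populations.

Messages are two-component stimuli ``(affective, cognitive)`` drawn from four
fixed archetypes.  Agents carry latent affective/cognitive attitudes toward
the message topic and two behavioural thresholds: a *noticing* threshold (how
much affective stimulation it takes to attend to a message at all) and a
*posting* threshold (how strong the combined dual-process evaluation must be
before the agent forwards).  Two agent models are supported:

``random``
    all four latent fields are independent ``U(0, 1)`` draws;
``personality``
    thresholds derive from Big Five traits sampled from a correlated
    multivariate normal and squashed onto ``(0, 1)`` with
    ``(tanh(x) + 1) / 2``.  Openness lowers the noticing threshold,
    conscientiousness raises the posting threshold, and extraversion is used
    downstream when placing agents on network nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTENT_TYPES",
    "TRAIT_NAMES",
    "Agent",
    "Message",
    "NotPositiveDefiniteError",
    "PersonalityProfile",
    "UnknownContentError",
    "agents_from_csv",
    "agents_to_csv",
    "big_five_correlation",
    "make_message",
    "make_personality_agent",
    "make_population",
    "make_random_agent",
    "sample_personalities",
    "sample_trait_normals",
    "squash",
]


class UnknownContentError(ValueError):
    """Raised when a message label is not one of the four archetypes."""


class NotPositiveDefiniteError(ValueError):
    """Raised when a trait correlation matrix admits no Cholesky factor."""


#: Canonical trait order used throughout the package (OCEAN).
TRAIT_NAMES = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)

#: The four content archetypes: label -> (affective, cognitive) stimulus.
CONTENT_TYPES = {
    "affective": (0.8, 0.2),
    "cognitive": (0.2, 0.8),
    "both": (0.8, 0.8),
    "weak": (0.2, 0.2),
}


@dataclass(frozen=True)
class Message:
    """A stimulus with an affective and a cognitive component, both in [0, 1]."""

    affective: float
    cognitive: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.affective <= 1.0 and 0.0 <= self.cognitive <= 1.0):
            raise ValueError("message stimulus values must lie in [0, 1]")


@dataclass(frozen=True)
class PersonalityProfile:
    """Big Five trait scores, each squashed onto the open unit interval."""

    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.openness,
            self.conscientiousness,
            self.extraversion,
            self.agreeableness,
            self.neuroticism,
        )


@dataclass
class Agent:
    """One simulated social-network user.

    Attitudes are mutable (forwarding a message pulls them toward the message
    values); thresholds are fixed for the agent's lifetime.
    """

    id: int
    a_affective: float
    a_cognitive: float
    t_noticing: float
    t_posting: float
    profile: Optional[PersonalityProfile] = None


def make_message(label: str) -> Message:
    """Return the fixed message archetype for ``label``.

    The four archetypes are ``affective`` (0.8, 0.2), ``cognitive``
    (0.2, 0.8), ``both`` (0.8, 0.8) and ``weak`` (0.2, 0.2).
    """
    try:
        affective, cognitive = CONTENT_TYPES[label]
    except KeyError:
        raise UnknownContentError(
            f"unknown content type {label!r}; expected one of {sorted(CONTENT_TYPES)}"
        ) from None
    return Message(affective=affective, cognitive=cognitive, label=label)


def squash(x):
    """Map a real value onto (0, 1) via ``(tanh(x) + 1) / 2``.

    Strictly increasing and bijective onto the open unit interval.  Accepts
    scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("squash requires finite input")
    out = (np.tanh(arr) + 1.0) / 2.0
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def big_five_correlation() -> np.ndarray:
    """The default 5x5 Big Five trait correlation matrix.

    Rows/columns follow :data:`TRAIT_NAMES`.  Off-diagonal values are the
    published pairwise trait correlations (e.g. openness-extraversion 0.41).
    """
    o, c, e, a, n = range(5)
    m = np.eye(5)

    def put(i: int, j: int, r: float) -> None:
        m[i, j] = m[j, i] = r

    put(o, c, 0.24)
    put(o, e, 0.41)
    put(o, a, 0.22)
    put(o, n, -0.09)
    put(c, e, 0.15)
    put(c, a, 0.27)
    put(c, n, -0.20)
    put(e, a, 0.35)
    put(e, n, -0.24)
    put(a, n, -0.05)
    return m


def _cholesky(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
        raise NotPositiveDefiniteError("correlation matrix must be symmetric 5x5")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            "correlation matrix is not positive definite"
        ) from None


def sample_trait_normals(
    n: int, corr: Optional[np.ndarray] = None, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw ``n`` pre-squash trait vectors from N(0, corr) via Cholesky.

    Returns an ``(n, 5)`` array in :data:`TRAIT_NAMES` order.  These are the
    raw correlated normals; :func:`sample_personalities` squashes them onto
    the unit interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if corr is None:
        corr = big_five_correlation()
    rng = np.random.default_rng(rng)
    chol = _cholesky(corr)
    z = rng.standard_normal((n, 5))
    return z @ chol.T


def sample_personalities(
    n: int, corr: Optional[np.ndarray] = None, rng: Optional[np.random.Generator] = None
) -> list[PersonalityProfile]:
    """Sample ``n`` Big Five profiles with the given trait correlation."""
    raw = sample_trait_normals(n, corr=corr, rng=rng)
    squashed = (np.tanh(raw) + 1.0) / 2.0
    return [PersonalityProfile(*(float(v) for v in row)) for row in squashed]


def _draw_attitude(rng: np.random.Generator, attitude_dist: str) -> float:
    if attitude_dist == "uniform":
        return float(rng.random())
    if attitude_dist == "squashed_normal":
        return squash(float(rng.standard_normal()))
    raise ValueError(
        f"unknown attitude_dist {attitude_dist!r}; "
        "expected 'uniform' or 'squashed_normal'"
    )


def make_random_agent(
    id: int, rng: np.random.Generator, attitude_dist: str = "uniform"
) -> Agent:
    """An agent whose attitudes and thresholds are all independent U(0, 1)."""
    return Agent(
        id=id,
        a_affective=_draw_attitude(rng, attitude_dist),
        a_cognitive=_draw_attitude(rng, attitude_dist),
        t_noticing=float(rng.random()),
        t_posting=float(rng.random()),
    )


def make_personality_agent(
    id: int,
    profile: PersonalityProfile,
    rng: np.random.Generator,
    attitude_dist: str = "uniform",
) -> Agent:
    """An agent whose thresholds derive from its Big Five profile.

    The noticing threshold is the mean of a fresh U(0, 1) draw and
    ``1 - openness`` (more open agents notice more easily); the posting
    threshold is the mean of an independent U(0, 1) draw and
    conscientiousness (more conscientious agents post less readily).
    Attitudes are drawn exactly as for random agents.
    """
    a_aff = _draw_attitude(rng, attitude_dist)
    a_cog = _draw_attitude(rng, attitude_dist)
    t_noticing = (float(rng.random()) + (1.0 - profile.openness)) / 2.0
    t_posting = (float(rng.random()) + profile.conscientiousness) / 2.0
    return Agent(
        id=id,
        a_affective=a_aff,
        a_cognitive=a_cog,
        t_noticing=t_noticing,
        t_posting=t_posting,
        profile=profile,
    )


def make_population(
    n: int,
    agent_model: str,
    rng: np.random.Generator,
    corr: Optional[np.ndarray] = None,
    attitude_dist: str = "uniform",
) -> list[Agent]:
    """Construct ``n`` agents under the ``random`` or ``personality`` model."""
    if agent_model == "random":
        return [make_random_agent(i, rng, attitude_dist) for i in range(n)]
    if agent_model == "personality":
        profiles = sample_personalities(n, corr=corr, rng=rng)
        return [
            make_personality_agent(i, p, rng, attitude_dist)
            for i, p in enumerate(profiles)
        ]
    raise ValueError(
        f"unknown agent_model {agent_model!r}; expected 'random' or 'personality'"
    )


def agents_to_csv(agents: Sequence[Agent], path) -> None:
    """Dump a population to CSV (traits are NA for random agents)."""
    rows = []
    for ag in agents:
        row = {
            "id": ag.id,
            "a_affective": ag.a_affective,
            "a_cognitive": ag.a_cognitive,
            "t_noticing": ag.t_noticing,
            "t_posting": ag.t_posting,
        }
        for name in TRAIT_NAMES:
            row[name] = getattr(ag.profile, name) if ag.profile is not None else math.nan
        rows.append(row)
    # %.17g keeps the round trip lossless for float64
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def agents_from_csv(path) -> list[Agent]:
    """Reload a population written by :func:`agents_to_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "a_affective", "a_cognitive", "t_noticing", "t_posting"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"agent CSV is missing columns: {sorted(missing)}")
    agents = []
    for _, row in df.iterrows():
        profile = None
        if all(name in df.columns for name in TRAIT_NAMES) and not math.isnan(
            row["openness"]
        ):
            profile = PersonalityProfile(*(float(row[t]) for t in TRAIT_NAMES))
        agents.append(
            Agent(
                id=int(row["id"]),
                a_affective=float(row["a_affective"]),
                a_cognitive=float(row["a_cognitive"]),
                t_noticing=float(row["t_noticing"]),
                t_posting=float(row["t_posting"]),
                profile=profile,
            )
        )
    return agents
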