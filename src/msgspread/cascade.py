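"""The cascade engine: noticing, dual-process evaluation, synchronous forwarding.

A cascade starts from a forced seed node (the "opinion leader") that sends
the message unconditionally.  Each step, every pending sender delivers the
message to all its neighbours simultaneously and retires; an unaware
recipient first checks whether the message's affective stimulus exceeds its
noticing threshold, then — if noticed — compares the dual-process evaluation

    score = sqrt( (m_aff + a_aff)/2 * (m_cog + a_cog)/2 )

against its posting threshold.  Forwarders adapt their attitudes toward the
message and become the next step's senders.  Agents never send twice and
never change their mind, so the cascade terminates in at most ``n`` steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import networkx as nx

from msgspread.population import Agent, Message

__all__ = [
    "AgentState",
    "CascadeState",
    "Trajectory",
    "adapt_attitude",
    "decides_to_forward",
    "forwarding_score",
    "init_cascade",
    "notices",
    "run_cascade",
    "step",
]


class AgentState(Enum):
    UNAWARE = "unaware"
    RECEIVED_IGNORED = "received_ignored"
    RECEIVED_DECLINED = "received_declined"
    PENDING_SEND = "pending_send"
    SENT = "sent"


#: States in which an agent has received the message.
_RECEIVED_STATES = frozenset(
    {
        AgentState.RECEIVED_IGNORED,
        AgentState.RECEIVED_DECLINED,
        AgentState.PENDING_SEND,
        AgentState.SENT,
    }
)


def notices(msg: Message, agent: Agent) -> bool:
    """True iff the message's affective stimulus exceeds the noticing threshold."""
    return msg.affective > agent.t_noticing


def forwarding_score(msg: Message, agent: Agent) -> float:
    """Geometric mean of the affective and cognitive process values.

    Each process value is the mean of message stimulus and agent attitude,
    so a strong activation on *both* channels is needed for a high score.
    """
    affective = (msg.affective + agent.a_affective) / 2.0
    cognitive = (msg.cognitive + agent.a_cognitive) / 2.0
    return math.sqrt(affective * cognitive)


def decides_to_forward(msg: Message, agent: Agent) -> bool:
    """True iff the dual-process score exceeds the posting threshold."""
    return forwarding_score(msg, agent) > agent.t_posting


def adapt_attitude(agent: Agent, msg: Message, strategy: str = "average") -> Agent:
    """Update a forwarding agent's attitudes in place and return it.

    ``average`` (default) moves each attitude to the midpoint of its old
    value and the message value; ``overwrite`` adopts the message values;
    ``none`` leaves attitudes untouched.  Because forwarders never evaluate
    again, the choice cannot alter the cascade — it only changes the
    population's post-hoc attitude distribution.
    """
    if strategy == "average":
        agent.a_affective = (agent.a_affective + msg.affective) / 2.0
        agent.a_cognitive = (agent.a_cognitive + msg.cognitive) / 2.0
    elif strategy == "overwrite":
        agent.a_affective = msg.affective
        agent.a_cognitive = msg.cognitive
    elif strategy != "none":
        raise ValueError(f"unknown adaptation strategy {strategy!r}")
    return agent


@dataclass
class Trajectory:
    """Cumulative per-step counts for one cascade run.

    Entry ``k`` of each series is the cumulative count after step ``k``
    (step 0 is the seeding).  ``completed`` is False only if the safety cap
    interrupted the run, which cannot happen under the one-send-per-agent
    rule.
    """

    n_agents: int
    received: list[int] = field(default_factory=list)
    noticed: list[int] = field(default_factory=list)
    forwarded: list[int] = field(default_factory=list)
    completed: bool = True

    @property
    def n_steps(self) -> int:
        return len(self.forwarded) - 1

    @property
    def final_received(self) -> int:
        return self.received[-1]

    @property
    def final_noticed(self) -> int:
        return self.noticed[-1]

    @property
    def final_forwarded(self) -> int:
        return self.forwarded[-1]

    @property
    def frac_received(self) -> float:
        return self.final_received / self.n_agents

    @property
    def frac_noticed(self) -> float:
        return self.final_noticed / self.n_agents

    @property
    def frac_forwarded(self) -> float:
        """Fraction of *all* agents that forwarded."""
        return self.final_forwarded / self.n_agents

    @property
    def frac_forwarded_among_received(self) -> float:
        """Fraction of agents that forwarded among those that received."""
        return self.final_forwarded / self.final_received


@dataclass
class CascadeState:
    graph: nx.Graph
    placement: dict[int, Agent]
    msg: Message
    states: dict[int, AgentState]
    active: set[int]
    step_no: int
    trajectory: Trajectory
    adaptation: str = "average"
    evaluation: str = "first_receipt"

    @property
    def done(self) -> bool:
        return not self.active


def init_cascade(
    g: nx.Graph,
    placement: dict[int, Agent],
    msg: Message,
    seed: int,
    adaptation: str = "average",
    evaluation: str = "first_receipt",
) -> CascadeState:
    """Start a cascade with ``seed`` as unconditional sender.

    The seed bypasses its own noticing/posting checks (it introduces the
    content) and is counted in all three cumulative series.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot seed a cascade in an empty graph")
    if seed not in g:
        raise ValueError(f"seed node {seed} is not in the graph")
    if evaluation not in ("first_receipt", "every_receipt"):
        raise ValueError(f"unknown evaluation policy {evaluation!r}")
    states = {node: AgentState.UNAWARE for node in g.nodes()}
    states[seed] = AgentState.PENDING_SEND
    trajectory = Trajectory(n_agents=g.number_of_nodes())
    trajectory.received.append(1)
    trajectory.noticed.append(1)
    trajectory.forwarded.append(1)
    return CascadeState(
        graph=g,
        placement=placement,
        msg=msg,
        states=states,
        active={seed},
        step_no=0,
        trajectory=trajectory,
        adaptation=adaptation,
        evaluation=evaluation,
    )


def _evaluate(state: CascadeState, node: int) -> AgentState:
    agent = state.placement[node]
    if not notices(state.msg, agent):
        return AgentState.RECEIVED_IGNORED
    if not decides_to_forward(state.msg, agent):
        return AgentState.RECEIVED_DECLINED
    adapt_attitude(agent, state.msg, state.adaptation)
    return AgentState.PENDING_SEND


def step(state: CascadeState, msg: Optional[Message] = None) -> CascadeState:
    """Advance the cascade by one synchronous generation (in place).

    All active senders deliver simultaneously; simultaneous deliveries to one
    agent count as a single receipt.  Under the default ``first_receipt``
    policy only unaware recipients evaluate; ``every_receipt`` re-evaluates
    previously declining agents on each new delivery (provably equivalent,
    since no decision input changes after the first evaluation).
    """
    if msg is not None and msg != state.msg:
        raise ValueError("cascades carry a single immutable message")
    if not state.active:
        raise ValueError("cascade has terminated: no active senders")

    recipients: set[int] = set()
    for sender in state.active:
        recipients.update(state.graph.neighbors(sender))
        state.states[sender] = AgentState.SENT
    state.active = set()

    if state.evaluation == "first_receipt":
        eligible = [v for v in recipients if state.states[v] is AgentState.UNAWARE]
    else:
        eligible = [
            v
            for v in recipients
            if state.states[v]
            in (
                AgentState.UNAWARE,
                AgentState.RECEIVED_IGNORED,
                AgentState.RECEIVED_DECLINED,
            )
        ]

    traj = state.trajectory
    new_received = new_noticed = new_forwarded = 0
    for node in sorted(eligible):
        was_unaware = state.states[node] is AgentState.UNAWARE
        outcome = _evaluate(state, node)
        if was_unaware:
            new_received += 1
            if outcome is not AgentState.RECEIVED_IGNORED:
                new_noticed += 1
        if outcome is AgentState.PENDING_SEND:
            if not was_unaware and state.states[node] is AgentState.RECEIVED_IGNORED:
                new_noticed += 1  # unreachable under fixed inputs; kept for safety
            new_forwarded += 1
            state.active.add(node)
        state.states[node] = outcome

    state.step_no += 1
    traj.received.append(traj.received[-1] + new_received)
    traj.noticed.append(traj.noticed[-1] + new_noticed)
    traj.forwarded.append(traj.forwarded[-1] + new_forwarded)
    return state


def run_cascade(
    g: nx.Graph,
    placement: dict[int, Agent],
    msg: Message,
    seed: int,
    max_steps: Optional[int] = None,
    adaptation: str = "average",
    evaluation: str = "first_receipt",
) -> Trajectory:
    """Run a cascade to termination and return its trajectory.

    ``max_steps`` is a safety cap (default: the number of agents, which the
    one-send-per-agent rule can never exceed); if it ever triggers,
    ``Trajectory.completed`` is False.
    """
    if max_steps is None:
        max_steps = g.number_of_nodes()
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = init_cascade(g, placement, msg, seed, adaptation, evaluation)
    while state.active:
        if state.step_no >= max_steps:
            state.trajectory.completed = False
            break
        step(state)
    return state.trajectory
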