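"""Markov state space for the CVD secondary-prevention model.

The model tracks five acute cardiovascular events (ischaemic stroke,
myocardial infarction, unstable angina, elective coronary
revascularisation, and peripheral artery disease / non-coronary
revascularisation), each with an event-year ("acute") phase and a chronic
("post") phase, plus an absorbing dead state.  Transient ischaemic attack
is handled as a cost-only event and has no alive state.

Severity ranking (1 = worst) follows the utility-based ordering used for
post-state resolution: when a person with a CVD history experiences a new
event, they end up in the post state of the *more severe* of the two.
Because a cohort Markov chain is memoryless, the acute phase is
represented internally by tunnel states keyed by ``(event, return_post)``:
the event being experienced and the post state the cohort resolves to
afterwards.  Reporting aggregates tunnels back to one acute state per
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Canonical event ordering (by severity rank, 1 = worst).
ISCHAEMIC_STROKE = "ischaemic_stroke"
MI = "mi"
UNSTABLE_ANGINA = "unstable_angina"
ELECTIVE_REVASC = "elective_revasc"
PAD = "pad"
TIA = "tia"  # cost-only, no alive state
DEAD = "dead"

EVENTS: tuple[str, ...] = (ISCHAEMIC_STROKE, MI, UNSTABLE_ANGINA, ELECTIVE_REVASC, PAD)

SEVERITY_RANK: dict[str, int] = {
    ISCHAEMIC_STROKE: 1,
    MI: 2,
    UNSTABLE_ANGINA: 3,
    ELECTIVE_REVASC: 4,
    PAD: 5,
}

RANK_TO_EVENT: dict[int, str] = {r: e for e, r in SEVERITY_RANK.items()}


class ConfigurationError(ValueError):
    """Raised for invalid model configuration."""


def post_state(event: str) -> str:
    if event not in EVENTS:
        raise ConfigurationError(f"unknown event type: {event!r}")
    return f"post_{event}"


def event_of_post(state: str) -> str:
    if not state.startswith("post_"):
        raise ConfigurationError(f"not a post state: {state!r}")
    event = state[len("post_"):]
    if event not in EVENTS:
        raise ConfigurationError(f"unknown event type: {event!r}")
    return event


def resolve_post_state(current_post: str, new_event: str) -> str:
    """Destination post state after a new event on top of an existing history.

    The cohort keeps the post state of the more severe condition (lower
    severity rank): a new, less severe event returns people to the post
    state of their earlier, worse event.
    """
    prior = event_of_post(current_post)
    if new_event not in EVENTS:
        raise ConfigurationError(f"unknown event type: {new_event!r}")
    worst = min((SEVERITY_RANK[prior], prior), (SEVERITY_RANK[new_event], new_event))[1]
    return post_state(worst)


@dataclass(frozen=True)
class StateSpace:
    """Indexed state space: post states, acute tunnel states, dead.

    Acute tunnels ``acute_<event>__<return>`` exist for every pair where
    the return event is at least as severe as the event being experienced
    (the only reachable combinations under severity resolution).
    """

    posts: tuple[str, ...] = field(default_factory=tuple)
    acutes: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @classmethod
    def default(cls) -> "StateSpace":
        posts = tuple(post_state(e) for e in EVENTS)
        acutes = []
        for e in EVENTS:
            for r in EVENTS:
                if SEVERITY_RANK[r] <= SEVERITY_RANK[e]:
                    acutes.append((e, r))
        return cls(posts=posts, acutes=tuple(acutes))

    # -- naming ---------------------------------------------------------
    @staticmethod
    def acute_name(event: str, return_event: str) -> str:
        return f"acute_{event}__{return_event}"

    @property
    def names(self) -> tuple[str, ...]:
        return self.posts + tuple(self.acute_name(e, r) for e, r in self.acutes) + (DEAD,)

    @property
    def n_states(self) -> int:
        return len(self.posts) + len(self.acutes) + 1

    @property
    def dead_index(self) -> int:
        return self.n_states - 1

    def index(self, name: str) -> int:
        return self.names.index(name)

    def post_index(self, event: str) -> int:
        return self.posts.index(post_state(event))

    def acute_index(self, event: str, return_event: str) -> int:
        return len(self.posts) + self.acutes.index((event, return_event))

    def acute_indices_of_event(self, event: str) -> list[int]:
        """All tunnel states in which ``event`` is the acute event."""
        return [len(self.posts) + i for i, (e, _r) in enumerate(self.acutes) if e == event]

    def alive_indices(self) -> list[int]:
        return list(range(self.n_states - 1))

    def resolved_event(self, state_index: int) -> str:
        """Event whose post state this alive state resolves to if no new event."""
        if state_index < len(self.posts):
            return event_of_post(self.posts[state_index])
        if state_index < self.n_states - 1:
            _e, r = self.acutes[state_index - len(self.posts)]
            return r
        raise ConfigurationError("dead state has no resolved event")

    def acute_event(self, state_index: int) -> str | None:
        """Acute event occupied in this state, or None for post states."""
        if len(self.posts) <= state_index < self.n_states - 1:
            return self.acutes[state_index - len(self.posts)][0]
        return None
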