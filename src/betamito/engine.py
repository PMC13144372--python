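"""Exact stochastic simulation (Gillespie direct method).

The kernel is model-agnostic: a model is a mutable state object with a
``t`` attribute plus a list of :class:`Rule` objects.  Each rule exposes a
propensity (may be zero when its guard fails) and an effect.  Waiting times
are exponential with rate equal to the total propensity and the firing rule
is chosen with probability proportional to its propensity — i.e. the
semantics of a continuous-time Markov chain.

Rules whose reactants are attributed compartments (mitochondria) perform
their own internal selection inside ``execute``; the kernel only deals in
per-rule aggregate propensities, which the beta-cell model keeps cheap via
incrementally maintained sums.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Protocol, Sequence

import numpy as np


class PropensityError(RuntimeError):
    """A rule produced a NaN or negative propensity."""


class Rule(Protocol):
    name: str

    def propensity(self, state: Any) -> float: ...

    def execute(self, state: Any, rng: np.random.Generator) -> Optional[dict]: ...


@dataclass
class EventRecord:
    """One rule firing: time, rule name and rule-specific detail."""
    t: float
    rule: str
    info: Optional[dict] = None

    def to_json_dict(self) -> dict:
        d = {"t": self.t, "rule": self.rule}
        if self.info:
            d.update(self.info)
        return d


@dataclass
class Trajectory:
    """Snapshots, event bookkeeping and the final state of one run."""
    seed: Optional[int] = None
    config: Any = None
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    events: Optional[list] = None           # full log only when requested
    event_counts: Counter = field(default_factory=Counter)
    # cumulative per-rule counts sampled at each snapshot time
    count_history: list = field(default_factory=list)
    t_final: float = 0.0
    absorbed: bool = False
    final_state: Any = None


class Simulator:
    """Direct-method SSA over a fixed list of rules.

    Parameters
    ----------
    rules
        Rule objects; order is fixed for the whole run.
    state
        Mutable state with attribute ``t`` (simulation time, seconds).
    rng
        Seeded ``numpy.random.Generator``; the single source of randomness.
    on_time_advance
        Optional hook ``f(state, dt)`` applied for every elapsed interval
        (also between events and snapshot times).  Used for continuous
        variables such as the Ca2+ relaxation.
    """

    def __init__(self, rules: Sequence[Rule], state: Any,
                 rng: np.random.Generator,
                 on_time_advance: Optional[Callable[[Any, float], None]] = None):
        self.rules = list(rules)
        self.state = state
        self.rng = rng
        self.on_time_advance = on_time_advance
        self._props = np.zeros(len(self.rules))

    def propensities(self) -> np.ndarray:
        """One non-negative propensity per rule; guard failures give 0."""
        for i, rule in enumerate(self.rules):
            a = rule.propensity(self.state)
            if a < 0.0 or a != a or a == float("inf"):
                raise PropensityError(
                    f"rule {rule.name!r} produced invalid propensity {a!r}")
            self._props[i] = a
        return self._props

    def _advance_clock(self, dt: float) -> None:
        if dt > 0.0:
            self.state.t += dt
            if self.on_time_advance is not None:
                self.on_time_advance(self.state, dt)

    def advance(self) -> Optional[EventRecord]:
        """Fire one event; returns None at absorption (total propensity 0)."""
        props = self.propensities()
        total = float(props.sum())
        if total <= 0.0:
            return None
        dt = self.rng.exponential(1.0 / total)
        self._advance_clock(dt)
        idx = self._pick(props, total)
        rule = self.rules[idx]
        info = rule.execute(self.state, self.rng)
        return EventRecord(self.state.t, rule.name, info)

    def _pick(self, props: np.ndarray, total: float) -> int:
        x = self.rng.random() * total
        acc = 0.0
        for i in range(len(props)):
            acc += props[i]
            if x < acc:
                return i
        return len(props) - 1  # guard against float round-off

    def run(self, t_end: float, record_interval: float,
            snapshot_fn: Callable[[Any], Any],
            record_events: bool = False) -> Trajectory:
        """Simulate until ``t_end`` (or absorption), recording snapshots.

        Snapshots are taken at 0, record_interval, 2*record_interval, ...
        and at ``t_end``; continuous variables are relaxed across snapshot
        boundaries so the recorded values are exact at the snapshot time.
        """
        traj = Trajectory(events=[] if record_events else None)
        state = self.state

        def take_snapshot():
            traj.snapshot_times.append(state.t)
            traj.snapshots.append(snapshot_fn(state))
            traj.count_history.append(dict(traj.event_counts))

        take_snapshot()
        next_rec = record_interval if record_interval > 0 else t_end
        while state.t < t_end:
            props = self.propensities()
            total = float(props.sum())
            if total <= 0.0:
                traj.absorbed = True
                break
            dt = self.rng.exponential(1.0 / total)
            t_event = state.t + dt
            # emit snapshots that fall before the event (or the horizon)
            while next_rec <= min(t_event, t_end) + 1e-12:
                self._advance_clock(next_rec - state.t)
                take_snapshot()
                next_rec += record_interval
                if record_interval <= 0:
                    break
            if t_event > t_end:
                self._advance_clock(t_end - state.t)
                break
            self._advance_clock(t_event - state.t)
            idx = self._pick(props, total)
            rule = self.rules[idx]
            info = rule.execute(state, self.rng)
            traj.event_counts[rule.name] += 1
            if record_events:
                traj.events.append(EventRecord(state.t, rule.name, info))
        if not traj.snapshot_times or traj.snapshot_times[-1] < state.t - 1e-12:
            take_snapshot()
        traj.t_final = state.t
        traj.final_state = state
        return traj
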