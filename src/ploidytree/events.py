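"""Copy-number mutation events and their probability model.

A cell state is an integer tuple ``(p, g1, ..., gn)``: the copy number of
the ploidy probe followed by the copy numbers of *n* gene probes.  A single
mutational step may change the state by one of the *allowed event types*:

* gain or loss of one copy of a single gene (ploidy unchanged),
* gain or loss of one in ploidy with every gene unchanged (chromosome
  missegregation that spares the probed genes), or
* gain or loss of one in ploidy with **all** genes moving in the same
  direction (concerted whole-genome-scale change).

For one gene probe this yields six event types; for two gene probes,
eight.  Events are represented as delta vectors in ``{-1, 0, +1}^(n+1)``
with the ploidy component first.

States are bounded: ploidy stays >= 1, gene counts stay >= 0, and all
counts are capped at the panel's ``max_copy`` (9 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .errors import ContractError, MismatchedPloidyError

Delta = Tuple[int, ...]
Pattern = Tuple[int, ...]

#: smallest probability any allowed event type may take after an update
DEFAULT_FLOOR = 1e-6


@lru_cache(maxsize=None)
def allowed_event_types(n_genes: int) -> Tuple[Delta, ...]:
    """All allowed delta vectors for ``n_genes`` gene probes, sorted
    lexicographically (deterministic order used for tie-breaking)."""
    if n_genes < 1:
        raise ContractError("need at least one gene probe")
    events = set()
    for s in (1, -1):
        events.add((s,) + (0,) * n_genes)      # pure ploidy change
        events.add((s,) * (n_genes + 1))       # concerted ploidy + all genes
        for i in range(n_genes):
            d = [0] * (n_genes + 1)
            d[i + 1] = s
            events.add(tuple(d))               # single-gene change
    return tuple(sorted(events))


def is_allowed_event(delta: Sequence[int]) -> bool:
    d = tuple(delta)
    return len(d) >= 2 and d in allowed_event_types(len(d) - 1)


def _max_copy(panel) -> int:
    # accept either a ProbePanel-like object or a bare integer cap
    return getattr(panel, "max_copy", panel)


def in_bounds(state: Sequence[int], panel) -> bool:
    cap = _max_copy(panel)
    return (
        1 <= state[0] <= cap
        and all(0 <= g <= cap for g in state[1:])
    )


def allowed_transitions(state: Pattern, panel) -> List[Tuple[Pattern, Delta]]:
    """In-bound successors of ``state`` under the allowed event types.

    Returned in lexicographic order of the delta vector.
    """
    out = []
    for delta in allowed_event_types(len(state) - 1):
        succ = tuple(s + d for s, d in zip(state, delta))
        if in_bounds(succ, panel):
            out.append((succ, delta))
    return out


def event_of_edge(parent: Pattern, child: Pattern) -> Delta | None:
    """The allowed event taking ``parent`` to ``child``, or None."""
    if len(parent) != len(child):
        raise ContractError("patterns have different lengths")
    delta = tuple(c - p for p, c in zip(parent, child))
    return delta if is_allowed_event(delta) else None


def decompose_edge(parent: Pattern, child: Pattern) -> Tuple[Delta, ...]:
    """Express an arbitrary copy-number change as a sequence of allowed
    event types.

    If the raw delta is itself allowed it is returned alone.  If ploidy
    changes by one while the genes move inconsistently, the change is read
    as the concerted ploidy event in the ploidy's direction followed by the
    minimal single-gene corrections.  A raw delta of e.g. ``(1, 1, 0)``
    therefore decomposes to ``(1, 1, 1)`` then ``(0, 0, -1)``.  If ploidy
    does not change, the gene changes decompose into unit single-gene
    steps.

    Raises
    ------
    MismatchedPloidyError
        If the endpoints differ in ploidy by two or more; such edges are
        ignored by tally routines.
    """
    if len(parent) != len(child):
        raise ContractError("patterns have different lengths")
    delta = tuple(c - p for p, c in zip(parent, child))
    if all(d == 0 for d in delta):
        raise ContractError("parent and child are identical")
    if abs(delta[0]) >= 2:
        raise MismatchedPloidyError(
            f"ploidy jump of {delta[0]} between {parent} and {child}"
        )
    if is_allowed_event(delta):
        return (delta,)
    n = len(delta) - 1
    parts: List[Delta] = []
    if delta[0] != 0:
        s = delta[0]
        parts.append((s,) * (n + 1))
        residual = [d - s for d in delta[1:]]
    else:
        residual = list(delta[1:])
    for i, r in enumerate(residual):
        if r == 0:
            continue
        step = 1 if r > 0 else -1
        unit = [0] * (n + 1)
        unit[i + 1] = step
        for _ in range(abs(r)):
            parts.append(tuple(unit))
    return tuple(parts)


@dataclass
class MutationFrequencies:
    """A probability distribution over event types.

    Houses both the EM-estimated event probabilities and realized
    (simulated) event distributions.  ``from_tallies`` applies a small
    probability floor so that every allowed type keeps strictly positive
    probability and ``-log p`` edge weights stay finite.
    """

    probs: Dict[Delta, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if self.probs and not math.isclose(total, 1.0, abs_tol=1e-7):
            raise ContractError(f"probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise ContractError("negative probability")

    # -- constructors -------------------------------------------------
    @classmethod
    def uniform(cls, event_types: Iterable[Delta]) -> "MutationFrequencies":
        evs = list(event_types)
        return cls({ev: 1.0 / len(evs) for ev in evs})

    @classmethod
    def from_tallies(
        cls,
        tallies: Mapping[Delta, float],
        event_types: Iterable[Delta],
        floor: float = DEFAULT_FLOOR,
    ) -> "MutationFrequencies":
        """Normalize nonnegative tallies into a floored distribution.

        Types below the floor are pinned exactly at ``floor`` and the
        remaining mass is distributed proportionally over the rest.
        """
        evs = list(event_types)
        total = float(sum(max(tallies.get(ev, 0.0), 0.0) for ev in evs))
        if total <= 0:
            return cls.uniform(evs)
        raw = {ev: max(tallies.get(ev, 0.0), 0.0) / total for ev in evs}
        if floor <= 0:
            return cls(raw)
        if floor * len(evs) >= 1.0:
            raise ContractError("floor too large for the event set")
        low = [ev for ev in evs if raw[ev] < floor]
        high_mass = sum(raw[ev] for ev in evs if raw[ev] >= floor)
        while True:
            scale = (1.0 - floor * len(low)) / high_mass
            # scaling may push further types below the floor; iterate
            newly_low = [
                ev for ev in evs
                if ev not in low and raw[ev] * scale < floor
            ]
            if not newly_low:
                break
            low.extend(newly_low)
            high_mass -= sum(raw[ev] for ev in newly_low)
        probs = {
            ev: floor if ev in low else raw[ev] * scale for ev in evs
        }
        return cls(probs)

    # -- queries ------------------------------------------------------
    def prob(self, ev: Delta) -> float:
        try:
            return self.probs[tuple(ev)]
        except KeyError:
            raise ContractError(f"unknown event type {ev}") from None

    def weight(self, ev: Delta) -> float:
        """Minimization edge weight ``-log p`` of an event."""
        p = self.prob(ev)
        if p <= 0:
            raise ContractError(f"event {ev} has zero probability")
        return -math.log(p)

    def support(self) -> Tuple[Delta, ...]:
        return tuple(sorted(self.probs))

    def max_abs_diff(self, other: "MutationFrequencies") -> float:
        keys = set(self.probs) | set(other.probs)
        return max(
            abs(self.probs.get(k, 0.0) - other.probs.get(k, 0.0))
            for k in keys
        )

    def tv_distance(self, other: "MutationFrequencies") -> float:
        keys = set(self.probs) | set(other.probs)
        return 0.5 * sum(
            abs(self.probs.get(k, 0.0) - other.probs.get(k, 0.0))
            for k in keys
        )

    def copy(self) -> "MutationFrequencies":
        return MutationFrequencies(dict(self.probs))


def edge_weight(ev: Delta, freqs: MutationFrequencies) -> float:
    """``-log p`` of an event under ``freqs`` (always finite thanks to the
    probability floor)."""
    return freqs.weight(ev)
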