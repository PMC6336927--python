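"""Object behaviors as high-order sequences of displacement codes.

A behavior — a stapler opening, a lid rotating — changes an object's
morphology but not its identity.  It is represented as an ordered sequence of
displacement keys: the component's placement steps through the sequence as
the behavior unfolds.  Opening and closing are built from the same elements
in reverse order, so first-order transitions are ambiguous; prediction must
be *high-order*, conditioning on enough preceding context to disambiguate.

The sequence memory here is a variable-order suffix model: every suffix of
length 1..max_order observed before a symbol maps to the set of symbols that
followed it, and prediction uses the longest matching suffix.  This keeps the
high-order prediction contract exact and testable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

from .displacement import DisplacementKey
from .grid_modules import Phase
from .location_codes import ModuleSet
from .object_models import ObjectLibrary

__all__ = [
    "BehaviorSequence",
    "SequenceModel",
    "learn_sequence",
    "predict",
    "recall",
    "apply_behavior",
]

Symbol = Hashable


@dataclass(frozen=True)
class BehaviorSequence:
    """An identified behavior: at least two displacement-key steps, all
    conforming to one module set."""

    id: str
    steps: tuple[DisplacementKey, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValueError("a behavior needs at least 2 steps")
        object.__setattr__(self, "steps", tuple(self.steps))


@dataclass
class SequenceModel:
    """Variable-order sequence memory over hashable symbols.

    ``contexts`` maps each observed suffix (length 1..max_order) to the set
    of symbols seen immediately after it; prediction by longest matching
    suffix is deterministic given the stored map.
    """

    max_order: int = 3
    contexts: dict[tuple[Symbol, ...], set[Symbol]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")


def learn_sequence(model: SequenceModel, seq: Sequence[Symbol]) -> None:
    """Record every (suffix -> next symbol) pair of the sequence.

    For each position i >= 1 and each suffix length L = 1..min(i, max_order),
    the suffix seq[i-L:i] gains seq[i] as an observed successor.  Learning
    the same sequence again changes nothing.
    """
    if len(seq) < 2:
        raise ValueError("sequences must have at least 2 symbols")
    seq = list(seq)
    for i in range(1, len(seq)):
        for L in range(1, min(i, model.max_order) + 1):
            suffix = tuple(seq[i - L:i])
            model.contexts.setdefault(suffix, set()).add(seq[i])


def predict(model: SequenceModel, recent: Sequence[Symbol]) -> set[Symbol]:
    """Next-symbol set under the longest stored suffix of ``recent``.

    Empty set when no suffix (up to max_order) has ever been observed.
    """
    if len(recent) < 1:
        raise ValueError("recent context must be non-empty")
    recent = list(recent)
    for L in range(min(len(recent), model.max_order), 0, -1):
        suffix = tuple(recent[-L:])
        if suffix in model.contexts:
            return set(model.contexts[suffix])
    return set()


def recall(model: SequenceModel, seed: Sequence[Symbol], max_len: int) -> list[Symbol]:
    """Replay a behavior from a seed: extend while the prediction is unique.

    Stops on ambiguity (more than one continuation), on a dead end (none), or
    at ``max_len`` symbols.
    """
    if len(seed) < 1:
        raise ValueError("seed must be non-empty")
    out = list(seed)
    while len(out) < max_len:
        nxt = predict(model, out)
        if len(nxt) != 1:
            break
        out.append(next(iter(nxt)))
    return out


def apply_behavior(
    lib: ObjectLibrary,
    parent_id: str,
    component_index: int,
    behavior: BehaviorSequence,
    step_index: int,
    ms: ModuleSet,
) -> None:
    """Move a component through a behavior: replace its placement with the
    displacement at ``step_index`` (bin-centre phases of the stored key).

    The component's identity and frames are unchanged — only its relative
    position moves, so feature resolution through the parent reflects the
    new morphology immediately.
    """
    parent = lib[parent_id]
    if not 0 <= component_index < len(parent.components):
        raise IndexError(f"component index {component_index} out of range")
    if not 0 <= step_index < len(behavior.steps):
        raise IndexError(f"step index {step_index} out of range")
    comp = parent.components[component_index]
    key = behavior.steps[step_index]
    if len(key.cells) != len(ms):
        raise ValueError("behavior step does not conform to the module set")
    deltas = tuple(
        Phase((c.a + 0.5) / m.bins[0], (c.b + 0.5) / m.bins[1])
        for c, m in zip(key.cells, ms)
    )
    comp.placement = type(comp.placement)(
        deltas=deltas,
        frame_from=comp.placement.frame_from,
        frame_to=comp.placement.frame_to,
    )
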