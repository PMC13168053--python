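"""Qualitative comparison statements and their evaluation.

A statement compares one (variant, observable, time) readout against another,
e.g.::

    WT.MEK_pRDS at time=300 < N78G.MEK_pRDS at time=300

The binary observation is ``z = 0`` for ``<``/``<=`` (left below right) and
``z = 1`` for ``>``/``>=``.  The model's prediction is the Heaviside step
``H(delta)`` of the output difference ``delta = g(a) - g(b)`` computed on raw
(unscaled) copy numbers, with the tie convention ``H(0) = 1`` so that ties
satisfy ``>=`` and violate ``<``.  Each statement carries a scale ``s > 0``
used by the Bernoulli-logistic likelihood and a weight ``w = 1/s`` used by
the hinge penalty.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

from .network import OBSERVABLE_NAMES, VARIANTS

__all__ = [
    "Condition",
    "ComparisonProperty",
    "PropertySet",
    "PropertyError",
    "parse_property",
    "format_property",
    "evaluate_property",
    "count_satisfied",
    "read_prop_file",
    "write_prop_file",
]

_RELATIONS = ("<", ">", "<=", ">=")
_FLIP = {"<": ">=", "<=": ">", ">": "<=", ">=": "<"}


class PropertyError(ValueError):
    """Malformed or invalid property statement."""


@dataclass(frozen=True)
class Condition:
    """One side of a comparison: a readout of a variant at a time point."""

    variant: str
    observable: str
    time: float

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise PropertyError(f"unknown variant {self.variant!r}")
        if self.observable not in OBSERVABLE_NAMES:
            raise PropertyError(f"unknown observable {self.observable!r}")
        if self.time < 0:
            raise PropertyError(f"negative time {self.time}")


@dataclass(frozen=True)
class ComparisonProperty:
    """One qualitative observation with its penalty weight w = 1/s.

    ``weight`` is the stored field; the logistic noise scale is the derived
    ``scale = 1/weight``, so weight annotations round-trip exactly through
    the text format.
    """

    left: Condition
    right: Condition
    relation: str
    weight: float = 1.0
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise PropertyError(f"unknown relation {self.relation!r}")
        if not self.weight > 0:
            raise PropertyError(f"weight must be > 0, got {self.weight}")
        self.left.validate()
        self.right.validate()

    @property
    def z(self) -> int:
        """Observed outcome: 1 for '>'/'>=', 0 for '<'/'<='."""
        return 1 if self.relation in (">", ">=") else 0

    @property
    def scale(self) -> float:
        return 1.0 / self.weight

    def mirrored(self) -> "ComparisonProperty":
        """Swap sides and flip the relation (same empirical content)."""
        return replace(self, left=self.right, right=self.left,
                       relation=_FLIP[self.relation])


@dataclass
class PropertySet:
    """Ordered collection of comparison properties."""

    properties: List[ComparisonProperty]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties)

    def __getitem__(self, i: int) -> ComparisonProperty:
        return self.properties[i]

    def conditions(self) -> List[Condition]:
        out = []
        for p in self.properties:
            out.extend((p.left, p.right))
        return out

    def required_times(self) -> Dict[str, List[float]]:
        """Map variant -> sorted times needed to evaluate this set."""
        req: Dict[str, set] = {}
        for c in self.conditions():
            req.setdefault(c.variant, set()).add(c.time)
        return {v: sorted(ts) for v, ts in req.items()}


# ---------------------------------------------------------------------------
# grammar

_COND = r"(\w+)\.(\w+)\s+at\s+time=([0-9eE+.\-]+)"
_LINE = re.compile(
    rf"^\s*{_COND}\s*(<=|>=|<|>)\s*{_COND}\s*(?:weight=([0-9eE+.\-]+)\s*)?$"
)


def parse_property(line: str, scale: float = 1.0) -> ComparisonProperty:
    """Parse one statement line.

    ``scale`` is the default noise scale s (weight 1/s); a trailing
    ``weight=<w>`` annotation overrides it with s = 1/w.
    """
    m = _LINE.match(line)
    if m is None:
        raise PropertyError(f"malformed property statement: {line!r}")
    lv, lo, lt, op, rv, ro, rt, w = m.groups()
    try:
        left = Condition(lv, lo, float(lt))
        right = Condition(rv, ro, float(rt))
    except ValueError as e:  # float() failure
        raise PropertyError(f"bad number in {line!r}: {e}") from None
    weight = float(w) if w is not None else 1.0 / scale
    if w is not None and not weight > 0:
        raise PropertyError(f"weight must be > 0, got {weight}")
    return ComparisonProperty(left, right, op, weight=weight, source=line.strip())


def _fmt_number(x: float) -> str:
    """Shortest decimal form that parses back to exactly ``x``."""
    short = f"{x:g}"
    return short if float(short) == x else repr(x)


def format_property(prop: ComparisonProperty) -> str:
    """Canonical text form; re-parses to an equal structure."""
    def cond(c: Condition) -> str:
        return f"{c.variant}.{c.observable} at time={_fmt_number(c.time)}"

    text = f"{cond(prop.left)} {prop.relation} {cond(prop.right)}"
    if prop.weight != 1.0:
        text += f" weight={_fmt_number(prop.weight)}"
    return text


def read_prop_file(path, scale: float = 1.0) -> PropertySet:
    """Read a PROP file: one statement per line, '#' comments, blank lines."""
    props: List[ComparisonProperty] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                props.append(parse_property(line, scale=scale))
            except PropertyError as e:
                raise PropertyError(f"{path}:{lineno}: {e}") from None
    return PropertySet(props, provenance=str(path))


def write_prop_file(path, props: PropertySet) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for p in props:
            fh.write(format_property(p) + "\n")


# ---------------------------------------------------------------------------
# evaluation

def _lookup(trajectories: Mapping[str, "Trajectory"], c: Condition) -> float:
    try:
        traj = trajectories[c.variant]
    except KeyError:
        raise PropertyError(
            f"no trajectory for variant {c.variant!r}"
        ) from None
    return traj.at(c.observable, c.time)


def evaluate_property(
    prop: ComparisonProperty, trajectories: Mapping[str, "Trajectory"]
) -> Dict[str, object]:
    """Evaluate one property against simulated trajectories.

    Returns a record with the output difference ``delta``, the predicted
    outcome ``H(delta)`` (ties count as >=) and whether the prediction
    matches the observation.
    """
    delta = _lookup(trajectories, prop.left) - _lookup(trajectories, prop.right)
    predicted = 1 if delta >= 0 else 0
    return {
        "property": prop,
        "delta": delta,
        "predicted": predicted,
        "observed": prop.z,
        "satisfied": predicted == prop.z,
    }


def count_satisfied(
    props: PropertySet | Sequence[ComparisonProperty],
    trajectories: Mapping[str, "Trajectory"],
) -> Tuple[int, List[Dict[str, object]]]:
    """Number of satisfied statements plus the per-statement report."""
    report = [evaluate_property(p, trajectories) for p in props]
    return sum(1 for r in report if r["satisfied"]), report
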