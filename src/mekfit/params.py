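"""Parameters of the MEK-isoform ERK cascade model.

The model tracks EGFR -> SOS1 -> RAS -> RAF -> MEK1/2 -> ERK signaling with
ERK-mediated negative feedback on SOS1 and on MEK1 (Thr292).  A full parameter
set consists of 28 adjustable rate constants, 8 fixed structural quantities
(receptor/SOS1 turnover constants carried as inert values, the MEK1 fraction
and the MEK2/MEK1 activity ratio) and 10 initial copy numbers, plus three
scaling factors that map copy numbers of the wild-type model onto relative
(arbitrary-unit) measurements and one shared noise scale ``sigma``.

Units: unimolecular rate constants in s^-1, bimolecular in (molecules*s)^-1,
copy numbers in molecules per cell, scaling factors in AU per molecule.
"""

from __future__ import annotations

from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ParameterSet",
    "RATE_NAMES",
    "FIXED_NAMES",
    "INITIAL_NAMES",
    "SCALE_NAMES",
    "ADJUSTABLE_NAMES",
    "REFERENCE_PARAMS",
    "BEST_FIT_PARAMS",
    "OPTIMIZATION_BOUNDS",
    "BAYES_BOUNDS",
]

#: The 28 rate constants adjusted during maximum-likelihood fitting.
RATE_NAMES: Tuple[str, ...] = (
    "c1L", "c2", "t1", "d3", "b1", "n1", "b2", "n2", "b3", "n3", "b4", "n4",
    "a1", "i1", "a2", "i2", "p1", "u1", "p2a", "p2b", "u2", "p3", "u3",
    "p4", "u4", "b5", "n5", "u5",
)

#: Quantities held fixed in all fits (receptor/SOS1 turnover constants are
#: inert under the pre-stimulation convention; see :mod:`mekfit.simulate`).
FIXED_NAMES: Tuple[str, ...] = (
    "s1", "d1", "s2", "d2", "c1", "c1init", "MEK1_fraction", "X",
)

#: Initial copy numbers (molecules per cell).
INITIAL_NAMES: Tuple[str, ...] = (
    "EGFR0", "SOS10", "RAS0", "RAF0", "MEK_tot0", "MEK10", "MEK1_T292p0",
    "MEK20", "ERK0", "PHP_MEK0",
)

#: Scaling factors applied to wild-type outputs for quantitative comparison.
SCALE_NAMES: Tuple[str, ...] = ("ScalepEGFR", "ScalepERK", "ScalepSOS1")

#: The 31 adjustable parameters of the global fit.
ADJUSTABLE_NAMES: Tuple[str, ...] = RATE_NAMES + SCALE_NAMES

_ALL_NAMES = RATE_NAMES + FIXED_NAMES + INITIAL_NAMES + SCALE_NAMES + ("sigma",)


class ParameterSet(Mapping[str, float]):
    """Immutable named parameter vector for the cascade model.

    Behaves as a read-only mapping over the full name set (46 model
    parameters + 3 scaling factors + sigma).  Missing names take their
    literature reference values; unknown names raise ``KeyError``.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float] | None = None, **kwargs: float):
        merged: Dict[str, float] = dict(_REFERENCE_VALUES)
        for src in (values or {}), kwargs:
            for name, val in src.items():
                if name not in merged:
                    raise KeyError(f"unknown parameter {name!r}")
                merged[name] = float(val)
        for name, val in merged.items():
            if val < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {val}")
        object.__setattr__(self, "_values", merged)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(_ALL_NAMES)

    def __len__(self) -> int:
        return len(_ALL_NAMES)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ParameterSet):
            return self._values == other._values
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._values[n] for n in _ALL_NAMES))

    def __repr__(self) -> str:
        changed = {
            n: v for n, v in self._values.items() if v != _REFERENCE_VALUES[n]
        }
        return f"ParameterSet({changed!r})"

    def replace(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        merged = dict(self._values)
        for name, val in kwargs.items():
            if name not in merged:
                raise KeyError(f"unknown parameter {name!r}")
            merged[name] = float(val)
        out = ParameterSet.__new__(ParameterSet)
        object.__setattr__(out, "_values", merged)
        return out

    def as_dict(self) -> Dict[str, float]:
        return dict(self._values)


# Literature reference estimates for the cascade model (the values the study
# of this pathway established by manual tuning; copy numbers per cell).
_REFERENCE_VALUES: Dict[str, float] = {
    "c1L": 2.0e-2,
    "c2": 2.0e-7,
    "t1": 1.0e2,
    "d3": 1.0e-3,
    "b1": 4.0e-8,
    "n1": 2.0e-3,
    "b2": 1.0e-5,
    "n2": 1.0e-3,
    "b3": 1.0e-5,
    "n3": 3.0e-2,
    "b4": 1.0e-5,
    "n4": 1.0e-3,
    "a1": 1.5e-7,
    "i1": 2.0e-2,
    "a2": 4.0e-8,
    "i2": 1.0e-2,
    "p1": 1.5e-7,
    "u1": 5.0e-3,
    "p2a": 1.0e-6,
    "p2b": 5.0e-6,
    "u2": 2.0e-2,
    "p3": 2.0e-9,
    "u3": 1.0e-3,
    "p4": 1.2e-9,
    "u4": 2.0e-4,
    "b5": 4.0e-9,
    "n5": 2.0e-4,
    "u5": 2.0e1,
    # fixed / structural
    "s1": 2.5,
    "d1": 5.0e-6,
    "s2": 1.0,
    "d2": 5.0e-6,
    "c1": 2.0e-2,
    "c1init": 0.0,
    "MEK1_fraction": 6.7e-1,
    "X": 5.0,
    # initial copy numbers
    "EGFR0": 5.0e5,
    "SOS10": 2.0e5,
    "RAS0": 5.0e5,
    "RAF0": 5.0e5,
    "MEK_tot0": 2.0e5,
    "MEK10": 1.34e5,
    "MEK1_T292p0": 0.0,
    "MEK20": 6.6e4,
    "ERK0": 3.0e6,
    "PHP_MEK0": 3.0e6,
    # scaling factors and noise scale (AU)
    "ScalepEGFR": 1.1e-4,
    "ScalepERK": 3.2e-6,
    "ScalepSOS1": 1.1e-4,
    "sigma": 1.1,
}

#: Reference parameter set (original manually tuned estimates).
REFERENCE_PARAMS = ParameterSet()

# Best-fit values from the global hybrid-objective fit of the same model.
_BEST_FIT_VALUES: Dict[str, float] = {
    "c1L": 7.4e-3,
    "c2": 9.3e-9,
    "t1": 9.9e1,
    "d3": 2.0e-3,
    "b1": 2.4e-8,
    "n1": 6.5e-4,
    "b2": 4.2e-6,
    "n2": 2.6e-4,
    "b3": 9.9e-5,
    "n3": 8.0e-2,
    "b4": 2.9e-4,
    "n4": 3.5e-3,
    "a1": 2.3e-7,
    "i1": 3.9e-1,
    "a2": 3.3e-8,
    "i2": 2.7e-2,
    "p1": 3.5e-6,
    "u1": 9.5e-4,
    "p2a": 5.2e-7,
    "p2b": 2.3e-5,
    "u2": 6.7e-2,
    "p3": 1.1e-9,
    "u3": 2.6e-4,
    "p4": 6.5e-10,
    "u4": 3.2e-4,
    "b5": 1.7e-8,
    "n5": 3.9e-3,
    "u5": 1.9e1,
    "ScalepEGFR": 1.1e-4,
    "ScalepERK": 3.2e-6,
    "ScalepSOS1": 1.1e-4,
    "sigma": 1.1,
}

#: Best-fit parameter set of the published global fit.
BEST_FIT_PARAMS = ParameterSet(_BEST_FIT_VALUES)

#: Box constraints used for maximum-likelihood optimization (31 entries).
OPTIMIZATION_BOUNDS: Dict[str, Tuple[float, float]] = {
    "c1L": (9.0e-4, 4.0e-2),
    "c2": (9.0e-9, 4.0e-6),
    "t1": (99.0, 101.0),
    "d3": (8.0e-5, 3.0e-2),
    "b1": (2.0e-9, 6.0e-7),
    "n1": (9.0e-5, 4.0e-2),
    "b2": (8.0e-7, 3.0e-4),
    "n2": (8.0e-5, 3.0e-2),
    "b3": (8.0e-7, 3.0e-4),
    "n3": (1.0e-3, 5.0e-1),
    "b4": (8.0e-7, 3.0e-4),
    "n4": (8.0e-5, 3.0e-2),
    "a1": (1.27e-8, 1.29e-6),
    "i1": (9.0e-4, 4.0e-1),
    "a2": (2.0e-9, 6.0e-7),
    "i2": (8.0e-4, 3.0e-1),
    "p1": (8.0e-9, 4.0e-6),
    "u1": (3.0e-4, 7.0e-2),
    "p2a": (8.0e-8, 3.0e-5),
    "p2b": (1.0e-6, 5.0e-4),
    "u2": (9.0e-4, 4.0e-1),
    "p3": (9.0e-11, 4.0e-8),
    "u3": (8.0e-5, 3.0e-2),
    "p4": (9.0e-11, 3.0e-8),
    "u4": (9.0e-6, 4.0e-3),
    "b5": (2.0e-10, 6.0e-8),
    "n5": (9.0e-6, 4.0e-3),
    "u5": (19.0, 21.0),
    "ScalepEGFR": (3.0e-5, 6.0e-5),
    "ScalepERK": (2.0e-6, 5.0e-6),
    "ScalepSOS1": (9.0e-5, 3.0e-4),
}

#: Box prior used in Bayesian uncertainty quantification (6 sampled
#: parameters).  Note the published ScalepEGFR best fit lies outside its own
#: printed sampling box; the boxes are kept as printed.
BAYES_BOUNDS: Dict[str, Tuple[float, float]] = {
    "d3": (1.0e-5, 1.0e-1),
    "u3": (1.0e-5, 1.0e-1),
    "ScalepEGFR": (3.0e-5, 6.0e-5),
    "ScalepERK": (2.0e-6, 5.0e-6),
    "ScalepSOS1": (9.0e-5, 3.0e-4),
    "sigma": (1.0e-1, 1.0e1),
}
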