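"""Rule-based construction of the MEK-isoform ERK cascade reaction network.

Species are structured tuples; the network is generated by iterating rule
application to a fixpoint starting from the initially populated species of a
given cell-line variant, so the inventory is always exactly the reachable
set.  Dimers are canonicalized by sorting their protomer descriptors, so AB
and BA label the same species.

Species encoding
----------------
``('EGFR', lig)``                 free receptor subunit, ``lig`` 0/1.
``('EGFRD', ph, (s, s))``         receptor dimer; ``ph`` 0/1 transphosphorylation
                                  state (both subunits); each slot ``''`` (empty),
                                  ``'S'`` (SOS1) or ``'Sp'`` (phospho-SOS1);
                                  slots sorted; SOS1 binds phospho dimers only.
``('SOS', p)``                    free SOS1, ``p`` 0/1 feedback phosphorylation.
``('RAS', g)``                    ``g`` 0 = GDP, 1 = GTP.
``('RAF', a)``                    ``a`` 0/1 activity.
``('ERK', p)``                    ``p`` 0 = unphosphorylated, 1 = doubly
                                  phosphorylated (active).
``('PHP',)``                      free PHP phosphatase.
``('MEK', protomer)``             MEK monomer.
``('MEKD', (protomer, protomer))``  MEK dimer, protomers sorted.

A MEK protomer is ``(iso, act, t292, php)`` with ``iso`` 1/2, ``act`` 0/1
activation-site phosphorylation, ``t292`` 0/1 Thr292 phosphorylation (MEK1
only), ``php`` 0/1 PHP bound (requires ``t292 == 1``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .params import ParameterSet, REFERENCE_PARAMS

__all__ = [
    "VARIANTS",
    "OBSERVABLE_NAMES",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "apply_variant",
]

#: The five cell-line variants of the model.
VARIANTS: Tuple[str, ...] = ("WT", "KO", "N78G", "T292A", "T292D")

#: Observables every trajectory reports.
OBSERVABLE_NAMES: Tuple[str, ...] = (
    "MEK_pRDS", "pERK1_2_wt", "pEGFR", "pSOS1", "pMEK1", "pMEK2", "MEK1_T292p",
)

Species = tuple


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``factor`` is the site multiplicity (number of equivalent ways the rule
    matches the reactant species); the propensity is
    ``factor * k * x[reactants...]``.
    """

    reactants: Tuple[Species, ...]
    products: Tuple[Species, ...]
    rate: str
    factor: int = 1


@dataclass
class ReactionNetwork:
    """Reachable species inventory and reaction list for one variant."""

    variant: str
    species: List[Species]
    reactions: List[Reaction]
    index: Dict[Species, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.species)}

    # -- initial state -----------------------------------------------------
    def initial_state(self, params: ParameterSet) -> "np.ndarray":
        """Initial copy-number vector for ``params`` (variant already applied)."""
        import numpy as np

        x0 = np.zeros(len(self.species))
        for sp, value in _initial_species(params).items():
            if value and sp not in self.index:
                raise ValueError(
                    f"species {sp} carries initial copies but is not in the "
                    f"{self.variant} network"
                )
            if sp in self.index:
                x0[self.index[sp]] = value
        return x0

    # -- linear functionals over the state ---------------------------------
    def observable_matrix(self) -> "np.ndarray":
        """Rows = observables (in OBSERVABLE_NAMES order), columns = species."""
        import numpy as np

        w = np.zeros((len(OBSERVABLE_NAMES), len(self.species)))
        for j, sp in enumerate(self.species):
            pro = _protomers(sp)
            n_act1 = sum(1 for p in pro if p[0] == 1 and p[1] == 1)
            n_act2 = sum(1 for p in pro if p[0] == 2 and p[1] == 1)
            w[0, j] = n_act1 + n_act2                       # MEK_pRDS
            w[4, j] = n_act1                                # pMEK1
            w[5, j] = n_act2                                # pMEK2
            w[6, j] = sum(1 for p in pro if p[0] == 1 and p[2] == 1)  # T292p
            if sp[0] == "ERK" and sp[1] == 1:
                w[1, j] = 1.0                               # pERK1_2_wt
            if sp[0] == "EGFRD" and sp[1] == 1:
                w[2, j] = 2.0                               # pEGFR
            if sp[0] == "SOS" and sp[1] == 1:
                w[3, j] = 1.0                               # pSOS1
            if sp[0] == "EGFRD":
                w[3, j] += sp[2].count("Sp")
        return w

    def moiety_matrix(self) -> Tuple[List[str], "np.ndarray", List[bool]]:
        """Conserved-moiety weights.

        Returns (names, weights, conserved_flags); EGFR material is flagged
        non-conserved because of the d3 degradation sink.
        """
        import numpy as np

        names = ["MEK1", "MEK2", "ERK", "RAS", "RAF", "SOS1", "PHP", "EGFR"]
        w = np.zeros((len(names), len(self.species)))
        for j, sp in enumerate(self.species):
            pro = _protomers(sp)
            w[0, j] = sum(1 for p in pro if p[0] == 1)
            w[1, j] = sum(1 for p in pro if p[0] == 2)
            w[6, j] = sum(1 for p in pro if p[0] == 1 and p[3] == 1)
            if sp[0] == "ERK":
                w[2, j] = 1.0
            elif sp[0] == "RAS":
                w[3, j] = 1.0
            elif sp[0] == "RAF":
                w[4, j] = 1.0
            elif sp[0] == "SOS":
                w[5, j] = 1.0
            elif sp[0] == "PHP":
                w[6, j] += 1.0
            elif sp[0] == "EGFR":
                w[7, j] = 1.0
            elif sp[0] == "EGFRD":
                w[7, j] = 2.0
                w[5, j] = sum(1 for s in sp[2] if s)
        conserved = [True] * 7 + [False]
        return names, w, conserved

    # -- export ------------------------------------------------------------
    def format_species(self, sp: Species) -> str:
        return _label(sp)

    def to_text(self) -> str:
        """Human-readable reaction list, one reaction per line."""
        lines = [f"# variant: {self.variant}",
                 f"# species: {len(self.species)}  reactions: {len(self.reactions)}"]
        for r in self.reactions:
            lhs = " + ".join(_label(s) for s in r.reactants)
            rhs = " + ".join(_label(s) for s in r.products) or "0"
            fac = f"  x{r.factor}" if r.factor != 1 else ""
            lines.append(f"{lhs} -> {rhs}  [{r.rate}]{fac}")
        return "\n".join(lines) + "\n"

    def species_csv(self) -> str:
        """Species inventory: label plus per-moiety material counts."""
        names, w, conserved = self.moiety_matrix()
        lines = ["species," + ",".join(names)]
        for j, sp in enumerate(self.species):
            counts = ",".join(f"{int(w[i, j])}" for i in range(len(names)))
            lines.append(f"{_label(sp)},{counts}")
        return "\n".join(lines) + "\n"

    def export(self, outdir) -> None:
        """Write the reaction list and species inventory for auditing."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"reactions_{self.variant}.txt").write_text(self.to_text())
        (outdir / f"species_{self.variant}.csv").write_text(self.species_csv())


# ---------------------------------------------------------------------------
# species helpers

def _protomers(sp: Species) -> Tuple[tuple, ...]:
    if sp[0] == "MEK":
        return (sp[1],)
    if sp[0] == "MEKD":
        return sp[1]
    return ()


def _mek(pro: tuple) -> Species:
    return ("MEK", pro)


def _mekd(a: tuple, b: tuple) -> Species:
    return ("MEKD", tuple(sorted((a, b))))


def _with_protomer(sp: Species, i: int, new: tuple) -> Species:
    """Replace protomer ``i`` of a MEK species, re-canonicalizing."""
    if sp[0] == "MEK":
        return _mek(new)
    pro = list(sp[1])
    pro[i] = new
    return ("MEKD", tuple(sorted(pro)))


def _egfrd(ph: int, slots: Sequence[str]) -> Species:
    return ("EGFRD", ph, tuple(sorted(slots)))


def _label(sp: Species) -> str:
    kind = sp[0]
    if kind == "EGFR":
        return "EGFR(L)" if sp[1] else "EGFR"
    if kind == "EGFRD":
        slots = ".".join(s if s else "-" for s in sp[2])
        return f"EGFRD({'p' if sp[1] else 'u'};{slots})"
    if kind == "SOS":
        return "SOS1p" if sp[1] else "SOS1"
    if kind == "RAS":
        return "RAS_GTP" if sp[1] else "RAS_GDP"
    if kind == "RAF":
        return "RAF*" if sp[1] else "RAF"
    if kind == "ERK":
        return "ppERK" if sp[1] else "ERK"
    if kind == "PHP":
        return "PHP"
    if kind == "MEK":
        return _protomer_label(sp[1])
    if kind == "MEKD":
        return ":".join(_protomer_label(p) for p in sp[1])
    raise ValueError(f"unknown species {sp!r}")


def _protomer_label(p: tuple) -> str:
    iso, act, t292, php = p
    tags = []
    if act:
        tags.append("aP")
    if t292:
        tags.append("292p")
    if php:
        tags.append("PHP")
    return f"MEK{iso}" + ("[" + ",".join(tags) + "]" if tags else "")


def _initial_species(params: ParameterSet) -> Dict[Species, float]:
    mek1_plain = params.MEK10 - params.MEK1_T292p0
    if mek1_plain < -1e-9 * max(params.MEK10, 1.0):
        raise ValueError("MEK1_T292p0 exceeds MEK10")
    return {
        ("EGFR", 0): params.EGFR0,
        ("SOS", 0): params.SOS10,
        ("RAS", 0): params.RAS0,
        ("RAF", 0): params.RAF0,
        ("ERK", 0): params.ERK0,
        ("PHP",): params.PHP_MEK0,
        _mek((1, 0, 0, 0)): max(mek1_plain, 0.0),
        _mek((1, 0, 1, 0)): params.MEK1_T292p0,
        _mek((2, 0, 0, 0)): params.MEK20,
    }


# ---------------------------------------------------------------------------
# variants

def apply_variant(base: ParameterSet, variant: str) -> ParameterSet:
    """Transform a parameter set for one of the five cell-line variants.

    WT: unchanged.  KO: MEK1 knocked out.  N78G: MEK1 cannot dimerize with
    itself or MEK2.  T292A: no ERK feedback phosphorylation of MEK1.
    T292D: phosphomimetic — all MEK1 starts Thr292-phosphorylated and the
    mark is permanent.
    """
    if variant == "WT":
        return base
    if variant == "KO":
        return base.replace(MEK10=0.0, MEK1_T292p0=0.0)
    if variant == "N78G":
        return base.replace(b2=0.0, b4=0.0)
    if variant == "T292A":
        return base.replace(p4=0.0)
    if variant == "T292D":
        return base.replace(MEK1_T292p0=base.MEK10, u4=0.0)
    raise ValueError(f"unknown variant {variant!r}")


# rules structurally absent in each variant (beyond what parameter zeros
# already imply); used so the reachable species set is variant-correct
_DISABLED_RULES: Dict[str, frozenset] = {
    "WT": frozenset(),
    "KO": frozenset(),
    "N78G": frozenset({"mek1_homodimer", "heterodimer"}),
    "T292A": frozenset({"t292_phos"}),
    "T292D": frozenset({"t292_dephos"}),
}


# ---------------------------------------------------------------------------
# rule application

def _apply_rules(species: set, disabled: frozenset) -> List[Reaction]:
    """All reactions whose reactants are drawn from ``species``."""
    out: List[Reaction] = []
    add = out.append
    S = sorted(species)

    for sp in S:
        kind = sp[0]

        # R1 ligand engagement (post-stimulation rate c1L)
        if sp == ("EGFR", 0):
            add(Reaction((sp,), (("EGFR", 1),), "c1L"))

        # R3 dimer transphosphorylation
        if kind == "EGFRD" and sp[1] == 0:
            add(Reaction((sp,), (_egfrd(1, sp[2]),), "t1"))

        # R4 degradation of ligand-bound dimers; bound SOS1 returns free
        if kind == "EGFRD":
            freed = tuple(("SOS", 1 if s == "Sp" else 0) for s in sp[2] if s)
            add(Reaction((sp,), freed, "d3"))

        # R6 SOS1 unbinding
        if kind == "EGFRD" and sp[1] == 1:
            for tag, p in (("S", 0), ("Sp", 1)):
                n = sp[2].count(tag)
                if n:
                    slots = list(sp[2])
                    slots[slots.index(tag)] = ""
                    add(Reaction((sp,), (_egfrd(1, slots), ("SOS", p)), "n1", n))

        # R8 / R10 deactivation of RAS and RAF
        if sp == ("RAS", 1):
            add(Reaction((sp,), (("RAS", 0),), "i1"))
        if sp == ("RAF", 1):
            add(Reaction((sp,), (("RAF", 0),), "i2"))

        # R12 constitutive dephosphorylation of MEK activation sites (u1)
        pros = _protomers(sp)
        if pros:
            mods = [
                _with_protomer(sp, i, (p[0], 0, p[2], p[3]))
                for i, p in enumerate(pros) if p[1] == 1
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp,), (prod,), "u1", n))

        # R14/R16/R18 MEK dimer dissociation
        if kind == "MEKD":
            a, b = sp[1]
            rate = {(1, 1): "n2", (2, 2): "n3", (1, 2): "n4"}[
                tuple(sorted((a[0], b[0])))
            ]
            add(Reaction((sp,), (_mek(a), _mek(b)), rate))

        # R16' ERK dephosphorylation
        if sp == ("ERK", 1):
            add(Reaction((sp,), (("ERK", 0),), "u2"))

        # R22 free SOS1 dephosphorylation
        if sp == ("SOS", 1):
            add(Reaction((sp,), (("SOS", 0),), "u3"))
        # bound phospho-SOS1 dephosphorylation
        if kind == "EGFRD" and "Sp" in sp[2]:
            n = sp[2].count("Sp")
            slots = list(sp[2])
            slots[slots.index("Sp")] = "S"
            add(Reaction((sp,), (_egfrd(1, slots),), "u3", n))

        # R24 Thr292 dephosphorylation (only when PHP not bound)
        if pros and "t292_dephos" not in disabled:
            mods = [
                _with_protomer(sp, i, (1, p[1], 0, 0))
                for i, p in enumerate(pros)
                if p[0] == 1 and p[2] == 1 and p[3] == 0
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp,), (prod,), "u4", n))

        # R26 PHP unbinding
        if pros:
            mods = [
                _with_protomer(sp, i, (1, p[1], 1, 0))
                for i, p in enumerate(pros)
                if p[0] == 1 and p[3] == 1
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp,), (prod, ("PHP",)), "n5", n))

        # R27 PHP-driven dephosphorylation of activation sites (cis + partner)
        if pros:
            mods = []
            for i, p in enumerate(pros):
                if p[0] == 1 and p[3] == 1:       # catalytic PHP-bound protomer
                    for j, q in enumerate(pros):  # targets own + partner site
                        if q[1] == 1:
                            mods.append(
                                _with_protomer(sp, j, (q[0], 0, q[2], q[3]))
                            )
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp,), (prod,), "u5", n))

    # --- bimolecular rules ---
    has = species.__contains__

    # R2 receptor dimerization
    if has(("EGFR", 1)):
        add(Reaction((("EGFR", 1), ("EGFR", 1)), (_egfrd(0, ("", "")),), "c2"))

    for sp in S:
        kind = sp[0]

        # R5 SOS1 binding to phosphorylated dimers
        if kind == "EGFRD" and sp[1] == 1 and "" in sp[2]:
            n = sp[2].count("")
            for tag, p in (("S", 0), ("Sp", 1)):
                if has(("SOS", p)):
                    slots = list(sp[2])
                    slots[slots.index("")] = tag
                    add(Reaction((sp, ("SOS", p)), (_egfrd(1, slots),), "b1", n))

        # R7 RAS activation by receptor-bound (unphosphorylated) SOS1
        if kind == "EGFRD" and sp[1] == 1 and "S" in sp[2] and has(("RAS", 0)):
            add(Reaction(
                (("RAS", 0), sp), (("RAS", 1), sp), "a1", sp[2].count("S")
            ))

        # R9 RAF activation by RAS-GTP
        if sp == ("RAF", 0) and has(("RAS", 1)):
            add(Reaction((sp, ("RAS", 1)), (("RAF", 1), ("RAS", 1)), "a2"))

        pros = _protomers(sp)

        # R11 MEK activation-site phosphorylation by active RAF
        if pros and has(("RAF", 1)):
            mods = [
                _with_protomer(sp, i, (p[0], 1, p[2], p[3]))
                for i, p in enumerate(pros) if p[1] == 0
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp, ("RAF", 1)), (prod, ("RAF", 1)), "p1", n))

        # R19/R20 ERK phosphorylation by active MEK1 (p2a) / MEK2 (p2b)
        if pros and has(("ERK", 0)):
            for iso, rate in ((1, "p2a"), (2, "p2b")):
                n = sum(1 for p in pros if p[0] == iso and p[1] == 1)
                if n:
                    add(Reaction(
                        (("ERK", 0), sp), (("ERK", 1), sp), rate, n
                    ))

        # R21 ERK feedback phosphorylation of SOS1 (free and receptor-bound)
        if sp == ("SOS", 0) and has(("ERK", 1)):
            add(Reaction((sp, ("ERK", 1)), (("SOS", 1), ("ERK", 1)), "p3"))
        if kind == "EGFRD" and "S" in sp[2] and has(("ERK", 1)):
            slots = list(sp[2])
            slots[slots.index("S")] = "Sp"
            add(Reaction(
                (sp, ("ERK", 1)), (_egfrd(1, slots), ("ERK", 1)),
                "p3", sp[2].count("S"),
            ))

        # R23 ERK feedback phosphorylation of MEK1 Thr292
        if pros and "t292_phos" not in disabled and has(("ERK", 1)):
            mods = [
                _with_protomer(sp, i, (1, p[1], 1, 0))
                for i, p in enumerate(pros) if p[0] == 1 and p[2] == 0
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp, ("ERK", 1)), (prod, ("ERK", 1)), "p4", n))

        # R25 PHP binding to MEK1-Thr292p
        if pros and has(("PHP",)):
            mods = [
                _with_protomer(sp, i, (1, p[1], 1, 1))
                for i, p in enumerate(pros)
                if p[0] == 1 and p[2] == 1 and p[3] == 0
            ]
            for prod, n in sorted(Counter(mods).items()):
                add(Reaction((sp, ("PHP",)), (prod,), "b5", n))

    # R13/R15/R17 MEK dimerization among monomers (state-preserving)
    monomers = [sp for sp in S if sp[0] == "MEK"]
    seen = set()
    for m1 in monomers:
        for m2 in monomers:
            pair = tuple(sorted((m1, m2)))
            if pair in seen:
                continue
            seen.add(pair)
            isos = tuple(sorted((m1[1][0], m2[1][0])))
            rule, rate = {
                (1, 1): ("mek1_homodimer", "b2"),
                (2, 2): ("mek2_homodimer", "b3"),
                (1, 2): ("heterodimer", "b4"),
            }[isos]
            if rule in disabled:
                continue
            add(Reaction((pair[0], pair[1]), (_mekd(pair[0][1], pair[1][1]),),
                         rate))

    return out


def build_network(variant: str, params: ParameterSet | None = None) -> ReactionNetwork:
    """Expand the variant's rule set to its reachable-species fixpoint.

    ``params`` (default: reference values, pre-transformed per variant) only
    determines which species carry initial copies, hence the seed set.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    p = apply_variant(params or REFERENCE_PARAMS, variant)
    disabled = _DISABLED_RULES[variant]
    species = {sp for sp, v in _initial_species(p).items() if v > 0}
    # keep structural zero-seeds out (e.g. KO MEK1), but always seed the core
    # molecules so an all-zero parameter edge case still yields a network
    while True:
        reactions = _apply_rules(species, disabled)
        new = set()
        for r in reactions:
            new.update(r.products)
        new -= species
        if not new:
            break
        species |= new
    ordered = sorted(species)
    return ReactionNetwork(variant, ordered, reactions)
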