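"""Domain types and structural operations for the metabolic network.

The canonical CHO network bundled with the package has 46 state variables
and 35 reactions; seven reactions (LDH, GLNS, GLDH, AlaTA, ASTA, CK, AK)
are reversible pairs with separate forward and reverse maximum rates, so
the model carries 42 maximum-rate parameters, 48 affinity constants and
5 regulatory constants (95 kinetic parameters).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import canonical as C


class NetworkError(ValueError):
    """Raised for structurally invalid network definitions or parameters."""


# --------------------------------------------------------------------------
# Species / Reaction / NetworkDefinition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    id: str
    name: str
    compartment: str          # culture | extracellular | intracellular
    unit: str
    measured: bool = False
    dilution_applies: bool = False


@dataclass(frozen=True)
class Reaction:
    """One lumped biochemical reaction.

    ``stoichiometry`` is the net signed coefficient map (reversible pairs
    share a single net column, positive in the forward arrow direction).
    ``virtual_stoichiometry`` holds coefficients of derived species that
    are not state variables (the creatine pool's CR), used only by the
    moiety-closure validator.  ``kinetic_spec`` is the declarative wiring
    of the rate law (see :mod:`chokinet.canonical`).
    """

    id: str
    stoichiometry: dict
    reversible_pair: bool = False
    kinetic_spec: object = None
    regulation_terms: tuple = ()
    virtual_stoichiometry: dict = field(default_factory=dict)


@dataclass
class NetworkDefinition:
    species: list
    reactions: list
    moieties: dict
    aa_groups: dict

    def species_ids(self):
        return [s.id for s in self.species]

    def reaction_ids(self):
        return [r.id for r in self.reactions]

    def species_index(self):
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction(self, rid: str) -> Reaction:
        rid = C.REACTION_ALIASES.get(rid, rid)
        for r in self.reactions:
            if r.id == rid:
                return r
        raise NetworkError(f"unknown reaction id: {rid!r}")


# --------------------------------------------------------------------------
# ParameterSet
# --------------------------------------------------------------------------

def _species_unit(sid: str, compartment: str) -> str:
    if compartment == "culture":
        return C.COMPARTMENT_UNITS["culture"][sid]
    return C.COMPARTMENT_UNITS[compartment]


@dataclass
class ParameterSet:
    """All kinetic and auxiliary parameters with flat named access.

    Flat names: ``vmax.<rate>`` (42), ``Km.<reaction>.<species-or-pool>``
    (48), ``reg.<constant>`` (5), plus the auxiliary ``po_ratio``,
    ``gln_threshold``, ``gln_threshold_steepness`` and
    ``mab_leak_fraction``.
    """

    vmax: dict
    affinity: dict
    regulatory: dict
    po_ratio: float = C.PO_RATIO_DEFAULT
    gln_threshold: float = C.GLN_THRESHOLD_DEFAULT
    gln_threshold_steepness: float = C.GLN_THRESHOLD_STEEPNESS
    biomass_coeffs: dict = field(default_factory=lambda: dict(C.BIOMASS_COEFFS))
    mab_coeffs: dict = field(default_factory=lambda: dict(C.MAB_COEFFS))
    mab_leak_fraction: float = 1.0
    free_mask: set = field(default_factory=set)
    clone: str | None = None

    # -- flat-name access ---------------------------------------------------
    def get(self, name: str) -> float:
        kind, _, rest = name.partition(".")
        if kind == "vmax":
            return self.vmax[rest]
        if kind == "Km":
            rxn, _, sp = rest.partition(".")
            return self.affinity[(rxn, sp)]
        if kind == "reg":
            return self.regulatory[rest]
        if name in ("po_ratio", "gln_threshold", "gln_threshold_steepness",
                    "mab_leak_fraction"):
            return getattr(self, name)
        raise KeyError(name)

    def set(self, name: str, value: float) -> None:
        kind, _, rest = name.partition(".")
        if kind == "vmax":
            if rest not in self.vmax:
                raise KeyError(name)
            self.vmax[rest] = float(value)
        elif kind == "Km":
            rxn, _, sp = rest.partition(".")
            if (rxn, sp) not in self.affinity:
                raise KeyError(name)
            self.affinity[(rxn, sp)] = float(value)
        elif kind == "reg":
            if rest not in self.regulatory:
                raise KeyError(name)
            self.regulatory[rest] = float(value)
        elif name in ("po_ratio", "gln_threshold", "gln_threshold_steepness",
                      "mab_leak_fraction"):
            setattr(self, name, float(value))
        else:
            raise KeyError(name)

    def kinetic_parameter_names(self):
        names = [f"vmax.{r}" for r in self.vmax]
        names += [f"Km.{rxn}.{sp}" for (rxn, sp) in self.affinity]
        names += [f"reg.{k}" for k in self.regulatory]
        return names

    @property
    def n_kinetic_parameters(self) -> int:
        return len(self.vmax) + len(self.affinity) + len(self.regulatory)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def with_updates(self, updates: dict) -> "ParameterSet":
        out = self.copy()
        for k, v in updates.items():
            out.set(k, v)
        return out

    @classmethod
    def canonical_defaults(cls) -> "ParameterSet":
        return cls(vmax=dict(C.VMAX_DEFAULTS),
                   affinity=dict(C.AFFINITY_DEFAULTS),
                   regulatory=dict(C.REGULATORY_DEFAULTS))


# --------------------------------------------------------------------------
# StateVector
# --------------------------------------------------------------------------

class StateVector:
    """Named view on the 46 model states with nucleotide-ratio accessors."""

    __slots__ = ("values",)

    def __init__(self, values=None):
        if values is None:
            values = [C.INITIAL_STATE[s] for s in C.SPECIES_IDS]
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(C.SPECIES_IDS),):
            raise NetworkError(
                f"state vector must have {len(C.SPECIES_IDS)} entries, "
                f"got {arr.shape}")
        self.values = arr

    @classmethod
    def from_dict(cls, d: dict) -> "StateVector":
        unknown = set(d) - set(C.SPECIES_IDS)
        if unknown:
            raise NetworkError(f"unknown species: {sorted(unknown)}")
        base = dict(C.INITIAL_STATE)
        base.update(d)
        return cls([base[s] for s in C.SPECIES_IDS])

    def to_dict(self) -> dict:
        return dict(zip(C.SPECIES_IDS, self.values))

    def __getitem__(self, sid: str) -> float:
        return float(self.values[C.IX[sid]])

    def __setitem__(self, sid: str, v: float) -> None:
        self.values[C.IX[sid]] = v

    def __len__(self) -> int:
        return len(self.values)

    def _ratio(self, num, den):
        d = self[den]
        if d <= 0:
            raise ZeroDivisionError(f"{den} is non-positive; ratio undefined")
        return self[num] / d

    @property
    def atp_adp(self) -> float:
        return self._ratio("ATP", "ADP")

    @property
    def nadh_nad(self) -> float:
        return self._ratio("NADH", "NAD")

    @property
    def nadph_nadp(self) -> float:
        return self._ratio("NADPH", "NADP")

    @property
    def cr(self) -> float:
        """Free creatine, from the conserved creatine moiety total."""
        return C.CREATINE_TOTAL - self["PCR"]

    def copy(self) -> "StateVector":
        return StateVector(self.values.copy())


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def build_canonical_network() -> NetworkDefinition:
    """Construct the bundled canonical CHO network definition."""
    species = []
    for sid, name, comp, measured, dil in C.SPECIES_TABLE:
        species.append(Species(id=sid, name=name, compartment=comp,
                               unit=_species_unit(sid, comp),
                               measured=measured, dilution_applies=dil))
    # regulation targets keyed by rate slot -> reaction id
    reg_by_reaction = {}
    for term, info in C.REGULATION_TERMS.items():
        for target in info["targets"]:
            rid = target.split("__")[0].removesuffix("_f").removesuffix("_r")
            reg_by_reaction.setdefault(rid, []).append(term)

    reactions = []
    for rid in C.REACTION_IDS:
        if rid in C.REVERSIBLE_PAIRS:
            spec = {"forward": C.RATE_KINETICS[rid + "_f"],
                    "reverse": C.RATE_KINETICS[rid + "_r"]}
        else:
            spec = C.RATE_KINETICS[rid]
        reactions.append(Reaction(
            id=rid,
            stoichiometry=dict(C.REACTION_STOICH[rid]),
            reversible_pair=rid in C.REVERSIBLE_PAIRS,
            kinetic_spec=spec,
            regulation_terms=tuple(reg_by_reaction.get(rid, ())),
            virtual_stoichiometry=dict(
                C.REACTION_VIRTUAL_STOICH.get(rid, {})),
        ))
    return NetworkDefinition(species=species, reactions=reactions,
                             moieties={k: list(v)
                                       for k, v in C.MOIETIES.items()},
                             aa_groups={k: list(v)
                                        for k, v in C.AA_GROUPS.items()})


def stoichiometric_matrix(net: NetworkDefinition) -> np.ndarray:
    """Signed species x reactions matrix (46 x 35, net-flux convention)."""
    idx = net.species_index()
    S = np.zeros((len(net.species), len(net.reactions)))
    for j, rxn in enumerate(net.reactions):
        for sid, coeff in rxn.stoichiometry.items():
            if sid not in idx:
                raise NetworkError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}")
            S[idx[sid], j] = coeff
    return S


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    expected: object
    found: object

    def __str__(self):
        status = "PASS" if self.passed else "FAIL"
        return f"[{status}] {self.name}: expected {self.expected}, found {self.found}"


@dataclass
class ValidationReport:
    checks: list

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self):
        return "\n".join(str(c) for c in self.checks)

    def as_dict(self):
        return {c.name: {"passed": c.passed, "expected": c.expected,
                         "found": c.found} for c in self.checks}


def validate_network(net: NetworkDefinition,
                     params: ParameterSet | None = None) -> ValidationReport:
    """Check the printed structural counts and conservation invariants.

    Never raises on failure; every invariant is reported as pass/fail.
    """
    checks = []

    def add(name, expected, found, ok=None):
        checks.append(ValidationCheck(
            name, ok if ok is not None else expected == found,
            expected, found))

    add("reaction count", 35, len(net.reactions))
    add("species count", 46, len(net.species))

    pairs = sorted(r.id for r in net.reactions if r.reversible_pair)
    add("reversible pairs", sorted(C.REVERSIBLE_PAIRS), pairs)
    n_vmax = len(net.reactions) + len(pairs)
    add("maximum-rate parameters", 42, n_vmax)

    if params is not None:
        add("affinity constants", 48, len(params.affinity))
        add("regulatory constants", 5, len(params.regulatory))
        add("total kinetic parameters", 95, params.n_kinetic_parameters)
        positive = all(v > 0 for v in list(params.vmax.values())[:-1]) and \
            all(v > 0 for v in params.affinity.values()) and \
            all(v > 0 for v in params.regulatory.values()) and \
            params.vmax.get("mAb", 0.0) >= 0
        add("parameters strictly positive", True, positive)
        known = set(params.kinetic_parameter_names())
        add("free mask resolves", True,
            set(params.free_mask) <= known,
            ok=set(params.free_mask) <= known)

    # species references resolve
    ids = set(net.species_ids())
    bad_refs = sorted({sid for r in net.reactions
                       for sid in r.stoichiometry if sid not in ids})
    add("stoichiometry references resolve", [], bad_refs)

    # unique species ids
    dup = len(net.species) - len(ids)
    add("species ids unique", 0, dup)

    # moiety closure over all reactions except growth/mAb
    try:
        S = stoichiometric_matrix(net)
        idx = net.species_index()
        worst = 0.0
        for group, members in net.moieties.items():
            rows = [idx[m] for m in members if m in idx]
            for j, rxn in enumerate(net.reactions):
                if rxn.id in ("growth", "mAb"):
                    continue
                total = S[rows, j].sum()
                total += sum(v for sp, v in rxn.virtual_stoichiometry.items()
                             if sp in members)
                worst = max(worst, abs(total))
        add("moiety closure (non-biosynthetic reactions)", 0.0, worst,
            ok=worst < 1e-12)
    except NetworkError as exc:
        add("moiety closure (non-biosynthetic reactions)", 0.0, str(exc),
            ok=False)

    # amino-acid group coverage: all except GLN and GLU_x in exactly one group
    aa = [a for a in C.AMINO_ACIDS_EXT if a not in ("GLN", "GLU_x")]
    counts = {a: sum(a in g for g in net.aa_groups.values()) for a in aa}
    bad = sorted(a for a, n in counts.items() if n != 1)
    add("amino-acid group coverage", [], bad)

    # exactly one culture-compartment cell-density species
    xv = [s.id for s in net.species
          if s.compartment == "culture" and s.id == "Xv"]
    add("cell-density species", ["Xv"], xv)

    return ValidationReport(checks)
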