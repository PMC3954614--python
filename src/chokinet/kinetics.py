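"""Reaction-rate laws: multiplicative Michaelis-Menten kinetics with
nucleotide-ratio driving forces and the five glycolytic regulation terms.

Every directional rate is a maximum rate times a product of dimensionless
hyperbolic factors: one saturation term per kinetically limiting substrate,
a nucleotide-ratio driving force where the reaction is redox- or
energy-coupled, and the enabled regulation factors.  Uptake of
extracellular metabolites is modelled through the intracellular
enzyme-catalysed reactions, with the saturation term taken on the medium
concentration.  Two single-vmax reactions (PGI, MLD) use a reversible form
with an equilibrium-like back term; the seven reversible pairs carry
separate forward and reverse maximum rates and report a net flux.

The regulation terms:

* I   - hexokinase inhibition by its product G6P
* II  - phosphoglucose isomerase inhibition by PEP
* III - phosphofructokinase inhibition by G6P
* IV  - pyruvate kinase activation by F6P
* V   - lactate dehydrogenase (forward) inhibition by lactate

Alanine uptake (the reverse alanine transaminase) is gated by a smooth
threshold sigmoid on extracellular glutamine: cells only take up alanine
once glutamine approaches depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import canonical as C
from .network import NetworkDefinition, ParameterSet, StateVector, NetworkError


# --------------------------------------------------------------------------
# Elementary factors
# --------------------------------------------------------------------------

def saturation_term(conc: float, km: float) -> float:
    """Michaelis-Menten saturation conc/(km+conc)."""
    if km <= 0:
        raise ValueError(f"affinity constant must be positive, got {km}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return conc / (km + conc)


def inhibition_factor(effector: float, ki: float) -> float:
    """Hyperbolic inhibition 1/(1+effector/ki), in (0, 1]."""
    if ki <= 0:
        raise ValueError(f"inhibition constant must be positive, got {ki}")
    if effector < 0:
        raise ValueError(f"effector must be non-negative, got {effector}")
    return 1.0 / (1.0 + effector / ki)


def activation_factor(effector: float, ka: float) -> float:
    """Hyperbolic activation effector/(ka+effector), in [0, 1)."""
    if ka <= 0:
        raise ValueError(f"activation constant must be positive, got {ka}")
    if effector < 0:
        raise ValueError(f"effector must be non-negative, got {effector}")
    return effector / (ka + effector)


def threshold_activation(gln_ext: float, threshold: float,
                         steepness: float = C.GLN_THRESHOLD_STEEPNESS) -> float:
    """Low-glutamine activation gate in [0, 1].

    A Hill-type sigmoid that is ~1 when extracellular glutamine is far
    below the threshold and ~0 far above it, with value 0.5 exactly at the
    threshold.  Gates alanine uptake (reverse AlaTA).
    """
    if gln_ext < 0 or threshold < 0 or steepness < 0:
        raise ValueError("threshold activation arguments must be >= 0")
    if gln_ext == 0:
        return 1.0
    if threshold == 0:
        return 0.0
    return 1.0 / (1.0 + (gln_ext / threshold) ** steepness)


# --------------------------------------------------------------------------
# Regulation configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulationConfig:
    """Which of the regulation terms I-V are active.

    ``scenario`` is one of none | I | I+II | all, matching the four
    simulated regulation cases; individual terms can be overridden via
    ``overrides`` (term id -> bool).
    """

    scenario: str = "I+II"
    overrides: tuple = ()

    @property
    def enabled(self) -> frozenset:
        if self.scenario not in C.REGULATION_SCENARIOS:
            raise ValueError(
                f"unknown regulation scenario {self.scenario!r}; "
                f"expected one of {sorted(C.REGULATION_SCENARIOS)}")
        terms = set(C.REGULATION_SCENARIOS[self.scenario])
        for term, on in self.overrides:
            if term not in C.REGULATION_TERMS:
                raise ValueError(f"unknown regulation term {term!r}")
            (terms.add if on else terms.discard)(term)
        return frozenset(terms)

    @classmethod
    def from_scenario(cls, scenario: str) -> "RegulationConfig":
        cfg = cls(scenario=scenario)
        cfg.enabled  # validate eagerly
        return cfg


# --------------------------------------------------------------------------
# Compiled flux engine
# --------------------------------------------------------------------------
# The engine flattens the declarative wiring of canonical.RATE_KINETICS into
# index arrays so one call evaluates all 42 directional rates with a handful
# of vectorized operations.  Every factor is the hyperbola
#     f = num / (K * den + num)
# on an extended concentration vector ce = [states, 1, CR, pooled sums]:
#     saturation   num=c_s,  den=1,    K=Km       -> c/(Km+c)
#     ratio        num=c_a,  den=c_b,  K=K        -> r/(K+r), r=a/b
#     inhibition   num=1,    den=c_e,  K=1/Ki     -> 1/(1+e/Ki)
#     activation   num=c_e,  den=1,    K=Ka       -> e/(Ka+e)

_N_SPECIES = len(C.SPECIES_IDS)
_VIRTUAL_ONE = _N_SPECIES          # ce slot holding the constant 1
_CR_SLOT = _N_SPECIES + 1          # derived free creatine
_POOL_NAMES = list(C.KINETIC_POOLS)
_POOL_SLOT = {p: _N_SPECIES + 2 + i for i, p in enumerate(_POOL_NAMES)}
_CE_LEN = _N_SPECIES + 2 + len(_POOL_NAMES)
_POOL_IDX = {p: np.array([C.IX[s] for s in members])
             for p, members in C.KINETIC_POOLS.items()}
_GROWTH_AA_IDX = np.array([C.IX[a] for a in C.GROWTH_AA])

RATE_INDEX = {r: i for i, r in enumerate(C.RATE_NAMES)}
# two pseudo-slots for the back terms of the single-vmax reversible forms
_SLOT_NAMES = C.RATE_NAMES + ["PGI__back", "MLD__back"]
_SLOT_INDEX = {r: i for i, r in enumerate(_SLOT_NAMES)}
_N_SLOTS = len(_SLOT_NAMES)

_PAIR_F_IDX = np.array([RATE_INDEX[r + "_f"] for r in C.REVERSIBLE_PAIRS])
_PAIR_R_IDX = np.array([RATE_INDEX[r + "_r"] for r in C.REVERSIBLE_PAIRS])
_RXN_TO_NET_F = np.array([RATE_INDEX[r + "_f" if r in C.REVERSIBLE_PAIRS
                                     else r] for r in C.REACTION_IDS])


def _expand_factors(slot_name, spec, params, reg_enabled):
    """Yield (slot, num_idx, den_idx, K) rows for one rate slot."""
    slot = _SLOT_INDEX[slot_name]
    for f in spec:
        kind = f[0]
        if kind == "sat":
            _, sp, km_key = f
            yield slot, C.IX[sp], _VIRTUAL_ONE, params.affinity[km_key]
        elif kind == "satCR":
            _, km_key = f
            yield slot, _CR_SLOT, _VIRTUAL_ONE, params.affinity[km_key]
        elif kind == "pool":
            _, pool, km_key = f
            yield slot, _POOL_SLOT[pool], _VIRTUAL_ONE, params.affinity[km_key]
        elif kind == "ratio":
            _, num, den, km_key = f
            yield slot, C.IX[num], C.IX[den], params.affinity[km_key]
        elif kind == "refratio":
            _, num, den = f
            yield slot, C.IX[num], C.IX[den], C.REF_RATIOS[(num, den)]
        elif kind == "aaprod":
            _, km_key = f
            km = params.affinity[km_key]
            for i in _GROWTH_AA_IDX:
                yield slot, int(i), _VIRTUAL_ONE, km
        elif kind == "thresh":
            continue  # handled separately (needs a power law)
        else:  # pragma: no cover - defensive
            raise NetworkError(f"unknown kinetic factor kind {kind!r}")
    # regulation factors wired onto this slot
    for term in reg_enabled:
        info = C.REGULATION_TERMS[term]
        if slot_name not in info["targets"]:
            continue
        k = params.regulatory[info["constant"]]
        if k <= 0:
            raise ValueError(
                f"regulatory constant {info['constant']} must be positive")
        e_idx = C.IX[info["effector"]]
        if info["kind"] == "inhibition":
            yield slot, _VIRTUAL_ONE, e_idx, 1.0 / k
        else:
            yield slot, e_idx, _VIRTUAL_ONE, k


class FluxEngine:
    """Compiled evaluator of the 42 directional rates for one parameter set.

    Rebuild the engine whenever parameters or the regulation configuration
    change; evaluation itself is allocation-light and fast enough for use
    inside the ODE right-hand side.
    """

    def __init__(self, net: NetworkDefinition, params: ParameterSet,
                 reg: RegulationConfig | None = None,
                 mab_vmax_scale: float = 1.0):
        if reg is None:
            reg = RegulationConfig()
        enabled = reg.enabled
        self.net = net
        self.params = params
        self.reg = reg

        rows = []
        for slot_name in C.RATE_NAMES:
            spec = C.RATE_KINETICS[slot_name]
            if isinstance(spec, dict):  # single-vmax reversible form
                spec = spec["forward"]
            rows.extend(_expand_factors(slot_name, spec, params, enabled))
        for rxn, pseudo in (("PGI", "PGI__back"), ("MLD", "MLD__back")):
            spec = C.RATE_KINETICS[rxn]["back"]
            rows.extend(_expand_factors(pseudo, spec, params, enabled))

        rows.sort(key=lambda r: r[0])
        self._slot = np.array([r[0] for r in rows])
        self._num = np.array([r[1] for r in rows])
        self._den = np.array([r[2] for r in rows])
        self._K = np.array([r[3] for r in rows], dtype=float)
        # reduceat segment starts; every slot has at least one factor
        starts = np.searchsorted(self._slot, np.arange(_N_SLOTS))
        if not np.array_equal(np.unique(self._slot), np.arange(_N_SLOTS)):
            raise NetworkError("every rate slot needs at least one factor")
        self._starts = starts

        # reversible-pair rates are stored under their directional names
        missing = [r for r in C.RATE_NAMES if r not in params.vmax]
        if missing:
            raise NetworkError(f"missing vmax for rates {missing}")
        vmax = np.array([params.vmax[r] for r in C.RATE_NAMES], dtype=float)
        vmax[RATE_INDEX["mAb"]] *= mab_vmax_scale
        self._vmax42 = vmax
        self._vmax_slots = np.concatenate([
            vmax, [0.5 * params.vmax["PGI"], 0.5 * params.vmax["MLD"]]])
        self._i_gln = C.IX["GLN"]
        self._i_alatar = RATE_INDEX["AlaTA_r"]
        self._i_pgi = RATE_INDEX["PGI"]
        self._i_mld = RATE_INDEX["MLD"]
        self._i_pgi_b = _SLOT_INDEX["PGI__back"]
        self._i_mld_b = _SLOT_INDEX["MLD__back"]
        self._ce = np.empty(_CE_LEN)

    def rates(self, conc: np.ndarray) -> np.ndarray:
        """All 42 directional rates at non-negative concentrations."""
        ce = self._ce
        ce[:_N_SPECIES] = conc
        ce[_VIRTUAL_ONE] = 1.0
        ce[_CR_SLOT] = max(C.CREATINE_TOTAL - conc[C.IX["PCR"]], 0.0)
        for p, slot in _POOL_SLOT.items():
            ce[slot] = conc[_POOL_IDX[p]].sum()

        num = ce[self._num]
        den = ce[self._den]
        f = num / (self._K * den + num + 1e-300)
        prod = np.multiply.reduceat(f, self._starts)
        v = self._vmax_slots * prod
        # threshold gate on alanine uptake
        v[self._i_alatar] *= threshold_activation(
            conc[self._i_gln], self.params.gln_threshold,
            self.params.gln_threshold_steepness)
        # reversible single-vmax forms: net = fwd - 0.5*back
        out = v[:42].copy()
        out[self._i_pgi] -= v[self._i_pgi_b]
        out[self._i_mld] -= v[self._i_mld_b]
        return out

    def net_fluxes(self, conc: np.ndarray) -> np.ndarray:
        """Net fluxes of the 35 reactions (forward minus reverse)."""
        v = self.rates(conc)
        net = v[_RXN_TO_NET_F].copy()
        pair_pos = [i for i, r in enumerate(C.REACTION_IDS)
                    if r in C.REVERSIBLE_PAIRS]
        net[pair_pos] = v[_PAIR_F_IDX] - v[_PAIR_R_IDX]
        return net


def _check_state(state: StateVector) -> np.ndarray:
    conc = state.values
    if np.any(conc < 0):
        bad = [C.SPECIES_IDS[i] for i in np.where(conc < 0)[0]]
        raise ValueError(f"negative concentrations: {bad}")
    if not np.all(np.isfinite(conc)):
        raise ValueError("non-finite concentrations in state")
    return conc


def reaction_rate(rxn, state: StateVector, params: ParameterSet,
                  reg: RegulationConfig | None = None) -> float:
    """Net flux of a single reaction, mmol/(1e6 cells)/h.

    ``rxn`` is a reaction id (or Reaction); for reversible pairs this is
    forward minus reverse.  Directional rates of a pair are available via
    the ``"<id>_f"`` / ``"<id>_r"`` slot names.
    """
    rid = getattr(rxn, "id", rxn)
    rid = C.REACTION_ALIASES.get(rid, rid)
    engine = FluxEngine(None, params, reg)
    conc = _check_state(state)
    if rid in C.REACTION_IDS:
        j = C.REACTION_IDS.index(rid)
        return float(engine.net_fluxes(conc)[j])
    if rid in RATE_INDEX:  # directional slot of a reversible pair
        return float(engine.rates(conc)[RATE_INDEX[rid]])
    raise NetworkError(f"unknown reaction id: {rid!r}")


def flux_vector(state: StateVector, params: ParameterSet,
                reg: RegulationConfig | None = None) -> pd.Series:
    """Net fluxes of all 35 reactions plus the derived qO2.

    Order matches the canonical reaction order; the specific oxygen uptake
    rate qO2 = 0.5*(v_resp + v_leak) is appended as an extra entry.
    """
    engine = FluxEngine(None, params, reg)
    conc = _check_state(state)
    net = engine.net_fluxes(conc)
    qo2 = 0.5 * (net[C.REACTION_IDS.index("resp")]
                 + net[C.REACTION_IDS.index("leak")])
    return pd.Series(np.append(net, qo2), index=C.REACTION_IDS + ["qO2"])


def directional_rates(state: StateVector, params: ParameterSet,
                      reg: RegulationConfig | None = None) -> pd.Series:
    """All 42 directional rates (forward and reverse listed separately)."""
    engine = FluxEngine(None, params, reg)
    conc = _check_state(state)
    return pd.Series(engine.rates(conc), index=C.RATE_NAMES)
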