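"""Batch-culture mass balances and their integration.

The model tracks a shake-flask batch culture over 0-144 h: viable cell
density Xv grows at the specific rate mu = v_growth, extracellular
concentrations change with s*v*Xv (converted to mM/h), intracellular pools
(per 1e6 cells) change with s*v minus a growth-dilution term where it
applies, and the antibody titer accumulates from the mAb synthesis flux.
Recombinant expression is induced at ``induction_time`` by switching the
mAb maximum rate from its leaky fraction to the full value; integration is
restarted at the induction event.

Units: fluxes mmol/(1e6 cells)/h (growth: 1/h); Xv 1e6 cells/mL;
extracellular mM; intracellular nmol/(1e6 cells); mAb mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import canonical as C
from .kinetics import FluxEngine, RegulationConfig
from .network import (NetworkDefinition, ParameterSet, StateVector,
                      build_canonical_network)


class SimulationError(RuntimeError):
    pass


DEFAULT_SAMPLE_TIMES = tuple(float(t) for t in range(0, 145, 24))


@dataclass
class CultureSchedule:
    """Design of one batch culture run."""

    t_end: float = 144.0
    induction_time: float = 48.0
    induced: bool = False
    sample_times: tuple = DEFAULT_SAMPLE_TIMES
    initial_state: StateVector = field(default_factory=StateVector)

    def __post_init__(self):
        ts = np.asarray(self.sample_times, dtype=float)
        if np.any(ts < 0) or np.any(ts > self.t_end):
            raise ValueError("sample_times must lie within [0, t_end]")
        if not 0 < self.induction_time < self.t_end:
            raise ValueError("induction_time must lie inside (0, t_end)")
        self.sample_times = tuple(float(t) for t in ts)


_DERIVED_NAMES = ("qO2", "ATP_ADP_ratio", "NADH_NAD_ratio",
                  "NADPH_NADP_ratio", "mu")


@dataclass
class Trajectory:
    """Simulated time courses of states, fluxes and derived quantities."""

    times: np.ndarray
    states: pd.DataFrame          # times x 46 species
    rates: pd.DataFrame           # times x 42 directional rates
    net_fluxes: pd.DataFrame      # times x 35 reactions
    derived: pd.DataFrame         # times x derived quantities
    schedule: CultureSchedule | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise SimulationError("trajectory times must strictly increase")

    @staticmethod
    def variable_names():
        return list(C.SPECIES_IDS) + list(_DERIVED_NAMES)

    def value(self, variable: str, times=None) -> np.ndarray:
        """Time course of a state or derived variable, optionally
        linearly interpolated onto ``times``."""
        if variable in self.states.columns:
            y = self.states[variable].to_numpy()
        elif variable in self.derived.columns:
            y = self.derived[variable].to_numpy()
        elif variable in self.net_fluxes.columns:
            y = self.net_fluxes[variable].to_numpy()
        elif variable in self.rates.columns:
            y = self.rates[variable].to_numpy()
        else:
            raise KeyError(f"unknown trajectory variable {variable!r}")
        if times is None:
            return y
        times = np.asarray(times, dtype=float)
        if times.min() < self.times[0] - 1e-9 or \
                times.max() > self.times[-1] + 1e-9:
            raise ValueError("requested times outside the trajectory span")
        return np.interp(times, self.times, y)

    def state_at(self, t: float) -> StateVector:
        vals = [np.interp(t, self.times, self.states[s].to_numpy())
                for s in C.SPECIES_IDS]
        return StateVector(vals)


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

_I_XV = C.IX["Xv"]
_I_MAB = C.IX["mAb"]
_EXT_MASK = np.array([row[2] == "extracellular" for row in C.SPECIES_TABLE])
_INT_MASK = np.array([row[2] == "intracellular" for row in C.SPECIES_TABLE])
_DIL_MASK = np.array([row[4] for row in C.SPECIES_TABLE])
_J_GROWTH = C.REACTION_IDS.index("growth")
_J_MAB = C.REACTION_IDS.index("mAb")
_J_RESP = C.REACTION_IDS.index("resp")
_J_LEAK = C.REACTION_IDS.index("leak")


def _stoich_with_params(net: NetworkDefinition,
                        params: ParameterSet) -> np.ndarray:
    """Stoichiometric matrix with parameter-dependent columns refreshed
    (growth/mAb composition vectors, P/O-coupled respiration)."""
    from .network import stoichiometric_matrix

    S = stoichiometric_matrix(net)
    idx = net.species_index()
    for j, coeffs, atp_key in ((_J_GROWTH, params.biomass_coeffs, "ATP"),
                               (_J_MAB, params.mab_coeffs, "ATP")):
        S[:, j] = 0.0
        for sp, cval in coeffs.items():
            if sp == atp_key:
                S[idx["ATP"], j] -= cval
                S[idx["ADP"], j] += cval
            else:
                S[idx[sp], j] -= cval
    S[idx["ADP"], _J_RESP] = -2.0 * params.po_ratio
    S[idx["ATP"], _J_RESP] = +2.0 * params.po_ratio
    return S


class _Rhs:
    """Mass-balance right-hand side bound to one engine and matrix."""

    def __init__(self, net, params, reg, mab_vmax_scale=1.0):
        self.engine = FluxEngine(net, params, reg,
                                 mab_vmax_scale=mab_vmax_scale)
        self.S = _stoich_with_params(net, params)

    def __call__(self, t, y):
        conc = np.maximum(y, 0.0)
        v = self.engine.net_fluxes(conc)
        if not np.all(np.isfinite(v)):
            bad = [C.REACTION_IDS[i] for i in np.where(~np.isfinite(v))[0]]
            raise SimulationError(
                f"non-finite flux in {bad} at t={t:.3f} h; state={conc}")
        mu = v[_J_GROWTH]
        xv = conc[_I_XV]
        sv = self.S @ v
        dy = np.zeros_like(y)
        dy[_I_XV] = mu * xv
        dy[_I_MAB] = v[_J_MAB] * xv * C.MAB_RATE_FACTOR
        dy[_EXT_MASK] = sv[_EXT_MASK] * xv * C.EXTRACELLULAR_RATE_FACTOR
        dy[_INT_MASK] = sv[_INT_MASK] * C.INTRACELLULAR_RATE_FACTOR
        dy[_DIL_MASK] -= mu * conc[_DIL_MASK]
        return dy


def rhs(t: float, state: StateVector, params: ParameterSet,
        net: NetworkDefinition | None = None,
        schedule: CultureSchedule | None = None,
        reg: RegulationConfig | None = None) -> np.ndarray:
    """d(state)/dt at time t (public, convenience wrapper).

    The mAb maximum rate is at its induced value when ``schedule.induced``
    and t >= induction time, otherwise at the leaky fraction.
    """
    net = net or build_canonical_network()
    schedule = schedule or CultureSchedule()
    scale = 1.0 if (schedule.induced and t >= schedule.induction_time) \
        else params.mab_leak_fraction
    return _Rhs(net, params, reg, mab_vmax_scale=scale)(
        t, np.asarray(state.values, dtype=float))


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-7, "atol": 1e-9}


def _output_grid(schedule: CultureSchedule, step: float = 1.0) -> np.ndarray:
    grid = np.arange(0.0, schedule.t_end + 0.5 * step, step)
    t = np.union1d(np.round(grid, 9), np.round(schedule.sample_times, 9))
    return t[(t >= 0) & (t <= schedule.t_end)]


def simulate_batch(net: NetworkDefinition | None,
                   params: ParameterSet,
                   schedule: CultureSchedule | None = None,
                   reg: RegulationConfig | None = None,
                   solver_opts: dict | None = None,
                   output_step: float = 1.0) -> Trajectory:
    """Integrate the batch culture and return the full trajectory.

    Deterministic for fixed inputs.  With ``schedule.induced`` the mAb
    maximum rate switches from its leaky fraction to the full value exactly
    at the induction time (integration restarts at the event).
    """
    net = net or build_canonical_network()
    schedule = schedule or CultureSchedule()
    reg = reg or RegulationConfig()
    opts = dict(DEFAULT_SOLVER_OPTS)
    opts.update(solver_opts or {})

    t_out = _output_grid(schedule, output_step)
    y0 = np.asarray(schedule.initial_state.values, dtype=float)

    legs = []
    if schedule.induced:
        legs.append((0.0, schedule.induction_time, params.mab_leak_fraction))
        legs.append((schedule.induction_time, schedule.t_end, 1.0))
    else:
        legs.append((0.0, schedule.t_end, params.mab_leak_fraction))

    times, ys = [], []
    y = y0
    for t0, t1, scale in legs:
        f = _Rhs(net, params, reg, mab_vmax_scale=scale)
        te = t_out[(t_out >= t0) & (t_out <= t1)]
        if te.size == 0 or te[0] > t0:
            te = np.insert(te, 0, t0)
        if te[-1] < t1:
            te = np.append(te, t1)
        sol = solve_ivp(f, (t0, t1), y, t_eval=te, **opts)
        if not sol.success and opts.get("method") == "LSODA":
            # LSODA occasionally gives up on hard parameterizations; BDF is
            # slower but more forgiving
            bdf = dict(opts, method="BDF")
            sol = solve_ivp(f, (t0, t1), y, t_eval=te, **bdf)
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t0:.2f} h: "
                f"{sol.message}")
        keep = slice(0, None) if not times else slice(1, None)
        times.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1]

    t = np.concatenate(times)
    Y = np.concatenate(ys, axis=1)
    # deduplicate the induction-time stitch point
    t, uniq = np.unique(np.round(t, 9), return_index=True)
    Y = Y[:, uniq]
    Y = np.maximum(Y, 0.0)

    # evaluate fluxes along the trajectory with the correct induction leg
    n = t.size
    rates = np.empty((n, len(C.RATE_NAMES)))
    engines = {}
    for k in range(n):
        scale = 1.0 if (schedule.induced and t[k] >= schedule.induction_time) \
            else params.mab_leak_fraction
        if scale not in engines:
            engines[scale] = FluxEngine(net, params, reg,
                                        mab_vmax_scale=scale)
        rates[k] = engines[scale].rates(Y[:, k])

    rates_df = pd.DataFrame(rates, index=t, columns=C.RATE_NAMES)
    net_flux = _net_from_rates(rates)
    net_df = pd.DataFrame(net_flux, index=t, columns=C.REACTION_IDS)
    states_df = pd.DataFrame(Y.T, index=t, columns=C.SPECIES_IDS)

    with np.errstate(divide="ignore", invalid="ignore"):
        derived = pd.DataFrame({
            "qO2": 0.5 * (net_df["resp"] + net_df["leak"]),
            "ATP_ADP_ratio": states_df["ATP"] / states_df["ADP"],
            "NADH_NAD_ratio": states_df["NADH"] / states_df["NAD"],
            "NADPH_NADP_ratio": states_df["NADPH"] / states_df["NADP"],
            "mu": net_df["growth"],
        }, index=t)

    return Trajectory(times=t, states=states_df, rates=rates_df,
                      net_fluxes=net_df, derived=derived, schedule=schedule)


def _net_from_rates(rates: np.ndarray) -> np.ndarray:
    from .kinetics import RATE_INDEX, _PAIR_F_IDX, _PAIR_R_IDX, _RXN_TO_NET_F

    net = rates[:, _RXN_TO_NET_F].copy()
    pair_pos = [i for i, r in enumerate(C.REACTION_IDS)
                if r in C.REVERSIBLE_PAIRS]
    net[:, pair_pos] = rates[:, _PAIR_F_IDX] - rates[:, _PAIR_R_IDX]
    return net


def specific_rates(traj: Trajectory) -> pd.DataFrame:
    """Cell-specific rates along the trajectory.

    qGlc is the hexokinase flux, qGln the net glutaminase flux (forward
    minus reverse GLNS), qLac the net lactate dehydrogenase flux, and
    qO2 = 0.5*(v_resp + v_leak); all in mmol/(1e6 cells)/h, mu in 1/h.
    """
    return pd.DataFrame({
        "qGlc": traj.net_fluxes["HK"],
        "qGln": traj.net_fluxes["GLNS"],
        "qLac": traj.net_fluxes["LDH"],
        "qO2": traj.derived["qO2"],
        "mu": traj.derived["mu"],
        "qmAb": traj.net_fluxes["mAb"],
    }, index=traj.times)
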