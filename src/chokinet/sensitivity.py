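"""Post-fit one-at-a-time sensitivity sweeps.

Parameters are varied one at a time from -85% to +300% of their (optimal)
value; for each grid point the culture is re-simulated and the WSSRES
against the observations recomputed, then normalized to the 0%-change
value so every parameter row equals exactly 1 at the optimum.  The partial
sweep restricts the objective to one measured variable; because WSSRES is
additive over variables, unnormalized per-variable maps sum to the
unnormalized global map.  Parameters whose normalized row deviates from 1
by 15% or more anywhere on the grid are classified sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import ObservationSet, wssres_by_variable
from .calibrate import _simulate
from .kinetics import RegulationConfig
from .network import NetworkDefinition, ParameterSet, build_canonical_network
from .simulate import CultureSchedule

# the sweep span is -85% .. +300%; intermediate points are a package choice
DEFAULT_GRID = (-0.85, -0.50, -0.25, -0.10, 0.0,
                0.10, 0.25, 0.50, 1.00, 2.00, 3.00)


@dataclass
class SensitivityMap:
    """Normalized WSSRES surface over (parameter, relative change)."""

    grid: tuple
    values: pd.DataFrame          # parameters x grid, normalized to 0%
    raw: pd.DataFrame             # parameters x grid, unnormalized WSSRES
    base_wssres: float
    variable: str | None = None   # None for the global map
    failures: list = field(default_factory=list)

    @property
    def parameters(self):
        return list(self.values.index)


def _sweep(obs, net, params, parameters, grid, schedule, reg, variables):
    net = net or build_canonical_network()
    schedule = schedule or CultureSchedule()
    if parameters is None:
        parameters = [f"vmax.{r}" for r in params.vmax]
    grid = tuple(float(g) for g in grid)
    if 0.0 not in grid:
        grid = tuple(sorted(grid + (0.0,)))
    cols = [f"{g:+.2f}" for g in grid]

    def objective(pset):
        traj = _simulate(net, pset, schedule, reg)
        per_var = wssres_by_variable(obs, traj, variables)
        return float(sum(per_var.values()))

    base = objective(params)
    failures = []
    raw = {}
    for name in parameters:
        row = []
        for g in grid:
            if g == 0.0:
                row.append(base)
                continue
            trial = params.with_updates({name: params.get(name) * (1.0 + g)})
            try:
                row.append(objective(trial))
            except Exception as exc:
                failures.append((name, g, str(exc)))
                row.append(np.nan)
        raw[name] = row
    raw_df = pd.DataFrame.from_dict(raw, orient="index", columns=cols)
    denom = base if base > 0 else 1.0
    values = raw_df / denom
    if base > 0:
        values[f"{0.0:+.2f}"] = raw_df[f"{0.0:+.2f}"] / base  # exactly 1
    return SensitivityMap(grid=grid, values=values, raw=raw_df,
                          base_wssres=base,
                          variable=(variables[0] if variables else None),
                          failures=failures)


def global_sweep(obs: ObservationSet,
                 net: NetworkDefinition | None,
                 params: ParameterSet,
                 parameters=None,
                 grid=DEFAULT_GRID,
                 schedule: CultureSchedule | None = None,
                 reg: RegulationConfig | None = None) -> SensitivityMap:
    """Sweep every parameter one at a time against the full WSSRES.

    Deterministic: one simulation per (parameter, grid point); a failed
    simulation is recorded in ``failures`` and leaves a NaN cell.
    ``parameters`` defaults to all 42 maximum rates.
    """
    return _sweep(obs, net, params, parameters, grid, schedule, reg, None)


def partial_sweep(obs: ObservationSet,
                  net: NetworkDefinition | None,
                  params: ParameterSet,
                  variable: str,
                  parameters=None,
                  grid=DEFAULT_GRID,
                  schedule: CultureSchedule | None = None,
                  reg: RegulationConfig | None = None) -> SensitivityMap:
    """Like :func:`global_sweep` but with WSSRES restricted to one
    measured variable (per-variable contribution map)."""
    if variable not in obs.variables:
        raise KeyError(f"variable {variable!r} is not observed")
    return _sweep(obs, net, params, parameters, grid, schedule, reg,
                  [variable])


def classify_sensitive(smap: SensitivityMap,
                       threshold: float = 0.15):
    """Partition parameters into (sensitive, insensitive).

    A parameter is sensitive iff its normalized WSSRES deviates from 1 by
    at least ``threshold`` anywhere on the grid (default +/-15%); a
    parameter with exactly zero deviation is never sensitive, so threshold
    zero flags every parameter with any nonzero influence.
    """
    dev = (smap.values - 1.0).abs().max(axis=1, skipna=True)
    sensitive = [p for p in smap.parameters
                 if dev[p] > 0 and dev[p] >= threshold]
    insensitive = [p for p in smap.parameters if p not in set(sensitive)]
    return sensitive, insensitive
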