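"""File formats: tidy CSV for time series, YAML for the model document.

Conventions: tidy long-format CSV throughout, times in hours.
Trajectories: columns (time_h, variable, value, kind) with kind in
{state, flux, derived}.  Observations: columns (time_h, variable,
replicate, value).  The model document (network + parameters) round-trips
through a single YAML file.  Every run can write a manifest JSON (seed,
configuration hash, package version) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import canonical as C
from .calibrate import ObservationSet
from .network import (NetworkDefinition, ParameterSet,
                      build_canonical_network)
from .simulate import Trajectory


class SchemaError(ValueError):
    pass


def _read_csv_strict(path, numeric_columns):
    df = pd.read_csv(path)
    for col in numeric_columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column {col!r} is not parseable as numbers "
                f"(locale-specific decimal separators are not accepted): "
                f"{exc}") from None
    return df


# --------------------------------------------------------------------------
# Observations
# --------------------------------------------------------------------------

def write_observations(obs: ObservationSet, path) -> None:
    obs.records.to_csv(path, index=False,
                       columns=list(ObservationSet.REQUIRED_COLUMNS))


def read_observations(path) -> ObservationSet:
    df = _read_csv_strict(path, ("time_h", "replicate", "value"))
    missing = [c for c in ObservationSet.REQUIRED_COLUMNS
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return ObservationSet(df[list(ObservationSet.REQUIRED_COLUMNS)])


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    frames = []
    for df, kind in ((traj.states, "state"), (traj.rates, "flux"),
                     (traj.derived, "derived")):
        tidy = df.reset_index(names="time_h").melt(
            id_vars="time_h", var_name="variable", value_name="value")
        tidy["kind"] = kind
        frames.append(tidy)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, columns=["time_h", "variable", "value",
                                           "kind"])


def read_trajectory(path) -> Trajectory:
    df = _read_csv_strict(path, ("time_h", "value"))
    for col in ("variable", "kind"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    def pivot(kind):
        sub = df[df["kind"] == kind]
        return sub.pivot(index="time_h", columns="variable",
                         values="value").sort_index()

    states = pivot("state")
    rates = pivot("flux")
    derived = pivot("derived")
    missing = set(C.SPECIES_IDS) - set(states.columns)
    if missing:
        raise SchemaError(f"{path}: missing state variables {sorted(missing)}")
    states = states[C.SPECIES_IDS]
    rates = rates[[r for r in C.RATE_NAMES if r in rates.columns]]
    from .simulate import _net_from_rates
    net_fluxes = pd.DataFrame(_net_from_rates(rates.to_numpy()),
                              index=rates.index, columns=C.REACTION_IDS)
    return Trajectory(times=states.index.to_numpy(dtype=float),
                      states=states, rates=rates, net_fluxes=net_fluxes,
                      derived=derived)


# --------------------------------------------------------------------------
# Model document (network + parameters) as YAML
# --------------------------------------------------------------------------

def model_document(net: NetworkDefinition, params: ParameterSet) -> dict:
    return {
        "species": [{"id": s.id, "name": s.name, "compartment": s.compartment,
                     "unit": s.unit, "measured": s.measured,
                     "dilution_applies": s.dilution_applies}
                    for s in net.species],
        "reactions": [{"id": r.id,
                       "stoichiometry": {k: float(v) for k, v
                                         in r.stoichiometry.items()},
                       "reversible_pair": r.reversible_pair,
                       "regulation_terms": list(r.regulation_terms),
                       "virtual_stoichiometry": {
                           k: float(v) for k, v
                           in r.virtual_stoichiometry.items()}}
                      for r in net.reactions],
        "moieties": net.moieties,
        "aa_groups": net.aa_groups,
        "parameters": {
            "vmax": {k: float(v) for k, v in params.vmax.items()},
            "affinity": {f"{r}.{s}": float(v)
                         for (r, s), v in params.affinity.items()},
            "regulatory": {k: float(v) for k, v in params.regulatory.items()},
            "po_ratio": float(params.po_ratio),
            "gln_threshold": float(params.gln_threshold),
            "gln_threshold_steepness": float(params.gln_threshold_steepness),
            "mab_leak_fraction": float(params.mab_leak_fraction),
            "biomass_coeffs": {k: float(v)
                               for k, v in params.biomass_coeffs.items()},
            "mab_coeffs": {k: float(v)
                           for k, v in params.mab_coeffs.items()},
        },
    }


def save_model(net: NetworkDefinition, params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_document(net, params), fh, sort_keys=False)


def load_model(path):
    """Load (NetworkDefinition, ParameterSet) from a model YAML document.

    The network topology is rebuilt from the bundled canonical definition
    (it is frozen); the document's parameter values override the defaults.
    A document whose species/reaction inventory disagrees with the
    canonical one is rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    net = build_canonical_network()
    got_species = [s["id"] for s in doc.get("species", [])]
    got_rxns = [r["id"] for r in doc.get("reactions", [])]
    if got_species != net.species_ids() or got_rxns != net.reaction_ids():
        raise SchemaError(f"{path}: model inventory does not match the "
                          "canonical network")
    p = doc["parameters"]
    params = ParameterSet(
        vmax={k: float(v) for k, v in p["vmax"].items()},
        affinity={tuple(k.split(".", 1)): float(v)
                  for k, v in p["affinity"].items()},
        regulatory={k: float(v) for k, v in p["regulatory"].items()},
        po_ratio=float(p.get("po_ratio", C.PO_RATIO_DEFAULT)),
        gln_threshold=float(p.get("gln_threshold", C.GLN_THRESHOLD_DEFAULT)),
        gln_threshold_steepness=float(
            p.get("gln_threshold_steepness", C.GLN_THRESHOLD_STEEPNESS)),
        mab_leak_fraction=float(p.get("mab_leak_fraction", 1.0)),
    )
    if "biomass_coeffs" in p:
        params.biomass_coeffs = {k: float(v)
                                 for k, v in p["biomass_coeffs"].items()}
    if "mab_coeffs" in p:
        params.mab_coeffs = {k: float(v) for k, v in p["mab_coeffs"].items()}
    return net, params


# --------------------------------------------------------------------------
# Run manifests
# --------------------------------------------------------------------------

def write_manifest(path, config: dict, seed=None) -> dict:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "chokinet",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
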