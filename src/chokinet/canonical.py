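"""Canonical CHO-cell metabolic network: frozen machine-readable definition.

This module is the single source of truth for the bundled batch-culture
model: 46 state variables, 35 reactions (7 of them reversible pairs with
separate forward/reverse maximum rates, giving 42 vmax parameters),
48 affinity constants and 5 regulatory constants (95 kinetic parameters
in total).

The network covers glycolysis, the oxidative pentose phosphate branch,
the TCA cycle, glutaminolysis, lumped amino-acid catabolism (three groups
entering the TCA cycle via pyruvate-adjacent, glutamate/alpha-ketoglutarate
and succinate nodes, plus the asparagine/aspartate pair entering at
oxaloacetate), oxidative phosphorylation with a separate proton-leak
reaction, creatine/adenylate buffering, and lumped growth and monoclonal-
antibody synthesis reactions.

Exact published parameter tables for this cell line are not available;
the numeric defaults below are reconstructed order-of-magnitude values,
calibrated once so that the reference culture reproduces the canonical
qualitative behaviour of CHO shake-flask batch culture (glucose never
depleted, glutamine depleted around 96 h, growth arrest at glutamine
depletion, ATP/ADP ~ 10, NADH/NAD in 0.03-0.07, ~15% of oxygen uptake
uncoupled from ATP synthesis). They are labelled reconstructed defaults.

Sign convention: a positive flux runs in the direction written here
(the arrow direction of the network diagram); net fluxes of reversible
pairs may be negative.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Species inventory (46 states)
# --------------------------------------------------------------------------
# compartment -> unit:
#   culture        Xv: 1e6 cells/mL, mAb: mg/L
#   extracellular  mM
#   intracellular  nmol/(1e6 cells)

AMINO_ACIDS_EXT = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU_x", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# (id, name, compartment, measured, dilution_applies)
SPECIES_TABLE = [
    ("Xv", "viable cell density", "culture", True, False),
    ("mAb", "monoclonal antibody titer", "culture", True, False),
    # extracellular
    ("GLC", "glucose", "extracellular", True, False),
    ("LAC", "lactate", "extracellular", True, False),
    ("NH4", "ammonium", "extracellular", True, False),
    ("ALA", "alanine", "extracellular", True, False),
    ("ARG", "arginine", "extracellular", False, False),
    ("ASN", "asparagine", "extracellular", True, False),
    ("ASP", "aspartate", "extracellular", True, False),
    ("CYS", "cysteine", "extracellular", False, False),
    ("GLN", "glutamine", "extracellular", True, False),
    ("GLU_x", "glutamate (extracellular)", "extracellular", True, False),
    ("GLY", "glycine", "extracellular", False, False),
    ("HIS", "histidine", "extracellular", False, False),
    ("ILE", "isoleucine", "extracellular", False, False),
    ("LEU", "leucine", "extracellular", False, False),
    ("LYS", "lysine", "extracellular", False, False),
    ("MET", "methionine", "extracellular", False, False),
    ("PHE", "phenylalanine", "extracellular", False, False),
    ("PRO", "proline", "extracellular", False, False),
    ("SER", "serine", "extracellular", True, False),
    ("THR", "threonine", "extracellular", False, False),
    ("TRP", "tryptophan", "extracellular", False, False),
    ("TYR", "tyrosine", "extracellular", False, False),
    ("VAL", "valine", "extracellular", False, False),
    # intracellular
    ("G6P", "glucose 6-phosphate", "intracellular", True, True),
    ("F6P", "fructose 6-phosphate", "intracellular", False, True),
    ("GAP", "glyceraldehyde 3-phosphate", "intracellular", False, True),
    ("PEP", "phosphoenolpyruvate", "intracellular", True, True),
    ("PYR", "pyruvate", "intracellular", True, True),
    ("R5P", "ribose 5-phosphate", "intracellular", False, True),
    ("ACCOA", "acetyl-CoA", "intracellular", False, True),
    ("CIT", "citrate", "intracellular", False, True),
    ("AKG", "alpha-ketoglutarate", "intracellular", True, True),
    ("SUC", "succinate", "intracellular", True, True),
    ("MAL", "malate", "intracellular", True, True),
    ("OAA", "oxaloacetate", "intracellular", False, True),
    ("GLU", "glutamate (intracellular)", "intracellular", False, True),
    ("ATP", "ATP", "intracellular", True, False),
    ("ADP", "ADP", "intracellular", True, False),
    ("AMP", "AMP", "intracellular", True, False),
    ("NAD", "NAD+", "intracellular", True, False),
    ("NADH", "NADH", "intracellular", True, False),
    ("NADP", "NADP+", "intracellular", True, False),
    ("NADPH", "NADPH", "intracellular", True, False),
    ("PCR", "phosphocreatine", "intracellular", False, False),
]

SPECIES_IDS = [row[0] for row in SPECIES_TABLE]
IX = {sid: i for i, sid in enumerate(SPECIES_IDS)}

COMPARTMENT_UNITS = {
    "culture": {"Xv": "1e6 cells/mL", "mAb": "mg/L"},
    "extracellular": "mM",
    "intracellular": "nmol/(1e6 cells)",
}

# conserved creatine moiety: CR is derived, not a state
CREATINE_TOTAL = 14.0  # nmol/(1e6 cells); CR = CREATINE_TOTAL - PCR

MOIETIES = {
    "adenylate": ["ATP", "ADP", "AMP"],
    "nad": ["NAD", "NADH"],
    "nadp": ["NADP", "NADPH"],
    "creatine": ["PCR", "CR"],  # CR is virtual (conserved total)
}

# amino-acid catabolic groups; every amino acid except GLN and GLU_x
# belongs to exactly one group.  ALA enters pyruvate via reverse AlaTA.
AA_GROUPS = {
    "PYR": ["ALA", "SER", "GLY", "THR", "CYS", "TRP"],
    "GLU": ["HIS", "ARG", "PRO"],
    "SUC": ["LYS", "ILE", "LEU", "VAL", "TYR", "MET", "PHE"],
    "OAA": ["ASN", "ASP"],
}

# pooled concentrations used by the lumped transaminases (SAL handles SER,
# reverse AlaTA handles ALA, so the minor-PYR pool excludes them)
KINETIC_POOLS = {
    "aa_pyr_minor": ["GLY", "THR", "CYS", "TRP"],
    "aa_glu": ["HIS", "ARG", "PRO"],
    "aa_suc": ["LYS", "ILE", "LEU", "VAL", "TYR", "MET", "PHE"],
}

# amino acids drawn on by biomass and mAb synthesis kinetics (extracellular,
# all except glutamine which has its own affinity constant; glutamate is
# drawn from the intracellular pool and assumed non-limiting)
GROWTH_AA = [a for a in AMINO_ACIDS_EXT if a not in ("GLN", "GLU_x")]

# --------------------------------------------------------------------------
# Reactions (35) -- net stoichiometry on the 46 states
# --------------------------------------------------------------------------
REVERSIBLE_PAIRS = ["LDH", "GLNS", "GLDH", "AlaTA", "ASTA", "CK", "AK"]

# ATP yield of respiration per NADH oxidized is 2*(P/O); qO2 = 0.5*(resp+leak)
PO_RATIO_DEFAULT = 1.25

# biomass precursor stoichiometry, mmol per 1e6 cells of new biomass;
# the ATP coefficient 0.00043*3.78 is the growth energy-demand constant
# used by the ATP-partitioning biomarker.  Scarce residues (Cys, Trp, Met,
# His) carry smaller coefficients, reflecting their low protein abundance.
BIOMASS_ATP_COEFF = 0.00043 * 3.78
_SCARCE_AA = ("CYS", "TRP", "MET", "HIS")
BIOMASS_COEFFS = {
    "G6P": 1.0e-4,
    "R5P": 5.0e-5,
    "GLN": 2.0e-4,
    "GLU": 8.0e-5,           # intracellular glutamate
    **{a: (2.0e-5 if a in _SCARCE_AA else 8.0e-5) for a in GROWTH_AA},
    "ATP": BIOMASS_ATP_COEFF,
}

# mAb synthesis: flux is on a per-residue basis; 4 ATP per unit flux
MAB_ATP_COEFF = 4.0
MAB_COEFFS = {
    "GLN": 0.05,
    "GLU": 0.05,
    **{a: 0.05 for a in GROWTH_AA},
    "ATP": MAB_ATP_COEFF,
}

MAB_RESIDUE_MW = 150.0  # g/mol, average residue mass (per-residue flux basis)


def _growth_stoich() -> dict:
    st = {}
    for sp, c in BIOMASS_COEFFS.items():
        if sp == "ATP":
            st["ATP"] = -c
            st["ADP"] = +c
        else:
            st[sp] = st.get(sp, 0.0) - c
    return st


def _mab_stoich() -> dict:
    st = {}
    for sp, c in MAB_COEFFS.items():
        if sp == "ATP":
            st["ATP"] = -c
            st["ADP"] = +c
        else:
            st[sp] = st.get(sp, 0.0) - c
    return st


# reaction id -> net stoichiometry {species: coeff}; order is canonical
REACTION_STOICH = {
    "HK": {"GLC": -1, "G6P": +1, "ATP": -1, "ADP": +1},
    "PGI": {"G6P": -1, "F6P": +1},
    "PFK": {"F6P": -1, "GAP": +2, "ATP": -1, "ADP": +1},
    "PGK": {"GAP": -1, "PEP": +1, "NAD": -1, "NADH": +1, "ADP": -1, "ATP": +1},
    "PK": {"PEP": -1, "PYR": +1, "ADP": -1, "ATP": +1},
    "LDH": {"PYR": -1, "LAC": +1, "NADH": -1, "NAD": +1},
    "G6PDH": {"G6P": -1, "R5P": +1, "NADP": -2, "NADPH": +2},
    "EP": {"R5P": -1, "F6P": 2.0 / 3.0, "GAP": 1.0 / 3.0},
    "PDH": {"PYR": -1, "ACCOA": +1, "NAD": -1, "NADH": +1},
    "CS": {"ACCOA": -1, "OAA": -1, "CIT": +1},
    "CITS": {"CIT": -1, "AKG": +1, "NAD": -1, "NADH": +1},
    "AKGDH": {"AKG": -1, "SUC": +1, "NAD": -1, "NADH": +1},
    # succinyl-CoA is lumped out: SCOAS carries the substrate-level
    # phosphorylation, kinetically driven by the succinate pool
    "SCOAS": {"ADP": -1, "ATP": +1},
    "SDHFUM": {"SUC": -1, "MAL": +1, "NAD": -1, "NADH": +1},
    "MLD": {"MAL": -1, "OAA": +1, "NAD": -1, "NADH": +1},
    "PC": {"PYR": -1, "OAA": +1, "ATP": -1, "ADP": +1},
    "ME": {"MAL": -1, "PYR": +1, "NADP": -1, "NADPH": +1},
    # glutaminase direction forward; glutamine-synthetase direction reverse
    # (its ATP requirement is ratio-driven kinetically, lumped into ATPase
    # stoichiometrically)
    "GLNS": {"GLN": -1, "GLU": +1, "NH4": +1},
    "GLDH": {"GLU": -1, "AKG": +1, "NH4": +1, "NAD": -1, "NADH": +1},
    "AlaTA": {"PYR": -1, "GLU": -1, "ALA": +1, "AKG": +1},
    "ASTA": {"ASP": -1, "AKG": -1, "OAA": +1, "GLU": +1},
    "ASX": {"ASN": -1, "ASP": +1, "NH4": +1},
    "GluT": {"GLU": -1, "GLU_x": +1},
    "SAL": {"SER": -1, "PYR": +1, "NH4": +1},
    "AAPYRTA": {"GLY": -0.4, "THR": -0.4, "CYS": -0.1, "TRP": -0.1,
                "PYR": +1, "NH4": +1},
    "HISARGTA": {"HIS": -1.0 / 3.0, "ARG": -1.0 / 3.0, "PRO": -1.0 / 3.0,
                 "GLU": +1, "NH4": +1},
    "LYSILELEUVALTYRTA": {**{a: -1.0 / 7.0 for a in AA_GROUPS["SUC"]},
                          "SUC": +1, "NH4": +1},
    "resp": {"NADH": -1, "NAD": +1,
             "ADP": -2 * PO_RATIO_DEFAULT, "ATP": +2 * PO_RATIO_DEFAULT},
    "leak": {"NADH": -1, "NAD": +1},
    "ATPase": {"ATP": -1, "ADP": +1},
    "NADPHox": {"NADPH": -1, "NADP": +1},
    "CK": {"PCR": -1, "ADP": -1, "ATP": +1},
    "AK": {"ADP": -2, "ATP": +1, "AMP": +1},
    "growth": _growth_stoich(),
    "mAb": _mab_stoich(),
}

REACTION_IDS = list(REACTION_STOICH)

# virtual stoichiometry entries (species outside the 46 states) used only
# by the moiety-closure validator
REACTION_VIRTUAL_STOICH = {"CK": {"CR": +1}}

# alias recorded for the glutamine transport/synthetase naming ambiguity
REACTION_ALIASES = {"GlnT": "GLNS"}

# directional rate slots (42): forward for every reaction, reverse appended
# immediately after for the reversible pairs
RATE_NAMES = []
for rid in REACTION_IDS:
    if rid in REVERSIBLE_PAIRS:
        RATE_NAMES.append(rid + "_f")
        RATE_NAMES.append(rid + "_r")
    else:
        RATE_NAMES.append(rid)
assert len(RATE_NAMES) == 42

# --------------------------------------------------------------------------
# Kinetic wiring
# --------------------------------------------------------------------------
# Each directional rate is vmax times a product of hyperbolic factors:
#   ("sat", species, km_key)        c/(Km+c) substrate saturation
#   ("satCR",)                      saturation on the derived creatine pool
#   ("pool", pool_name, km_key)     saturation on a summed amino-acid pool
#   ("ratio", num, den, km_key)     r/(K+r) with r = c_num/c_den, K fitted
#   ("refratio", num, den)          r/(r0+r) with r0 a fixed homeostatic
#                                   reference ratio (structural constant)
#   ("aaprod", km_key)              product of saturations over GROWTH_AA
#                                   with one shared affinity constant
#   ("thresh",)                     low-glutamine threshold sigmoid
# Regulation terms I-V are attached separately (REGULATION_TERMS) and are
# multiplied in only when enabled.
# PGI and MLD use a reversible form with a single vmax:
#   v = vmax * (fwd_product - back_coeff * back_product)

REF_RATIOS = {
    ("ATP", "ADP"): 10.0,
    ("ADP", "ATP"): 0.1,
    ("NAD", "NADH"): 20.0,
    ("NADH", "NAD"): 0.05,
    ("NADP", "NADPH"): 0.5,
    ("NADPH", "NADP"): 2.0,
}

RATE_KINETICS = {
    "HK": [("sat", "GLC", ("HK", "GLC")), ("refratio", "ATP", "ADP")],
    "PGI": {"forward": [("sat", "G6P", ("PGI", "G6P"))],
            "back": [("sat", "F6P", ("PGI", "F6P"))],
            "back_coeff": 0.5},
    "PFK": [("sat", "F6P", ("PFK", "F6P"))],
    "PGK": [("sat", "GAP", ("PGK", "GAP")),
            ("refratio", "NAD", "NADH"), ("refratio", "ADP", "ATP")],
    "PK": [("sat", "PEP", ("PK", "PEP")), ("refratio", "ADP", "ATP")],
    "LDH_f": [("sat", "PYR", ("LDH", "PYR")), ("refratio", "NADH", "NAD")],
    "LDH_r": [("sat", "LAC", ("LDH", "LAC")), ("refratio", "NAD", "NADH")],
    "G6PDH": [("sat", "G6P", ("G6PDH", "G6P")),
              ("refratio", "NADP", "NADPH")],
    "EP": [("sat", "R5P", ("EP", "R5P"))],
    "PDH": [("sat", "PYR", ("PDH", "PYR")), ("refratio", "NAD", "NADH")],
    "CS": [("sat", "ACCOA", ("CS", "ACCOA")), ("sat", "OAA", ("CS", "OAA"))],
    "CITS": [("sat", "CIT", ("CITS", "CIT")), ("refratio", "NAD", "NADH")],
    "AKGDH": [("sat", "AKG", ("AKGDH", "AKG")), ("refratio", "NAD", "NADH")],
    "SCOAS": [("sat", "SUC", ("SCOAS", "SUC")), ("refratio", "ADP", "ATP")],
    "SDHFUM": [("sat", "SUC", ("SDHFUM", "SUC")),
               ("refratio", "NAD", "NADH")],
    "MLD": {"forward": [("sat", "MAL", ("MLD", "MAL")),
                        ("refratio", "NAD", "NADH")],
            "back": [("sat", "OAA", ("MLD", "OAA")),
                     ("refratio", "NADH", "NAD")],
            "back_coeff": 0.5},
    "PC": [("sat", "PYR", ("PC", "PYR")), ("refratio", "ATP", "ADP")],
    "ME": [("sat", "MAL", ("ME", "MAL")), ("refratio", "NADP", "NADPH")],
    "GLNS_f": [("sat", "GLN", ("GLNS", "GLN"))],
    "GLNS_r": [("sat", "GLU", ("GLNS", "GLU")), ("refratio", "ATP", "ADP")],
    "GLDH_f": [("sat", "GLU", ("GLDH", "GLU")), ("refratio", "NAD", "NADH")],
    "GLDH_r": [("sat", "AKG", ("GLDH", "AKG")), ("sat", "NH4", ("GLDH", "NH4")),
               ("refratio", "NADH", "NAD")],
    "AlaTA_f": [("sat", "PYR", ("AlaTA", "PYR"))],
    "AlaTA_r": [("sat", "ALA", ("AlaTA", "ALA")), ("thresh",)],
    "ASTA_f": [("sat", "ASP", ("ASTA", "ASP"))],
    "ASTA_r": [("sat", "OAA", ("ASTA", "OAA"))],
    "ASX": [("sat", "ASN", ("ASX", "ASN"))],
    "GluT": [("sat", "GLU", ("GluT", "GLU"))],
    "SAL": [("sat", "SER", ("SAL", "SER"))],
    "AAPYRTA": [("pool", "aa_pyr_minor", ("AAPYRTA", "pool"))],
    "HISARGTA": [("pool", "aa_glu", ("HISARGTA", "pool"))],
    "LYSILELEUVALTYRTA": [("pool", "aa_suc", ("LYSILELEUVALTYRTA", "pool"))],
    "resp": [("ratio", "NADH", "NAD", ("resp", "NADH")),
             ("ratio", "ADP", "ATP", ("resp", "ADP"))],
    "leak": [("refratio", "NADH", "NAD")],
    "ATPase": [("ratio", "ATP", "ADP", ("ATPase", "ATP"))],
    "NADPHox": [("refratio", "NADPH", "NADP")],
    "CK_f": [("sat", "PCR", ("CK", "PCR")), ("refratio", "ADP", "ATP")],
    "CK_r": [("satCR", ("CK", "CR")), ("refratio", "ATP", "ADP")],
    "AK_f": [("sat", "ADP", ("AK", "ADP"))],
    "AK_r": [("sat", "AMP", ("AK", "AMP")), ("refratio", "ATP", "ADP")],
    "growth": [("sat", "GLN", ("growth", "GLN")),
               ("sat", "G6P", ("growth", "G6P")),
               ("sat", "R5P", ("growth", "R5P")),
               ("aaprod", ("growth", "AA")),
               ("refratio", "ATP", "ADP")],
    "mAb": [("aaprod", ("mAb", "AA")), ("refratio", "ATP", "ADP")],
}

# Regulation terms I-V: (kind, target rate slot(s), effector, constant name)
# I   hexokinase inhibition by its product G6P
# II  phosphoglucose isomerase inhibition by PEP (applied to the net rate)
# III phosphofructokinase inhibition by G6P
# IV  pyruvate kinase activation by F6P
# V   lactate dehydrogenase forward-reaction inhibition by lactate
REGULATION_TERMS = {
    "I": {"kind": "inhibition", "targets": ["HK"], "effector": "G6P",
          "constant": "ki_hk_g6p"},
    "II": {"kind": "inhibition", "targets": ["PGI", "PGI__back"],
           "effector": "PEP", "constant": "ki_pgi_pep"},
    "III": {"kind": "inhibition", "targets": ["PFK"], "effector": "G6P",
            "constant": "ki_pfk_g6p"},
    "IV": {"kind": "activation", "targets": ["PK"], "effector": "F6P",
           "constant": "ka_pk_f6p"},
    "V": {"kind": "inhibition", "targets": ["LDH_f"], "effector": "LAC",
          "constant": "ki_ldhf_lac"},
}

REGULATION_SCENARIOS = {
    "none": frozenset(),
    "I": frozenset({"I"}),
    "I+II": frozenset({"I", "II"}),
    "all": frozenset({"I", "II", "III", "IV", "V"}),
}

# --------------------------------------------------------------------------
# Default parameter values (reconstructed)
# --------------------------------------------------------------------------
# maximum rates, mmol/(1e6 cells)/h (growth: 1/h)
VMAX_DEFAULTS = {
    "HK": 2.0e-4,
    "PGI": 4.5e-4,
    "PFK": 2.1e-4,
    "PGK": 1.16e-3,
    "PK": 5.8e-4,
    "LDH_f": 3.4e-4,
    "LDH_r": 4.0e-5,
    "G6PDH": 3.0e-5,
    "EP": 4.0e-6,
    "PDH": 1.6e-4,
    "CS": 2.6e-4,
    "CITS": 1.7e-4,
    "AKGDH": 1.8e-4,
    "SCOAS": 1.8e-4,
    "SDHFUM": 2.0e-4,
    "MLD": 3.0e-4,
    "PC": 2.0e-6,
    "ME": 8.0e-5,
    "GLNS_f": 3.3e-5,
    "GLNS_r": 8.0e-6,
    "GLDH_f": 2.0e-5,
    "GLDH_r": 1.4e-5,
    "AlaTA_f": 2.6e-5,
    "AlaTA_r": 3.0e-5,
    "ASTA_f": 3.0e-6,
    "ASTA_r": 2.0e-6,
    "ASX": 1.0e-6,
    "GluT": 1.0e-5,
    "SAL": 3.0e-6,
    "AAPYRTA": 1.5e-6,
    "HISARGTA": 2.2e-6,
    "LYSILELEUVALTYRTA": 3.0e-6,
    "resp": 9.6e-4,
    "leak": 8.4e-5,
    "ATPase": 1.46e-3,
    "NADPHox": 2.6e-5,
    "CK_f": 8.0e-5,
    "CK_r": 8.0e-5,
    "AK_f": 1.0e-5,
    "AK_r": 1.0e-5,
    "growth": 0.135,
    "mAb": 2.0e-6,
}

# affinity constants, keyed (reaction, species-or-pool); units follow the
# compartment of the species (mM extracellular, nmol/(1e6 cells)
# intracellular); the three *_ratio-style entries (resp, ATPase) are
# dimensionless constants on nucleotide ratios
AFFINITY_DEFAULTS = {
    ("HK", "GLC"): 1.0,
    ("PGI", "G6P"): 1.0,
    ("PGI", "F6P"): 0.5,
    ("PFK", "F6P"): 0.3,
    ("PGK", "GAP"): 0.3,
    ("PK", "PEP"): 0.3,
    ("LDH", "PYR"): 1.0,
    ("LDH", "LAC"): 10.0,
    ("G6PDH", "G6P"): 1.0,
    ("EP", "R5P"): 0.2,
    ("PDH", "PYR"): 1.0,
    ("CS", "ACCOA"): 0.5,
    ("CS", "OAA"): 0.5,
    ("CITS", "CIT"): 1.0,
    ("AKGDH", "AKG"): 0.5,
    ("SCOAS", "SUC"): 0.5,
    ("SDHFUM", "SUC"): 0.5,
    ("MLD", "MAL"): 10.0,
    ("MLD", "OAA"): 5.0,
    ("PC", "PYR"): 1.0,
    ("ME", "MAL"): 10.0,
    ("GLNS", "GLN"): 0.3,
    ("GLNS", "GLU"): 20.0,
    ("GLDH", "GLU"): 20.0,
    ("GLDH", "AKG"): 0.5,
    ("GLDH", "NH4"): 1.0,
    ("AlaTA", "PYR"): 1.0,
    ("AlaTA", "ALA"): 1.0,
    ("ASTA", "ASP"): 0.2,
    ("ASTA", "OAA"): 0.05,
    ("ASX", "ASN"): 0.3,
    ("GluT", "GLU"): 20.0,
    ("SAL", "SER"): 0.5,
    ("AAPYRTA", "pool"): 1.0,
    ("HISARGTA", "pool"): 1.0,
    ("LYSILELEUVALTYRTA", "pool"): 2.0,
    ("CK", "PCR"): 10.0,
    ("CK", "CR"): 4.0,
    ("AK", "ADP"): 1.2,
    ("AK", "AMP"): 0.4,
    ("growth", "GLN"): 0.15,
    ("growth", "G6P"): 0.1,
    ("growth", "R5P"): 0.01,
    ("growth", "AA"): 0.005,
    ("mAb", "AA"): 0.005,
    ("resp", "NADH"): 0.05,
    ("resp", "ADP"): 0.1,
    ("ATPase", "ATP"): 10.0,
}

# regulatory constants (one per regulation term)
REGULATORY_DEFAULTS = {
    "ki_hk_g6p": 1.0,
    "ki_pgi_pep": 0.3,
    "ki_pfk_g6p": 2.0,
    "ka_pk_f6p": 0.3,
    "ki_ldhf_lac": 20.0,
}

GLN_THRESHOLD_DEFAULT = 0.3       # mM extracellular glutamine
GLN_THRESHOLD_STEEPNESS = 4.0     # Hill exponent of the threshold sigmoid

# --------------------------------------------------------------------------
# Initial conditions of the reference shake-flask culture
# --------------------------------------------------------------------------
INITIAL_STATE = {
    "Xv": 0.2,      # seeded at 2e5 cells/mL
    "mAb": 0.0,
    "GLC": 30.0,    # medium glucose
    "LAC": 0.5,
    "NH4": 0.5,
    "ALA": 0.5,
    "ARG": 1.0,
    "ASN": 1.0,
    "ASP": 0.5,
    "CYS": 0.4,
    "GLN": 4.0,     # supplemented glutamine
    "GLU_x": 0.5,
    "GLY": 0.8,
    "HIS": 0.4,
    "ILE": 0.8,
    "LEU": 1.0,
    "LYS": 1.0,
    "MET": 0.3,
    "PHE": 0.8,
    "PRO": 0.6,
    "SER": 1.0,
    "THR": 0.8,
    "TRP": 0.3,
    "TYR": 0.8,
    "VAL": 0.8,
    "G6P": 1.0,
    "F6P": 0.3,
    "GAP": 0.3,
    "PEP": 0.3,
    "PYR": 1.0,
    "R5P": 0.2,
    "ACCOA": 0.5,
    "CIT": 1.0,
    "AKG": 0.5,
    "SUC": 0.5,
    "MAL": 1.0,
    "OAA": 0.05,
    "GLU": 20.0,
    "ATP": 12.0,
    "ADP": 1.2,
    "AMP": 0.4,
    "NAD": 10.0,
    "NADH": 0.5,
    "NADP": 0.03,
    "NADPH": 0.06,
    "PCR": 10.0,
}

# unit conversion factors used by the mass balances
EXTRACELLULAR_RATE_FACTOR = 1000.0   # mmol/mL/h -> mM/h
INTRACELLULAR_RATE_FACTOR = 1.0e6    # mmol -> nmol, per 1e6 cells
MAB_RATE_FACTOR = MAB_RESIDUE_MW * 1000.0  # residue flux -> mg/L/h
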