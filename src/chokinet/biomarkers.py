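"""Metabolic flux-ratio biomarkers for clone and induction comparison.

All quantities are pure functions of the directional flux vector (and a
few named constants), evaluated per time point:

* lactate production-to-glucose consumption ratio
  (vf(LDH) - vr(LDH)) / v(HK)
* pyruvate branch point: (v(PDH) + v(PC)) divided by the total inflow into
  the pyruvate pool (positive inflows among PK, SAL, the minor
  pyruvate-group transaminase, ME, and reverse AlaTA)
* percentage of pyruvate derived from glucose
* contributions of glucose / glutamine / other amino acids / pyruvate
  carboxylase to the TCA cycle: each entry flux (PDH, GLDH, ASTA +
  succinate-group transaminase, PC) over their clamped sum
* TCA cycle flux, v(SDH/FUM)
* specific glutamine uptake rate, vf(GLNS) - vr(GLNS)
* ATP turnover rate:
  v(PGK) + v(PK) + v(SCOAS) + vr(GlnT) + vf(CK) + vr(AK) + 2*(P/O)*v(resp)
* ATP partitioning: 100*0.00043*3.78*v(growth)/turnover for biomass and
  100*4*v(mAb)/turnover for antibody synthesis

Entry fluxes that run backwards (e.g. glutamate dehydrogenase producing
glutamate) are clamped to zero, so contribution fractions stay in [0, 1].
Undefined ratios (zero denominators) are reported as missing (NaN), never
infinite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import canonical as C
from .simulate import Trajectory

BIOMASS_ATP_PER_GROWTH = C.BIOMASS_ATP_COEFF      # 0.00043 * 3.78
MAB_ATP_PER_FLUX = C.MAB_ATP_COEFF                # 4


def _get(fluxes, key):
    v = fluxes[key]
    return float(v) if np.isscalar(v) or isinstance(v, (int, float)) else v


def lactate_glucose_ratio(fluxes) -> float:
    """(vf(LDH) - vr(LDH)) / v(HK); negative under net lactate uptake."""
    hk = _get(fluxes, "HK")
    if hk == 0:
        return float("nan")
    return (_get(fluxes, "LDH_f") - _get(fluxes, "LDH_r")) / hk


def pyruvate_branch_point(fluxes) -> float:
    """(v(PDH)+v(PC)) over the summed positive inflows to pyruvate.

    Inflows considered: PK, SAL, the minor pyruvate-group transaminase,
    malic enzyme, and reverse alanine transaminase; outflows (negative
    values) never enter the denominator.
    """
    inflow = (max(_get(fluxes, "PK"), 0.0)
              + max(_get(fluxes, "SAL"), 0.0)
              + max(_get(fluxes, "AAPYRTA"), 0.0)
              + max(_get(fluxes, "ME"), 0.0)
              + max(-(_get(fluxes, "AlaTA_f") - _get(fluxes, "AlaTA_r")), 0.0))
    if inflow <= 0:
        return float("nan")
    return (max(_get(fluxes, "PDH"), 0.0) + max(_get(fluxes, "PC"), 0.0)) \
        / inflow


def pct_pyruvate_from_glucose(fluxes) -> float:
    """Percentage of the pyruvate inflow supplied by glycolysis (PK)."""
    pk = max(_get(fluxes, "PK"), 0.0)
    inflow = (pk + max(_get(fluxes, "SAL"), 0.0)
              + max(_get(fluxes, "AAPYRTA"), 0.0)
              + max(_get(fluxes, "ME"), 0.0)
              + max(-(_get(fluxes, "AlaTA_f") - _get(fluxes, "AlaTA_r")), 0.0))
    if inflow <= 0:
        return float("nan")
    return 100.0 * pk / inflow


def tca_contributions(fluxes):
    """(glucose, glutamine, other amino acids, PC) fractions of TCA entry.

    Entry fluxes are PDH (glucose), net GLDH (glutamine via glutamate), the
    succinate-group transaminase plus net ASTA (other amino acids) and PC;
    negative entries are clamped to zero, so the four fractions are in
    [0, 1] and sum to 1 whenever the total is positive.
    """
    pdh = max(_get(fluxes, "PDH"), 0.0)
    gldh = max(_get(fluxes, "GLDH_f") - _get(fluxes, "GLDH_r"), 0.0)
    asta = max(_get(fluxes, "ASTA_f") - _get(fluxes, "ASTA_r"), 0.0)
    lys = max(_get(fluxes, "LYSILELEUVALTYRTA"), 0.0)
    pc = max(_get(fluxes, "PC"), 0.0)
    total = pdh + gldh + asta + lys + pc
    if total <= 0:
        return (float("nan"),) * 4
    return (pdh / total, gldh / total, (lys + asta) / total, pc / total)


def atp_turnover(fluxes, po_ratio: float = C.PO_RATIO_DEFAULT) -> float:
    """ATP production rate summed over the phosphorylating reactions.

    v(PGK) + v(PK) + v(SCOAS) + vr(GlnT) + vf(CK) + vr(AK)
    + 2*(P/O)*v(resp); each ATP-forming term is clamped at zero from
    below (vr(GlnT) is the reverse glutamine-synthetase flux).
    """
    terms = [_get(fluxes, "PGK"), _get(fluxes, "PK"), _get(fluxes, "SCOAS"),
             _get(fluxes, "GLNS_r"), _get(fluxes, "CK_f"),
             _get(fluxes, "AK_r")]
    return float(sum(max(v, 0.0) for v in terms)
                 + 2.0 * po_ratio * max(_get(fluxes, "resp"), 0.0))


def atp_partition(fluxes, turnover: float | None = None,
                  po_ratio: float = C.PO_RATIO_DEFAULT):
    """Percentages of ATP turnover spent on biomass and on mAb synthesis.

    biomass share = 100 * 0.00043 * 3.78 * v(growth) / turnover
    mAb share     = 100 * 4 * v(mAb) / turnover
    """
    if turnover is None:
        turnover = atp_turnover(fluxes, po_ratio)
    if not turnover > 0:
        return float("nan"), float("nan")
    biomass = 100.0 * BIOMASS_ATP_PER_GROWTH * _get(fluxes, "growth") \
        / turnover
    mab = 100.0 * MAB_ATP_PER_FLUX * _get(fluxes, "mAb") / turnover
    return biomass, mab


PANEL_COLUMNS = ["lac_glc_ratio", "pyr_branch_point", "pct_pyr_from_glc",
                 "contrib_glc_tca", "contrib_gln_tca", "contrib_other_aa_tca",
                 "contrib_pc_tca", "tca_flux", "gln_uptake", "atp_turnover",
                 "pct_atp_biomass", "pct_atp_mab",
                 "q_glc", "q_pk", "mu", "q_mab"]


def biomarker_panel(traj: Trajectory,
                    po_ratio: float = C.PO_RATIO_DEFAULT,
                    times=None) -> pd.DataFrame:
    """Evaluate the full biomarker panel along a trajectory.

    One row per time point (defaults to the schedule's sample times when
    available, else all trajectory times); pure function of the stored
    fluxes, so recomputation from a stored trajectory is bit-identical.
    """
    if times is None:
        times = (list(traj.schedule.sample_times)
                 if traj.schedule is not None else list(traj.times))
    times = np.asarray(times, dtype=float)

    rows = []
    for t in times:
        fx = {name: float(np.interp(t, traj.times, traj.rates[name]))
              for name in traj.rates.columns}
        # net conveniences for the single-direction reactions
        for rid in ("HK", "PK", "PGK", "PDH", "PC", "ME", "SAL", "AAPYRTA",
                    "LYSILELEUVALTYRTA", "SDHFUM", "SCOAS", "resp", "leak",
                    "growth", "mAb"):
            fx[rid] = fx.get(rid, fx.get(rid + "_f", 0.0))
        glc, gln, other, pc = tca_contributions(fx)
        turn = atp_turnover(fx, po_ratio)
        b_share, m_share = atp_partition(fx, turn)
        rows.append({
            "time_h": t,
            "lac_glc_ratio": lactate_glucose_ratio(fx),
            "pyr_branch_point": pyruvate_branch_point(fx),
            "pct_pyr_from_glc": pct_pyruvate_from_glucose(fx),
            "contrib_glc_tca": glc,
            "contrib_gln_tca": gln,
            "contrib_other_aa_tca": other,
            "contrib_pc_tca": pc,
            "tca_flux": fx["SDHFUM"],
            "gln_uptake": fx["GLNS_f"] - fx["GLNS_r"],
            "atp_turnover": turn,
            "pct_atp_biomass": b_share,
            "pct_atp_mab": m_share,
            "q_glc": fx["HK"],
            "q_pk": fx["PK"],
            "mu": fx["growth"],
            "q_mab": fx["mAb"],
        })
    return pd.DataFrame(rows).set_index("time_h")


def induction_ratio_panel(traj_induced: Trajectory,
                          traj_control: Trajectory,
                          po_ratio: float = C.PO_RATIO_DEFAULT,
                          times=None) -> pd.DataFrame:
    """Induced-to-control ratio of every panel entry at matching times.

    Identical trajectories give 1 everywhere; entries whose control value
    is zero are reported as missing (NaN), never infinite.
    """
    if times is None:
        times = (list(traj_induced.schedule.sample_times)
                 if traj_induced.schedule is not None
                 else list(traj_induced.times))
    a = biomarker_panel(traj_induced, po_ratio, times)
    b = biomarker_panel(traj_control, po_ratio, times)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    return ratio.replace([np.inf, -np.inf], np.nan)


def mab_carbon_fraction(q_mab: float, mw_mab: float = C.MAB_RESIDUE_MW,
                        mu: float = 0.04, dcw_pg: float = 350.0,
                        carbon_frac_mab: float = 0.53,
                        carbon_frac_x: float = 0.488) -> float:
    """Percentage of newly fixed carbon mass going into the antibody.

    Pure arithmetic on a specific productivity q_mab
    (mmol/(1e6 cells)/h, per-residue basis with average residue mass
    ``mw_mab`` g/mol), specific growth rate ``mu`` (1/h), dry cell weight
    ``dcw_pg`` (pg/cell) and the carbon mass fractions of antibody and
    biomass:

        100 * q*mw*fC_mab / (mu*DCW*fC_x + q*mw*fC_mab)
    """
    if q_mab < 0 or min(mw_mab, mu, dcw_pg, carbon_frac_mab,
                        carbon_frac_x) <= 0:
        raise ValueError("all inputs must be positive (q_mab >= 0)")
    # q [mmol/1e6c/h] * mw [g/mol] * 1e-3 -> g carbon-bearing mass /1e6c/h
    mab_c = q_mab * mw_mab * 1e-3 * carbon_frac_mab
    # dcw per 1e6 cells: pg/cell * 1e6 cells = 1e-6 g * dcw_pg
    growth_c = mu * dcw_pg * 1e-6 * carbon_frac_x
    return 100.0 * mab_c / (growth_c + mab_c)
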