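"""Canonical parameter fixtures for the EGFR-TKI xenograft system.

Population estimates for erlotinib and gefitinib in patient-derived NSCLC
xenograft mice: one-compartment oral PK per compound (gefitinib with a
dose-dependent volume term ``I``), shared tumor-growth and transit
parameters, compound-specific kill slopes ``k2`` with a high-dose covariate
for erlotinib, and a high-dose covariate on the damaged-to-resistant
conversion rate ``kSR``.  Random-effect magnitudes are log-normal SDs.

These values parameterize the synthetic-study generator and the shipped
simulation experiments.  The initial tumor volume at randomization is a
package convention (100 mm3, typical for xenograft studies at enrollment)
as is the 0.025 kg mouse body weight used for mg/kg-to-amount conversion.
"""

from __future__ import annotations

from .pk import PKParameters, threshold_concentration
from .tumor import BaseTGIParameters, ResistanceTGIParameters

__all__ = [
    "ERLOTINIB_PK",
    "GEFITINIB_PK",
    "HUMAN_ERLOTINIB_PK",
    "PD_FIXED_EFFECTS",
    "OMEGA",
    "ERLOTINIB_MW",
    "ERLOTINIB_FU",
    "CTH_INVITRO_UM",
    "erlotinib_threshold",
    "resistance_parameters",
    "base_parameters",
]

ERLOTINIB_MW = 393.4   # g/mol
ERLOTINIB_FU = 0.055   # fraction unbound in mouse plasma
CTH_INVITRO_UM = 1.0   # free in-vitro threshold killing resistant cells [uM]

ERLOTINIB_PK = PKParameters(ka=55.0, ke=7.56, V=0.127, I=0.0,
                            fu=ERLOTINIB_FU, MW=ERLOTINIB_MW)
GEFITINIB_PK = PKParameters(ka=55.0, ke=3.87, V=1.40, I=0.00772, MW=446.9)

# Representative adult human erlotinib PK (long half-life, large apparent
# volume); a config-level default for the hybrid human-PK simulation, not a
# fitted quantity.
HUMAN_ERLOTINIB_PK = PKParameters(ka=24.0, ke=0.46, V=232.0, I=0.0,
                                  fu=ERLOTINIB_FU, MW=ERLOTINIB_MW,
                                  body_weight=70.0)

DEFAULT_TV0 = 100.0  # mm3 at randomization; convention, not an estimate

# Shared PD fixed effects (resistance model); k2 keyed by compound with the
# high-dose (100 mg/kg) covariate values alongside.
PD_FIXED_EFFECTS = {
    "TV0": DEFAULT_TV0,
    "lambda0": 0.217,        # 1/d
    "lambda1": 42.8,         # mm3/d
    "k1": 1.52,              # 1/d
    "beta": 0.869,           # resistant/sensitive growth-rate ratio
    "kSR": 7.4e-3,           # 1/d, mid/low dose
    "kSR_high": 1.7e-3,      # 1/d, high-dose covariate value
    "k2": {"erlotinib": 9.21e-5, "gefitinib": 6.19e-4},   # L/ug/d, mid/low
    "k2_high": {"erlotinib": 3.15e-4, "gefitinib": 6.19e-4},
}

# Log-normal inter-individual SDs (random effects).
OMEGA = {
    "ke": {"erlotinib": 0.332, "gefitinib": 0.352},
    "V": {"erlotinib": 0.251, "gefitinib": 0.0278},
    "TV0": 0.3,
    "lambda0": 0.487,
    "lambda1": 0.653,
    "k1": 0.2,
    "beta": 0.742,
    "kSR": 0.1,
    "k2": {"erlotinib": 0.655, "gefitinib": 0.2},
}


def erlotinib_threshold() -> float:
    """Total plasma threshold [ug/L] above which resistant cells are killed."""
    return threshold_concentration(CTH_INVITRO_UM, ERLOTINIB_MW, ERLOTINIB_FU)


def _k2(compound: str, high_dose: bool) -> float:
    key = "k2_high" if high_dose else "k2"
    try:
        return PD_FIXED_EFFECTS[key][compound]
    except KeyError:
        raise KeyError(f"no canonical k2 for compound {compound!r}") from None


def base_parameters(compound: str = "erlotinib", high_dose: bool = True,
                    TV0: float = DEFAULT_TV0) -> BaseTGIParameters:
    """Canonical base-model parameter set for one compound/dose class."""
    p = PD_FIXED_EFFECTS
    return BaseTGIParameters(TV0=TV0, lambda0=p["lambda0"], lambda1=p["lambda1"],
                             k1=p["k1"], k2=_k2(compound, high_dose))


def resistance_parameters(compound: str = "erlotinib", high_dose: bool = True,
                          TV0: float = DEFAULT_TV0, der_enabled: bool = False,
                          k2R: float = 0.0, C_th: float | None = None,
                          der_form: str = "mass_action") -> ResistanceTGIParameters:
    """Canonical resistance-model parameter set for one compound/dose class."""
    p = PD_FIXED_EFFECTS
    ksr = p["kSR_high"] if high_dose else p["kSR"]
    if C_th is None:
        C_th = erlotinib_threshold() if der_enabled else float("inf")
    return ResistanceTGIParameters(
        TV0=TV0, lambda0=p["lambda0"], lambda1=p["lambda1"], k1=p["k1"],
        k2=_k2(compound, high_dose), kSR=ksr, beta=p["beta"],
        k2R=k2R, C_th=C_th, der_enabled=der_enabled, der_form=der_form)
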