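"""Package-level physical constants and numerical settings.

Every constant that influences simulation output is defined here (not
scattered through the code) so a run can be reproduced from the package
version alone.
"""

from __future__ import annotations

#: Reference body weight (kg) to which organ volumes, plasma flows and
#: enzyme expression amounts are anchored.
REFERENCE_BODY_WEIGHT_KG = 73.0

#: Allometric exponents used to rescale the reference physiology with body
#: weight: volumes scale linearly, perfusion flows with the classic 3/4 power.
ALLOMETRIC_EXPONENT_VOLUME = 1.0
ALLOMETRIC_EXPONENT_FLOW = 0.75

#: Reference organ volumes in litres at REFERENCE_BODY_WEIGHT_KG.
#: ``gut_lumen`` is volumeless bookkeeping (amount only, never a
#: concentration); the entry here is a placeholder that is never used as a
#: divisor.
REFERENCE_ORGAN_VOLUMES_L = {
    "gut_lumen": 1.0,
    "gut_wall": 1.1,
    "liver": 1.8,
    "kidney": 0.31,
    "arterial_plasma": 0.85,
    "venous_plasma": 1.9,
    "rest": 32.0,
}

#: Reference plasma flows in l/min at REFERENCE_BODY_WEIGHT_KG.  ``liver`` is
#: the hepatic-artery inflow; the gut-wall outflow drains into the liver
#: (portal circulation) so total hepatic perfusion is gut_wall + liver.
#: ``cardiac_output`` is the bookkeeping sum of all tissue inflows.
REFERENCE_PLASMA_FLOWS_L_PER_MIN = {
    "gut_wall": 0.63,
    "liver": 0.27,
    "kidney": 0.66,
    "rest": 1.54,
    "cardiac_output": 3.10,
}

#: Haematocrit of the reference individual; plasma fraction = 1 - haematocrit.
REFERENCE_HEMATOCRIT = 0.45

#: Per-organ lipid-capacity constants of the tissue partition rule
#: Kp(organ) = 1 + f_lipid(organ) * 10**lipophilicity * fraction_unbound.
#: Plasma compartments partition with Kp = 1 by definition.
F_LIPID = {
    "gut_wall": 0.02,
    "liver": 0.03,
    "kidney": 0.03,
    "rest": 0.05,
}

#: Effective absorptive area constant (1/cm): first-order oral absorption
#: rate ka (1/min) = intestinal_permeability (cm/min) * this constant.
#: Calibrated once so the mean-value midazolam model peaks between 0.5 and
#: 1.5 h after a 1 mg oral dose.
EFFECTIVE_AREA_CONSTANT_PER_CM = 20.0

#: Relative enzyme/transporter expression amounts at the reference body
#: weight, in the same arbitrary abundance unit into which the catalytic
#: constants absorb absolute enzyme content: organ-local Vmax (µmol/min)
#: = kcat (1/min) * expression.  Expression scales linearly with body weight
#: (organ mass).  Organs absent from a protein's map express nothing.
REFERENCE_EXPRESSION = {
    "CYP3A4": {"liver": 500.0, "gut_wall": 75.0},
    "UGT1A4": {"liver": 0.5, "kidney": 0.1, "gut_wall": 0.1},
    "ABCB1": {"gut_wall": 0.03, "liver": 0.03},
    "CYP2C9": {"liver": 2.5},
    "OATP1B1": {"liver": 0.02},
}

#: Stiff-capable integrator settings, fixed for reproducibility.
SOLVER_METHOD = "LSODA"
SOLVER_RTOL = 1e-8
SOLVER_ATOL = 1e-12

#: Relative tolerance at which the molar mass-balance ledger must close.
MASS_BALANCE_RTOL = 1e-6

#: CYP2C9 diplotype -> catalytic activity multiplier.  Only the phenotype
#: direction (poor metabolizer for *3/*3) is established; the numeric factors
#: are package defaults, overridable via the genotype activity table.
GENOTYPE_ACTIVITY = {
    "CYP2C9": {
        "*1/*1": 1.0,
        "*1/*2": 0.8,
        "*2/*2": 0.6,
        "*1/*3": 0.6,
        "*2/*3": 0.4,
        "*3/*3": 0.2,
    }
}

#: Diplotypes covered by the genotyping panel, per locus.
ASSAYED_DIPLOTYPES = {
    "CYP2C9": {"*1/*1", "*1/*2", "*2/*2", "*1/*3", "*2/*3", "*3/*3"},
    "CYP3A4": {"*1/*1", "*1/*22", "*22/*22", "*1/*1B", "*1B/*1B", "*1B/*22"},
    "CYP3A5": {"*1/*1", "*1/*3", "*3/*3"},
}
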