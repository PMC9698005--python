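"""Reaction-network inventory for the whole-body glucose/lipid model.

The model (MINGLeD: Model INtegrating GLucose and Lipid Dynamics) partitions
whole-body metabolism over four compartments — liver, plasma, periphery and
intestinal lumen — with 18 metabolite pools, 41 fluxes (j1..j41) and 39
kinetic parameters.  All reactions are irreversible and first order in a
single pool, with three deliberate exceptions:

* dietary inflows (j1 glucose, j11 triglyceride, j24 cholesterol) are
  zeroth-order forcings fixed by food intake and diet composition;
* amino-acid routing from dietary protein (j6–j9) is a zeroth-order forcing
  scaled by four partition parameters;
* the CETP exchange flux (j34) moves cholesterol from HDL to VLDL at a rate
  proportional to the plasma (VLDL) triglyceride pool, the accepted driver of
  CETP activity, rather than to its substrate pool.

Units: sterol/bile-acid/TG pools in µmol per mouse, carbohydrate pools in
µmol glucose equivalents, acetyl-CoA pools in µmol acetyl units.  Each flux
is expressed in the units of its substrate pool per day; conversions between
pools use the fixed stoichiometric yields below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "STATES",
    "STATE_INDEX",
    "FLUXES",
    "FLUX_INDEX",
    "PARAMETERS",
    "PARAMETER_INDEX",
    "FORCINGS",
    "N_STATES",
    "N_FLUXES",
    "N_PARAMETERS",
    "ACETYL_PER_G6P",
    "ACETYL_PER_TG",
    "ACETYL_PER_CHOL",
    "FA_PER_TG",
    "FluxDef",
    "stoichiometry_matrix",
]

# Stoichiometric yields for pool conversions (acetyl units per substrate unit
# and fatty acids per triglyceride).  Glucose -> 2 acetyl-CoA via glycolysis +
# pyruvate dehydrogenase; one TG carries three ~C16 fatty acids -> 24 acetyl;
# cholesterol synthesis consumes 18 acetyl-CoA.
ACETYL_PER_G6P = 2.0
ACETYL_PER_TG = 24.0
ACETYL_PER_CHOL = 18.0
FA_PER_TG = 3.0

COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "liver": (
        "g6p_liver",
        "accoa_liver",
        "tg_liver",
        "chol_liver",
        "ba_liver",
        "glycogen_liver",
    ),
    "plasma": (
        "glucose_plasma",
        "ffa_plasma",
        "vldl_tg",
        "vldl_chol",
        "hdl_chol",
    ),
    "periphery": (
        "g6p_periphery",
        "accoa_periphery",
        "tg_periphery",
        "chol_periphery",
    ),
    "intestinal_lumen": (
        "tg_lumen",
        "chol_lumen",
        "ba_lumen",
    ),
}

STATES: tuple[str, ...] = tuple(s for members in COMPARTMENTS.values() for s in members)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATES)}

# Forcing inputs (zeroth-order, µmol/day of the receiving pool's unit).
FORCINGS: tuple[str, ...] = ("diet_glucose", "diet_tg", "diet_cholesterol", "diet_protein")


@dataclass(frozen=True)
class FluxDef:
    """One flux of the network.

    kind:
      ``mass_action``    rate = k * x[rate_state]
      ``forcing``        rate = forcing value (diet inflow, parameter-free)
      ``scaled_forcing`` rate = f * forcing value (protein partition)
    ``rate_state`` defaults to the substrate; the CETP flux overrides it with
    the plasma-TG driver pool.
    """

    index: int  # 1-based j-index
    name: str
    kind: str
    substrate: str | None
    products: dict[str, float] = field(default_factory=dict)
    parameter: str | None = None
    forcing: str | None = None
    rate_state: str | None = None
    role: str = ""

    def __post_init__(self) -> None:
        if self.kind == "mass_action" and self.rate_state is None:
            object.__setattr__(self, "rate_state", self.substrate)


def _ma(index, name, substrate, products, role="", rate_state=None):
    return FluxDef(
        index=index,
        name=name,
        kind="mass_action",
        substrate=substrate,
        products=products,
        parameter=f"k_{name}",
        rate_state=rate_state,
        role=role,
    )


def _forcing(index, name, forcing, product, role=""):
    return FluxDef(
        index=index,
        name=name,
        kind="forcing",
        substrate=None,
        products={product: 1.0},
        forcing=forcing,
        role=role,
    )


def _scaled(index, name, product, role=""):
    return FluxDef(
        index=index,
        name=name,
        kind="scaled_forcing",
        substrate=None,
        products={product: 1.0},
        parameter=f"f_{name}",
        forcing="diet_protein",
        role=role,
    )


FLUXES: tuple[FluxDef, ...] = (
    _forcing(1, "diet_glucose_intake", "diet_glucose", "glucose_plasma",
             "dietary glucose entering plasma"),
    _ma(2, "glucose_uptake_liver", "glucose_plasma", {"g6p_liver": 1.0},
        "hepatic glucose uptake to G6P"),
    _ma(3, "glucose_uptake_periphery", "glucose_plasma", {"g6p_periphery": 1.0},
        "peripheral glucose uptake to G6P"),
    _ma(4, "hepatic_glucose_production", "g6p_liver", {"glucose_plasma": 1.0},
        "glucose release from liver G6P"),
    _ma(5, "glycogen_synthesis", "g6p_liver", {"glycogen_liver": 1.0},
        "liver glycogen deposition"),
    _scaled(6, "protein_to_liver_g6p", "g6p_liver",
            "gluconeogenic amino acids to liver G6P"),
    _scaled(7, "protein_to_liver_accoa", "accoa_liver",
            "ketogenic amino acids to liver acetyl-CoA"),
    _scaled(8, "protein_to_periphery_g6p", "g6p_periphery",
            "gluconeogenic amino acids to peripheral G6P"),
    _scaled(9, "protein_to_periphery_accoa", "accoa_periphery",
            "ketogenic amino acids to peripheral acetyl-CoA"),
    _ma(10, "glycogenolysis", "glycogen_liver", {"g6p_liver": 1.0},
        "glycogen breakdown to G6P"),
    _forcing(11, "diet_tg_intake", "diet_tg", "tg_lumen",
             "dietary triglyceride entering the intestinal lumen"),
    _ma(12, "fat_absorption_liver", "tg_lumen", {"tg_liver": 1.0},
        "lumen TG uptake routed to liver"),
    _ma(13, "fat_absorption_periphery", "tg_lumen", {"tg_periphery": 1.0},
        "lumen TG uptake routed to periphery"),
    _ma(14, "beta_oxidation_liver", "tg_liver", {"accoa_liver": ACETYL_PER_TG},
        "hepatic fat oxidation to acetyl-CoA"),
    _ma(15, "beta_oxidation_periphery", "tg_periphery",
        {"accoa_periphery": ACETYL_PER_TG},
        "peripheral fat oxidation to acetyl-CoA"),
    _ma(16, "glycolysis_liver", "g6p_liver", {"accoa_liver": ACETYL_PER_G6P},
        "liver G6P entering the Krebs cycle (glucose oxidation)"),
    _ma(17, "glycolysis_periphery", "g6p_periphery",
        {"accoa_periphery": ACETYL_PER_G6P},
        "peripheral G6P entering the Krebs cycle (glucose oxidation)"),
    _ma(18, "acetyl_oxidation_liver", "accoa_liver", {},
        "terminal oxidation of liver acetyl-CoA (CO2 out)"),
    _ma(19, "dnl_liver", "accoa_liver", {"tg_liver": 1.0 / ACETYL_PER_TG},
        "hepatic de novo lipogenesis"),
    _ma(20, "vldl_tg_production", "tg_liver", {"vldl_tg": 1.0},
        "VLDL-TG secretion by the liver"),
    _ma(21, "acetyl_oxidation_periphery", "accoa_periphery", {},
        "terminal oxidation of peripheral acetyl-CoA (CO2 out)"),
    _ma(22, "lipolysis_periphery", "tg_periphery", {"ffa_plasma": FA_PER_TG},
        "adipose lipolysis releasing FFA to plasma"),
    _ma(23, "ffa_uptake_liver", "ffa_plasma", {"tg_liver": 1.0 / FA_PER_TG},
        "hepatic FFA uptake and re-esterification"),
    _forcing(24, "diet_cholesterol_intake", "diet_cholesterol", "chol_lumen",
             "dietary cholesterol entering the intestinal lumen"),
    _ma(25, "dnl_periphery", "accoa_periphery", {"tg_periphery": 1.0 / ACETYL_PER_TG},
        "peripheral de novo lipogenesis"),
    _ma(26, "chol_synthesis_liver", "accoa_liver", {"chol_liver": 1.0 / ACETYL_PER_CHOL},
        "hepatic cholesterol synthesis"),
    _ma(27, "vldl_tg_uptake_periphery", "vldl_tg", {"tg_periphery": 1.0},
        "lipoprotein-lipase mediated VLDL-TG uptake by the periphery"),
    _ma(28, "fecal_tg_excretion", "tg_lumen", {},
        "unabsorbed fat leaving in feces"),
    _ma(29, "chol_synthesis_periphery", "accoa_periphery",
        {"chol_periphery": 1.0 / ACETYL_PER_CHOL},
        "peripheral cholesterol synthesis"),
    _ma(30, "bile_acid_synthesis", "chol_liver", {"ba_liver": 1.0},
        "hepatic conversion of cholesterol to bile acids"),
    _ma(31, "hdl_efflux", "chol_periphery", {"hdl_chol": 1.0},
        "peripheral cholesterol efflux to HDL"),
    _ma(32, "hdl_uptake_liver", "hdl_chol", {"chol_liver": 1.0},
        "hepatic HDL-cholesterol uptake"),
    _ma(33, "vldl_chol_production", "chol_liver", {"vldl_chol": 1.0},
        "VLDL-cholesterol secretion by the liver"),
    _ma(34, "cetp_transfer", "hdl_chol", {"vldl_chol": 1.0},
        "CETP-mediated HDL->VLDL cholesterol transfer, driven by plasma TG",
        rate_state="vldl_tg"),
    _ma(35, "tice", "vldl_chol", {"chol_lumen": 1.0},
        "trans-intestinal cholesterol excretion, driven by the VLDL-C pool"),
    _ma(36, "biliary_ba_secretion", "ba_liver", {"ba_lumen": 1.0},
        "biliary bile-acid secretion"),
    _ma(37, "biliary_chol_secretion", "chol_liver", {"chol_lumen": 1.0},
        "biliary cholesterol secretion"),
    _ma(38, "ba_reabsorption", "ba_lumen", {"ba_liver": 1.0},
        "intestinal bile-acid reabsorption (enterohepatic cycle)"),
    _ma(39, "fecal_ba_excretion", "ba_lumen", {},
        "fecal bile-acid loss"),
    _ma(40, "fecal_ns_excretion", "chol_lumen", {},
        "fecal neutral-sterol loss"),
    _ma(41, "chol_absorption", "chol_lumen", {"chol_liver": 1.0},
        "intestinal cholesterol absorption routed to liver"),
)

FLUX_INDEX: dict[str, int] = {f.name: i for i, f in enumerate(FLUXES)}

# 34 rate constants + 4 protein partitions + 1 fecal-fat hydrolysis fraction.
PARAMETERS: tuple[str, ...] = tuple(
    f.parameter for f in FLUXES if f.parameter is not None
) + ("f_fecal_ffa",)
PARAMETER_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAMETERS)}

N_STATES = len(STATES)
N_FLUXES = len(FLUXES)
N_PARAMETERS = len(PARAMETERS)


def stoichiometry_matrix() -> np.ndarray:
    """18 x 41 matrix S with dx/dt = S @ j.

    Substrate entries are -1 (flux in substrate units); product entries carry
    the stoichiometric yield.  Boundary fluxes (diet in, fecal out, terminal
    oxidation) have one-sided columns.
    """
    S = np.zeros((N_STATES, N_FLUXES))
    for col, flux in enumerate(FLUXES):
        if flux.substrate is not None:
            S[STATE_INDEX[flux.substrate], col] -= 1.0
        for product, coeff in flux.products.items():
            S[STATE_INDEX[product], col] += coeff
    return S


def _check_structure() -> None:
    assert len(COMPARTMENTS) == 4
    assert N_STATES == 18, N_STATES
    assert N_FLUXES == 41, N_FLUXES
    assert N_PARAMETERS == 39, N_PARAMETERS
    assert tuple(f.index for f in FLUXES) == tuple(range(1, 42))
    seen: set[str] = set()
    for members in COMPARTMENTS.values():
        assert not (set(members) & seen)
        seen |= set(members)
    assert seen == set(STATES)


_check_structure()
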