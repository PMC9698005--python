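"""Independent bookkeeping oracles for the kinetic network.

These are literal, hand-written transcriptions of the rate-law table and the
per-pool mass balances, deliberately kept independent of the vectorized
implementation (no stoichiometry matrix, no index machinery) so that they can
serve as an oracle for flux and derivative computations.
"""

import numpy as np

ACETYL_PER_G6P = 2.0
ACETYL_PER_TG = 24.0
ACETYL_PER_CHOL = 18.0
FA_PER_TG = 3.0


def rate_table(x: dict, k: dict, forcing: dict) -> dict:
    """Literal rate laws, flux name -> value."""
    return {
        "diet_glucose_intake": forcing["diet_glucose"],
        "glucose_uptake_liver": k["k_glucose_uptake_liver"] * x["glucose_plasma"],
        "glucose_uptake_periphery": k["k_glucose_uptake_periphery"] * x["glucose_plasma"],
        "hepatic_glucose_production": k["k_hepatic_glucose_production"] * x["g6p_liver"],
        "glycogen_synthesis": k["k_glycogen_synthesis"] * x["g6p_liver"],
        "protein_to_liver_g6p": k["f_protein_to_liver_g6p"] * forcing["diet_protein"],
        "protein_to_liver_accoa": k["f_protein_to_liver_accoa"] * forcing["diet_protein"],
        "protein_to_periphery_g6p": k["f_protein_to_periphery_g6p"] * forcing["diet_protein"],
        "protein_to_periphery_accoa": k["f_protein_to_periphery_accoa"] * forcing["diet_protein"],
        "glycogenolysis": k["k_glycogenolysis"] * x["glycogen_liver"],
        "diet_tg_intake": forcing["diet_tg"],
        "fat_absorption_liver": k["k_fat_absorption_liver"] * x["tg_lumen"],
        "fat_absorption_periphery": k["k_fat_absorption_periphery"] * x["tg_lumen"],
        "beta_oxidation_liver": k["k_beta_oxidation_liver"] * x["tg_liver"],
        "beta_oxidation_periphery": k["k_beta_oxidation_periphery"] * x["tg_periphery"],
        "glycolysis_liver": k["k_glycolysis_liver"] * x["g6p_liver"],
        "glycolysis_periphery": k["k_glycolysis_periphery"] * x["g6p_periphery"],
        "acetyl_oxidation_liver": k["k_acetyl_oxidation_liver"] * x["accoa_liver"],
        "dnl_liver": k["k_dnl_liver"] * x["accoa_liver"],
        "vldl_tg_production": k["k_vldl_tg_production"] * x["tg_liver"],
        "acetyl_oxidation_periphery": k["k_acetyl_oxidation_periphery"] * x["accoa_periphery"],
        "lipolysis_periphery": k["k_lipolysis_periphery"] * x["tg_periphery"],
        "ffa_uptake_liver": k["k_ffa_uptake_liver"] * x["ffa_plasma"],
        "diet_cholesterol_intake": forcing["diet_cholesterol"],
        "dnl_periphery": k["k_dnl_periphery"] * x["accoa_periphery"],
        "chol_synthesis_liver": k["k_chol_synthesis_liver"] * x["accoa_liver"],
        "vldl_tg_uptake_periphery": k["k_vldl_tg_uptake_periphery"] * x["vldl_tg"],
        "fecal_tg_excretion": k["k_fecal_tg_excretion"] * x["tg_lumen"],
        "chol_synthesis_periphery": k["k_chol_synthesis_periphery"] * x["accoa_periphery"],
        "bile_acid_synthesis": k["k_bile_acid_synthesis"] * x["chol_liver"],
        "hdl_efflux": k["k_hdl_efflux"] * x["chol_periphery"],
        "hdl_uptake_liver": k["k_hdl_uptake_liver"] * x["hdl_chol"],
        "vldl_chol_production": k["k_vldl_chol_production"] * x["chol_liver"],
        # CETP: substrate HDL-C, rate driven by the plasma (VLDL) TG pool
        "cetp_transfer": k["k_cetp_transfer"] * x["vldl_tg"],
        "tice": k["k_tice"] * x["vldl_chol"],
        "biliary_ba_secretion": k["k_biliary_ba_secretion"] * x["ba_liver"],
        "biliary_chol_secretion": k["k_biliary_chol_secretion"] * x["chol_liver"],
        "ba_reabsorption": k["k_ba_reabsorption"] * x["ba_lumen"],
        "fecal_ba_excretion": k["k_fecal_ba_excretion"] * x["ba_lumen"],
        "fecal_ns_excretion": k["k_fecal_ns_excretion"] * x["chol_lumen"],
        "chol_absorption": k["k_chol_absorption"] * x["chol_lumen"],
    }


def mass_balances(j: dict) -> dict:
    """Per-pool mass balance, state name -> dx/dt, from fluxes by name."""
    return {
        "g6p_liver": (
            j["glucose_uptake_liver"] + j["protein_to_liver_g6p"] + j["glycogenolysis"]
            - j["hepatic_glucose_production"] - j["glycogen_synthesis"] - j["glycolysis_liver"]
        ),
        "accoa_liver": (
            j["protein_to_liver_accoa"]
            + ACETYL_PER_G6P * j["glycolysis_liver"]
            + ACETYL_PER_TG * j["beta_oxidation_liver"]
            - j["acetyl_oxidation_liver"] - j["dnl_liver"] - j["chol_synthesis_liver"]
        ),
        "tg_liver": (
            j["fat_absorption_liver"]
            + j["dnl_liver"] / ACETYL_PER_TG
            + j["ffa_uptake_liver"] / FA_PER_TG
            - j["beta_oxidation_liver"] - j["vldl_tg_production"]
        ),
        "chol_liver": (
            j["chol_synthesis_liver"] / ACETYL_PER_CHOL
            + j["hdl_uptake_liver"] + j["chol_absorption"]
            - j["bile_acid_synthesis"] - j["vldl_chol_production"]
            - j["biliary_chol_secretion"]
        ),
        "ba_liver": (
            j["bile_acid_synthesis"] + j["ba_reabsorption"] - j["biliary_ba_secretion"]
        ),
        "glycogen_liver": j["glycogen_synthesis"] - j["glycogenolysis"],
        "glucose_plasma": (
            j["diet_glucose_intake"] + j["hepatic_glucose_production"]
            - j["glucose_uptake_liver"] - j["glucose_uptake_periphery"]
        ),
        "ffa_plasma": FA_PER_TG * j["lipolysis_periphery"] - j["ffa_uptake_liver"],
        "vldl_tg": j["vldl_tg_production"] - j["vldl_tg_uptake_periphery"],
        "vldl_chol": (
            j["vldl_chol_production"] + j["cetp_transfer"] - j["tice"]
        ),
        "hdl_chol": j["hdl_efflux"] - j["hdl_uptake_liver"] - j["cetp_transfer"],
        "g6p_periphery": (
            j["glucose_uptake_periphery"] + j["protein_to_periphery_g6p"]
            - j["glycolysis_periphery"]
        ),
        "accoa_periphery": (
            j["protein_to_periphery_accoa"]
            + ACETYL_PER_G6P * j["glycolysis_periphery"]
            + ACETYL_PER_TG * j["beta_oxidation_periphery"]
            - j["acetyl_oxidation_periphery"] - j["dnl_periphery"]
            - j["chol_synthesis_periphery"]
        ),
        "tg_periphery": (
            j["fat_absorption_periphery"]
            + j["dnl_periphery"] / ACETYL_PER_TG
            + j["vldl_tg_uptake_periphery"]
            - j["beta_oxidation_periphery"] - j["lipolysis_periphery"]
        ),
        "chol_periphery": (
            j["chol_synthesis_periphery"] / ACETYL_PER_CHOL - j["hdl_efflux"]
        ),
        "tg_lumen": (
            j["diet_tg_intake"] - j["fat_absorption_liver"]
            - j["fat_absorption_periphery"] - j["fecal_tg_excretion"]
        ),
        "chol_lumen": (
            j["diet_cholesterol_intake"] + j["tice"] + j["biliary_chol_secretion"]
            - j["fecal_ns_excretion"] - j["chol_absorption"]
        ),
        "ba_lumen": (
            j["biliary_ba_secretion"] - j["ba_reabsorption"] - j["fecal_ba_excretion"]
        ),
    }


def random_state(rng) -> dict:
    from mingled.network import STATES

    return {s: float(rng.uniform(0.1, 100.0)) for s in STATES}


def random_params(rng) -> dict:
    from mingled.network import PARAMETERS

    return {p: float(rng.uniform(0.0, 10.0)) for p in PARAMETERS}


def percentile_oracle(values, q):
    """Brute-force linear-interpolation percentile (sorted-order convention)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 1:
        return float(v[0])
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
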