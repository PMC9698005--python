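"""Downstream phenotype analyses.

Responder/non-responder stratification (baseline plasma TG < 1.0 mM on chow
defines non-responders), the fecal bile-acid hydrophobicity index, correlation
analyses between fecal outputs, group comparison of estimated flux
trajectories via median curves and 30% ensemble bands, and the
energy-imbalance arithmetic linking a fat-mass difference to daily energy
expenditure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .adapt import AdaptResult, summarize
from .exceptions import ConfigurationError, DomainError, ValidationError

__all__ = [
    "StratificationRule",
    "HydrophobicityTable",
    "BileAcidProfile",
    "HEUMAN_COEFFICIENTS",
    "stratify",
    "hydrophobicity_index",
    "correlate",
    "compare_flux_trajectories",
    "energy_imbalance",
    "imbalance_fraction",
]

#: Hydrophobicity coefficients on the Heuman scale for unconjugated bile
#: acids.  These are external literature constants (HPLC-derived indices,
#: taurocholate = 0 reference), shipped as editable defaults, not values
#: measured by this package.
HEUMAN_COEFFICIENTS: dict[str, float] = {
    "LCA": 1.00,
    "DCA": 0.72,
    "CDCA": 0.59,
    "CA": 0.13,
    "UDCA": -0.31,
    "HDCA": 0.35,
    "aMCA": -0.84,
    "bMCA": -0.78,
    "oMCA": -0.90,
}


@dataclass
class StratificationRule:
    """Baseline plasma-TG threshold rule: < threshold -> non-responder."""

    observable: str = "plasma_tg"
    threshold: float = 1.0  # mM
    baseline_time: float = 0.0  # days (week 0, chow)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be > 0")


@dataclass
class HydrophobicityTable:
    """Species -> hydrophobicity coefficient (dimensionless, Heuman scale)."""

    coefficients: dict = field(default_factory=lambda: dict(HEUMAN_COEFFICIENTS))

    def __getitem__(self, species: str) -> float:
        try:
            return float(self.coefficients[species])
        except KeyError:
            raise ConfigurationError(
                f"no hydrophobicity coefficient for species {species!r}"
            ) from None


@dataclass
class BileAcidProfile:
    """Molar bile-acid composition from one origin matrix."""

    amounts: dict  # species -> molar amount or fraction (>= 0)
    origin: str = "feces"  # feces | bile | plasma

    def fractions(self) -> dict:
        vals = {s: float(a) for s, a in self.amounts.items()}
        if any(v < 0 for v in vals.values()):
            raise ValidationError("negative bile-acid amount")
        total = sum(vals.values())
        if total <= 0:
            raise ValidationError("profile has zero total bile acid")
        return {s: v / total for s, v in vals.items()}


def stratify(per_mouse: pd.DataFrame, rule: StratificationRule | None = None) -> pd.DataFrame:
    """Assign responder/non-responder labels from baseline plasma TG.

    ``per_mouse`` is the long per-mouse frame (mouse_id, observable,
    time_days, value).  A mouse is a non-responder iff its baseline value is
    strictly below the threshold.  Mice without a baseline measurement are
    excluded with a warning.  Returns a frame (mouse_id, label, baseline)
    indexed like the input's mouse order.
    """
    rule = rule if rule is not None else StratificationRule()
    mice = list(dict.fromkeys(per_mouse["mouse_id"]))
    base = per_mouse[
        (per_mouse["observable"] == rule.observable)
        & (np.isclose(per_mouse["time_days"], rule.baseline_time))
    ].set_index("mouse_id")["value"]
    missing = [m for m in mice if m not in base.index]
    if missing:
        warnings.warn(
            f"no baseline {rule.observable} for {missing}; excluded from "
            "stratification",
            stacklevel=2,
        )
    kept = [m for m in mice if m in base.index]
    labels = [
        "non_responder" if base[m] < rule.threshold else "responder" for m in kept
    ]
    return pd.DataFrame(
        {"mouse_id": kept, "label": labels, "baseline": [float(base[m]) for m in kept]}
    )


def hydrophobicity_index(
    profile: BileAcidProfile, table: HydrophobicityTable | None = None
) -> float:
    """Molar-fraction-weighted hydrophobicity index: HFI = sum_s w_s * c_s."""
    table = table if table is not None else HydrophobicityTable()
    fracs = profile.fractions()
    return float(sum(w * table[s] for s, w in fracs.items()))


def correlate(x, y, method: str = "spearman") -> tuple[float, float, int]:
    """Correlation between paired series with pairwise-complete deletion.

    Returns (coefficient, p_value, n).  ``method`` is "spearman" (default,
    robust to the skewed fecal measures) or "pearson".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("series lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant series")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    return float(r), float(p), n


def compare_flux_trajectories(
    result_a: AdaptResult,
    result_b: AdaptResult,
    quantities,
    separation_frac: float = 0.5,
) -> pd.DataFrame:
    """Compare two groups' estimated trajectories quantity by quantity.

    For each named quantity (flux, state, parameter or observable) the two
    ensembles are summarized by median and 30% band on the common grid; per
    grid point the median difference (a - b) and whether the bands are
    disjoint are recorded.  A quantity is flagged ``separated`` when the
    bands are disjoint over at least ``separation_frac`` of the horizon.
    """
    if result_a.grid.shape != result_b.grid.shape or not np.allclose(
        result_a.grid, result_b.grid
    ):
        raise ValidationError("results are on different time grids")
    rows = []
    for name in quantities:
        med_a, lo_a, hi_a = summarize(result_a.quantity(name), result_a.config.band)
        med_b, lo_b, hi_b = summarize(result_b.quantity(name), result_b.config.band)
        diff = med_a - med_b
        disjoint = (hi_a < lo_b) | (hi_b < lo_a)
        inter = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
        union = np.maximum(hi_a, hi_b) - np.minimum(lo_a, lo_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            overlap = np.where(union > 0, np.clip(inter, 0, None) / union, 1.0)
        frac_disjoint = float(np.mean(disjoint))
        rows.append(
            {
                "quantity": name,
                "mean_median_diff": float(np.mean(diff)),
                "median_diff_sign": float(np.sign(np.mean(diff))),
                "mean_band_overlap": float(np.mean(overlap)),
                "frac_disjoint": frac_disjoint,
                "separated": bool(frac_disjoint >= separation_frac),
            }
        )
    return pd.DataFrame(rows)


def energy_imbalance(
    delta_fat_mass_g: float,
    period_days: float,
    fat_energy_density_kcal_per_g: float = 9.4,
) -> float:
    """Daily energy imbalance (kcal/day) implied by a fat-mass difference.

    A 5 g fat-mass divergence over 12 weeks at the body-fat energy density of
    9.4 kcal/g amounts to ~0.6 kcal/day.
    """
    if period_days <= 0:
        raise DomainError("period must be > 0")
    if delta_fat_mass_g < 0 or fat_energy_density_kcal_per_g <= 0:
        raise DomainError("fat mass must be >= 0 and energy density > 0")
    return delta_fat_mass_g * fat_energy_density_kcal_per_g / period_days


def imbalance_fraction(imbalance_kcal_day: float, total_ee_kcal_day: float) -> float:
    """Energy imbalance as a percentage of total daily energy expenditure."""
    if total_ee_kcal_day <= 0:
        raise DomainError("total energy expenditure must be > 0")
    return 100.0 * imbalance_kcal_day / total_ee_kcal_day
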