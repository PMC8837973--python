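"""Extract amounts → whole-organ / whole-plasma pool sizes.

A *pool* is the absolute amount (nmol) of an analyte in an entire
compartment: concentration × organ wet weight for tissues,
concentration × total plasma volume for plasma, and the total
recovered amount for lung lavage fluid (which has no meaningful
volume normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import PoolTable, ValidationError

__all__ = [
    "PlasmaVolumeModel",
    "estimate_plasma_volume",
    "plasma_volume_from_mass",
    "compute_pool",
    "concentration",
    "aggregate_totals",
    "pool_fractions",
    "whole_body_reference_nmol",
    "WHOLE_BODY_CHOLINE_PL_NMOL_PER_G",
]

#: Literature estimate of the whole-body choline-phospholipid pool per
#: gram body weight in the neonatal rat (nmol/g); reference for the
#: "fraction of total body choline lipids" computation.
WHOLE_BODY_CHOLINE_PL_NMOL_PER_G = 10_000.0


@dataclass(frozen=True)
class PlasmaVolumeModel:
    """Plasma volume from body weight.

    Blood volume is taken as a fixed fraction of body weight, plasma
    as the non-cellular blood fraction (1 − hematocrit), converted to
    volume with the plasma density.
    """

    blood_fraction: float = 0.125   # blood mass / body mass
    hematocrit: float = 0.40        # cellular volume fraction
    plasma_density: float = 1.025   # g/mL

    def __post_init__(self) -> None:
        if not (0 < self.blood_fraction < 1):
            raise ValidationError("blood_fraction must be in (0, 1)")
        if not (0 <= self.hematocrit <= 1):
            raise ValidationError("hematocrit must be in [0, 1]")
        if not (1.0 <= self.plasma_density <= 1.1):
            raise ValidationError("plasma_density must be in [1.0, 1.1] g/mL")


def estimate_plasma_volume(body_weight_g: float,
                           model: PlasmaVolumeModel | None = None) -> float:
    """Total plasma volume in µL.

    ``volume = body_weight · blood_fraction · (1 − hematocrit)
    / plasma_density · 1000``.
    """
    if body_weight_g <= 0:
        raise ValidationError("body weight must be positive")
    m = model or PlasmaVolumeModel()
    return (body_weight_g * m.blood_fraction * (1.0 - m.hematocrit)
            / m.plasma_density * 1000.0)


def plasma_volume_from_mass(plasma_mass_mg: float,
                            plasma_density: float = 1.025) -> float:
    """Plasma volume (µL) from a measured plasma compartment mass (mg).

    Both conventions for the plasma compartment size — model-derived
    from body weight, or measured mass divided by density — are
    supported; callers should record which one produced a number.
    """
    if plasma_mass_mg < 0:
        raise ValidationError("plasma mass must be non-negative")
    return plasma_mass_mg / plasma_density


def compute_pool(concentration_value: float, compartment_size: float) -> float:
    """Pool size (nmol) = concentration × compartment size.

    Units must match: nmol/mg × mg for tissue, nmol/µL × µL for
    plasma.  For lung lavage fluid pass the total recovered amount
    with ``compartment_size = 1``.
    """
    if concentration_value < 0 or compartment_size < 0:
        raise ValidationError("concentration and size must be non-negative")
    return concentration_value * compartment_size


def concentration(pool_nmol: float, compartment_size: float) -> float:
    """Inverse of :func:`compute_pool`: nmol/mg or nmol/µL."""
    if compartment_size <= 0:
        raise ValidationError("compartment size must be positive")
    return pool_nmol / compartment_size


def aggregate_totals(pools: PoolTable | pd.DataFrame,
                     by: tuple[str, ...] = ("analyte",)) -> pd.DataFrame:
    """Sum pools over matrices (per analyte by default).

    When per-animal rows are present include ``"animal_id"`` in ``by``
    so totals remain per-animal sums.
    """
    df = pools.df if isinstance(pools, PoolTable) else pools
    out = df.groupby(list(by), sort=False)["amount_nmol"].sum()
    return out.reset_index().rename(columns={"amount_nmol": "total_nmol"})


def pool_fractions(pool: float, reference: float) -> float:
    """Percent of a reference pool: ``100 · pool / reference``."""
    if reference <= 0:
        raise ValidationError("reference must be positive")
    return 100.0 * pool / reference


def whole_body_reference_nmol(
        body_weight_g: float,
        nmol_per_g: float = WHOLE_BODY_CHOLINE_PL_NMOL_PER_G) -> float:
    """Estimated whole-body choline-phospholipid pool (nmol)."""
    if body_weight_g <= 0:
        raise ValidationError("body weight must be positive")
    return body_weight_g * nmol_per_g
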