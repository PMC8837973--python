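"""Dose computation, dose-fraction and enrichment bookkeeping.

The injected tracer carries three trideuteromethyl groups per
molecule.  Downstream metabolites keep 3 (D9 species), 2 (D6-DMG
after betaine demethylation) or 1 (D3-methionine and everything made
through the methylation pathway).  When a labeled pool is expressed
as a fraction of the administered label, its absolute amount is
weighted by ``n_labeled_methyls / 3`` so that the three methyls of
each injected molecule are counted exactly once no matter how they
were split between metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ValidationError

__all__ = [
    "CHOLINE_CHLORIDE_MW",
    "D9_CHOLINE_CHLORIDE_MW",
    "DoseSpec",
    "compute_dose",
    "methyl_corrected_fraction",
    "enrichment",
    "label_balance",
    "fold_decrease",
]

#: Molar mass of unlabeled choline chloride, g/mol.
CHOLINE_CHLORIDE_MW = 139.62

#: Deuterium-vs-hydrogen mass excess per atom, g/mol.
_D_EXCESS = 1.00628

#: Molar mass of the injected compound: the chloride salt with nine
#: deuterium atoms (not the free cation — required to reproduce the
#: 336 nmol per g body weight dose constant).
D9_CHOLINE_CHLORIDE_MW = CHOLINE_CHLORIDE_MW + 9 * _D_EXCESS  # ≈ 148.68


@dataclass(frozen=True)
class DoseSpec:
    """Tracer dose: mg of compound per kg body weight."""

    dose_mg_per_kg: float = 50.0
    compound_mw: float = D9_CHOLINE_CHLORIDE_MW

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0 or self.compound_mw <= 0:
            raise ValidationError("dose and molar mass must be positive")

    @property
    def nmol_per_g(self) -> float:
        """nmol of tracer per g body weight (≈336 at defaults)."""
        return self.dose_mg_per_kg / self.compound_mw * 1e3


def compute_dose(body_weight_g: float,
                 spec: DoseSpec | None = None) -> float:
    """Administered tracer (nmol) for one animal."""
    if body_weight_g <= 0:
        raise ValidationError("body weight must be positive")
    spec = spec or DoseSpec()
    return body_weight_g * spec.nmol_per_g


def methyl_corrected_fraction(pool_nmol: float,
                              n_labeled_methyls: int,
                              dose_nmol: float) -> float:
    """Percent of administered label in one labeled pool.

    ``100 · pool · (n_labeled_methyls / 3) / dose``.  D9 species count
    in full; D6-DMG at 2/3; D3 species at 1/3, since only one of the
    three injected methyl groups reaches them.
    """
    if dose_nmol <= 0:
        raise ValidationError("dose must be positive")
    if n_labeled_methyls not in (1, 2, 3):
        raise ValidationError(
            f"n_labeled_methyls must be 1, 2 or 3, got {n_labeled_methyls}")
    if pool_nmol < 0:
        raise ValidationError("pool must be non-negative")
    return 100.0 * pool_nmol * (n_labeled_methyls / 3.0) / dose_nmol


def enrichment(labeled_nmol: float, unlabeled_nmol: float) -> float:
    """Deuterium enrichment: ``100 · labeled / (labeled + unlabeled)``."""
    if labeled_nmol < 0 or unlabeled_nmol < 0:
        raise ValidationError("amounts must be non-negative")
    total = labeled_nmol + unlabeled_nmol
    if total <= 0:
        raise ValidationError("labeled + unlabeled must be positive")
    return 100.0 * labeled_nmol / total


def label_balance(fractions: pd.DataFrame | dict) -> dict:
    """Total recovered label at one time point, plus the residual.

    Parameters
    ----------
    fractions
        Either a mapping category → percent of dose, or a DataFrame
        with a ``percent_of_dose`` column (one row per category).

    Returns
    -------
    dict with ``recovered`` (sum over categories, %) and ``residual``
    (100 − recovered: label in unobserved compartments — excretion,
    carcass, intestine — never imputed to any of them).
    """
    if isinstance(fractions, pd.DataFrame):
        values = fractions["percent_of_dose"].tolist()
    else:
        values = list(fractions.values())
    if any(v < 0 or v > 100 for v in values):
        raise ValidationError("category percentages must lie in [0, 100]")
    recovered = float(sum(values))
    return {"recovered": recovered, "residual": 100.0 - recovered}


def fold_decrease(initial: float, later: float,
                  per_animal_values: tuple = ()) -> dict:
    """Fold-decrease between two time points, both conventions.

    ``ratio_of_means`` divides the two group means.  If per-animal
    (initial, later) pairs are supplied, ``mean_of_ratios`` averages
    the per-animal ratios instead; the two can differ noticeably for
    skewed data and reports should say which convention was used.
    """
    if later <= 0 or initial <= 0:
        raise ValidationError("amounts must be positive")
    out = {"ratio_of_means": initial / later}
    if per_animal_values:
        ratios = []
        for a, b in per_animal_values:
            if a <= 0 or b <= 0:
                raise ValidationError("per-animal amounts must be positive")
            ratios.append(a / b)
        out["mean_of_ratios"] = sum(ratios) / len(ratios)
    return out
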