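"""Raw SRM ion counts → absolute amounts per extract.

Three steps, in order:

1. **Natural-abundance ¹³C correction.**  Within one lipid class the
   species ladder is 2 Da apart per double bond, so the M+2
   isotopologue of a more unsaturated species (two ¹³C atoms) is
   recorded under the SRM channel of its one-double-bond-fewer
   neighbour.  The spillover probabilities form a sparse correction
   matrix that is inverted against the raw counts.
2. **Internal-standard ratio quantification** with an optional
   chain-length ionization response model.
3. **Acyl sub-group aggregation** of PC/PE species (di-saturated,
   C18:1, C18:2, C20:4, C22:6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .core_io import ACYL_GROUPS, AnalyteSpec, ValidationError

__all__ = [
    "P13_DEFAULT",
    "CorrectionMatrix",
    "ResponseModel",
    "build_c13_matrix",
    "apply_isotope_correction",
    "quantify_by_internal_standard",
    "group_species",
]

#: Natural abundance of ¹³C.
P13_DEFAULT = 0.0107

#: |Δm/z − 2| tolerance (Da) for recognizing an M+2 channel overlap.
MZ_TOLERANCE = 0.30


@dataclass(frozen=True)
class CorrectionMatrix:
    """Square ¹³C spillover matrix for one lipid-class species ladder.

    ``matrix[i, j]`` is the probability that a molecule of species
    ``j`` is recorded under the SRM channel of species ``i``.  The
    diagonal is 1 (each species is recorded under its own channel with
    the monoisotopic transition); the only off-diagonal entries are
    the M+2 (two ¹³C atoms) overlaps onto the channel 2 Da above.
    """

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.species)
        if m.shape != (n, n):
            raise ValidationError("correction matrix shape mismatch")
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("correction matrix must have unit diagonal")
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("correction entries must lie in [0, 1]")


def _p_m2(n_carbons: int, p13: float) -> float:
    """Probability of exactly two ¹³C among ``n_carbons`` atoms."""
    return float(binom.pmf(2, n_carbons, p13))


def build_c13_matrix(species: Sequence[AnalyteSpec],
                     p13: float = P13_DEFAULT) -> CorrectionMatrix:
    """Build the M+2 spillover matrix for one same-class ladder.

    Parameters
    ----------
    species
        Specs sharing a lipid class and diagnostic product ion,
        in any order (sorted internally by precursor m/z).
    p13
        Natural ¹³C abundance, in [0, 0.02] (0 gives the identity
        matrix).

    Raises
    ------
    ValidationError
        If the species mix classes or product ions, or two precursors
        fall within the m/z tolerance of each other (ambiguous channel
        assignment).
    """
    if not species:
        raise ValidationError("empty species list")
    if not (0 <= p13 <= 0.02):
        raise ValidationError(f"p13 out of range [0, 0.02]: {p13}")
    classes = {s.lipid_class for s in species}
    if len(classes) > 1:
        raise ValidationError(f"species mix lipid classes: {sorted(classes)}")
    products = {round(s.product_mz, 1) for s in species}
    if len(products) > 1:
        raise ValidationError(
            "species mix diagnostic product ions; correct each label "
            f"channel family separately (got {sorted(products)})")
    ordered = sorted(species, key=lambda s: s.precursor_mz)
    mz = np.array([s.precursor_mz for s in ordered])
    for i in range(len(ordered) - 1):
        if mz[i + 1] - mz[i] < MZ_TOLERANCE:
            raise ValidationError(
                f"ambiguous m/z assignment: {ordered[i].name} and "
                f"{ordered[i + 1].name} within {MZ_TOLERANCE} Da")
    n = len(ordered)
    C = np.eye(n)
    for j, donor in enumerate(ordered):
        for i in range(n):
            if i == j:
                continue
            if abs((mz[i] - mz[j]) - 2.0) <= MZ_TOLERANCE:
                C[i, j] = _p_m2(donor.n_carbons, p13)
    return CorrectionMatrix(tuple(s.name for s in ordered), C)


def apply_isotope_correction(
        raw_counts: np.ndarray | Sequence[float],
        correction: CorrectionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``C · x = raw`` for the spillover-free counts ``x``.

    Negative solutions — noise at low abundance — are clipped to zero
    and flagged.

    Returns
    -------
    corrected : ndarray
        Counts in the matrix species order, clipped at zero.
    clipped : ndarray of bool
        Flags marking entries that were negative before clipping.
    """
    raw = np.asarray(raw_counts, dtype=float)
    C = correction.matrix
    if raw.shape[-1] != C.shape[0]:
        raise ValidationError(
            f"counts length {raw.shape[-1]} != matrix order {C.shape[0]}")
    if abs(np.linalg.det(C)) < 1e-12:
        raise ValidationError("singular correction matrix")
    x = np.linalg.solve(C, raw.T).T
    # flag genuinely negative solutions (noise at low abundance);
    # round-off-level negatives at true zeros are silently zeroed
    scale = np.max(np.abs(raw), axis=-1, keepdims=True)
    clipped = x < -1e-12 * scale
    return np.where(x < 0, 0.0, x), clipped


@dataclass(frozen=True)
class ResponseModel:
    """Ionization response as an affine function of acyl carbon number.

    ``response(spec) = baseline + slope · (n_carbons − n_ref)``, with
    the reference carbon number that of the class internal standard so
    the IS itself has response ``baseline`` (1.0 by default).  The
    default slope of 0 applies no chain-length correction; supply a
    fitted slope from a calibration series to enable it.
    """

    baseline: float = 1.0
    slope_per_carbon: float = 0.0
    reference_carbons: int = 48  # PC20:0/20:0

    def response(self, spec: AnalyteSpec) -> float:
        r = self.baseline + self.slope_per_carbon * (
            spec.n_carbons - self.reference_carbons)
        if r <= 0:
            raise ValidationError(
                f"{spec.name}: non-positive predicted response {r:.3g}")
        return r


def quantify_by_internal_standard(corrected_count: float,
                                  is_count: float,
                                  is_amount_nmol: float,
                                  response: float = 1.0,
                                  dilution_factor: float = 1.0) -> float:
    """Amount in the extract from the analyte/IS count ratio.

    ``amount = corrected_count / is_count · is_amount / response``.

    The internal standard is spiked into the primary extract and
    co-diluted with the analytes, so the count ratio is invariant to
    dilution; ``dilution_factor`` is validated (≥1) and recorded but
    does not enter the ratio.
    """
    if is_count <= 0:
        raise ValidationError(
            f"internal-standard count must be positive, got {is_count}")
    if dilution_factor < 1:
        raise ValidationError(f"dilution_factor < 1: {dilution_factor}")
    if response <= 0:
        raise ValidationError(f"non-positive response factor: {response}")
    return corrected_count / is_count * is_amount_nmol / response


def group_species(amounts: Mapping[str, float],
                  specs: Mapping[str, AnalyteSpec]) -> dict:
    """Aggregate PC/PE species amounts into acyl sub-groups.

    Parameters
    ----------
    amounts
        Species name → amount (nmol).
    specs
        Species name → :class:`AnalyteSpec` (the registry is
        authoritative for the single acyl-group tag of each species).

    Returns
    -------
    dict with keys ``groups`` (sub-group → summed amount),
    ``class_total`` (sum over all species, including untagged ones),
    ``coverage`` (grouped / total, expected >0.95 for a complete
    panel) and ``ungrouped`` (names tagged ``n/a``, excluded from
    sub-groups but kept in the class total).
    """
    groups = {g: 0.0 for g in ACYL_GROUPS if g != "n/a"}
    total = 0.0
    ungrouped = []
    for name, amount in amounts.items():
        spec = specs[name]
        total += amount
        if spec.acyl_group == "n/a":
            ungrouped.append(name)
        else:
            groups[spec.acyl_group] += amount
    grouped_sum = sum(groups.values())
    coverage = grouped_sum / total if total > 0 else float("nan")
    return {"groups": groups, "class_total": total,
            "coverage": coverage, "ungrouped": ungrouped}
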