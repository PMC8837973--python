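"""Domain types, analyte registry and tabular I/O.

The package works in one canonical unit system throughout: amounts in
nmol, tissue masses in mg, plasma volumes in µL, time in hours.  Report
layers convert to mixed nmol/µmol presentations only at the very end.

An :class:`AnalyteSpec` describes one SRM channel — a metabolite or
phospholipid species in one deuterium label state, with its
precursor→product transition, carbon count (for natural-abundance
¹³C correction) and the internal standard it is quantified against.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "LIPID_CLASSES",
    "LABEL_STATES",
    "METHYLS_BY_LABEL",
    "MATRICES",
    "ORGANS",
    "ACYL_GROUPS",
    "AnalyteSpec",
    "Registry",
    "AnimalRecord",
    "MeasurementTable",
    "PoolTable",
    "load_registry",
    "default_registry",
    "read_animals",
    "write_animals",
    "read_measurements",
    "write_measurements",
    "read_pool_table",
    "write_pool_table",
    "reference_pools",
    "reference_label_fractions",
]

#: Analyte classes: free choline metabolites vs. the three choline
#: phospholipid classes plus phosphatidylethanolamine.
LIPID_CLASSES = ("water_soluble", "PC", "lysoPC", "SPH", "PE")

#: Deuterium label states.  D9 = three trideuteromethyl groups (the
#: injected tracer), D3 = one (methylation products), D6 = two
#: (dimethylglycine from betaine demethylation), D4_IS = the
#: tetradeuterated choline internal standard.
LABEL_STATES = ("unlabeled", "D9", "D3", "D6", "D4_IS")

#: Labeled trideuteromethyl groups carried per molecule in each label
#: state; the basis of the methyl-count dose correction.
METHYLS_BY_LABEL = {"unlabeled": 0, "D9": 3, "D3": 1, "D6": 2, "D4_IS": 0}

#: Sample matrices.  LLF is lung lavage fluid (recovered surfactant).
MATRICES = ("liver", "plasma", "lung", "LLF", "cerebrum", "cerebellum")

#: Solid organs with a wet weight recorded per animal.
ORGANS = ("liver", "lung", "cerebrum", "cerebellum")

#: PC/PE acyl sub-groups: two saturated residues, or one oleic,
#: linoleic, arachidonic or docosahexaenoic residue.
ACYL_GROUPS = ("sat", "C18:1", "C18:2", "C20:4", "C22:6", "n/a")


class ValidationError(ValueError):
    """Raised when an input table or registry violates its invariants."""


@dataclass(frozen=True)
class AnalyteSpec:
    """One SRM-measured species in one label state.

    Parameters
    ----------
    name
        Unique analyte identifier, e.g. ``"D9-choline"`` or
        ``"D9-PC34:2"``.
    lipid_class
        One of :data:`LIPID_CLASSES`.
    label_state
        One of :data:`LABEL_STATES`.
    precursor_mz, product_mz
        The SRM transition in Da; precursor must exceed product.
    n_carbons
        Total carbon atoms of the molecule (drives the ¹³C
        natural-abundance correction).
    n_labeled_methyls
        Labeled trideuteromethyl groups; must agree with
        :data:`METHYLS_BY_LABEL` for the label state.
    internal_standard
        Name of the internal-standard analyte this species is
        quantified against; ``None`` only for internal standards.
    acyl_group
        PC/PE fatty-acyl sub-group tag, ``"n/a"`` otherwise.
    is_internal_standard
        Marks the registry entries that are themselves spiked
        standards (D4-choline, PC20:0/20:0, PE14:0/14:0).
    """

    name: str
    lipid_class: str
    label_state: str
    precursor_mz: float
    product_mz: float
    n_carbons: int
    n_labeled_methyls: int = None  # type: ignore[assignment]
    internal_standard: str | None = None
    acyl_group: str = "n/a"
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValidationError(
                f"{self.name}: unknown class {self.lipid_class!r}")
        if self.label_state not in LABEL_STATES:
            raise ValidationError(
                f"{self.name}: unknown label state {self.label_state!r}")
        if self.n_labeled_methyls is None:
            object.__setattr__(
                self, "n_labeled_methyls", METHYLS_BY_LABEL[self.label_state])
        if self.n_labeled_methyls != METHYLS_BY_LABEL[self.label_state]:
            raise ValidationError(
                f"{self.name}: label {self.label_state} implies "
                f"{METHYLS_BY_LABEL[self.label_state]} labeled methyls, "
                f"got {self.n_labeled_methyls}")
        if not (self.precursor_mz > self.product_mz > 0):
            raise ValidationError(
                f"{self.name}: require precursor_mz > product_mz > 0 "
                f"({self.precursor_mz} → {self.product_mz})")
        if self.n_carbons <= 0:
            raise ValidationError(f"{self.name}: n_carbons must be positive")
        if self.acyl_group not in ACYL_GROUPS:
            raise ValidationError(
                f"{self.name}: unknown acyl group {self.acyl_group!r}")
        if not self.is_internal_standard and self.internal_standard is None:
            raise ValidationError(
                f"{self.name}: non-IS analyte must name an internal standard")


class Registry:
    """Immutable collection of :class:`AnalyteSpec`, indexed by name."""

    def __init__(self, specs: Iterable[AnalyteSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValidationError(f"duplicate analyte names: {dupes}")
        self._by_name = {s.name: s for s in specs}
        for s in specs:
            if s.internal_standard is not None:
                is_spec = self._by_name.get(s.internal_standard)
                if is_spec is None:
                    raise ValidationError(
                        f"{s.name}: internal standard "
                        f"{s.internal_standard!r} not in registry")
                if not is_spec.is_internal_standard:
                    raise ValidationError(
                        f"{s.name}: {s.internal_standard!r} is not flagged "
                        "as an internal standard")

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AnalyteSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"analyte {name!r} not in registry") from None

    def names(self) -> list[str]:
        return list(self._by_name)

    def by_class(self, lipid_class: str,
                 label_state: str | None = None,
                 include_is: bool = True) -> list[AnalyteSpec]:
        """All specs of one class, optionally restricted to one label."""
        out = [s for s in self if s.lipid_class == lipid_class]
        if label_state is not None:
            out = [s for s in out if s.label_state == label_state]
        if not include_is:
            out = [s for s in out if not s.is_internal_standard]
        return out


def _spec_from_record(rec: Mapping) -> AnalyteSpec:
    return AnalyteSpec(
        name=str(rec["name"]),
        lipid_class=str(rec["class"]),
        label_state=str(rec["label_state"]),
        precursor_mz=float(rec["precursor_mz"]),
        product_mz=float(rec["product_mz"]),
        n_carbons=int(rec["n_carbons"]),
        n_labeled_methyls=rec.get("n_labeled_methyls"),
        internal_standard=rec.get("internal_standard"),
        acyl_group=str(rec.get("acyl_group", "n/a")),
        is_internal_standard=bool(rec.get("is_internal_standard", False)),
    )


def load_registry(path: str | Path) -> Registry:
    """Load an analyte/transition registry from a YAML file.

    The file holds a list under the key ``analytes``, one mapping per
    analyte (see the packaged default registry for the schema).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "analytes" not in doc:
        raise ValidationError(f"{path}: no 'analytes' key")
    return Registry(_spec_from_record(rec) for rec in doc["analytes"])


def default_registry() -> Registry:
    """The packaged default SRM panel.

    Contains the full water-soluble transition set (choline, betaine,
    phosphocholine, glycerophosphocholine, dimethylglycine, methionine,
    carnitine and their deuterated analogues, plus CDP-choline), the
    PC/lyso-PC/SPH species ladders in unlabeled, D9 and D3 states, the
    PE species panel, and the three internal standards.
    """
    ref = resources.files("cholinetrace.data").joinpath(
        "default_registry.yaml")
    with resources.as_file(ref) as path:
        return load_registry(path)


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: identity, dose metadata and compartment sizes."""

    animal_id: str
    body_weight: float          # g
    time_point: float           # h after injection
    organ_weights: Mapping[str, float]  # organ -> wet weight, mg
    dose_mg_per_kg: float = 50.0
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError(f"{self.animal_id}: body_weight must be > 0")
        if self.time_point <= 0:
            raise ValidationError(f"{self.animal_id}: time_point must be > 0")
        for organ, w in self.organ_weights.items():
            if organ not in ORGANS:
                raise ValidationError(
                    f"{self.animal_id}: unknown organ {organ!r}")
            if w <= 0:
                raise ValidationError(
                    f"{self.animal_id}: organ weight {organ} must be > 0")


_ANIMAL_COLUMNS = ["animal_id", "body_weight_g", "time_point_h",
                   "liver_mg", "lung_mg", "cerebrum_mg", "cerebellum_mg",
                   "dose_mg_per_kg"]


def read_animals(path: str | Path) -> list[AnimalRecord]:
    """Read animal metadata from CSV (columns ``animal_id,
    body_weight_g, time_point_h, liver_mg, lung_mg, cerebrum_mg,
    cerebellum_mg, dose_mg_per_kg[, sex]``)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty animal table")
    missing = [c for c in _ANIMAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(AnimalRecord(
            animal_id=str(row["animal_id"]),
            body_weight=float(row["body_weight_g"]),
            time_point=float(row["time_point_h"]),
            organ_weights={o: float(row[f"{o}_mg"]) for o in ORGANS},
            dose_mg_per_kg=float(row["dose_mg_per_kg"]),
            sex=(str(row["sex"]) if "sex" in df.columns
                 and pd.notna(row.get("sex")) else None),
        ))
    return out


def write_animals(animals: Iterable[AnimalRecord], path: str | Path) -> None:
    rows = []
    for a in animals:
        row = {"animal_id": a.animal_id, "body_weight_g": a.body_weight,
               "time_point_h": a.time_point,
               **{f"{o}_mg": a.organ_weights[o] for o in ORGANS},
               "dose_mg_per_kg": a.dose_mg_per_kg}
        if a.sex is not None:
            row["sex"] = a.sex
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class _FrameTable:
    """Thin validated wrapper around a long-format DataFrame."""

    REQUIRED: tuple[str, ...] = ()

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{type(self).__name__}: missing columns {missing}")
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def _offenders(mask: pd.Series) -> str:
        rows = list(mask[mask].index[:10])
        return f"rows {rows}"


class MeasurementTable(_FrameTable):
    """Long table of raw SRM ion counts.

    Columns: ``animal_id, matrix, analyte, ion_count`` plus optional
    ``dilution_factor`` (≥1, defaults 1) and ``injected_fraction``
    (∈(0,1], defaults 1).  Dilution factors live here rather than in
    the registry because they vary by matrix and phase.
    """

    REQUIRED = ("animal_id", "matrix", "analyte", "ion_count")

    def __init__(self, df: pd.DataFrame, registry: Registry | None = None):
        self.registry = registry
        if "dilution_factor" not in df.columns:
            df = df.assign(dilution_factor=1.0)
        if "injected_fraction" not in df.columns:
            df = df.assign(injected_fraction=1.0)
        super().__init__(df)

    def _validate(self) -> None:
        df = self.df
        if df.empty:
            raise ValidationError("empty measurement table")
        bad = ~df["matrix"].isin(MATRICES)
        if bad.any():
            names = sorted(df.loc[bad, "matrix"].unique())
            raise ValidationError(
                f"unknown matrices {names} at {self._offenders(bad)}")
        neg = df["ion_count"] < 0
        if neg.any():
            raise ValidationError(
                f"negative ion counts at {self._offenders(neg)}")
        dil = df["dilution_factor"] < 1
        if dil.any():
            raise ValidationError(
                f"dilution_factor < 1 at {self._offenders(dil)}")
        frac = ~df["injected_fraction"].between(0, 1, inclusive="right")
        if frac.any():
            raise ValidationError(
                f"injected_fraction outside (0, 1] at {self._offenders(frac)}")
        if self.registry is not None:
            unknown = ~df["analyte"].isin(self.registry.names())
            if unknown.any():
                names = sorted(df.loc[unknown, "analyte"].unique())
                raise ValidationError(
                    f"unknown analytes {names} at {self._offenders(unknown)}")
            # Lavage fluid is too dilute for the water phase: no
            # water-soluble analyte may be reported for LLF.
            ws = df["analyte"].map(
                lambda a: self.registry[a].lipid_class == "water_soluble")
            bad = (df["matrix"] == "LLF") & ws
            if bad.any():
                raise ValidationError(
                    "water-soluble analytes reported for LLF at "
                    f"{self._offenders(bad)}")


class PoolTable(_FrameTable):
    """Absolute amounts (nmol) per animal × matrix × analyte.

    An optional ``concentration`` column carries nmol/mg tissue or
    nmol/µL plasma; the ``amount_nmol`` column is canonical.
    """

    REQUIRED = ("animal_id", "matrix", "analyte", "amount_nmol")

    def _validate(self) -> None:
        df = self.df
        bad = ~df["matrix"].isin(MATRICES)
        if bad.any():
            names = sorted(df.loc[bad, "matrix"].unique())
            raise ValidationError(
                f"unknown matrices {names} at {self._offenders(bad)}")
        neg = df["amount_nmol"] < 0
        if neg.any():
            raise ValidationError(
                f"negative amounts at {self._offenders(neg)}")


def read_measurements(path: str | Path,
                      registry: Registry | None = None) -> MeasurementTable:
    """Read a measurement table from CSV and validate it."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty measurement file")
    return MeasurementTable(df, registry=registry)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_pool_table(path: str | Path) -> PoolTable:
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty pool file")
    return PoolTable(df)


def write_pool_table(table: PoolTable, path: str | Path) -> None:
    """Write a pool table to CSV; full float precision so that a
    write→read round trip is lossless."""
    table.df.to_csv(path, index=False)


def reference_pools() -> pd.DataFrame:
    """Packaged reference endogenous pool sizes for day-14 rats.

    Whole-study means ± SE (N = 27 animals) of organ wet weights and
    endogenous (unlabeled + deuterated) pools of choline, its
    water-soluble metabolites and the choline phospholipid classes, in
    canonical units (nmol, mg).  The plasma "organ weight" is the
    plasma compartment mass in mg.
    """
    ref = resources.files("cholinetrace.data").joinpath(
        "reference_pools.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_label_fractions() -> pd.DataFrame:
    """Packaged reference dose-fraction time course.

    Percent of the administered trideuteromethyl label recovered in the
    analyzed compartments, by category (water-soluble D9-derived
    metabolites, D9-phospholipids, D3-phospholipids) at 1.5, 6 and
    24 h; means ± SE of 8–10 animals per time point.  These summary
    values are the calibration reference for the tracer simulator.
    """
    ref = resources.files("cholinetrace.data").joinpath(
        "reference_label_fractions.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
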