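"""End-to-end orchestration: validate → quantify → pools → fractions
→ contrasts, with a serializable run configuration and a run log that
records every physiological constant used."""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (AnimalRecord, MeasurementTable, PoolTable, Registry,
                      ValidationError, default_registry, load_registry,
                      read_animals, read_measurements, write_pool_table)
from .kinetics_stats import compare_groups
from .label_accounting import DoseSpec, compute_dose
from .pools import (WHOLE_BODY_CHOLINE_PL_NMOL_PER_G, PlasmaVolumeModel,
                    concentration, plasma_volume_from_mass,
                    pool_fractions, whole_body_reference_nmol)
from .quantify import apply_isotope_correction, build_c13_matrix
from .simulator import (DEFAULT_IS_AMOUNTS_NMOL, _channel_families,
                        _is_for_class)

__all__ = [
    "RunConfig",
    "quantify_measurements",
    "category_fractions",
    "fraction_summary",
    "descriptive_fractions",
    "run_all",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one analysis run."""

    animals_path: str
    measurements_path: str
    out_dir: str | None = None
    registry_path: str | None = None
    plasma_model: PlasmaVolumeModel = field(default_factory=PlasmaVolumeModel)
    dose: DoseSpec = field(default_factory=DoseSpec)
    n_stat_families: int = 1
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        doc["plasma_model"] = PlasmaVolumeModel(**doc.get("plasma_model", {}))
        doc["dose"] = DoseSpec(**doc.get("dose", {}))
        return cls(**doc)


def quantify_measurements(measurements: MeasurementTable,
                          registry: Registry | None = None,
                          is_amounts: dict | None = None) -> PoolTable:
    """Raw SRM counts → absolute amounts, one row per analyte.

    Counts are grouped into SRM channel families (one per lipid class
    × label state; all water-soluble analytes together), corrected
    for ¹³C spillover within each family, and quantified against the
    family's internal-standard count and spike amount.  Extracts here
    represent whole compartments, so the returned amounts are pool
    sizes (nmol).
    """
    registry = registry or default_registry()
    is_amounts = is_amounts or DEFAULT_IS_AMOUNTS_NMOL
    df = measurements.df
    is_counts = (df[df["analyte"].map(
        lambda a: a in registry and registry[a].is_internal_standard)]
        .set_index(["animal_id", "matrix", "analyte"])["ion_count"])
    frames = []
    for (lipid_class, label), specs in _channel_families(registry).items():
        names = [s.name for s in specs]
        sub = df[df["analyte"].isin(names)]
        if sub.empty:
            continue
        is_name = _is_for_class(lipid_class)
        is_amt = is_amounts[is_name]
        wide = sub.pivot_table(index=["animal_id", "matrix"],
                               columns="analyte", values="ion_count",
                               aggfunc="sum", fill_value=0.0)
        if lipid_class == "water_soluble":
            order = [n for n in names if n in wide.columns]
            corrected = wide.reindex(columns=order, fill_value=0.0).to_numpy()
        else:
            C = build_c13_matrix(specs)
            order = list(C.species)
            raw = wide.reindex(columns=order, fill_value=0.0).to_numpy()
            corrected, _ = apply_isotope_correction(raw, C)
        ratios = np.empty_like(corrected)
        for r, (animal, matrix) in enumerate(wide.index):
            try:
                isc = float(is_counts.loc[(animal, matrix, is_name)])
            except KeyError:
                raise ValidationError(
                    f"no internal-standard ({is_name}) count for sample "
                    f"{animal}/{matrix}") from None
            if isc <= 0:
                raise ValidationError(
                    f"zero internal-standard ({is_name}) count for sample "
                    f"{animal}/{matrix}")
            ratios[r] = corrected[r] / isc * is_amt
        long = pd.DataFrame(ratios, index=wide.index, columns=order)
        long = long.stack().rename("amount_nmol").reset_index()
        long.columns = ["animal_id", "matrix", "analyte", "amount_nmol"]
        frames.append(long)
    if not frames:
        raise ValidationError("no quantifiable analytes in measurement table")
    return PoolTable(pd.concat(frames, ignore_index=True))


def _category(spec) -> str | None:
    if spec.is_internal_standard:
        return None
    if spec.lipid_class in ("PC", "lysoPC", "SPH"):
        if spec.label_state == "D9":
            return "D9_phospholipid"
        if spec.label_state == "D3":
            return "D3_phospholipid"
        return None
    if spec.lipid_class == "water_soluble" and spec.label_state in (
            "D9", "D6", "D3"):
        return "water_soluble_D9_derived"
    return None


def category_fractions(pools: PoolTable,
                       animals: list[AnimalRecord],
                       registry: Registry | None = None,
                       dose: DoseSpec | None = None) -> pd.DataFrame:
    """Per-animal methyl-corrected percent of dose by label category."""
    registry = registry or default_registry()
    dose = dose or DoseSpec()
    meta = {a.animal_id: a for a in animals}
    df = pools.df.copy()
    df["category"] = df["analyte"].map(
        lambda n: _category(registry[n]) if n in registry else None)
    df = df.dropna(subset=["category"])
    df["weight"] = df["analyte"].map(
        lambda n: registry[n].n_labeled_methyls / 3.0)
    rows = []
    for (animal, cat), g in df.groupby(["animal_id", "category"]):
        a = meta[animal]
        dose_nmol = compute_dose(a.body_weight, dose)
        weighted = float((g["amount_nmol"] * g["weight"]).sum())
        rows.append({"animal_id": animal, "time_point_h": a.time_point,
                     "category": cat,
                     "percent_of_dose": 100.0 * weighted / dose_nmol})
    return pd.DataFrame(rows)


def fraction_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SE of dose fractions per time point × category."""
    g = per_animal.groupby(["time_point_h", "category"])["percent_of_dose"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "percent_of_dose", "sem": "se",
                               "count": "n"})


def descriptive_fractions(reference: pd.DataFrame,
                          body_weight_g: float = 28.2) -> dict[str, float]:
    """Descriptive organ fractions from a reference pool table.

    Computes, for each solid organ, its percent of body mass and its
    choline-phospholipid pool as percent of the whole-body
    choline-phospholipid estimate (10 µmol per g body weight); plus
    the analyzed compartments' share of body weight, the summed
    analyzed choline-phospholipid pool as percent of that whole-body
    estimate, and the plasma choline-phospholipid concentration
    (µmol/mL).
    """
    body_mg = body_weight_g * 1000.0
    whole_body = whole_body_reference_nmol(body_weight_g)
    lipids = reference[reference["analyte"].isin(["PC", "lysoPC", "SPH"])]
    chopl = lipids.groupby("matrix")["amount_nmol"].sum()
    total_chopl = float(chopl.sum())
    sizes = (reference.dropna(subset=["compartment_size"])
             .drop_duplicates("matrix").set_index("matrix")
             ["compartment_size"])
    out: dict[str, float] = {}
    for organ in ("liver", "cerebrum", "cerebellum", "lung"):
        out[f"{organ}_pct_body_mass"] = pool_fractions(
            sizes[organ], body_mg)
        out[f"{organ}_pct_choline_lipids"] = pool_fractions(
            chopl[organ], whole_body)
    out["compartments_pct_body_weight"] = pool_fractions(
        float(sizes.sum()), body_mg)
    out["choline_lipids_pct_whole_body"] = pool_fractions(
        total_chopl, whole_body)
    plasma_vol = plasma_volume_from_mass(sizes["plasma"])
    out["plasma_choline_pl_umol_per_ml"] = concentration(
        chopl["plasma"], plasma_vol)  # nmol/µL ≡ µmol/mL
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and return the report bundle.

    Stages: validate inputs → quantify counts → pool table →
    dose-fraction report → time-point contrasts.  Deterministic for
    fixed config and inputs; the log lists every constant used.
    Writes CSVs into ``config.out_dir`` when given.
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        print(msg, file=sys.stderr)

    say(f"constants: blood_fraction={config.plasma_model.blood_fraction} "
        f"hematocrit={config.plasma_model.hematocrit} "
        f"plasma_density={config.plasma_model.plasma_density} g/mL "
        f"dose={config.dose.dose_mg_per_kg} mg/kg "
        f"({config.dose.nmol_per_g:.1f} nmol/g) "
        f"whole_body_ref={WHOLE_BODY_CHOLINE_PL_NMOL_PER_G / 1000:.0f} "
        "umol/g")
    registry = (load_registry(config.registry_path)
                if config.registry_path else default_registry())
    try:
        animals = read_animals(config.animals_path)
        measurements = read_measurements(config.measurements_path,
                                         registry=registry)
    except ValidationError as err:
        raise ValidationError(f"stage validate: {err}") from err
    say(f"validate: {len(animals)} animals, {len(measurements)} "
        "measurement rows")
    try:
        pools = quantify_measurements(measurements, registry)
    except ValidationError as err:
        raise ValidationError(f"stage quantify: {err}") from err
    say(f"quantify: {len(pools)} pool rows")
    per_animal = category_fractions(pools, animals, registry, config.dose)
    fractions = fraction_summary(per_animal)
    say(f"fractions: {len(fractions)} category × time summaries")
    contrasts = _contrast_table(per_animal, config.n_stat_families)
    say(f"contrasts: {len(contrasts)} pairwise time comparisons")
    bundle = {"pools": pools.df, "fractions": fractions,
              "per_animal_fractions": per_animal,
              "contrasts": contrasts, "log": log}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pool_table(pools, out / "pools.csv")
        fractions.to_csv(out / "fractions.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return bundle


def _contrast_table(per_animal: pd.DataFrame, n_families: int) -> pd.DataFrame:
    """Tukey-within-family, Bonferroni-across-families time contrasts
    of the per-animal dose fractions, one family per category."""
    rows = []
    cats = sorted(per_animal["category"].unique())
    n_families = max(n_families, len(cats))
    for cat, g in per_animal.groupby("category"):
        times = sorted(g["time_point_h"].unique())
        groups = [g.loc[g["time_point_h"] == t, "percent_of_dose"].to_numpy()
                  for t in times]
        if len(groups) < 2 or any(len(x) < 2 for x in groups):
            continue
        for res in compare_groups(groups, labels=[str(t) for t in times],
                                  n_families=n_families):
            rows.append({"category": cat, "pair": "-".join(res["pair"]),
                         "p_raw": res["p_raw"], "p_adj": res["p_adj"],
                         "significant": res["significant"]})
    return pd.DataFrame(rows)
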