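"""First-order compartmental simulator of the choline tracer network.

The injected trideuterated-methyl choline bolus is followed through a
linear mass-action network of (organ, species, label) compartments:
intraperitoneal absorption into plasma; cellular uptake; de novo PC
synthesis through phosphocholine and CDP-choline; hepatic choline
oxidation to betaine; betaine demethylation handing one labeled
methyl to methionine (leaving D6-dimethylglycine); methylation-driven
D3-PC synthesis; PC catabolism through lyso-PC and
glycerophosphocholine back to free choline; sphingomyelin synthesis
by phosphocholine transfer from PC; hepatic VLDL and pulmonary HDL
secretion of PC into plasma with organ re-uptake; and apical
secretion into bile (liver) and lung lavage fluid (surfactant).

Linear kinetics are justified at tracer doses (choline transporters
operate far below saturation) and make the system exactly solvable,
so conservation and closed-form cross-checks are sharp.  Unlabeled
endogenous pools are not simulated; they are held at their
steady-state reference values.

Label bookkeeping is per trideuteromethyl group: every edge maps the
methyl groups of one consumed molecule completely onto its products
(betaine consumption yields dimethylglycine *plus* a methionine-bound
methyl), so the methyl-weighted total over all compartments —
including the unobserved peritoneum, carcass and bile — is conserved
exactly.

Default rate constants are the package's own calibration: they are
chosen so the deterministic trajectories reproduce the reference
dose-fraction time course (see
:func:`cholinetrace.core_io.reference_label_fractions`) and the
organ-level PC kinetics of the study design this generator emulates.
They are calibrated summaries, not fitted per-animal estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .core_io import (METHYLS_BY_LABEL, AnimalRecord, MeasurementTable,
                      PoolTable, Registry, ValidationError, default_registry,
                      reference_pools)
from .label_accounting import DoseSpec
from .pools import estimate_plasma_volume
from .quantify import build_c13_matrix

__all__ = [
    "TracerNetwork",
    "SimulationConfig",
    "DEFAULT_RATES",
    "default_network",
    "simulate",
    "dose_fractions",
    "sample_study",
    "fit_transfer_rate",
    "OBSERVED_ORGANS",
    "DEFAULT_IS_AMOUNTS_NMOL",
]

#: Compartment organs reported in the study design (the measured set).
OBSERVED_ORGANS = ("liver", "plasma", "lung", "LLF", "cerebrum", "cerebellum")

#: Unobserved organs: injection site, the rest of the body (muscle,
#: kidney, intestine, excretion) and biliary secretion.
HIDDEN_ORGANS = ("peritoneum", "carcass", "bile")

_WATER_SPECIES = ("choline", "phosphocholine", "CDP-choline", "GPC",
                  "betaine", "DMG", "methionine")
_LIPID_SPECIES = ("PC", "PCm", "lysoPC", "SPH")

#: Internal-standard spike amounts per extract (nmol).
DEFAULT_IS_AMOUNTS_NMOL = {
    "D4-choline": 10.0,
    "PC20:0/20:0": 50.0,
    "PE14:0/14:0": 20.0,
}

_IS_BASE_COUNT = 1.0e6


def _cid(organ: str, species: str, label: str) -> str:
    return f"{organ}:{species}:{label}"


def _label_of(cid: str) -> str:
    return cid.rsplit(":", 1)[1]


def methyl_weight(cid: str) -> float:
    """Labeled-methyl weight of a compartment: n_labeled_methyls / 3."""
    return METHYLS_BY_LABEL[_label_of(cid)] / 3.0


@dataclass(frozen=True)
class TracerNetwork:
    """Compartments plus first-order edges.

    Each edge is ``(source, rate, products)``: the source compartment
    loses material at ``rate`` (per hour) and *every* product
    compartment gains the full molar flux (a two-product edge is a
    molecular split, e.g. betaine → dimethylglycine + a
    methionine-bound methyl group).
    """

    compartments: tuple[str, ...]
    edges: tuple[tuple[str, float, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        known = set(self.compartments)
        for src, k, prods in self.edges:
            if k < 0:
                raise ValidationError(f"negative rate on edge from {src}")
            if src not in known or any(p not in known for p in prods):
                raise ValidationError(f"edge {src}→{prods} uses unknown "
                                      "compartments")
            w_src = methyl_weight(src)
            w_out = sum(methyl_weight(p) for p in prods)
            if abs(w_src - w_out) > 1e-12:
                raise ValidationError(
                    f"edge {src}→{prods} does not conserve labeled methyls "
                    f"({w_src:.3f} → {w_out:.3f})")

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.compartments)}

    def rate_matrix(self) -> np.ndarray:
        """System matrix A of ``dx/dt = A·x``."""
        idx = self.index()
        n = len(self.compartments)
        A = np.zeros((n, n))
        for src, k, prods in self.edges:
            j = idx[src]
            A[j, j] -= k
            for p in prods:
                A[idx[p], j] += k
        return A

    def methyl_weights(self) -> np.ndarray:
        return np.array([methyl_weight(c) for c in self.compartments])


#: Calibrated default rate constants (per hour).
DEFAULT_RATES: dict[str, float] = {
    # intraperitoneal absorption
    "k_abs": 5.661,
    # plasma free-choline uptake
    "k_cho_up_liver": 70.85,
    "k_cho_up_lung": 3.853,
    "k_cho_up_cerebrum": 0.05,
    "k_cho_up_cerebellum": 0.02,
    "k_cho_up_carcass": 120.0,
    "k_cho_efflux": 0.30,
    # return of the whole-body exchangeable choline/betaine pools
    # into plasma (gives the observed fast-then-slow decay)
    "k_cho_return": 0.001,
    "k_bet_return": 0.6097,
    # choline kinase / CTP:phosphocholine cytidylyltransferase /
    # CDP-choline:DAG cholinephosphotransferase
    "k_ck_liver": 2.305,
    "k_ck_lung": 20.0,
    "k_ck_cerebrum": 3.0,
    "k_ck_cerebellum": 3.0,
    "k_ct_liver": 4.453,
    "k_ct_lung": 1.2,
    "k_ct_cerebrum": 0.05317,
    "k_ct_cerebellum": 0.05317,
    "k_cpt": 25.0,
    # hepatic choline oxidation and the betaine/methionine branch
    "k_ox": 1.941,
    "k_bhmt": 0.438,
    "k_bet_out": 0.1601,
    "k_bet_in": 0.25,
    "k_bet_carcass": 1.849,
    "k_dmg_out": 0.05482,
    "k_dmg_carcass": 3.0,
    "k_dmg_deg": 3.0,
    "k_met_out": 0.05,
    "k_met_carcass": 3.0,
    "k_met_use": 0.005,
    "k_pemt": 1.429,
    # PC trafficking
    "k_vldl": 0.1,
    "k_bile": 0.5,
    "k_pc_up_liver": 0.005,
    "k_pc_up_lung": 0.02504,
    "k_pc_up_cerebrum": 0.01824,
    "k_pc_up_cerebellum": 0.007572,
    "k_pc_up_carcass": 0.001,
    "k_hdl": 0.4423,
    "k_surf": 0.004432,
    # PC catabolism and sphingomyelin synthesis
    "k_memb_liver": 0.4414,
    "k_memb_lung": 0.02,
    "k_vldl_slow": 0.03814,
    "k_surf_m": 0.001673,
    "k_pla": 0.010,
    "k_lyso": 0.40,
    "k_gpc": 0.60,
    "k_sms_liver": 0.0015,
    "k_sms_lung": 0.0060,
    "k_sms_cerebrum": 0.0015,
    "k_sms_cerebellum": 0.0015,
}

_TISSUES = ("liver", "lung", "cerebrum", "cerebellum")


def default_network(rates: Mapping[str, float] | None = None) -> TracerNetwork:
    """Build the packaged network topology.

    Parameters
    ----------
    rates
        Optional overrides of :data:`DEFAULT_RATES` (unknown keys are
        rejected).
    """
    R = dict(DEFAULT_RATES)
    if rates:
        unknown = set(rates) - set(R)
        if unknown:
            raise ValidationError(f"unknown rate constants: {sorted(unknown)}")
        R.update(rates)

    edges: list[tuple[str, float, tuple[str, ...]]] = []

    def add(src, k, *prods):
        if k > 0:
            edges.append((src, float(k), tuple(prods)))

    # the tracer itself and its recycled D3 analogue share the
    # CDP-choline machinery
    for lab in ("D9", "D3"):
        add(_cid("peritoneum", "choline", lab), R["k_abs"] if lab == "D9"
            else 0.0, _cid("plasma", "choline", lab))
        for organ in _TISSUES:
            add(_cid("plasma", "choline", lab), R[f"k_cho_up_{organ}"],
                _cid(organ, "choline", lab))
            add(_cid(organ, "choline", lab), R["k_cho_efflux"],
                _cid("plasma", "choline", lab))
            add(_cid(organ, "choline", lab), R[f"k_ck_{organ}"],
                _cid(organ, "phosphocholine", lab))
            add(_cid(organ, "phosphocholine", lab), R[f"k_ct_{organ}"],
                _cid(organ, "CDP-choline", lab))
            add(_cid(organ, "CDP-choline", lab), R["k_cpt"],
                _cid(organ, "PC", lab))
            # catabolic arm and sphingomyelin synthesis
            add(_cid(organ, "PC", lab), R["k_pla"],
                _cid(organ, "lysoPC", lab))
            add(_cid(organ, "lysoPC", lab), R["k_lyso"],
                _cid(organ, "GPC", lab))
            add(_cid(organ, "GPC", lab), R["k_gpc"],
                _cid(organ, "choline", lab))
            add(_cid(organ, "PC", lab), R[f"k_sms_{organ}"],
                _cid(organ, "SPH", lab))
        add(_cid("plasma", "choline", lab), R["k_cho_up_carcass"],
            _cid("carcass", "choline", lab))
        add(_cid("carcass", "choline", lab), R["k_cho_return"],
            _cid("plasma", "choline", lab))
        # PC trafficking between organs via plasma lipoproteins.
        # Liver and lung carry two PC pools: a nascent secretory pool
        # ("PC", fed by de novo synthesis, exported quickly) and a
        # membrane pool ("PCm", incorporated and turned over slowly).
        add(_cid("liver", "PC", lab), R["k_vldl"], _cid("plasma", "PC", lab))
        add(_cid("liver", "PC", lab), R["k_bile"], _cid("bile", "PC", lab))
        add(_cid("liver", "PC", lab), R["k_memb_liver"],
            _cid("liver", "PCm", lab))
        add(_cid("liver", "PCm", lab), R["k_vldl_slow"],
            _cid("plasma", "PC", lab))
        add(_cid("liver", "PCm", lab), R["k_pla"],
            _cid("liver", "lysoPC", lab))
        for organ in _TISSUES:
            target_pool = "PCm" if organ in ("liver", "lung") else "PC"
            add(_cid("plasma", "PC", lab), R[f"k_pc_up_{organ}"],
                _cid(organ, target_pool, lab))
        add(_cid("plasma", "PC", lab), R["k_pc_up_carcass"],
            _cid("carcass", "PC", lab))
        add(_cid("lung", "PC", lab), R["k_hdl"], _cid("plasma", "PC", lab))
        add(_cid("lung", "PC", lab), R["k_memb_lung"],
            _cid("lung", "PCm", lab))
        add(_cid("lung", "PC", lab), R["k_surf"], _cid("LLF", "PC", lab))
        add(_cid("lung", "PCm", lab), R["k_surf_m"],
            _cid("LLF", "PC", lab))
        add(_cid("lung", "PCm", lab), R["k_pla"],
            _cid("lung", "lysoPC", lab))

    # hepatic oxidation feeds the one-carbon branch (tracer only; the
    # minor oxidation of recycled D3-choline is neglected)
    add(_cid("liver", "choline", "D9"), R["k_ox"],
        _cid("liver", "betaine", "D9"))
    add(_cid("liver", "betaine", "D9"), R["k_bet_out"],
        _cid("plasma", "betaine", "D9"))
    add(_cid("plasma", "betaine", "D9"), R["k_bet_in"],
        _cid("liver", "betaine", "D9"))
    add(_cid("plasma", "betaine", "D9"), R["k_bet_carcass"],
        _cid("carcass", "betaine", "D9"))
    add(_cid("carcass", "betaine", "D9"), R["k_bet_return"],
        _cid("plasma", "betaine", "D9"))
    # demethylation: one methyl to the methionine pool, two stay on DMG
    add(_cid("liver", "betaine", "D9"), R["k_bhmt"],
        _cid("liver", "DMG", "D6"), _cid("liver", "methionine", "D3"))
    add(_cid("liver", "DMG", "D6"), R["k_dmg_out"],
        _cid("plasma", "DMG", "D6"))
    add(_cid("plasma", "DMG", "D6"), R["k_dmg_carcass"],
        _cid("carcass", "DMG", "D6"))
    add(_cid("liver", "DMG", "D6"), R["k_dmg_deg"],
        _cid("carcass", "DMG", "D6"))
    add(_cid("liver", "methionine", "D3"), R["k_met_out"],
        _cid("plasma", "methionine", "D3"))
    add(_cid("plasma", "methionine", "D3"), R["k_met_carcass"],
        _cid("carcass", "methionine", "D3"))
    add(_cid("liver", "methionine", "D3"), R["k_met_use"],
        _cid("carcass", "methionine", "D3"))
    # PE tri-methylation with label-diluted methyl donor yields
    # predominantly singly-labeled PC
    add(_cid("liver", "methionine", "D3"), R["k_pemt"],
        _cid("liver", "PC", "D3"))

    comps = sorted({c for src, _, prods in edges for c in (src, *prods)}
                   | {_cid("peritoneum", "choline", "D9")})
    return TracerNetwork(tuple(comps), tuple(edges))


def simulate(network: TracerNetwork,
             dose_nmol: float,
             times: Sequence[float],
             rtol: float = 1e-10,
             atol: float = 1e-12) -> pd.DataFrame:
    """Integrate the linear system from a bolus in the peritoneum.

    Returns a DataFrame indexed by compartment with one column per
    requested time (plus t = 0).
    """
    if dose_nmol < 0:
        raise ValidationError("dose must be non-negative")
    times = sorted(set(float(t) for t in times))
    if any(t < 0 for t in times):
        raise ValidationError("times must be non-negative")
    A = network.rate_matrix()
    idx = network.index()
    x0 = np.zeros(len(network.compartments))
    x0[idx[_cid("peritoneum", "choline", "D9")]] = dose_nmol
    t_end = max(times) if times else 0.0
    sol = solve_ivp(lambda t, x: A @ x, (0.0, max(t_end, 1e-9)), x0,
                    t_eval=[t for t in times if t > 0] or None,
                    method="LSODA", rtol=rtol,
                    atol=atol * max(dose_nmol, 1.0), jac=lambda t, x: A)
    if not sol.success:
        raise RuntimeError(f"tracer integration failed: {sol.message}")
    cols: dict[float, np.ndarray] = {}
    if 0.0 in times or not times:
        cols[0.0] = x0
    for t, x in zip(sol.t, sol.y.T):
        cols[float(t)] = np.clip(x, 0.0, None)
    out = pd.DataFrame(cols, index=list(network.compartments))
    return out[sorted(cols)]


def _category_of(cid: str) -> str | None:
    organ, species, label = cid.split(":")
    if organ not in OBSERVED_ORGANS:
        return None
    if species in _LIPID_SPECIES:
        if label == "D9":
            return "D9_phospholipid"
        if label == "D3":
            return "D3_phospholipid"
    elif label in ("D9", "D6", "D3"):
        return "water_soluble_D9_derived"
    return None


def dose_fractions(trajectories: pd.DataFrame, dose_nmol: float
                   ) -> pd.DataFrame:
    """Methyl-corrected percent of dose per category and time point.

    Categories follow the reference report: water-soluble
    tracer-derived metabolites, D9-phospholipids and
    D3-phospholipids, summed over the observed organs and plasma.
    """
    weights = np.array([methyl_weight(c) for c in trajectories.index])
    cats = [_category_of(c) for c in trajectories.index]
    rows = []
    for cat in ("water_soluble_D9_derived", "D9_phospholipid",
                "D3_phospholipid"):
        mask = np.array([c == cat for c in cats])
        for t in trajectories.columns:
            amount = float(
                (trajectories[t].to_numpy() * weights)[mask].sum())
            rows.append({"time_point_h": float(t), "category": cat,
                         "percent_of_dose": 100.0 * amount / dose_nmol})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic study generation


#: Equilibrium PC acyl sub-group profiles per matrix (fractions of
#: class total over sat / C18:1 / C18:2 / C20:4 / C22:6).
EQUILIBRIUM_PC_PROFILE: dict[str, dict[str, float]] = {
    "liver":      {"sat": 0.22, "C18:1": 0.12, "C18:2": 0.30,
                   "C20:4": 0.26, "C22:6": 0.10},
    "plasma":     {"sat": 0.25, "C18:1": 0.10, "C18:2": 0.35,
                   "C20:4": 0.22, "C22:6": 0.08},
    "lung":       {"sat": 0.50, "C18:1": 0.22, "C18:2": 0.10,
                   "C20:4": 0.16, "C22:6": 0.02},
    "LLF":        {"sat": 0.70, "C18:1": 0.15, "C18:2": 0.08,
                   "C20:4": 0.05, "C22:6": 0.02},
    "cerebrum":   {"sat": 0.45, "C18:1": 0.267, "C18:2": 0.065,
                   "C20:4": 0.171, "C22:6": 0.047},
    "cerebellum": {"sat": 0.45, "C18:1": 0.287, "C18:2": 0.07,
                   "C20:4": 0.141, "C22:6": 0.052},
}

#: Acyl profile of freshly synthesized hepatic PC (linoleoyl-rich
#: de novo output, before remodeling).
SYNTHESIS_PC_PROFILE = {"sat": 0.20, "C18:1": 0.15, "C18:2": 0.40,
                        "C20:4": 0.15, "C22:6": 0.10}

#: Organ-specific acyl remodeling relaxation rates toward the local
#: equilibrium profile (per hour).  Large = newly made PC instantly
#: matches endogenous composition.
REMODELING_RATE = {"liver": 0.05, "plasma": 0.02, "lung": 5.0,
                   "LLF": 5.0, "cerebrum": 0.12, "cerebellum": 0.12}

#: Split of each acyl sub-group over its registry species.
_SPECIES_SPLIT = {
    "sat": (("PC32:0", 1.0),),
    "C18:1": (("PC34:1", 1.0),),
    "C18:2": (("PC34:2", 0.7), ("PC36:2", 0.3)),
    "C20:4": (("PC36:4", 0.6), ("PC38:4", 0.4)),
    "C22:6": (("PC38:6", 0.6), ("PC40:6", 0.4)),
}


def labeled_pc_profile(matrix: str, t: float) -> dict[str, float]:
    """Acyl sub-group profile of labeled PC in one matrix at time t.

    Exponential relaxation from the hepatic synthesis profile toward
    the organ's equilibrium profile — a single remodeling rate per
    organ, not a full deacylation/re-acylation cycle model.
    """
    eq = EQUILIBRIUM_PC_PROFILE[matrix]
    k = REMODELING_RATE[matrix]
    w = float(np.exp(-k * t))
    return {g: eq[g] + (SYNTHESIS_PC_PROFILE[g] - eq[g]) * w for g in eq}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of the synthetic experiment.

    Defaults are the emulated study's conditions: three sacrifice
    times, 9 animals per time point, day-14 pups of ~28 g, biological
    between-animal variation of 15% (multiplicative lognormal) and a
    5% technical noise on ion counts.
    """

    n_animals_per_timepoint: int = 9
    time_points: tuple[float, ...] = (1.5, 6.0, 24.0)
    body_weight_mean_g: float = 28.2
    body_weight_sd_g: float = 2.1
    animal_cv: float = 0.15
    technical_cv: float = 0.05
    dose: DoseSpec = field(default_factory=DoseSpec)
    seed: int = 20220720

    def __post_init__(self) -> None:
        if self.n_animals_per_timepoint < 1:
            raise ValidationError("need at least one animal per time point")
        if any(t <= 0 for t in self.time_points):
            raise ValidationError("time points must be positive")
        if self.animal_cv < 0 or self.technical_cv < 0:
            raise ValidationError("noise CVs must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


_WS_ANALYTE = {
    ("choline", "unlabeled"): "choline",
    ("choline", "D9"): "D9-choline",
    ("choline", "D3"): "D3-choline",
    ("phosphocholine", "unlabeled"): "phosphocholine",
    ("phosphocholine", "D9"): "D9-phosphocholine",
    ("CDP-choline", "unlabeled"): "CDP-choline",
    ("CDP-choline", "D9"): "D9-CDP-choline",
    ("GPC", "unlabeled"): "GPC",
    ("GPC", "D9"): "D9-GPC",
    ("betaine", "unlabeled"): "betaine",
    ("betaine", "D9"): "D9-betaine",
    ("DMG", "unlabeled"): "DMG",
    ("DMG", "D6"): "D6-DMG",
    ("methionine", "unlabeled"): "methionine",
    ("methionine", "D3"): "D3-methionine",
}

_LIPID_DILUTION = 157.0
_WATER_DILUTION = {"liver": 110.0, "plasma": 7.5, "lung": 7.5,
                   "cerebrum": 7.5, "cerebellum": 7.5}


def _species_amounts(matrix: str, species: str, label: str, amount: float,
                     t: float) -> dict[str, float]:
    """Distribute a class-level labeled/unlabeled amount over the
    registry species of that class."""
    if species not in ("PC", "lysoPC", "SPH"):
        name = _WS_ANALYTE.get((species, label))
        return {name: amount} if name else {}
    prefix = {"unlabeled": "", "D9": "D9-", "D3": "D3-"}[label]
    if species == "PC":
        if label == "unlabeled":
            profile = EQUILIBRIUM_PC_PROFILE[matrix]
        else:
            profile = labeled_pc_profile(matrix, t)
        out: dict[str, float] = {}
        for grp, frac in profile.items():
            for sp, w in _SPECIES_SPLIT[grp]:
                out[f"{prefix}{sp}"] = amount * frac * w
        return out
    if species == "lysoPC":
        return {f"{prefix}lysoPC16:0": amount}
    return {f"{prefix}SPH16:0": amount}


def sample_study(network: TracerNetwork | None = None,
                 config: SimulationConfig | None = None,
                 registry: Registry | None = None,
                 trajectories: pd.DataFrame | None = None
                 ) -> tuple[list[AnimalRecord], PoolTable, MeasurementTable]:
    """Generate one synthetic study: animals, truth pools, raw counts.

    Per-animal true pools are the deterministic trajectory value
    scaled by the animal's dose and a lognormal between-animal effect;
    endogenous pools are the steady-state reference concentrations
    scaled by the animal's organ weights.  Raw SRM counts are then
    synthesized by the forward model of the quantify module (internal
    standard ratios, ¹³C isotopologue spillover, technical noise), so
    that quantification followed by pool computation inverts this
    generator up to noise.

    Returns ``(animals, truth_pools, measurements)``; the same seed
    reproduces identical tables.
    """
    config = config or SimulationConfig()
    registry = registry or default_registry()
    if trajectories is None:
        network = network or default_network()
        # linear system: simulate a unit dose once, scale per animal
        trajectories = simulate(network, 1.0, config.time_points)
    rng = np.random.default_rng(config.seed)
    ref = reference_pools()
    ref = ref[ref["analyte"] != "TMAO"]

    animals: list[AnimalRecord] = []
    pool_rows: list[dict] = []
    n = config.n_animals_per_timepoint
    organ_ref = (ref.drop_duplicates("matrix")
                 .set_index("matrix")[["compartment_size",
                                       "compartment_size_se"]])
    # per-animal organ weights: reference mean with the between-animal
    # SD implied by the reference SE (N = 27)
    organ_sd = organ_ref["compartment_size_se"] * np.sqrt(27.0)

    aid = 0
    for t in config.time_points:
        for _ in range(n):
            aid += 1
            bw = float(np.clip(
                rng.normal(config.body_weight_mean_g,
                           config.body_weight_sd_g), 5.0, None))
            weights = {}
            for organ in ("liver", "lung", "cerebrum", "cerebellum"):
                mu = organ_ref.loc[organ, "compartment_size"]
                sd = organ_sd.loc[organ]
                # organs scale with body size
                scale = bw / config.body_weight_mean_g
                weights[organ] = float(np.clip(
                    rng.normal(mu * scale, sd), mu * 0.3, None))
            animals.append(AnimalRecord(
                animal_id=f"A{aid:03d}", body_weight=bw, time_point=t,
                organ_weights=weights,
                dose_mg_per_kg=config.dose.dose_mg_per_kg))

    traj = trajectories
    for a in animals:
        t = a.time_point
        dose_nmol = a.body_weight * config.dose.nmol_per_g
        plasma_vol = estimate_plasma_volume(a.body_weight)
        # labeled pools from the kinetic model
        per_class: dict[tuple[str, str, str], float] = {}
        for cid in traj.index:
            organ, species, label = cid.split(":")
            if organ not in OBSERVED_ORGANS:
                continue
            frac = float(traj.loc[cid, t])
            if frac <= 0:
                continue
            if species == "PCm":
                species = "PC"
            noise = float(_lognormal_factor(rng, config.animal_cv, None))
            key = (organ, species, label)
            per_class[key] = per_class.get(key, 0.0) + (
                dose_nmol * frac * noise)
        # endogenous pools at steady state, scaled to the animal
        for _, row in ref.iterrows():
            matrix = row["matrix"]
            if matrix == "LLF":
                scale = 1.0
            elif matrix == "plasma":
                scale = plasma_vol / (2151.0 / 1.025)
            else:
                scale = a.organ_weights[matrix] / row["compartment_size"]
            noise = float(_lognormal_factor(rng, config.animal_cv, None))
            per_class[(matrix, row["analyte"], "unlabeled")] = (
                row["amount_nmol"] * scale * noise)
        for (matrix, species, label), amount in per_class.items():
            for analyte, amt in _species_amounts(
                    matrix, species, label, amount, t).items():
                if analyte in registry:
                    pool_rows.append({"animal_id": a.animal_id,
                                      "matrix": matrix, "analyte": analyte,
                                      "amount_nmol": amt})

    truth = PoolTable(pd.DataFrame(pool_rows))
    measurements = _synthesize_counts(truth, registry, config, rng)
    return animals, truth, measurements


def _channel_families(registry: Registry) -> dict[tuple[str, str], list]:
    """Group non-IS lipid specs into (class, label) SRM channel
    families; all water-soluble analytes form one family (their
    transitions are ≥3 Da apart, so no isotopologue spillover)."""
    fams: dict[tuple[str, str], list] = {}
    for s in registry:
        if s.is_internal_standard:
            continue
        key = (("water_soluble", "all") if s.lipid_class == "water_soluble"
               else (s.lipid_class, s.label_state))
        fams.setdefault(key, []).append(s)
    return fams


def _is_for_class(lipid_class: str) -> str:
    return ("D4-choline" if lipid_class == "water_soluble"
            else "PE14:0/14:0" if lipid_class == "PE" else "PC20:0/20:0")


def _synthesize_counts(truth: PoolTable, registry: Registry,
                       config: SimulationConfig,
                       rng: np.random.Generator) -> MeasurementTable:
    """Forward model: pools → raw SRM ion counts with ¹³C spillover
    and multiplicative technical noise."""
    df = truth.df
    frames = []
    for (lipid_class, label), specs in _channel_families(registry).items():
        names = [s.name for s in specs]
        sub = df[df["analyte"].isin(names)]
        if sub.empty:
            continue
        is_name = _is_for_class(lipid_class)
        is_amt = DEFAULT_IS_AMOUNTS_NMOL[is_name]
        wide = sub.pivot_table(index=["animal_id", "matrix"],
                               columns="analyte", values="amount_nmol",
                               aggfunc="sum", fill_value=0.0)
        if lipid_class == "water_soluble":
            order = [n for n in names if n in wide.columns]
            counts = wide.reindex(columns=order, fill_value=0.0).to_numpy()
            counts = counts / is_amt * _IS_BASE_COUNT
        else:
            C = build_c13_matrix(specs)
            order = list(C.species)
            base = (wide.reindex(columns=order, fill_value=0.0).to_numpy()
                    / is_amt * _IS_BASE_COUNT)
            counts = base @ C.matrix.T
        counts = counts * _lognormal_factor(rng, config.technical_cv,
                                            counts.shape)
        long = pd.DataFrame(counts, index=wide.index, columns=order)
        long = long.stack().rename("ion_count").reset_index()
        long.columns = ["animal_id", "matrix", "analyte", "ion_count"]
        frames.append(long)
    meas = pd.concat(frames, ignore_index=True)
    # internal-standard rows: the nominal spike count per extract
    is_rows = (meas[["animal_id", "matrix"]].drop_duplicates()
               .reset_index(drop=True))
    is_frames = [meas]
    for is_name in ("D4-choline", "PC20:0/20:0"):
        rows = is_rows.copy()
        if is_name == "D4-choline":
            rows = rows[rows["matrix"] != "LLF"]
        rows["analyte"] = is_name
        rows["ion_count"] = _IS_BASE_COUNT
        is_frames.append(rows)
    meas = pd.concat(is_frames, ignore_index=True)
    water = meas["analyte"].map(
        lambda a: registry[a].lipid_class == "water_soluble")
    meas["dilution_factor"] = np.where(
        water, meas["matrix"].map(_WATER_DILUTION).fillna(7.5),
        _LIPID_DILUTION)
    meas["injected_fraction"] = 1.0
    return MeasurementTable(meas, registry=registry)


# ---------------------------------------------------------------------------
# Transfer-rate estimation


def fit_transfer_rate(times: Sequence[float],
                      source: Sequence[float],
                      target: Sequence[float]) -> dict:
    """Least-squares estimate of one first-order transfer rate.

    Model: the donor pool decays mono-exponentially,
    ``S(t) = S₀·e^{−λt}``, and the recipient integrates a first-order
    transfer from it, ``T(t) = T₀ + k·S₀·(1 − e^{−λt})/λ``.  The four
    parameters (S₀, λ, k, T₀) are fitted jointly to both observed
    series.  For a pure two-compartment transfer λ = k and the fit is
    exact; in general k is the transfer rate and λ the donor's total
    turnover.

    Returns a dict with ``k``, ``decay`` (λ), ``residual`` (root mean
    squared misfit) — requires at least three time points.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if t.size < 3 or s.size != t.size or y.size != t.size:
        raise ValidationError("need ≥3 aligned time points")
    s_scale = max(float(np.abs(s).max()), 1e-12)

    def unpack(p):
        s0, lam, k, y0 = p
        lam = max(lam, 1e-9)
        growth = -np.expm1(-lam * t) / lam
        return s0 * np.exp(-lam * t), y0 + k * s0 * growth

    def resid(p):
        s_hat, y_hat = unpack(p)
        return np.concatenate([(s_hat - s), (y_hat - y)]) / s_scale

    # moment-based starting values
    lam0 = 0.1
    pos = s > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(s[pos]), 1)[0]
        lam0 = max(-slope, 1e-3)
    auc = np.trapezoid(s, t)
    k0 = (y[-1] - y[0]) / auc if auc > 0 else 0.0
    p0 = [max(s[0], 1e-6 * s_scale), lam0, k0, y[0]]
    fit = least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        bounds=([0, 1e-9, -np.inf, -np.inf],
                                [np.inf] * 4))
    s0, lam, k, y0 = fit.x
    rmse = float(np.sqrt(np.mean(fit.fun ** 2)) * s_scale)
    return {"k": float(k), "decay": float(lam), "source0": float(s0),
            "target0": float(y0), "residual": rmse}
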