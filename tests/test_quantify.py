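"""Isotopologue correction, IS quantification and species grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cholinetrace.core_io import AnalyteSpec, ValidationError
from cholinetrace.quantify import (CorrectionMatrix, ResponseModel,
                                   apply_isotope_correction, build_c13_matrix,
                                   group_species,
                                   quantify_by_internal_standard)


def _pc(name, mz, n_carbons, acyl="sat"):
    return AnalyteSpec(name=name, lipid_class="PC", label_state="unlabeled",
                       precursor_mz=mz, product_mz=184.07,
                       n_carbons=n_carbons, internal_standard="PC20:0/20:0",
                       acyl_group=acyl)


def exact_m2_probability(n_atoms: int, p13: float) -> float:
    """Independent oracle: P(exactly two heavy isotopes among n atoms)
    by explicit polynomial expansion over atoms."""
    coeffs = np.array([1.0])
    for _ in range(n_atoms):
        coeffs = np.convolve(coeffs, [1.0 - p13, p13])
    return float(coeffs[2])


class TestBuildMatrix:
    def test_zero_abundance_gives_identity(self, registry):
        species = registry.by_class("PC", "unlabeled", include_is=False)
        C = build_c13_matrix(species, p13=0.0)
        assert np.array_equal(C.matrix, np.eye(len(species)))

    def test_m2_entry_matches_enumeration_oracle(self, registry):
        """The double-bond neighbour spillover (e.g. PC34:2 recorded in
        the PC34:1 channel) equals the exact two-heavy-atom
        isotopologue probability for a 42-carbon lipid."""
        species = [_pc("PC34:1", 760.59, 42, "C18:1"),
                   _pc("PC34:2", 758.57, 42, "C18:2")]
        C = build_c13_matrix(species, p13=0.0107)
        j = C.species.index("PC34:2")
        i = C.species.index("PC34:1")
        assert C.matrix[i, j] == pytest.approx(
            exact_m2_probability(42, 0.0107), rel=1e-12)
        # donor above in m/z receives nothing from below
        assert C.matrix[j, i] == 0.0

    def test_default_panel_matrix_is_valid(self, registry):
        for label in ("unlabeled", "D9", "D3"):
            species = registry.by_class("PC", label, include_is=False)
            C = build_c13_matrix(species)
            assert np.allclose(np.diag(C.matrix), 1.0)
            assert (C.matrix >= 0).all() and (C.matrix <= 1).all()
            assert abs(np.linalg.det(C.matrix)) > 1e-6

    def test_ambiguous_mz_rejected(self):
        species = [_pc("a", 700.0, 40), _pc("b", 700.1, 40)]
        with pytest.raises(ValidationError, match="ambiguous"):
            build_c13_matrix(species)

    def test_mixed_classes_rejected(self, registry):
        mixed = [registry["PC32:0"], registry["SPH16:0"]]
        with pytest.raises(ValidationError, match="class"):
            build_c13_matrix(mixed)

    def test_out_of_range_abundance_rejected(self, registry):
        species = registry.by_class("PC", "unlabeled", include_is=False)
        with pytest.raises(ValidationError, match="p13"):
            build_c13_matrix(species, p13=0.5)


class TestApplyCorrection:
    def test_identity_leaves_counts_unchanged(self):
        C = CorrectionMatrix(("a", "b"), np.eye(2))
        corrected, clipped = apply_isotope_correction([10.0, 5.0], C)
        assert np.array_equal(corrected, [10.0, 5.0])
        assert not clipped.any()

    def test_zero_vector_maps_to_zero(self, registry):
        species = registry.by_class("PC", "unlabeled", include_is=False)
        C = build_c13_matrix(species)
        corrected, _ = apply_isotope_correction(np.zeros(len(species)), C)
        assert np.array_equal(corrected, np.zeros(len(species)))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e6), min_size=8, max_size=8),
           st.floats(0.001, 0.02))
    def test_correction_inverts_forward_synthesis(self, registry, x, p13):
        """Round trip: synthesizing spillover counts as C·x and
        correcting recovers x to 1e-9 relative."""
        species = registry.by_class("PC", "unlabeled", include_is=False)
        C = build_c13_matrix(species, p13=p13)
        x = np.asarray(x)
        raw = C.matrix @ x
        corrected, clipped = apply_isotope_correction(raw, C)
        assert not clipped.any()
        assert np.allclose(corrected, x, rtol=1e-9, atol=1e-9)

    def test_negative_solutions_clipped_and_flagged(self):
        C = CorrectionMatrix(("a", "b"),
                             np.array([[1.0, 0.0], [0.5, 1.0]]))
        # channel b holds less than the spillover from a implies
        corrected, clipped = apply_isotope_correction([100.0, 10.0], C)
        assert corrected[1] == 0.0
        assert clipped[1] and not clipped[0]


class TestQuantify:
    @pytest.mark.parametrize("count,is_count,is_amt,expected", [
        (1000.0, 1000.0, 10.0, 10.0),
        (2000.0, 1000.0, 10.0, 20.0),
        (0.0, 1000.0, 10.0, 0.0),
    ])
    def test_ratio_quantification(self, count, is_count, is_amt, expected):
        assert quantify_by_internal_standard(
            count, is_count, is_amt) == pytest.approx(expected)

    def test_zero_is_count_errors(self):
        with pytest.raises(ValidationError, match="internal-standard"):
            quantify_by_internal_standard(100.0, 0.0, 10.0)

    def test_quantification_is_linear_in_counts(self, rng):
        counts = rng.uniform(10, 1e5, 20)
        a1 = [quantify_by_internal_standard(c, 1e6, 50.0) for c in counts]
        a3 = [quantify_by_internal_standard(3 * c, 1e6, 50.0)
              for c in counts]
        assert np.allclose(a3, np.multiply(a1, 3.0))

    def test_response_model_scales_amounts(self, registry):
        model = ResponseModel(slope_per_carbon=0.01)
        spec = registry["PC32:0"]  # 40 carbons vs reference 48
        r = model.response(spec)
        assert r == pytest.approx(1.0 - 0.08)
        amt = quantify_by_internal_standard(1000.0, 1000.0, 10.0, response=r)
        assert amt == pytest.approx(10.0 / r)

    def test_nonpositive_response_rejected(self, registry):
        model = ResponseModel(slope_per_carbon=0.2)
        with pytest.raises(ValidationError, match="response"):
            model.response(registry["PC32:0"])


class TestGroupSpecies:
    def test_one_species_per_group_passthrough(self, registry):
        amounts = {"PC32:0": 1.0, "PC34:1": 2.0, "PC34:2": 3.0,
                   "PC36:4": 4.0, "PC38:6": 5.0}
        out = group_species(amounts, {n: registry[n] for n in amounts})
        assert out["groups"] == {"sat": 1.0, "C18:1": 2.0, "C18:2": 3.0,
                                 "C20:4": 4.0, "C22:6": 5.0}
        assert out["coverage"] == pytest.approx(1.0)

    def test_known_subgroup_split_recovered(self, registry):
        """A panel built with a 50/10/10/20/10 sub-group split is
        recovered exactly, including the two-species groups."""
        total = 1000.0
        amounts = {"PC32:0": 500.0, "PC34:1": 100.0,
                   "PC34:2": 70.0, "PC36:2": 30.0,
                   "PC36:4": 120.0, "PC38:4": 80.0,
                   "PC38:6": 60.0, "PC40:6": 40.0}
        out = group_species(amounts, {n: registry[n] for n in amounts})
        fracs = {g: v / total for g, v in out["groups"].items()}
        assert fracs == pytest.approx({"sat": 0.5, "C18:1": 0.1,
                                       "C18:2": 0.1, "C20:4": 0.2,
                                       "C22:6": 0.1})

    def test_untagged_species_kept_in_class_total(self, registry):
        amounts = {"PC32:0": 90.0, "SPH16:0": 10.0}
        specs = {n: registry[n] for n in amounts}
        out = group_species(amounts, specs)
        assert out["ungrouped"] == ["SPH16:0"]
        assert out["class_total"] == pytest.approx(100.0)
        assert sum(out["groups"].values()) <= out["class_total"]
        assert out["coverage"] == pytest.approx(0.9)
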