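"""Jarzynski aggregation, comparator score, scaling and ranking statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrcgbsa.conformers import RSchedule
from mrcgbsa.errors import ConfigurationError, DomainError, UndefinedCorrelationError
from mrcgbsa.fixtures import ToySystemSpec, make_ligand_series, make_toy_complex
from mrcgbsa.scoring import (
    KT_300,
    delta_delta_g,
    jarzynski_free_energy,
    linear_affinity,
    make_affinity_table,
    mrc_score,
    pearson_r,
    s_mmgbsa_score,
    shell_work_samples,
)


class TestWorkSamples:
    def test_constant_grid_gives_constant_work(self):
        U = np.tile([10.0, 12.0], (4, 1))
        np.testing.assert_array_equal(shell_work_samples(U, 0), [-2.0] * 4)

    def test_replicate_pairing_subtracts_along_lineage(self):
        U = np.array([[1.0, 2.0], [3.0, 5.0]])
        np.testing.assert_array_equal(shell_work_samples(U, 0), [-1.0, -2.0])

    def test_replicate_permutation_leaves_multiset(self):
        rng = np.random.default_rng(0)
        U = rng.normal(size=(6, 3))
        w = shell_work_samples(U, 1)
        wp = shell_work_samples(U[::-1], 1)
        np.testing.assert_allclose(sorted(w), sorted(wp))


class TestJarzynski:
    def test_zero_variance_is_exact(self):
        for c in (-3.0, 0.0, 7.25):
            assert jarzynski_free_energy([c, c, c], KT_300) == pytest.approx(c, abs=1e-12)

    def test_two_sample_value_matches_direct_arithmetic(self):
        kT = 0.5961
        expected = -kT * math.log((math.exp(-1 / kT) + math.exp(-2 / kT)) / 2)
        assert jarzynski_free_energy([1.0, 2.0], kT) == pytest.approx(expected, rel=1e-12)

    def test_empty_work_rejected(self):
        with pytest.raises(DomainError):
            jarzynski_free_energy([], KT_300)

    def test_extreme_work_stays_finite(self):
        kT = KT_300
        for scale in (700.0, -700.0):
            val = jarzynski_free_energy([0.0, scale * kT], kT)
            assert math.isfinite(val)
        # dominated by the lowest work value
        assert jarzynski_free_energy([0.0, 700 * KT_300], KT_300) == \
            pytest.approx(KT_300 * math.log(2), rel=1e-9)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_jensen_second_law_bound(self, work):
        dg = jarzynski_free_energy(work, KT_300)
        assert dg <= np.mean(work) + 1e-9
        if np.ptp(work) > 1e-12:
            assert dg < np.mean(work)


class TestMrcScore:
    def test_two_shell_constant_columns(self):
        U = np.tile([-10.0, 0.0], (5, 1))
        res = mrc_score(U, RSchedule((0.0, 1.0)))
        assert res.total_score == pytest.approx(-10.0, abs=1e-12)

    def test_zero_variance_grid_telescopes(self):
        sched = RSchedule((0.0, 0.5, 1.0, 4.0, 9.0))
        col = np.array([-20.0, -12.0, -5.0, 1.0, 3.0])
        U = np.tile(col, (7, 1))
        res = mrc_score(U, sched)
        assert res.total_score == pytest.approx(col[0] - col[-1], abs=1e-10)
        assert sum(res.shell_scores) == pytest.approx(res.total_score)

    def test_column_shift_moves_adjacent_scores_oppositely(self, rng):
        U = rng.normal(size=(8, 4))
        sched = RSchedule((0.0, 1.0, 2.0, 3.0))
        base = mrc_score(U, sched)
        c = 2.75
        U2 = U.copy()
        U2[:, 2] += c
        shifted = mrc_score(U2, sched)
        assert shifted.shell_scores[1] == pytest.approx(base.shell_scores[1] - c)
        assert shifted.shell_scores[2] == pytest.approx(base.shell_scores[2] + c)
        assert shifted.total_score == pytest.approx(base.total_score)

    def test_ensemble_equals_replicate_at_zero_variance(self):
        U = np.tile([-8.0, -1.0, 2.0], (4, 1))
        sched = RSchedule((0.0, 1.0, 2.0))
        a = mrc_score(U, sched, pairing_mode="replicate")
        b = mrc_score(U, sched, pairing_mode="ensemble")
        np.testing.assert_allclose(a.shell_scores, b.shell_scores, atol=1e-10)

    def test_unbinding_direction_negates_at_zero_variance(self):
        U = np.tile([-8.0, -1.0, 2.0], (4, 1))
        sched = RSchedule((0.0, 1.0, 2.0))
        fwd = mrc_score(U, sched, direction="binding")
        rev = mrc_score(U, sched, direction="unbinding")
        assert rev.total_score == pytest.approx(-fwd.total_score, abs=1e-10)

    def test_single_shell_rejected(self):
        with pytest.raises(DomainError):
            mrc_score(np.ones((3, 1)), RSchedule((0.0,)))


class TestSMmgbsa:
    def test_noninteracting_system_scores_zero(self):
        sys_ = make_toy_complex(ToySystemSpec(pocket_depth=0.0))
        score = s_mmgbsa_score(sys_, minimize=False, gamma_sasa=0.0)
        assert score == pytest.approx(0.0, abs=1e-10)

    def test_single_lj_contact_at_minimum(self):
        from mrcgbsa.structures import AtomRecord, ComplexSystem, MolecularStructure

        sigma, eps = 3.0, 0.8
        d = 2 ** (1 / 6) * sigma
        rec = MolecularStructure([AtomRecord("R1", "C", [0, 0, 0], lj_sigma=sigma,
                                             lj_epsilon=eps)], role="receptor")
        lig = MolecularStructure([AtomRecord("L1", "C", [d, 0, 0], lj_sigma=sigma,
                                             lj_epsilon=eps)], role="ligand")
        score = s_mmgbsa_score(ComplexSystem(rec, lig), minimize=False,
                               gamma_sasa=0.0)
        assert score == pytest.approx(-eps, rel=1e-12)

    def test_deeper_pockets_score_monotonically_lower(self):
        series = make_ligand_series(ToySystemSpec(), [1.0, 2.0, 3.0])
        scores = [s_mmgbsa_score(e.system, eps_in=4.0) for e in series]
        assert scores[0] > scores[1] > scores[2]


class TestAffinityMaps:
    def test_linear_affinity_examples(self):
        assert linear_affinity(-30.0, 0.25, 0.91) == pytest.approx(-6.59)
        assert linear_affinity(123.0, 0.0, 4.2) == 4.2
        assert linear_affinity(-7.0, 1.0, 0.0) == -7.0

    def test_reference_row_is_zero_and_scaling_applied(self):
        tab = make_affinity_table(["a", "b"], [-10.0, -20.0], [-4.0, -9.0])
        out = delta_delta_g(tab, alpha=0.20)
        ref = out.set_index("ligand")
        assert ref.loc["a", "ddg_calc"] == 0.0  # highest dg_exp is the reference
        assert ref.loc["b", "ddg_calc"] == pytest.approx(-2.0)

    def test_tie_breaks_by_label_with_warning(self, caplog):
        tab = make_affinity_table(["b", "a", "c"], [-1.0, -2.0, -3.0],
                                  [-5.0, -5.0, -8.0])
        with caplog.at_level("WARNING"):
            out = delta_delta_g(tab)
        assert "tie" in caplog.text
        assert out.set_index("ligand").loc["a", "ddg_calc"] == 0.0

    def test_no_reference_determinable(self):
        tab = make_affinity_table(["a", "b"], [-1.0, -2.0])
        with pytest.raises(ConfigurationError):
            delta_delta_g(tab)


class TestPearson:
    def test_textbook_values(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)
        assert pearson_r(x, [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(DomainError):
            pearson_r([1.0, 2.0], [1.0, 2.0])
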