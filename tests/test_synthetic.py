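import numpy as np
import pandas as pd
import pytest

from dndea import (
    generate_planted_frontier,
    generate_two_stage_panel,
    solve_all,
    solve_dmu,
)
from dndea.exceptions import GenerationError
from dndea.spec import ROLE_BAD, ROLE_INPUT, ROLE_LINK

_BAD_DIR = {ROLE_INPUT, ROLE_LINK, ROLE_BAD}


class TestPlantedFrontier:
    def test_planted_units_score_one_and_dominated_below(self):
        panel = generate_planted_frontier(10, 2, n_efficient=3, seed=7)
        for sol in solve_all(panel.spec, panel.data):
            if sol.dmu in panel.planted_efficient_ids:
                assert sol.theta == pytest.approx(1.0, abs=1e-7)
            else:
                assert sol.theta < 1 - 1e-6

    def test_unit_inflation_factors_make_every_dmu_efficient(self):
        panel = generate_planted_frontier(
            6, 2, n_efficient=2, seed=3, inflation=(1.0, 1.0), deflation=(1.0, 1.0)
        )
        for sol in solve_all(panel.spec, panel.data):
            assert sol.theta == pytest.approx(1.0, abs=1e-7)

    def test_same_seed_reproduces_identical_panel(self):
        a = generate_planted_frontier(8, 3, n_efficient=3, seed=42)
        b = generate_planted_frontier(8, 3, n_efficient=3, seed=42)
        pd.testing.assert_frame_equal(a.data.to_long(), b.data.to_long())
        assert a.certificates == b.certificates

    def test_dominance_certificates_verify_without_solver(self):
        panel = generate_planted_frontier(9, 2, n_efficient=3, seed=11)
        role_of = {(d, v): r for d, v, r in panel.spec.storage_cells()}
        eff = panel.planted_efficient_ids
        for dmu, cert in panel.certificates.items():
            w = np.array([cert["weights"][e] for e in eff])
            for key, factor in cert["factors"].items():
                division, variable, period = key.split("|")
                combo = w @ np.array(
                    [panel.data.value(e, period, division, variable) for e in eff]
                )
                observed = panel.data.value(dmu, period, division, variable)
                assert observed == pytest.approx(combo * factor, rel=1e-12)
                if role_of[(division, variable)] in _BAD_DIR:
                    assert observed >= combo  # inflated: combination dominates
                else:
                    assert observed <= combo

    def test_values_strictly_positive_no_zero_replacement(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            panel = generate_planted_frontier(12, 3, n_efficient=3, seed=1)
        assert (panel.data.to_long()["value"] > 0).all()

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(GenerationError):
            generate_planted_frontier(5, 1, n_efficient=6, seed=0)
        with pytest.raises(GenerationError):
            generate_planted_frontier(5, 0, n_efficient=2, seed=0)


class TestTwoStagePanel:
    def test_defaults_validate_against_preset_and_ids_partition(self):
        panel = generate_two_stage_panel(n_dmu=10, n_periods=2, seed=2)
        assert panel.data.n_dmu == 10 and panel.data.n_periods == 2
        assert panel.planted_efficient_ids
        assert set(panel.certificates) == (
            set(panel.data.dmu_ids) - set(panel.planted_efficient_ids)
        )

    def test_two_dmu_dominated_unit_inefficient_in_both_stages(self):
        panel = generate_two_stage_panel(n_dmu=2, n_periods=2, seed=8)
        (dom,) = [d for d in panel.data.dmu_ids
                  if d not in panel.planted_efficient_ids]
        sol = solve_dmu(panel.spec, panel.data, dom)
        from dndea import division_efficiency

        for k in panel.spec.divisions:
            assert division_efficiency(sol, k) < 1 - 1e-6

    def test_dispersion_must_be_positive(self):
        with pytest.raises(GenerationError):
            generate_two_stage_panel(n_dmu=5, stage1_dispersion=0.0, seed=0)
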