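"""Glu/Phe delta-15N trophic position and marine-fraction estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodiet.aa_nitrogen import (
    DEFAULT_PARAMS,
    HTLSpec,
    MARINE_PHE_FISH_AVG,
    MARINE_PHE_LOWEST_FISH,
    NitrogenParams,
    PairedDelta,
    TERRESTRIAL_PHE,
    f_marine_htl,
    f_marine_phe,
    infer_terrestrial_endmember,
    propagate_sd,
    sensitivity_sweep,
    tp_marine,
    tp_mixed,
    tp_terrestrial,
)
from paleodiet.bulk_mixing import EndMember
from paleodiet.data_model import ValidationError

HUMAN_AVG = PairedDelta(18.1, 11.5)
RAT_AVG = PairedDelta(14.9, 10.4)


class TestTrophicPosition:
    def test_human_average_marine_assumption(self):
        assert round(tp_marine(HUMAN_AVG).tp, 2) == 1.42

    def test_rat_average_marine_assumption(self):
        assert tp_marine(RAT_AVG).tp == pytest.approx(1.145, abs=0.01)

    def test_human_average_terrestrial_assumption(self):
        assert round(tp_terrestrial(HUMAN_AVG).tp, 2) == 2.97

    def test_rat_average_terrestrial_assumption(self):
        assert round(tp_terrestrial(RAT_AVG).tp, 2) == 2.70

    def test_producer_baseline_is_tp_one(self):
        k = DEFAULT_PARAMS
        p = PairedDelta(5.0 - k.beta_marine, 5.0)
        assert tp_marine(p, k).tp == pytest.approx(1.0)

    def test_terrestrial_herbivore_is_tp_two(self):
        k = DEFAULT_PARAMS
        p = PairedDelta(5.0 + k.delta_glu_phe - k.beta_terrestrial, 5.0)
        assert tp_terrestrial(p, k).tp == pytest.approx(2.0)

    def test_mixed_diet_human_average(self):
        p = PairedDelta(18.2, 11.6)  # glu - phe = 6.6
        assert tp_mixed(p, 0.50).tp == pytest.approx(2.197, abs=0.005)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_mixed_boundaries_reduce_to_pure_estimators(self, f):
        p = PairedDelta(17.3, 10.9, 0.4, 0.5)
        k = NitrogenParams(sd_beta_marine=0.2, sd_beta_terrestrial=0.3, sd_delta=0.1)
        mixed = tp_mixed(p, f, k)
        pure = tp_marine(p, k) if f == 1.0 else tp_terrestrial(p, k)
        assert mixed.tp == pure.tp
        assert mixed.sd == pure.sd

    def test_f_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            tp_mixed(HUMAN_AVG, 1.2)

    @given(
        gp=st.floats(-5.0, 15.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
    )
    @settings(deadline=None)
    def test_monotone_nonincreasing_in_f(self, gp, f1, f2):
        p = PairedDelta(gp + 10.0, 10.0)
        lo, hi = sorted((f1, f2))
        assert tp_mixed(p, hi).tp <= tp_mixed(p, lo).tp + 1e-12


class TestMarineFractionHTL:
    def test_human_average(self):
        p = PairedDelta(18.2, 11.6)  # glu - phe = 6.6
        assert round(f_marine_htl(p).f, 2) == 0.49

    def test_consistency_with_terrestrial_tp(self):
        p = PairedDelta(17.0, 11.0, 0.0, 0.0)
        htl = HTLSpec(level=tp_terrestrial(p).tp, lo=0.0, hi=5.0)
        assert f_marine_htl(p, htl).f == pytest.approx(0.0, abs=1e-12)

    def test_consistency_with_marine_tp(self):
        p = PairedDelta(17.0, 11.0)
        htl = HTLSpec(level=tp_marine(p).tp, lo=0.0, hi=5.0)
        assert f_marine_htl(p, htl).f == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_betas_rejected(self):
        k = NitrogenParams(beta_marine=8.4, beta_terrestrial=8.4)
        with pytest.raises(ValidationError):
            f_marine_htl(HUMAN_AVG, HTLSpec(), k)


class TestTerrestrialEndMemberInversion:
    def test_study_inversion_value(self):
        assert infer_terrestrial_endmember(11.6, 0.5, 1.0) == pytest.approx(22.2)

    def test_f_zero_returns_consumer_value(self):
        assert infer_terrestrial_endmember(11.6, 0.0, 1.0) == 11.6

    def test_f_one_is_domain_error(self):
        with pytest.raises(ValidationError):
            infer_terrestrial_endmember(11.6, 1.0, 1.0)

    @given(
        phe=st.floats(2.0, 20.0),
        f=st.floats(0.0, 0.95),
        mar=st.floats(-2.0, 2.0),
    )
    @settings(deadline=None)
    def test_forward_mass_balance_recovers_consumer(self, phe, f, mar):
        terr = infer_terrestrial_endmember(phe, f, mar)
        forward = f * mar + (1.0 - f) * terr
        assert forward == pytest.approx(phe, abs=1e-10)


class TestMarineFractionPhe:
    def test_human_average(self):
        assert round(f_marine_phe(11.6).f, 2) == 0.50

    def test_highest_human_individual(self):
        assert round(f_marine_phe(14.0).f, 2) == 0.39

    def test_terrestrial_end_member_consumer_gives_zero(self):
        assert f_marine_phe(TERRESTRIAL_PHE.mean).f == pytest.approx(0.0)

    def test_equal_end_members_rejected(self):
        em = EndMember(5.0, 0.1, "collagen")
        with pytest.raises(ValidationError):
            f_marine_phe(6.0, terr_em=em, mar_em=em)

    @given(glu=st.floats(12.0, 25.0), phe=st.floats(6.0, 14.0))
    @settings(deadline=None)
    def test_round_trip_with_htl_estimator(self, glu, phe):
        """With the terrestrial end member set to the mass-balance inversion
        of the HTL solution, both marine-fraction estimators agree."""
        p = PairedDelta(glu, phe)
        f_htl = f_marine_htl(p)
        if not 0.0 <= f_htl.f <= 0.95:
            return
        terr = infer_terrestrial_endmember(phe, f_htl.f, MARINE_PHE_FISH_AVG.mean)
        if abs(terr - MARINE_PHE_FISH_AVG.mean) < 0.5:
            return
        f_phe = f_marine_phe(
            phe,
            terr_em=EndMember(terr, 0.0, "collagen"),
            mar_em=EndMember(MARINE_PHE_FISH_AVG.mean, 0.0, "collagen"),
        )
        assert f_phe.f == pytest.approx(f_htl.f, abs=1e-10)


class TestErrorPropagation:
    def test_zero_input_sds_give_zero_for_every_estimator(self):
        p = PairedDelta(18.1, 11.5)
        em0 = EndMember(22.7, 0.0, "collagen")
        em1 = EndMember(0.4, 0.0, "collagen")
        assert propagate_sd("tp_marine", p=p) == 0.0
        assert propagate_sd("tp_terrestrial", p=p) == 0.0
        assert propagate_sd("tp_mixed", p=p, f=0.5) == 0.0
        assert propagate_sd("f_marine_htl", p=p) == 0.0
        assert propagate_sd("f_marine_phe", phe_consumer=11.6, terr_em=em0, mar_em=em1) == 0.0

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValidationError):
            propagate_sd("nope")

    def test_tp_terrestrial_sd_against_monte_carlo(self):
        p = PairedDelta(18.1, 11.5, 0.5, 0.5)
        analytic = tp_terrestrial(p).sd
        rng = np.random.default_rng(7)
        n = 10**6
        draws = (rng.normal(18.1, 0.5, n) - rng.normal(11.5, 0.5, n) + 8.4) / 7.6 + 1
        assert draws.std() == pytest.approx(analytic, rel=0.02)

    def test_f_marine_phe_sd_at_highest_human_against_monte_carlo(self):
        analytic = f_marine_phe(14.0, 0.41).sd
        rng = np.random.default_rng(8)
        n = 10**6
        x = rng.normal(14.0, 0.41, n)
        terr = rng.normal(22.7, 0.9, n)
        mar = rng.normal(0.4, 0.6, n)
        f = (x - terr) / (mar - terr)
        assert f.std() == pytest.approx(analytic, rel=0.02)


class TestSensitivitySweep:
    # consumer averages: human glu-phe difference 6.6 at phe 11.6;
    # rat phe 11.4 with a glu-phe difference of 4.5 (terrestrial TP 2.70)
    HUMAN = PairedDelta(18.2, 11.6, 0.41, 0.41)
    RAT = PairedDelta(15.9, 11.4, 0.41, 0.41)

    def test_totora_grid_point_reproduces_study_values(self):
        table = sensitivity_sweep(
            self.HUMAN, self.RAT, [22.7], mar_em=MARINE_PHE_LOWEST_FISH
        )
        row = table.iloc[0]
        assert row["f_human"] == pytest.approx(0.50, abs=0.01)
        assert row["tp_human"] == pytest.approx(2.20, abs=0.01)

    def test_grid_below_consumer_phe_flagged_infeasible(self):
        table = sensitivity_sweep(self.HUMAN, self.RAT, [10.0])
        row = table.iloc[0]
        assert not row["feasible_human"]
        assert math.isnan(row["tp_human"])

    def test_low_rat_trophic_positions_eliminated(self):
        table = sensitivity_sweep(self.HUMAN, self.RAT, [22.7], min_rat_tp=2.0)
        assert bool(table.iloc[0]["rat_tp_eliminated"]) == (table.iloc[0]["tp_rat"] < 2.0)

    def test_max_human_rat_gap_below_0_37_over_study_grid(self):
        """Across the plausible terrestrial end-member range shared by humans
        and rats, mixed-diet trophic positions differ by less than 0.37."""
        grid = list(np.arange(14.0, 22.7001, 0.1))
        table = sensitivity_sweep(self.HUMAN, self.RAT, grid)
        both = table[table["feasible_human"] & table["feasible_rat"]]
        gap = (both["tp_human"] - both["tp_rat"]).abs().max()
        assert gap < 0.37

    def test_empty_grid_is_error(self):
        with pytest.raises(ValidationError):
            sensitivity_sweep(self.HUMAN, self.RAT, [])

    def test_grid_at_or_below_marine_end_member_is_error(self):
        with pytest.raises(ValidationError):
            sensitivity_sweep(self.HUMAN, self.RAT, [0.5])
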