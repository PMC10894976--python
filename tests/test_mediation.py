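import dataclasses

import numpy as np
import pandas as pd
import pytest

from mrpath.exceptions import UndefinedProportionError
from mrpath.mediation import (
    MediationMR,
    mediation_table,
    screen_mediators,
    two_step_mediation,
)
from mrpath.simulate import scenario_library, simulate_summary_stats


class TestTwoStepMediation:
    def test_dead_second_step_means_no_mediation(self):
        res = two_step_mediation(0.3, 0.05, 0.0, 0.1, total_effect=0.5)
        assert res.indirect == 0.0
        assert res.proportion == 0.0
        assert res.proportion_ci[0] == pytest.approx(-res.proportion_ci[1])

    def test_full_mediation_identity(self):
        res = two_step_mediation(-0.4, 0.05, 1.0, 0.0, total_effect=-0.4)
        assert res.proportion == pytest.approx(1.0)

    def test_worked_example_matches_bootstrap_oracle(self):
        beta1, se1, beta2, se2, total = -0.28, 0.028, 0.62, 0.10, -0.4845
        res = two_step_mediation(beta1, se1, beta2, se2, total)
        assert res.proportion == pytest.approx(0.358, abs=0.001)
        rng = np.random.default_rng(7)
        draws = rng.normal(beta1, se1, 50_000) * rng.normal(beta2, se2, 50_000) / total
        boot_se = draws.std(ddof=1)
        assert res.proportion_se == pytest.approx(boot_se, rel=0.05)
        # bootstrap CI quantiles agree with the delta CI to the same tolerance
        lo, hi = res.proportion_ci
        assert lo == pytest.approx(np.quantile(draws, 0.025), abs=0.02)
        assert hi == pytest.approx(np.quantile(draws, 0.975), abs=0.02)

    def test_indirect_identity_holds_exactly(self):
        res = two_step_mediation(-0.2, 0.01, 0.5, 0.02, total_effect=-0.4)
        assert res.indirect == res.beta1 * res.beta2
        assert res.proportion * res.total_effect == pytest.approx(res.indirect)

    def test_zero_total_effect_raises(self):
        with pytest.raises(UndefinedProportionError):
            two_step_mediation(0.1, 0.01, 0.1, 0.01, total_effect=0.0)

    def test_out_of_range_proportion_warns_but_returns(self):
        with pytest.warns(UserWarning, match="inconsistent mediation"):
            res = two_step_mediation(0.5, 0.01, 0.9, 0.01, total_effect=0.1)
        assert res.out_of_range
        assert res.proportion == pytest.approx(4.5)

    def test_propagating_total_uncertainty_widens_ci(self):
        fixed = two_step_mediation(-0.28, 0.028, 0.62, 0.1, -0.4845, 0.05)
        prop = two_step_mediation(-0.28, 0.028, 0.62, 0.1, -0.4845, 0.05,
                                  propagate_total=True)
        assert prop.proportion_se > fixed.proportion_se
        assert prop.proportion == fixed.proportion

    def test_invariant_to_exposure_recoding(self):
        # flipping the exposure's coding flips beta1 and the total effect
        a = two_step_mediation(-0.28, 0.028, 0.62, 0.1, -0.4845)
        b = two_step_mediation(0.28, 0.028, 0.62, 0.1, 0.4845)
        assert a.proportion == pytest.approx(b.proportion)
        assert a.proportion_se == pytest.approx(b.proportion_se)


class TestMediationTable:
    def test_empty_input_gives_headers_only(self):
        df = mediation_table([])
        assert len(df) == 0
        assert "proportion_pct" in df.columns

    def test_sorted_by_outcome_then_descending_proportion(self):
        rows = [
            two_step_mediation(-0.2, 0.01, 0.5, 0.02, -0.5, mediator=f"m{i}",
                               outcome=o)
            for i, o in enumerate(["b", "a"])
        ]
        rows.append(two_step_mediation(-0.1, 0.01, 0.5, 0.02, -0.5,
                                       mediator="m2", outcome="a"))
        df = mediation_table(rows)
        assert df["outcome"].tolist() == ["a", "a", "b"]
        assert df["proportion"].iloc[0] >= df["proportion"].iloc[1]

    def test_roundtrip_preserves_numeric_fields(self, tmp_path):
        rows = [two_step_mediation(-0.28, 0.028, 0.62, 0.1, -0.4845)]
        df = mediation_table(rows)
        path = tmp_path / "med.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        for col in ("beta1", "beta2", "proportion", "proportion_se"):
            assert back[col].iloc[0] == pytest.approx(df[col].iloc[0], rel=1e-12)


@pytest.fixture(scope="module")
def scenario():
    cfg = scenario_library()["partial-mediation"]
    return simulate_summary_stats(dataclasses.replace(cfg, seed=11))


class TestScreenMediators:
    def test_true_mediator_passes_all_criteria(self, scenario):
        d = scenario
        reports = screen_mediators(d.exposure, [d.mediator], d.outcome, ld=d.ld)
        rep = reports[0]
        assert rep.criterion1 and rep.criterion2 and rep.criterion3 and rep.criterion4
        assert rep.eligible
        assert rep.stats["beta1"] == pytest.approx(-0.28, abs=0.06)
        assert rep.stats["beta2"] == pytest.approx(0.62, abs=0.15)

    def test_reverse_direction_candidate_fails_criterion1(self, scenario):
        # swap roles: the "mediator" candidate is actually upstream of the
        # exposure, so the reverse-direction test must reject it
        d = scenario
        reports = screen_mediators(d.mediator, [d.exposure], d.outcome, ld=d.ld)
        rep = reports[0]
        assert rep.criterion1 is False
        assert not rep.eligible

    def test_null_mediator_fails_outcome_criteria(self):
        cfg = scenario_library()["total-effect-only"]  # beta2 = 0
        d = simulate_summary_stats(dataclasses.replace(cfg, seed=3))
        reports = screen_mediators(d.exposure, [d.mediator], d.outcome, ld=d.ld)
        rep = reports[0]
        assert rep.criterion2 is False or rep.criterion3 is False
        assert not rep.eligible

    def test_screen_recovery_rate_over_replicates(self):
        cfg = scenario_library()["partial-mediation"]
        eligible = 0
        n = 15
        for s in range(n):
            d = simulate_summary_stats(dataclasses.replace(cfg, seed=100 + s))
            rep = screen_mediators(d.exposure, [d.mediator], d.outcome, ld=d.ld)[0]
            eligible += rep.eligible
        assert eligible / n >= 0.9


class TestMediationModel:
    def test_end_to_end_proportion_recovery(self):
        cfg = scenario_library()["partial-mediation"]
        d = simulate_summary_stats(dataclasses.replace(cfg, seed=21))
        model = MediationMR(d.exposure, [d.mediator], d.outcome, ld=d.ld)
        results, reports = model.fit()
        assert len(results) == 1
        res = results[0]
        assert res.proportion == pytest.approx(d.truth.mediation_proportion, abs=0.1)
        lo, hi = res.proportion_ci
        assert lo < d.truth.mediation_proportion < hi
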