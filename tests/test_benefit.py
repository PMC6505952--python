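import numpy as np
import pandas as pd
import pytest

import offsetgain as og


class TestConditionScore:
    @pytest.mark.parametrize("value,reference,expected", [
        (60.0, 60.0, 1.0),     # at the benchmark the score caps at 1
        (120.0, 60.0, 1.0),    # exceeding it earns no extra condition
        (0.0, 60.0, 0.0),
        (30.0, 60.0, 0.5),
    ])
    def test_reference_ratio_capped_at_one(self, value, reference, expected):
        assert og.condition_score(value, reference) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            og.condition_score(-1.0, 10.0)
        with pytest.raises(ValueError):
            og.condition_score(1.0, 0.0)

    def test_vectorised_and_bounded(self):
        vals = np.linspace(0, 200, 101)
        bc = og.condition_score(vals, 100.0)
        assert np.all((bc >= 0) & (bc <= 1))
        assert np.all(np.diff(bc) >= 0)  # monotone in value


class TestAggregatePointBenefit:
    def test_full_record_arithmetic(self):
        rec = og.PointScoreRecord("e", "s", 60, 70, 50)
        assert og.aggregate_point_benefit(rec) == {"MG": 10, "AL": 10, "TB": 20}

    def test_missing_bau_leaves_al_tb_absent(self):
        rec = og.PointScoreRecord("e", "s", 84, 84)
        out = og.aggregate_point_benefit(rec)
        assert out == {"MG": 0, "AL": None, "TB": None}

    def test_negative_benefits_permitted(self):
        rec = og.PointScoreRecord("e", "s", 39, 30, 45)
        assert og.aggregate_point_benefit(rec) == {"MG": -9, "AL": -6, "TB": -15}


def _degenerate(mu, attribute="forb_richness"):
    src = og.RouletteElicitation("e1", "s1", attribute, "reference",
                                 0.0, max(2 * mu, 1.0), tuple([10] * 10))
    return og.FittedDistribution("normal", (mu, 1e-12), 0.0, src)


class TestPooledBenefit:
    def test_pool_size_is_experts_times_draws(self, small_panel,
                                              moderate_scenario):
        cfg, records, _ = small_panel
        samples = og.pooled_benefit(records, moderate_scenario.start_values,
                                    draws_per_expert=30,
                                    rng=np.random.default_rng(0))
        counts = samples.groupby("attribute").size()
        assert (counts == cfg.n_experts_roulette * 30).all()

    def test_fern_attributes_excluded_by_default(self, small_panel,
                                                 moderate_scenario):
        _, records, _ = small_panel
        samples = og.pooled_benefit(records, moderate_scenario.start_values,
                                    draws_per_expert=5,
                                    rng=np.random.default_rng(0))
        assert not set(samples["attribute"]) & {"fern_cover", "fern_richness"}

    def test_tb_is_al_plus_mg_exactly(self, small_panel, moderate_scenario):
        _, records, _ = small_panel
        samples = og.pooled_benefit(records, moderate_scenario.start_values,
                                    draws_per_expert=25,
                                    rng=np.random.default_rng(1))
        assert np.array_equal(samples["TB"], samples["AL"] + samples["MG"])
        bc = samples[["BC_start", "BC_bau", "BC_offset"]].to_numpy()
        assert np.nanmin(bc) >= 0 and np.nanmax(bc) <= 1

    def test_no_change_panel_gives_zero_benefit(self):
        start = 12.0
        fitted = {
            ("e1", "forb_richness", state): _degenerate(start)
            for state in ("reference", "future_bau", "future_offset")
        }
        samples = og.pooled_benefit([], {"forb_richness": start},
                                    draws_per_expert=50,
                                    rng=np.random.default_rng(2),
                                    fitted=fitted)
        assert np.allclose(samples[["AL", "MG", "TB"]], 0.0, atol=1e-9)

    def test_missing_reference_distribution_is_an_error(self):
        fitted = {("e1", "forb_richness", "future_offset"): _degenerate(10.0)}
        with pytest.raises(ValueError, match="reference"):
            og.pooled_benefit([], {"forb_richness": 10.0},
                              rng=np.random.default_rng(0), fitted=fitted)

    def test_dominated_offset_gives_negative_mean_mg(self):
        """Offset future stochastically below the reference, start at the
        reference mean: a brute-force Monte-Carlo oracle fixes the sign of
        the expected MG, and the pooled estimate must agree."""
        mu_ref, mu_off, sd, start = 50.0, 43.0, 5.0, 50.0
        rng = np.random.default_rng(3)
        R = np.maximum(rng.normal(mu_ref, sd, 1_000_000), 0.5)
        V = np.maximum(rng.normal(mu_off, sd, 1_000_000), 0.0)
        oracle = np.mean(np.minimum(V / R, 1) - np.minimum(start / R, 1))
        assert oracle < 0

        src = og.RouletteElicitation("e1", "s1", "forb_richness", "reference",
                                     30.0, 70.0, tuple([10] * 10))
        fitted = {
            ("e1", "forb_richness", "reference"):
                og.FittedDistribution("normal", (mu_ref, sd), 0.0, src),
            ("e1", "forb_richness", "future_offset"):
                og.FittedDistribution("normal", (mu_off, sd), 0.0, src),
        }
        samples = og.pooled_benefit([], {"forb_richness": start},
                                    draws_per_expert=10_000,
                                    rng=np.random.default_rng(4),
                                    fitted=fitted)
        assert samples["MG"].mean() < 0

    def test_upward_offset_shift_never_decreases_median_mg(self, small_panel,
                                                           moderate_scenario):
        _, records, _ = small_panel
        fitted = og.fit_panel(records)
        shifted = {
            key: (og.FittedDistribution(d.family,
                                        (d.params[0] + 5.0, d.params[1]),
                                        d.fit_sse, d.source)
                  if key[2] == "future_offset" and d.family == "normal" else d)
            for key, d in fitted.items()
        }
        base = og.pooled_benefit([], moderate_scenario.start_values,
                                 draws_per_expert=40,
                                 rng=np.random.default_rng(5), fitted=fitted)
        up = og.pooled_benefit([], moderate_scenario.start_values,
                               draws_per_expert=40,
                               rng=np.random.default_rng(5), fitted=shifted)
        for attribute in base["attribute"].unique():
            if og.WSGW_ATTRIBUTES[attribute].is_percent:
                continue  # only normal-family attributes were shifted
            m0 = base.loc[base.attribute == attribute, "MG"].median()
            m1 = up.loc[up.attribute == attribute, "MG"].median()
            assert m1 >= m0 - 1e-12


class TestSummarize:
    def _frame(self, tb):
        tb = np.asarray(tb, dtype=float)
        return pd.DataFrame({
            "expert_id": "e", "scenario_id": "s", "attribute": "a",
            "draw": np.arange(tb.size), "AL": 0.0, "MG": tb, "TB": tb,
            "BC_start": 0.5, "BC_bau": 0.5, "BC_offset": 0.5,
        })

    def test_sign_fractions(self):
        out = og.summarize(self._frame([-1, 0, 1]), zero_tolerance=1e-9)
        assert out.loc[0, "fraction_negative_TB"] == pytest.approx(1 / 3)
        assert out.loc[0, "fraction_zero_TB"] == pytest.approx(1 / 3)

    def test_constant_samples_collapse_quartiles(self):
        out = og.summarize(self._frame([0.25] * 10))
        assert (out.loc[0, "TB_q25"] == out.loc[0, "TB_median"]
                == out.loc[0, "TB_q75"] == 0.25)

    def test_normal_tb_median_recovered(self):
        rng = np.random.default_rng(6)
        out = og.summarize(self._frame(rng.normal(0.05, 0.1, 2100)))
        assert abs(out.loc[0, "TB_median"] - 0.05) < 0.01

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            og.summarize(self._frame([]).iloc[0:0])


class TestMgVsStart:
    def test_start_at_reference_caps_median_mg_at_zero(self):
        """When every attribute starts at its reference scale and the offset
        future equals the reference distribution, the condition cap forces
        the median management gain to zero."""
        cfg = og.GeneratorConfig(n_experts_roulette=8,
                                 true_MG_function=(0.0, 0.0),
                                 true_AL_slope=0.0, bias_sd=0.0, seed=9)
        scen = og.Scenario(id="ref", vegetation_class="WSGW",
                           start_values=dict(og.REFERENCE_MEANS),
                           states_elicited=("reference", "future_offset"))
        records, _ = og.simulate_roulette_elicitations(
            scen, cfg, np.random.default_rng(9))
        samples = og.pooled_benefit(records, scen.start_values,
                                    draws_per_expert=60,
                                    rng=np.random.default_rng(10))
        table = og.mg_vs_start(samples)
        assert (table["MG_median"].abs() < 0.02).all()
        assert (table["BC_start_median"] > 0.9).all()

    def test_generator_truth_negative_rank_correlation(self, small_panel,
                                                       moderate_scenario):
        """With true MG linear in (1 - BC_start), attributes starting lower
        must show larger median gains across scenarios."""
        from scipy.stats import spearmanr

        cfg = og.GeneratorConfig(n_experts_roulette=8, bias_sd=0.02, seed=21)
        frames = []
        for scen in og.make_default_scenarios().values():
            records, _ = og.simulate_roulette_elicitations(
                scen, cfg, np.random.default_rng(21))
            frames.append(og.pooled_benefit(records, scen.start_values,
                                            draws_per_expert=40,
                                            rng=np.random.default_rng(22)))
        table = og.mg_vs_start(pd.concat(frames, ignore_index=True))
        rho = spearmanr(table["BC_start_median"], table["MG_median"]).statistic
        assert rho < 0
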