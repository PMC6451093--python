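"""Selection-cascade rules, funnel arithmetic and ground-truth recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from g2screen import hit_selection as hs
from g2screen import synthetic_data as sd


def _zmi(a, b):
    return pd.DataFrame({sd.ARRAYSCAN: [a], sd.ACUMEN: [b]}, index=["G1"])


class TestPrimaryHits:
    @pytest.mark.parametrize(
        "z_a,z_b,z_cell,hit,toxic_excluded",
        [
            (3.0, 2.6, 0.0, True, False),   # all cutoffs passed
            (3.0, 2.0, 0.0, False, False),  # second instrument fails
            (4.0, 4.0, -2.0, False, True),  # cell-count rule excludes
            (2.5, 2.6, 0.0, False, False),  # ties fail (strict comparison)
        ],
    )
    def test_dual_instrument_and_toxicity_rules(self, z_a, z_b, z_cell, hit, toxic_excluded):
        res = hs.primary_hits(_zmi(z_a, z_b), pd.Series([z_cell], index=["G1"]))
        assert bool(res.loc["G1", "hit"]) is hit
        assert bool(res.loc["G1", "toxic_excluded"]) is toxic_excluded

    def test_or_logic_configurable(self):
        criteria = hs.SelectionCriteria(primary_logic="or")
        res = hs.primary_hits(_zmi(3.0, 2.0), pd.Series([0.0], index=["G1"]), criteria)
        assert bool(res.loc["G1", "hit"])

    def test_missing_stream_marks_unevaluable(self):
        res = hs.primary_hits(_zmi(3.0, np.nan), pd.Series([0.0], index=["G1"]))
        assert bool(res.loc["G1", "unevaluable"])
        assert not bool(res.loc["G1", "hit"])


def _poc(icrf_a, icrf_b=None, bleo=100.0, nodrug=90.0):
    genes = ["G1"]
    def frame(a, b):
        return pd.DataFrame({sd.ARRAYSCAN: [a], sd.ACUMEN: [b]}, index=genes)
    return {
        sd.ICRF: frame(icrf_a, icrf_b if icrf_b is not None else icrf_a),
        sd.BLEO: frame(bleo, bleo),
        sd.NO_DRUG: frame(nodrug, nodrug),
    }


class TestValidationScreen:
    def test_repeats_with_selective_annotation(self):
        res = hs.validation_screen(_poc(400.0, 250.0, bleo=100.0, nodrug=90.0))
        row = res.loc["G1"]
        assert row["repeated"] and row["bleo_selective"] and not row["accumulator"]

    def test_accumulator_excluded_regardless_of_icrf(self):
        res = hs.validation_screen(_poc(400.0, 400.0, nodrug=300.0))
        row = res.loc["G1"]
        assert row["accumulator"] and not row["repeated"]

    def test_below_cutoff_does_not_repeat(self):
        res = hs.validation_screen(_poc(200.0, 150.0))
        assert not res.loc["G1", "repeated"]

    def test_missing_condition_raises(self):
        with pytest.raises(KeyError):
            hs.validation_screen({sd.ICRF: _poc(400.0)[sd.ICRF]})


class TestCounterScreen:
    @pytest.mark.parametrize(
        "icrf,bleo,etop,ir,nodrug,selective",
        [
            (400.0, 150.0, 100.0, 120.0, 80.0, True),
            (400.0, 250.0, 100.0, 120.0, 80.0, False),  # 400 <= 2 x 250
            (300.0, 10.0, 10.0, 10.0, 10.0, False),     # fails absolute cutoff
        ],
    )
    def test_fold_and_absolute_rules(self, icrf, bleo, etop, ir, nodrug, selective):
        poc = {
            cond: pd.Series([v], index=["G1"])
            for cond, v in zip(
                (sd.ICRF, sd.BLEO, sd.ETOP, sd.IR, sd.NO_DRUG),
                (icrf, bleo, etop, ir, nodrug),
            )
        }
        res = hs.counter_screen(poc)
        assert bool(res.loc["G1", "selective"]) is selective

    def test_missing_comparator_unevaluable(self):
        poc = {
            cond: pd.Series([400.0], index=["G1"])
            for cond in (sd.ICRF, sd.BLEO, sd.ETOP, sd.IR)
        }
        poc[sd.NO_DRUG] = pd.Series([np.nan], index=["G1"])
        res = hs.counter_screen(poc)
        assert bool(res.loc["G1", "unevaluable"])
        assert not bool(res.loc["G1", "selective"])


class TestDeconvolution:
    @pytest.mark.parametrize(
        "values,on_target,n_pass",
        [
            ([160, 200, 30, 40], True, 2),
            ([160, 30, 40, 20], False, 1),
            ([0, 0, 0, 0], False, 0),
            ([151, 151, 151, 151], True, 4),
            ([150, 150, 160, 20], False, 1),  # ties fail
        ],
    )
    def test_two_of_four_rule(self, values, on_target, n_pass):
        got_on, got_n = hs.deconvolute(values)
        assert (got_on, got_n) == (on_target, n_pass)

    def test_exhaustive_pattern_oracle(self):
        # all 16 pass/fail patterns match the >=2-of-4 rule by enumeration
        for pattern in itertools.product([0, 1], repeat=4):
            values = [300.0 if b else 50.0 for b in pattern]
            on_target, n_pass = hs.deconvolute(values)
            assert n_pass == sum(pattern)
            assert on_target == (sum(pattern) >= 2)

    def test_missing_duplexes_count_as_failures(self):
        assert hs.deconvolute([300.0, np.nan, np.nan, np.nan]) == (False, 1)

    def test_five_duplexes_rejected(self):
        with pytest.raises(ValueError):
            hs.deconvolute([1, 2, 3, 4, 5])


class TestStageSummary:
    def test_screening_funnel_percentages(self):
        report = hs.stage_summary(
            [("primary", 317), ("repeated", 151), ("deconvolution_input", 138),
             ("on_target", 48)],
            branches=[("accumulator", 6, "primary")],
        )
        by_name = {e["stage"]: e for e in report["stages"]}
        assert by_name["repeated"]["pct"] == 47.6
        assert by_name["on_target"]["pct_int"] == 35
        assert report["branches"][0]["pct"] == 1.9

    def test_second_line_validation_rate(self):
        report = hs.stage_summary([("repeated", 151), ("second_line", 115)])
        assert report["stages"][1]["pct"] == 76.2

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError):
            hs.stage_percentage(3, 0)


class TestCriteria:
    def test_roundtrip_json(self, tmp_path):
        c = hs.SelectionCriteria(primary_logic="or")
        path = tmp_path / "criteria.json"
        c.to_json(path)
        back = hs.SelectionCriteria.from_json(path)
        assert back == c

    def test_fold_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            hs.SelectionCriteria(counter_fold=1.0)


class TestCascadeOnSimulatedCampaign:
    def test_planted_classes_recovered(self, hit_table, small_library):
        effects = small_library.effects
        true_hits = set(effects.genes_of_class("icrf_selective_abrogator", min_on_target=2))
        final = set(hit_table[hit_table["classification"] == hs.ON_TARGET].index)
        assert final == true_hits

    def test_off_target_pool_fails_deconvolution(self, hit_table, small_library):
        off_target = [
            g
            for g in small_library.effects.genes_of_class("icrf_selective_abrogator")
            if sum(small_library.effects[g].on_target) < 2
        ]
        assert off_target
        for g in off_target:
            assert hit_table.loc[g, "n_duplexes_pass"] < 2
            assert not hit_table.loc[g, "on_target"]

    def test_toxic_and_accumulators_excluded_with_reason(self, hit_table, small_library):
        effects = small_library.effects
        for g in effects.genes_of_class("toxic"):
            assert hit_table.loc[g, "classification"] == hs.EXCLUDED_TOXIC
        for g in effects.genes_of_class("mitotic_accumulator"):
            assert hit_table.loc[g, "classification"] == hs.EXCLUDED_ACCUMULATOR

    def test_toxic_genes_absent_from_all_hit_sets(self, hit_table, small_library):
        for g in small_library.effects.genes_of_class("toxic"):
            row = hit_table.loc[g]
            assert not (row["primary_hit"] or row["repeated"] or row["selective"]
                        or row["on_target"])

    def test_pan_checkpoint_genes_not_selective(self, hit_table, small_library):
        for g in small_library.effects.genes_of_class("pan_checkpoint_abrogator"):
            assert not hit_table.loc[g, "selective"]
            assert hit_table.loc[g, "repeated"]  # they do repeat under ICRF

    def test_monotonicity_in_icrf_poc(self, aggregated):
        # raising a gene's ICRF POC (all else fixed) never removes it from a set
        agg = aggregated.copy()
        gene = agg.loc[agg["condition"] == sd.ICRF, "gene"].iloc[0]
        base = hs.run_cascade(agg)
        boosted = agg.copy()
        sel = (boosted["gene"] == gene) & (boosted["condition"] == sd.ICRF)
        boosted.loc[sel, "POC_MI"] += 500.0
        boosted.loc[sel, "z_MI"] += 50.0
        after = hs.run_cascade(boosted)
        for col in ("primary_hit", "repeated", "selective"):
            if base.loc[gene, col]:
                assert after.loc[gene, col]

    def test_classifications_recheckable_from_logged_measures(self, hit_table):
        # independent re-derivation of every stage from the logged measures
        c = hs.SelectionCriteria()
        for gene, row in hit_table.iterrows():
            if row["classification"] == hs.UNEVALUABLE:
                continue
            pass_mi = (row[f"z_icrf_{sd.ARRAYSCAN}"] > 2.5) and (
                row[f"z_icrf_{sd.ACUMEN}"] > 2.5
            )
            toxic = not (row["z_cellcount"] > -1.5)
            assert toxic == row["toxic"]
            assert (pass_mi and not toxic) == row["primary_hit"]
            repeated = (
                row["primary_hit"]
                and row[f"poc_{sd.ICRF}_{sd.ARRAYSCAN}"] > 350
                and row[f"poc_{sd.ICRF}_{sd.ACUMEN}"] > 200
                and not row["accumulator"]
            )
            assert repeated == row["repeated"]
            icrf = row[f"poc_{sd.ICRF}_{sd.ARRAYSCAN}"]
            selective = repeated and icrf > 350 and all(
                icrf > 2 * row[f"poc_{cond}_{sd.ARRAYSCAN}"]
                for cond in (sd.BLEO, sd.ETOP, sd.IR, sd.NO_DRUG)
            )
            assert selective == row["selective"]

    def test_funnel_counts_consistent(self, hit_table):
        report = hs.cascade_funnel(hit_table)
        counts = {e["stage"]: e["count"] for e in report["stages"]}
        assert counts["library"] == len(hit_table)
        assert counts["on_target"] <= counts["icrf_selective"] <= counts["repeated"]
        assert counts["repeated"] <= counts["primary"]
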