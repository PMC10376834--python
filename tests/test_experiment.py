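"""Pairing design, the 1 mm identification rule, factorial summaries and
the three-way ANOVA against a direct mean-decomposition oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sinusid as sd
from sinusid.errors import InvalidConfigError
from sinusid.experiment import ANOVA_TERMS, BONFERRONI_ALPHA


def anova_oracle(table):
    """Balanced 2x2x2 fixed-effects decomposition straight from cell and
    marginal means (no model fitting)."""
    y = table["rms"].to_numpy(float)
    grand = y.mean()
    factors = ("sex", "side", "group")
    means = {}
    for k in range(1, 4):
        for combo in itertools.combinations(factors, k):
            means[combo] = table.groupby(list(combo), observed=True)["rms"].mean()

    def marginal(combo, row):
        key = tuple(row[f] for f in combo)
        return means[combo][key if len(key) > 1 else key[0]]

    ss = {}
    n = len(table)
    for a in factors:
        ss[a] = sum((means[(a,)][lvl] - grand) ** 2 * count
                    for lvl, count in table[a].value_counts().items())
    for a, b in itertools.combinations(factors, 2):
        term = 0.0
        for _, row in table.drop_duplicates(subset=[a, b]).iterrows():
            count = ((table[a] == row[a]) & (table[b] == row[b])).sum()
            effect = (marginal((a, b), row) - marginal((a,), row)
                      - marginal((b,), row) + grand)
            term += count * effect ** 2
        ss[f"{a}:{b}"] = term
    term = 0.0
    for _, row in table.drop_duplicates(subset=list(factors)).iterrows():
        count = ((table.sex == row.sex) & (table.side == row.side)
                 & (table.group == row.group)).sum()
        effect = (marginal(factors, row)
                  - marginal(("sex", "side"), row)
                  - marginal(("sex", "group"), row)
                  - marginal(("side", "group"), row)
                  + marginal(("sex",), row) + marginal(("side",), row)
                  + marginal(("group",), row) - grand)
        term += count * effect ** 2
    ss["sex:side:group"] = term
    cell_mean = table.groupby(list(factors), observed=True)["rms"].transform("mean")
    ss["Residual"] = float(((y - cell_mean) ** 2).sum())
    df_resid = n - 8
    out = {"ss": ss, "F": {}, "p": {}}
    from scipy.stats import f as f_dist
    for term_name in ANOVA_TERMS:
        f_value = (ss[term_name] / 1.0) / (ss["Residual"] / df_resid)
        out["F"][term_name] = f_value
        out["p"][term_name] = float(f_dist.sf(f_value, 1, df_resid))
    return out


def random_balanced_table(rng, reps=5):
    rows = []
    for sex, side, group in itertools.product("MF", ("right", "left"),
                                              ("match", "mismatch")):
        for _ in range(reps):
            rows.append({"sex": sex, "side": side, "group": group,
                         "rms": rng.uniform(0.05, 3.0)})
    return pd.DataFrame(rows)


class TestBuildPairs:
    def test_full_design_counts(self):
        config = sd.CohortConfig(n_per_sex=2, seed=1, mesh_subdivisions=1)
        pairs = sd.build_pairs(sd.generate_cohort(config))
        groups = [p.group for p in pairs]
        assert groups.count("match") == 8 and groups.count("mismatch") == 8

    def test_pairs_never_mix_sex_or_side(self, small_cohort):
        for pair in sd.build_pairs(small_cohort):
            assert pair.reference.sex == pair.moving.sex
            assert pair.reference.side == pair.moving.side
            assert pair.reference.acquisition == "AM"
            assert pair.moving.acquisition == "PM"

    def test_single_subject_cannot_mismatch(self):
        config = sd.CohortConfig(n_per_sex=1, seed=1, mesh_subdivisions=1)
        with pytest.raises(InvalidConfigError):
            sd.build_pairs(sd.generate_cohort(config))

    def test_group_label_consistency_enforced(self, small_cohort):
        am = small_cohort.get("M000", "right", "AM")
        pm = small_cohort.get("M000", "right", "PM")
        with pytest.raises(InvalidConfigError):
            sd.ComparisonPair(reference=am, moving=pm, group="mismatch")


class TestClassify:
    @pytest.mark.parametrize("value,expected", [
        (0.26, "match"),       # typical same-subject RMS
        (2.44, "mismatch"),    # typical different-subject RMS
        (1.0, "mismatch"),     # boundary assigned to mismatch
        (0.0, "match"),
    ])
    def test_threshold_rule(self, value, expected):
        assert sd.classify(value) == expected

    def test_negative_rms_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.classify(-0.1)


class TestRunExperiment:
    def test_row_count_and_determinism(self, small_cohort):
        pairs = sd.build_pairs(small_cohort)
        table = sd.run_experiment(pairs)
        assert len(table) == 16
        assert not table["failed"].any()
        again = sd.run_experiment(sd.build_pairs(small_cohort))
        assert np.array_equal(table["rms"].to_numpy(), again["rms"].to_numpy())

    def test_scale_consistency_of_rms(self, small_cohort):
        """Doubling all coordinates doubles the RMS through the pipeline."""
        am = small_cohort.get("F000", "right", "AM").mesh
        pm = small_cohort.get("F001", "right", "PM").mesh

        def pipeline_rms(scale):
            reference, moving = am.copy(), pm.copy()
            reference.vertices = reference.vertices * scale
            moving.vertices = moving.vertices * scale
            transform, _ = sd.icp_register(moving, reference)
            moving.vertices = transform.apply(moving.vertices)
            return sd.rms(sd.point_to_surface_field(reference, moving))

        assert pipeline_rms(2.0) == pytest.approx(2.0 * pipeline_rms(1.0),
                                                  rel=1e-6)


class TestThreeWayAnova:
    def test_matches_mean_decomposition_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            table = random_balanced_table(rng)
            result = sd.three_way_anova(table)
            oracle = anova_oracle(table)
            for term in ANOVA_TERMS:
                assert result.table.loc[term, "sum_sq"] == pytest.approx(
                    oracle["ss"][term], rel=1e-9, abs=1e-12)
                assert result.table.loc[term, "F"] == pytest.approx(
                    oracle["F"][term], rel=1e-9)
                assert result.table.loc[term, "p"] == pytest.approx(
                    oracle["p"][term], rel=1e-6)
            assert result.table.loc["Residual", "sum_sq"] == pytest.approx(
                oracle["ss"]["Residual"], rel=1e-9)

    def test_ss_partition_and_eta_squared_bounds(self):
        rng = np.random.default_rng(29)
        table = random_balanced_table(rng, reps=4)
        result = sd.three_way_anova(table)
        y = table["rms"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert result.ss_total == pytest.approx(ss_total, rel=1e-9)
        etas = result.table.loc[list(ANOVA_TERMS), "eta_squared"]
        assert ((etas >= 0) & (etas <= 1)).all()
        assert etas.sum() <= 1.0 + 1e-12

    def test_pure_group_effect_has_eta_squared_one(self):
        rows = []
        for sex, side, group in itertools.product("MF", ("right", "left"),
                                                  ("match", "mismatch")):
            value = 0.2 if group == "match" else 2.0
            rows.extend([{"sex": sex, "side": side, "group": group,
                          "rms": value}] * 3)
        result = sd.three_way_anova(pd.DataFrame(rows))
        assert result.eta_squared("group") == pytest.approx(1.0)
        for term in ANOVA_TERMS:
            if term != "group":
                assert result.eta_squared(term) == pytest.approx(0.0, abs=1e-9)

    def test_permuting_rms_destroys_group_effect(self):
        """Permutation sanity: after shuffling RMS against the labels, the
        group p-value behaves like a null p-value (rarely small)."""
        rng = np.random.default_rng(31)
        base = random_balanced_table(rng, reps=6)
        # inject a strong group effect, then destroy it by permutation
        base.loc[base.group == "mismatch", "rms"] += 5.0
        assert sd.three_way_anova(base).table.loc["group", "p"] < 1e-6
        p_values = []
        for _ in range(40):
            shuffled = base.copy()
            shuffled["rms"] = rng.permutation(shuffled["rms"].to_numpy())
            p_values.append(sd.three_way_anova(shuffled).table.loc["group", "p"])
        assert np.mean(np.asarray(p_values) < 0.05) <= 0.25
        assert np.mean(p_values) > 0.2

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(3)
        table = random_balanced_table(rng)
        with pytest.raises(InvalidConfigError):
            sd.three_way_anova(table[~((table.sex == "M")
                                       & (table.side == "left"))])

    def test_unbalanced_table_flagged(self):
        rng = np.random.default_rng(4)
        table = random_balanced_table(rng, reps=4)
        result = sd.three_way_anova(table.drop(index=[0, 1]))
        assert not result.balanced
        assert result.notes

    def test_corrected_alpha_is_bonferroni_three(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 3)
        rng = np.random.default_rng(5)
        assert sd.three_way_anova(random_balanced_table(rng)
                                  ).alpha_corrected == pytest.approx(0.0167,
                                                                     abs=5e-4)


class TestSummarize:
    def test_hand_computed_cell(self):
        table = pd.DataFrame([
            {"sex": "M", "side": "right", "group": "match", "rms": 0.2},
            {"sex": "M", "side": "right", "group": "match", "rms": 0.4},
        ])
        row = sd.summarize(table).iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.1414, abs=1e-4)
        assert row["max"] == 0.4 and row["min"] == 0.2

    def test_single_value_cell_has_zero_sd(self):
        table = pd.DataFrame([{"sex": "F", "side": "left",
                               "group": "mismatch", "rms": 2.2}])
        row = sd.summarize(table).iloc[0]
        assert row["sd"] == 0.0
        assert row["mean"] == row["max"] == row["min"] == 2.2

    def test_pooled_rows_are_weighted_cell_means(self):
        rng = np.random.default_rng(6)
        table = random_balanced_table(rng, reps=3)
        summary = sd.summarize(table)
        pooled = summary[(summary.sex == "all") & (summary.group == "match")]
        expected = table.loc[table.group == "match", "rms"].mean()
        assert pooled["mean"].iloc[0] == pytest.approx(expected, rel=1e-12)
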