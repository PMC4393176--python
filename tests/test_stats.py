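"""Cohort statistics: summaries, pooled t-test, mixed repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

from lvmotion.stats import (
    mixed_anova,
    rm_anova_bonferroni,
    summarize,
    unpaired_t_test,
)

TIMEPOINTS = ["d2", "d7", "d14", "d28"]


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance Student's t (independent of scipy)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def make_table(rng, n_per_group=(9, 6), group_shift=0.0, time_slope=0.0, sd=1.0,
               metric="m", timepoints=TIMEPOINTS):
    rows = []
    for g, n, shift in zip(["control", "treated"], n_per_group, [0.0, group_shift]):
        for j in range(n):
            subj = rng.normal(0, sd / 2)
            for k, tp in enumerate(timepoints):
                rows.append(
                    dict(animal=f"{g}-{j}", group=g, timepoint=tp, metric=metric,
                         value=shift + subj + time_slope * k + rng.normal(0, sd))
                )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_mean_and_sem(self):
        table = pd.DataFrame(
            dict(animal=list("abc"), group="g", timepoint="d2", metric="m",
                 value=[1.0, 2.0, 3.0])
        )
        out = summarize(table, "m")
        assert len(out) == 1
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sem"] == pytest.approx(1 / np.sqrt(3), abs=1e-4)
        assert out.loc[0, "sem"] == pytest.approx(0.5774, abs=1e-4)

    def test_sample_means_near_generative_means(self, rng):
        table = make_table(rng, n_per_group=(30, 30), group_shift=2.0)
        out = summarize(table, "m")
        for _, row in out.iterrows():
            mu = 2.0 if row["group"] == "treated" else 0.0
            assert abs(row["mean"] - mu) < 4 * row["sem"]

    def test_missing_metric_and_duplicate_rows_rejected(self):
        table = pd.DataFrame(
            dict(animal=["a", "a"], group="g", timepoint="d2", metric="m", value=[1.0, 2.0])
        )
        with pytest.raises(ValueError, match="duplicate"):
            summarize(table, "m")
        with pytest.raises(ValueError, match="not present"):
            summarize(table.drop_duplicates("animal"), "other")


class TestUnpairedTTest:
    def test_identical_samples(self):
        r = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_matches_closed_form_oracle(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        r = unpaired_t_test(a, b)
        assert r.statistic == pytest.approx(pooled_t_oracle(a, b), abs=1e-10)
        assert r.statistic == pytest.approx(-1.0954, abs=1e-4)
        assert r.df == 6
        assert r.pvalue == pytest.approx(0.3153, abs=1e-4)

    def test_symmetry_under_sample_swap(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 5)
        r1, r2 = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])


class TestMixedAnova:
    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        table = make_table(rng, group_shift=0.6, time_slope=0.2)
        mine = mixed_anova(table)
        ref = pg.mixed_anova(
            data=table, dv="value", within="timepoint", subject="animal", between="group"
        ).set_index("Source")
        for src, ref_src in (("group", "group"), ("time", "timepoint"), ("group:time", "Interaction")):
            row = mine.set_index("source").loc[src]
            assert row["F"] == pytest.approx(ref.loc[ref_src, "F"], rel=1e-9)
            assert row["p"] == pytest.approx(ref.loc[ref_src, "p_unc"], rel=1e-9)
            assert row["ss"] == pytest.approx(ref.loc[ref_src, "SS"], rel=1e-9)

    def test_bonferroni_adjustment_definition(self, rng):
        table = make_table(rng, group_shift=1.0)
        res = rm_anova_bonferroni(table, "m", TIMEPOINTS)
        assert np.allclose(
            res.posthoc["p_adj"], np.minimum(1.0, res.posthoc["p_raw"] * len(TIMEPOINTS))
        )

    def test_incomplete_animals_dropped_complete_case(self, rng, caplog):
        table = make_table(rng)
        table = table[~((table["animal"] == "control-0") & (table["timepoint"] == "d28"))]
        with caplog.at_level("WARNING"):
            res = rm_anova_bonferroni(table, "m", TIMEPOINTS)
        assert res.dropped_animals == ["control-0"]
        assert "dropping" in caplog.text
        # group df reflects the removed animal: (9-1) + 6 subjects, 2 groups
        assert res.anova.set_index("source").loc["group", "df"] == 1

    def test_strong_group_separation_always_detected(self):
        # means 5 within-animal SDs apart -> essentially certain detection
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            table = make_table(rng, group_shift=5.0, sd=1.0)
            res = rm_anova_bonferroni(table, "m", TIMEPOINTS)
            hits += res.anova.set_index("source").loc["group", "p"] < 0.05
        assert hits == 50
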