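"""Generator contracts: determinism, planted-signal structure, count laws."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from methclock.io import merge_complementary
from methclock.synthetic import (
    AgesDays,
    AgesYears,
    SimulationConfig,
    simulate_cohort,
    summarize_site_counts,
)


def small_config(**kw):
    base = dict(
        n_samples=12, n_cpgs=300, n_age_cpgs=30, seed=5,
        age_model=AgesYears(0.13, 6.0), dropout_rate=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_degenerate_ages_with_planted_signal(self):
        with pytest.raises(ValueError, match="single age"):
            small_config(age_model=AgesDays((14,)))

    def test_degenerate_ages_fine_without_signal(self):
        small_config(age_model=AgesDays((14,)), n_age_cpgs=0)

    @pytest.mark.parametrize(
        "kw", [dict(dropout_rate=1.0), dict(n_age_cpgs=400), dict(n_cpgs=0),
               dict(treatment_shift={"ghost": 1.0})],
    )
    def test_rejects_invalid_configs(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestSimulateCohort:
    def test_zero_shift_epigenetic_equals_chronological(self):
        cohort = simulate_cohort(small_config(
            treatment_levels=("control", "enlarged"), treatment_shift={},
        ))
        meta = cohort.metadata.set_index("sample")
        assert np.allclose(cohort.truth.epigenetic_age, meta["age"])

    def test_treatment_shift_moves_epigenetic_age(self):
        cohort = simulate_cohort(small_config(
            treatment_levels=("control", "reduced"),
            treatment_shift={"reduced": 0.5},
        ))
        meta = cohort.metadata.set_index("sample")
        shift = cohort.truth.epigenetic_age - meta["age"]
        assert np.allclose(shift[meta["treatment"] == "control"], 0.0)
        assert np.allclose(shift[meta["treatment"] == "reduced"], 0.5)

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config(dropout_rate=0.1)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors and len(match) == len(names)

    def test_counts_valid_and_strands_sum(self):
        cohort = simulate_cohort(small_config())
        truth_pos = dict(zip(cohort.truth.site_id, cohort.truth.position))
        for table in cohort.calls.values():
            cov = table["meth"] + table["unmeth"]
            assert (cov >= 1).all()
            assert (table["meth"] >= 0).all() and (table["unmeth"] >= 0).all()
            merged = merge_complementary(table)
            assert merged["ratio"].between(0, 1).all()
        assert len(truth_pos) == 300

    def test_null_cohort_has_no_age_correlation(self):
        # 50 samples, no planted slopes: nearly every site's ratio is
        # uncorrelated with age (|r| < 0.3 expected for ~97% under the null)
        cfg = small_config(n_samples=50, n_cpgs=400, n_age_cpgs=0, seed=21)
        cohort = simulate_cohort(cfg)
        meta = cohort.metadata.set_index("sample")
        ratios = {
            s: pd.Series(
                merge_complementary(t)["ratio"].to_numpy(),
                index=merge_complementary(t)["pos"].to_numpy(),
            )
            for s, t in cohort.calls.items()
        }
        matrix = pd.DataFrame(ratios)
        ages = meta.loc[matrix.columns, "age"].to_numpy()
        ages_c = ages - ages.mean()
        vals = matrix.to_numpy()
        vc = vals - vals.mean(axis=1, keepdims=True)
        denom = np.sqrt((vc ** 2).sum(axis=1) * (ages_c ** 2).sum())
        r = np.where(denom > 0, (vc @ ages_c) / np.where(denom == 0, 1, denom), 0.0)
        assert (np.abs(r) < 0.3).mean() >= 0.95

    def test_stronger_slopes_strengthen_age_correlation(self):
        mean_abs_r = []
        for scale in (0.05, 0.2, 0.6):
            cfg = small_config(n_samples=30, seed=9, slope_scale=scale)
            cohort = simulate_cohort(cfg)
            meta = cohort.metadata.set_index("sample")
            age_sites = set(cohort.truth.site_id[cohort.truth.slope != 0])
            cols = {}
            for s, t in cohort.calls.items():
                m = merge_complementary(t)
                ids = m["chrom"].astype(str) + ":" + m["pos"].astype(str)
                cols[s] = pd.Series(m["ratio"].to_numpy(), index=ids)
            matrix = pd.DataFrame(cols).loc[sorted(age_sites)]
            ages = meta.loc[matrix.columns, "age"]
            rs = matrix.T.corrwith(ages)
            mean_abs_r.append(rs.abs().mean())
        assert mean_abs_r[0] < mean_abs_r[1] < mean_abs_r[2]


class TestSummarizeSiteCounts:
    def test_complementary_pairs_counted_once(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "pos": [10, 11, 20, 21, 30, 31],
                "strand": ["+", "-", "+", "-", "+", "-"],
                "meth": 1,
                "unmeth": 1,
            }
        )
        assert summarize_site_counts({"s": table}).loc["s"] == 3

    def test_empty_sample_counts_zero(self):
        empty = pd.DataFrame(
            columns=["chrom", "pos", "strand", "meth", "unmeth"]
        )
        assert summarize_site_counts({"s": empty}).loc["s"] == 0

    def test_dropout_expectation(self):
        # dropout 0.1 on 1000 CpGs: per-sample counts ~ Binomial(1000, 0.9)
        cfg = small_config(
            n_samples=20, n_cpgs=1000, n_age_cpgs=0, dropout_rate=0.1, seed=13
        )
        counts = summarize_site_counts(simulate_cohort(cfg).calls)
        se_mean = np.sqrt(1000 * 0.1 * 0.9 / 20)
        assert abs(counts.mean() - 900) < 4 * se_mean

    def test_reads_from_directory(self, tmp_path):
        simulate_cohort(small_config(n_samples=3), out_dir=tmp_path)
        counts = summarize_site_counts(tmp_path)
        assert len(counts) == 3 and (counts == 300).all()
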