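"""Synthetic cohort generator: composition, round trip, survival and count
calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from popseg import CohortGenerator, GeneratorConfig, segment_cohort
from popseg.config import DEFAULT_PROPORTIONS
from popseg.errors import ConfigError, DataIntegrityError
from popseg.segments import SEGMENT_ORDER
from popseg.simulate import FOLLOWUP_DAYS, piecewise_exponential_rates


def equal_proportions():
    return {s: 1 / 6 for s in SEGMENT_ORDER}


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        bad = dict(DEFAULT_PROPORTIONS)
        bad["MOSTLY_HEALTHY"] += 0.1
        with pytest.raises(ConfigError, match="sum to 1"):
            GeneratorConfig(segment_proportions=bad)

    def test_yearly_survival_must_be_nonincreasing(self):
        ys = {s: (0.9, 0.95, 0.8) if s == "END_OF_LIFE" else (1.0, 1.0, 1.0)
              for s in SEGMENT_ORDER}
        with pytest.raises(ConfigError, match="nonincreasing"):
            GeneratorConfig(yearly_survival=ys)

    def test_negative_rate_rejected(self):
        cfg = GeneratorConfig()
        rates = {k: dict(v) for k, v in cfg.followup_rates.items()}
        rates["ED"]["END_OF_LIFE"] = -1.0
        with pytest.raises(ConfigError, match="rate"):
            GeneratorConfig(followup_rates=rates)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_patients=123, seed=9)
        cfg.to_yaml(tmp_path / "config.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "config.yaml") == cfg


class TestCohortComposition:
    def test_segment_shares_match_configured_proportions(self):
        """Default composition at n=100,000: empirical shares within half a
        percentage point of 58.8 / 24.5 / 5.3 / 10.7 / 0.5 / 0.2."""
        cfg = GeneratorConfig(n_patients=100_000, seed=1)
        _, _, truth = CohortGenerator(cfg).generate_cohort()
        shares = truth.value_counts(normalize=True) * 100
        expected = dict(zip(SEGMENT_ORDER, [58.8, 24.5, 5.3, 10.7, 0.5, 0.2]))
        for seg, target in expected.items():
            assert abs(shares.get(seg, 0.0) - target) < 0.5

    def test_empty_cohort(self):
        cfg = GeneratorConfig(n_patients=0)
        patients, encounters, truth = CohortGenerator(cfg).generate_cohort()
        assert len(patients) == 0 and len(encounters) == 0 and len(truth) == 0

    def test_degenerate_mixture_all_mostly_healthy(self):
        props = {s: 0.0 for s in SEGMENT_ORDER}
        props["MOSTLY_HEALTHY"] = 1.0
        cfg = GeneratorConfig(n_patients=100, segment_proportions=props, seed=5)
        patients, encounters, truth = CohortGenerator(cfg).generate_cohort()
        assert len(patients) == 100
        labels = segment_cohort(patients, encounters)
        assert (labels == "MOSTLY_HEALTHY").all()

    def test_ages_within_bounds_and_adults_only(self, small_cohort):
        ages = small_cohort["patients"]["age_2012"]
        assert ages.between(21, 100).all()

    @pytest.mark.parametrize("seed", [0, 7])
    def test_round_trip_classification(self, seed):
        """The default rule set reproduces the generator's ground truth for
        every patient, including frequent-admitter encounter constraints."""
        cfg = GeneratorConfig(n_patients=4000, seed=seed,
                              segment_proportions=equal_proportions())
        patients, encounters, truth = CohortGenerator(cfg).generate_cohort()
        labels = segment_cohort(patients, encounters)
        assert (labels.loc[truth.index] == truth).all()
        adm = encounters[(encounters["kind"] == "INPATIENT")
                         & (encounters["date"].dt.year == 2012)]
        per_patient = adm.groupby("patient_id").size()
        freq = truth.index[truth == "COMPLEX_CHRONIC_FREQ"]
        nonfreq = truth.index[truth != "COMPLEX_CHRONIC_FREQ"]
        assert (per_patient.reindex(freq).fillna(0) >= 3).all()
        assert (per_patient.reindex(nonfreq).fillna(0) <= 2).all()

    def test_every_patient_has_a_baseline_encounter(self, small_cohort):
        enc = small_cohort["encounters"]
        enc_2012 = enc[enc["date"].dt.year == 2012]
        assert set(small_cohort["patients"]["patient_id"]) == set(enc_2012["patient_id"])


class TestFollowup:
    def test_no_mortality_limit(self):
        ys = {s: (1.0, 1.0, 1.0) for s in SEGMENT_ORDER}
        cfg = GeneratorConfig(n_patients=1000, seed=3, yearly_survival=ys)
        gen = CohortGenerator(cfg)
        patients, _, truth = gen.generate_cohort()
        _, out = gen.sample_followup_outcomes(patients, truth)
        assert out["death_date"].isna().all()

    def test_zero_rates_give_zero_followup_encounters(self):
        rates = {k: {s: 0.0 for s in SEGMENT_ORDER} for k in ("ED", "SOC", "INPATIENT")}
        cfg = GeneratorConfig(n_patients=500, seed=3, followup_rates=rates)
        gen = CohortGenerator(cfg)
        patients, _, truth = gen.generate_cohort()
        followup, _ = gen.sample_followup_outcomes(patients, truth)
        assert len(followup) == 0

    def test_end_of_life_three_year_survival_calibration(self):
        """Fraction alive at day 1094 within 2 points of the configured
        58.2% three-year survival."""
        props = {s: 0.0 for s in SEGMENT_ORDER}
        props["END_OF_LIFE"] = 1.0
        cfg = GeneratorConfig(n_patients=5000, seed=11, segment_proportions=props)
        gen = CohortGenerator(cfg)
        patients, _, truth = gen.generate_cohort()
        _, out = gen.sample_followup_outcomes(patients, truth)
        alive = out["death_date"].isna().mean() * 100
        assert abs(alive - 58.2) < 2.0

    def test_yearly_survival_structure_matches_piecewise_model(self):
        """Empirical survival at each year knot tracks the configured
        probabilities (piecewise-exponential construction)."""
        props = {s: 0.0 for s in SEGMENT_ORDER}
        props["COMPLEX_CHRONIC_FREQ"] = 1.0
        cfg = GeneratorConfig(n_patients=20_000, seed=13, segment_proportions=props)
        gen = CohortGenerator(cfg)
        patients, _, truth = gen.generate_cohort()
        _, out = gen.sample_followup_outcomes(patients, truth)
        days = (out["death_date"] - pd.Timestamp("2013-01-01")).dt.days
        for knot, target in zip((365, 730, 1094), cfg.yearly_survival["COMPLEX_CHRONIC_FREQ"]):
            alive = 1.0 - (days.notna() & (days < knot)).mean()
            assert abs(alive - target) < 0.015

    def test_no_encounters_after_death(self):
        cfg = GeneratorConfig(n_patients=3000, seed=17,
                              segment_proportions={
                                  **{s: 0.0 for s in SEGMENT_ORDER}, "END_OF_LIFE": 1.0})
        sim = CohortGenerator(cfg).generate()
        merged = sim["encounters"].merge(
            sim["patients"][["patient_id", "death_date"]], on="patient_id")
        followup = merged[merged["date"] >= "2013-01-01"]
        dead = followup[followup["death_date"].notna()]
        assert (dead["date"] <= dead["death_date"]).all()

    def test_missing_segment_raises(self, small_cohort):
        gen = CohortGenerator(GeneratorConfig(n_patients=10, seed=1))
        patients, _, truth = gen.generate_cohort()
        with pytest.raises(DataIntegrityError):
            gen.sample_followup_outcomes(patients, truth.iloc[:5])

    def test_dispersion_zero_gives_poisson_counts(self):
        """With alpha -> 0 the per-segment variance/mean ratio of follow-up
        counts approaches 1."""
        props = {s: 0.0 for s in SEGMENT_ORDER}
        props["STABLE_CHRONIC"] = 1.0
        ys = {s: (1.0, 1.0, 1.0) for s in SEGMENT_ORDER}
        cfg = GeneratorConfig(
            n_patients=4000, seed=19, segment_proportions=props, yearly_survival=ys,
            dispersion={"ED": 0.0, "SOC": 0.0, "INPATIENT": 0.0})
        sim = CohortGenerator(cfg).generate()
        enc = sim["encounters"]
        soc = enc[(enc["kind"] == "SOC") & (enc["date"] >= "2013-01-01")]
        counts = soc.groupby("patient_id").size().reindex(
            sim["patients"]["patient_id"], fill_value=0)
        ratio = counts.var(ddof=1) / counts.mean()
        assert abs(ratio - 1.0) < 0.15


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self, tmp_path):
        from popseg.io import write_cohort
        cfg = GeneratorConfig(n_patients=300, seed=21)
        a = CohortGenerator(cfg).generate()
        b = CohortGenerator(cfg).generate()
        pd.testing.assert_frame_equal(a["patients"], b["patients"])
        pd.testing.assert_frame_equal(a["encounters"], b["encounters"])
        write_cohort(a["patients"], a["encounters"], tmp_path / "a")
        write_cohort(b["patients"], b["encounters"], tmp_path / "b")
        assert (tmp_path / "a" / "encounters.csv").read_bytes() == \
               (tmp_path / "b" / "encounters.csv").read_bytes()
        c = CohortGenerator(GeneratorConfig(n_patients=300, seed=22)).generate()
        assert not c["encounters"].equals(a["encounters"])


def test_piecewise_rates_reproduce_knot_survival():
    rates = piecewise_exponential_rates((0.746, 0.646, 0.582))
    spans = np.array([365, 365, 364])
    surv = np.exp(-np.cumsum(rates * spans))
    assert np.allclose(surv, [0.746, 0.646, 0.582])
    assert FOLLOWUP_DAYS == 1094
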