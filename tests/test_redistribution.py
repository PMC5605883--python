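"""Source exclusion rules, garbage-code redistribution (all three methods),
and completeness correction."""

import numpy as np
import pandas as pd
import pytest

from codkit.redistribution import (
    GarbageMap,
    GarbageMapEntry,
    completeness_correct,
    exclude_low_quality,
    redistribute,
)
from codkit.synthdata import SimConfig, observe, simulate_truth

STRATUM = ["location", "year", "age", "sex"]


def _completeness(rows):
    return pd.DataFrame(rows, columns=["location", "year", "completeness"])


def _garbage(rows):
    return pd.DataFrame(rows, columns=["location", "year",
                                       "major_garbage_fraction"])


class TestExcludeLowQuality:
    def _records(self, locations):
        return pd.DataFrame({
            "location": locations, "year": 2010, "age": 10, "sex": "male",
            "source": "VR", "code": "ncd_0", "deaths": 10.0,
        })

    def test_incomplete_vr_excluded(self):
        recs = self._records([0])
        kept, log, flags = exclude_low_quality(
            recs, _completeness([(0, 2010, 0.4)]), _garbage([(0, 2010, 0.1)]))
        assert len(kept) == 0
        assert log.iloc[0]["reason"] == "completeness"

    def test_majority_garbage_excluded(self):
        recs = self._records([0])
        kept, log, flags = exclude_low_quality(
            recs, _completeness([(0, 2010, 0.9)]), _garbage([(0, 2010, 0.6)]))
        assert len(kept) == 0
        assert log.iloc[0]["reason"] == "garbage"

    def test_marginal_completeness_flagged_not_dropped(self):
        recs = self._records([0])
        kept, log, flags = exclude_low_quality(
            recs, _completeness([(0, 2010, 0.6)]), _garbage([(0, 2010, 0.1)]))
        assert len(kept) == len(recs)
        assert flags.iloc[0]["non_representative"]

    def test_va_rules_when_completeness_unknown(self):
        recs = self._records([0]).assign(source="VA")
        kept, log, flags = exclude_low_quality(
            recs, _completeness([]), _garbage([(0, 2010, 0.1)]))
        assert len(kept) == len(recs)
        assert "VA rules" in log.iloc[0]["reason"]


class TestRedistribute:
    def test_proportional_split_oracle(self, stratum_records, hier):
        gmap = GarbageMap([GarbageMapEntry("gb_major_1", 1, "proportional",
                                           ("ncd_0", "ncd_1"))])
        out = redistribute(stratum_records, gmap, hier)
        got = out.set_index("code")["deaths"]
        assert got["ncd_0"] == pytest.approx(33.0)
        assert got["ncd_1"] == pytest.approx(77.0)

    def test_no_garbage_is_identity(self, stratum_records, hier):
        recs = stratum_records[stratum_records["code"] != "gb_major_1"]
        gmap = GarbageMap.proportional_default(hier)
        out = redistribute(recs, gmap, hier)
        assert out["deaths"].sum() == pytest.approx(recs["deaths"].sum())
        assert set(out["code"]) == set(recs["code"])

    def test_all_zero_targets_fall_back_to_uniform(self, hier):
        recs = pd.DataFrame({
            "location": 0, "year": 2010, "age": 10, "sex": "male",
            "source": "VR", "code": ["gb_major_1"], "deaths": [12.0],
        })
        gmap = GarbageMap([GarbageMapEntry("gb_major_1", 1, "proportional",
                                           ("cmnn_0", "ncd_0", "injury_0"))])
        out = redistribute(recs, gmap, hier)
        assert np.allclose(out["deaths"], 4.0)
        assert out["deaths"].sum() == pytest.approx(12.0, abs=1e-9)

    def test_fixed_proportions(self, stratum_records, hier):
        gmap = GarbageMap([GarbageMapEntry("gb_major_1", 1, "fixed",
                                           ("ncd_0", "ncd_1"), (0.9, 0.1))])
        out = redistribute(stratum_records, gmap, hier)
        got = out.set_index("code")["deaths"]
        assert got["ncd_0"] == pytest.approx(39.0)
        assert got["ncd_1"] == pytest.approx(71.0)

    def test_fixed_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GarbageMapEntry("g", 1, "fixed", ("a", "b"), (0.7, 0.2))

    def test_negative_proportions_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            GarbageMapEntry("g", 1, "fixed", ("a", "b"), (1.2, -0.2))

    def test_unmapped_garbage_code_rejected(self, stratum_records, hier):
        gmap = GarbageMap([GarbageMapEntry("gb_major_2", 2, "proportional",
                                           ("ncd_0",))])
        with pytest.raises(ValueError, match="gb_major_1"):
            redistribute(stratum_records, gmap, hier)

    @pytest.mark.parametrize("method", ["proportional", "fixed", "regression"])
    def test_conservation_per_stratum(self, hier, method):
        """Total deaths in every location-year-age-sex stratum survive
        redistribution to 1e-9, for every method, at 30% garbage."""
        cfg = SimConfig(
            n_locations=3, year_start=2010, year_end=2012, hierarchy=hier,
            sdi_start=np.array([0.55, 0.7, 0.9]), base_population=50_000,
            garbage_p_max=0.6, garbage_age_steepness=0.0,  # flat 30%
            source_types=np.array(["VR"] * 3, dtype=object), seed=21,
        )
        recs = observe(simulate_truth(cfg), cfg)
        leaves = tuple(hier.most_detailed())
        if method == "fixed":
            props = tuple(1.0 / len(leaves) for _ in leaves)
            entries = [GarbageMapEntry(c, l, "fixed", leaves, props)
                       for c, l in hier.garbage_codes.items()]
        else:
            entries = [GarbageMapEntry(c, l, method, leaves)
                       for c, l in hier.garbage_codes.items()]
        out = redistribute(recs, GarbageMap(entries), hier)
        before = recs.groupby(STRATUM)["deaths"].sum()
        after = out.groupby(STRATUM)["deaths"].sum()
        aligned = pd.concat([before, after], axis=1).fillna(0.0)
        assert np.allclose(aligned.iloc[:, 0], aligned.iloc[:, 1], atol=1e-9)
        assert not out["code"].map(hier.is_garbage).any()

    def test_recovers_truth_as_garbage_vanishes(self, hier):
        """redistribute(observe(truth)) cause-fraction bias shrinks towards 0
        as the garbage-coding level falls.  A fixed uniform-split map is used
        so misallocation is possible at all: the bias it induces must scale
        with the amount of garbage and vanish without it."""
        leaves = tuple(hier.most_detailed())
        props = tuple(1.0 / len(leaves) for _ in leaves)
        gmap = GarbageMap([GarbageMapEntry(c, l, "fixed", leaves, props)
                           for c, l in hier.garbage_codes.items()])
        biases = []
        for g in (0.6, 0.2, 0.0):
            cfg = SimConfig(
                n_locations=2, year_start=2010, year_end=2011, hierarchy=hier,
                sdi_start=np.array([0.7, 0.9]), base_population=400_000,
                garbage_p_max=g, garbage_age_steepness=0.0,
                source_types=np.array(["VR", "VR"], dtype=object),
                completeness=pd.DataFrame({
                    "location": [0, 0, 1, 1], "year": [2010, 2011] * 2,
                    "completeness": 1.0}),
                seed=9,
            )
            truth = simulate_truth(cfg)
            recs = observe(truth, cfg)
            out = redistribute(recs, gmap, hier)
            true_frac = (truth.groupby("cause")["deaths"].sum()
                         / truth["deaths"].sum())
            est_frac = (out.groupby("code")["deaths"].sum()
                        / out["deaths"].sum()).reindex(true_frac.index)
            biases.append(float((est_frac - true_frac).abs().sum()))
        assert biases[0] > biases[1] > biases[2]
        assert biases[2] < 0.02  # nothing to redistribute, Poisson noise only


class TestCompletenessCorrect:
    def _env(self, rows):
        return pd.DataFrame(rows, columns=STRATUM + ["envelope"])

    def test_fraction_times_envelope(self, stratum_records, hier):
        recs = stratum_records[stratum_records["code"] != "gb_major_1"].assign(
            deaths=[25.0, 75.0])
        env = self._env([(0, 2010, 10, "male", 200.0)])
        out = completeness_correct(recs, env)
        assert sorted(out["deaths"]) == [pytest.approx(50.0),
                                         pytest.approx(150.0)]

    def test_identity_when_already_complete(self, stratum_records):
        recs = stratum_records[stratum_records["code"] != "gb_major_1"]
        env = self._env([(0, 2010, 10, "male", 100.0)])
        out = completeness_correct(recs, env)
        assert np.allclose(out["deaths"], recs["deaths"])

    def test_cell_sum_equals_envelope(self):
        rng = np.random.default_rng(4)
        recs = pd.DataFrame({
            "location": 0, "year": 2010, "age": 10, "sex": "male",
            "code": [f"c{i}" for i in range(5)],
            "deaths": rng.uniform(1, 50, 5),
        })
        env = self._env([(0, 2010, 10, "male", 321.5)])
        out = completeness_correct(recs, env)
        assert out["deaths"].sum() == pytest.approx(321.5, abs=1e-9)

    def test_invariant_to_count_rescaling(self, stratum_records):
        recs = stratum_records[stratum_records["code"] != "gb_major_1"]
        env = self._env([(0, 2010, 10, "male", 500.0)])
        a = completeness_correct(recs, env)
        b = completeness_correct(recs.assign(deaths=recs["deaths"] * 7.3), env)
        assert np.allclose(a["deaths"], b["deaths"])

    def test_zero_envelope_with_deaths_raises(self, stratum_records):
        recs = stratum_records[stratum_records["code"] != "gb_major_1"]
        env = self._env([(0, 2010, 10, "male", 0.0)])
        with pytest.raises(ValueError, match="envelope"):
            completeness_correct(recs, env)
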