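"""Peptide-group mapping, aggregation, match-between-runs, the missing
value filter and the calibrated glog normalization."""

import numpy as np
import pandas as pd
import pytest

import metaprot as mp
from metaprot import quant
from metaprot.quant import NORMALIZED, QuantMatrix

from conftest import groups_from_truth


def make_psms(rows):
    return pd.DataFrame(rows, columns=["sample", "scan", "peptide",
                                       "proteins", "mz", "rt_min",
                                       "intensity"])


TWO_GROUPS = [
    mp.ProteinGroup("G1", "P1", ["P1", "P2"], {"P1": 1.0, "P2": 0.97}),
    mp.ProteinGroup("G2", "P3", ["P3"], {"P3": 1.0}),
]
COHORTS2 = pd.Series(["healthy", "UC"], index=["S1", "S2"], name="cohort")


class TestPeptideGroupMap:
    def test_single_accession_not_shared(self):
        psms = make_psms([("S1", 1, "AAAAAAK", "P1", 400.0, 10.0, 5.0)])
        m = quant.build_peptide_group_map(psms, TWO_GROUPS)
        assert m.loc[0, "group_id"] == "G1" and not m.loc[0, "shared"]

    def test_accessions_spanning_groups_flagged_shared(self):
        psms = make_psms([("S1", 1, "AAAAAAK", "P1;P3", 400.0, 10.0, 5.0)])
        m = quant.build_peptide_group_map(psms, TWO_GROUPS)
        assert bool(m.loc[0, "shared"])

    def test_unknown_accession_raises(self):
        psms = make_psms([("S1", 1, "AAAAAAK", "PX", 400.0, 10.0, 5.0)])
        with pytest.raises(KeyError):
            quant.build_peptide_group_map(psms, TWO_GROUPS)

    def test_shared_flags_match_brute_force(self, small_study):
        cfg, db, psms, _, truth = small_study
        groups = groups_from_truth(truth)
        m = quant.build_peptide_group_map(psms, groups)
        acc2grp = {a: g.group_id for g in groups for a in g.members}
        ident = psms[psms["peptide"].str.len() > 0]
        expected = {}
        for pep, accs in zip(ident["peptide"], ident["proteins"]):
            expected.setdefault(pep, set()).update(
                acc2grp[a] for a in accs.split(";"))
        for _, row in m.iterrows():
            assert row["shared"] == (len(expected[row["peptide"]]) > 1)


class TestAggregate:
    def test_sums_within_group(self):
        psms = make_psms([
            ("S1", 1, "AAAAAAK", "P1", 400.0, 10.0, 2.0),
            ("S1", 2, "CCCCCCK", "P2", 420.0, 11.0, 4.0),
        ])
        m = quant.build_peptide_group_map(psms, TWO_GROUPS)
        qm = quant.aggregate_intensities(psms, m, COHORTS2)
        assert qm.values.loc["G1", "S1"] == 6.0
        assert np.isnan(qm.values.loc["G1", "S2"])

    def test_group_with_only_shared_peptide_absent(self):
        psms = make_psms([
            ("S1", 1, "AAAAAAK", "P1;P3", 400.0, 10.0, 2.0),
            ("S1", 2, "CCCCCCK", "P1", 420.0, 11.0, 4.0),
        ])
        m = quant.build_peptide_group_map(psms, TWO_GROUPS)
        qm = quant.aggregate_intensities(psms, m, COHORTS2)
        assert "G2" not in qm.values.index  # its only peptide was shared
        assert qm.values.loc["G1", "S1"] == 4.0

    def test_matches_nested_loop_accumulation(self, small_study):
        cfg, db, psms, _, truth = small_study
        m = quant.build_peptide_group_map(psms, groups_from_truth(truth))
        qm = quant.aggregate_intensities(psms, m, cfg.cohorts)
        pep2 = m.set_index("peptide")
        acc = {}
        ident = psms[(psms["peptide"].str.len() > 0) & (psms["intensity"] > 0)]
        for _, row in ident.iterrows():
            info = pep2.loc[row["peptide"]]
            if info["shared"]:
                continue
            key = (info["group_id"], row["sample"])
            acc[key] = acc.get(key, 0.0) + row["intensity"]
        for (gid, sample), total in acc.items():
            assert qm.values.loc[gid, sample] == pytest.approx(total)
        assert qm.values.notna().sum().sum() == len(acc)

    def test_conserves_unshared_intensity(self, small_study):
        cfg, db, psms, _, truth = small_study
        m = quant.build_peptide_group_map(psms, groups_from_truth(truth))
        qm = quant.aggregate_intensities(psms, m, cfg.cohorts)
        unshared = set(m[~m["shared"]]["peptide"])
        expected = psms[psms["peptide"].isin(unshared)]["intensity"].sum()
        assert qm.values.sum().sum() == pytest.approx(expected)


class TestMatchBetweenRuns:
    BASE = [
        ("S1", 1, "AAAAAAK", "P1", 500.0000, 10.0, 8.0),
        ("S2", 9, "CCCCCCK", "P3", 700.0000, 50.0, 3.0),
    ]

    def _run(self, feature):
        psms = make_psms(self.BASE + [feature])
        return quant.match_between_runs(psms, ppm_tol=10, rt_window_min=15)

    def test_within_tolerance_transferred(self):
        out = self._run(("S2", 1, "", "", 500.0049, 12.0, 5.0))  # 9.8 ppm
        row = out[(out["sample"] == "S2") & (out["scan"] == 1)].iloc[0]
        assert row["peptide"] == "AAAAAAK" and row["mbr"]

    def test_beyond_ppm_not_transferred(self):
        out = self._run(("S2", 1, "", "", 500.0060, 12.0, 5.0))  # 12 ppm
        row = out[(out["sample"] == "S2") & (out["scan"] == 1)].iloc[0]
        assert row["peptide"] == "" and not row["mbr"]

    def test_beyond_rt_window_not_transferred(self):
        out = self._run(("S2", 1, "", "", 500.0000, 30.0, 5.0))  # drt 20
        row = out[(out["sample"] == "S2") & (out["scan"] == 1)].iloc[0]
        assert row["peptide"] == ""

    def test_closest_ppm_wins(self):
        psms = make_psms(self.BASE + [
            ("S2", 1, "", "", 500.0049, 10.0, 5.0),
            ("S2", 2, "", "", 500.0010, 10.0, 6.0),
        ])
        out = quant.match_between_runs(psms)
        assert out[(out["sample"] == "S2") & (out["scan"] == 2)
                   ].iloc[0]["peptide"] == "AAAAAAK"
        assert out[(out["sample"] == "S2") & (out["scan"] == 1)
                   ].iloc[0]["peptide"] == ""

    def test_never_overwrites_existing_identification(self):
        psms = make_psms(self.BASE + [
            ("S2", 1, "GGGGGGR", "P1", 500.0001, 10.0, 5.0)])
        out = quant.match_between_runs(psms)
        row = out[(out["sample"] == "S2") & (out["scan"] == 1)].iloc[0]
        assert row["peptide"] == "GGGGGGR" and not row["mbr"]

    def test_recovers_simulated_dropouts(self, small_study):
        cfg, db, psms, _, truth = small_study
        out = quant.match_between_runs(psms)
        transferred = out[out["mbr"]]
        assert len(transferred) > 0
        # a transferred feature's m/z sits within 10 ppm of its donor median
        donors = out[(out["peptide"].str.len() > 0) & ~out["mbr"]]
        med = donors.groupby("peptide")["mz"].median()
        ppm = ((transferred["mz"] - med[transferred["peptide"]].to_numpy())
               .abs() / med[transferred["peptide"]].to_numpy() * 1e6)
        assert (ppm <= 10).all()


class TestFilterMissing:
    def _matrix(self, n1_obs, n2_obs):
        vals = [np.nan] * 8 + [np.nan] * 10
        for i in range(n1_obs):
            vals[i] = 5.0
        for i in range(n2_obs):
            vals[8 + i] = 5.0
        samples = [f"H{i}" for i in range(8)] + [f"U{i}" for i in range(10)]
        cohorts = pd.Series(["healthy"] * 8 + ["UC"] * 10, index=samples)
        return QuantMatrix(values=pd.DataFrame([vals], index=["G"],
                                               columns=samples),
                          cohorts=cohorts)

    @pytest.mark.parametrize("n1,n2,kept", [
        (0, 0, False),   # rule 1: both cohorts all-null
        (3, 3, False),   # rule 3: both below 4
        (0, 3, False),   # rule 2: one all-null, other below 4
        (5, 0, True),    # no rule fires: presence/absence candidate
        (4, 0, True),
        (3, 4, True),
        (8, 10, True),
    ])
    def test_three_rules(self, n1, n2, kept):
        out = quant.filter_missing(self._matrix(n1, n2))
        assert ("G" in out.values.index) == kept

    def test_zero_sample_cohort_rejected(self):
        vals = pd.DataFrame([[1.0]], index=["G"], columns=["S1"])
        qm = QuantMatrix(values=vals,
                         cohorts=pd.Series({"S1": "healthy"}))
        with pytest.raises(ValueError, match="zero samples"):
            quant.filter_missing(qm)


class TestNormalizeGlog:
    def _random_matrix(self, rng, n=40):
        vals = 2.0 ** rng.normal(20, 2, size=(n, 4))
        vals[rng.random((n, 4)) < 0.1] = np.nan
        samples = ["H1", "H2", "U1", "U2"]
        return QuantMatrix(
            values=pd.DataFrame(vals, columns=samples,
                                index=[f"G{i}" for i in range(n)]),
            cohorts=pd.Series(["healthy", "healthy", "UC", "UC"],
                              index=samples))

    def test_median_zero_mad_one(self):
        qm = self._random_matrix(np.random.default_rng(0))
        out = quant.normalize_glog(qm)
        assert out.scale == NORMALIZED
        for col in out.values.columns:
            x = out.values[col].dropna()
            assert np.median(x) == pytest.approx(0.0, abs=1e-9)
            assert np.median(np.abs(x)) == pytest.approx(1.0, abs=1e-7)

    def test_idempotent_on_normalized_matrix(self):
        qm = quant.normalize_glog(self._random_matrix(
            np.random.default_rng(1)))
        again = quant.normalize_glog(qm)
        pd.testing.assert_frame_equal(qm.values, again.values)

    def test_monotone_within_sample(self):
        qm = self._random_matrix(np.random.default_rng(2))
        out = quant.normalize_glog(qm)
        for col in out.values.columns:
            both = pd.concat([qm.values[col], out.values[col]],
                             axis=1, keys=["raw", "norm"]).dropna()
            ordered = both.sort_values("raw")
            assert ordered["norm"].is_monotonic_increasing

    def test_scale_factor_absorbed(self):
        """Two samples differing by a multiplicative constant normalize to
        identical columns."""
        rng = np.random.default_rng(3)
        base = 2.0 ** rng.normal(20, 2, size=50)
        vals = pd.DataFrame({"H1": base, "H2": base, "U1": 7.3 * base,
                             "U2": base})
        qm = QuantMatrix(values=vals,
                         cohorts=pd.Series(["healthy", "healthy", "UC", "UC"],
                                           index=vals.columns))
        out = quant.normalize_glog(qm)
        np.testing.assert_allclose(out.values["U1"], out.values["H1"],
                                   atol=1e-6)

    def test_missing_stays_missing(self):
        qm = self._random_matrix(np.random.default_rng(4))
        out = quant.normalize_glog(qm)
        pd.testing.assert_frame_equal(qm.values.isna(), out.values.isna())

    def test_too_few_values_rejected(self):
        vals = pd.DataFrame({"H1": [1.0, 2.0, np.nan, np.nan],
                             "U1": [1.0, 2.0, 3.0, 4.0]},
                            index=list("ABCD"))
        qm = QuantMatrix(values=vals,
                         cohorts=pd.Series(["healthy", "UC"],
                                           index=["H1", "U1"]))
        with pytest.raises(ValueError, match="fewer than 3"):
            quant.normalize_glog(qm)


def test_filter_literal_rules_agree_with_shortcut_on_random_patterns():
    """The three literal rules equal keep iff max(n1, n2) >= 4 on random
    8-vs-10 missingness patterns (dense check, complements the built-in
    cross-check assertion)."""
    rng = np.random.default_rng(11)
    n = 2000
    obs = rng.random((n, 18)) < rng.random((n, 1))
    vals = pd.DataFrame(np.where(obs, 1.0, np.nan),
                        columns=[f"H{i}" for i in range(8)]
                        + [f"U{i}" for i in range(10)],
                        index=[f"G{i}" for i in range(n)])
    cohorts = pd.Series(["healthy"] * 8 + ["UC"] * 10, index=vals.columns)
    qm = QuantMatrix(values=vals, cohorts=cohorts)
    kept = set(quant.filter_missing(qm).values.index)
    n1 = obs[:, :8].sum(axis=1)
    n2 = obs[:, 8:].sum(axis=1)
    expect = set(vals.index[np.maximum(n1, n2) >= 4])
    assert kept == expect
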