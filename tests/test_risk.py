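"""Risk-quotient formulas, site-level aggregation, and exceedance counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apiarisk.risk import (
    DEFAULT_CONSTANTS,
    ConsumptionConstants,
    DataIntegrityError,
    ThresholdRegistry,
    ToxicityError,
    compute_rq_acute,
    compute_rq_chronic,
    compute_site_rqs,
    exceedance_report,
    select_chronic_endpoint,
    total_rq,
)
from apiarisk.synthetic import (
    PlantedDetection,
    SyntheticConfig,
    CompoundSpec,
    default_toxicity_reference,
    generate_residues,
)


def residue_row(site="s1", prox="near", year="2021", tp="T2", matrix="nectar",
                compound="thiamethoxam", conc=1.0, censoring="detected"):
    return {
        "site_id": site, "proximity": prox, "year": year, "time_point": tp,
        "matrix": matrix, "compound": compound,
        "concentration_ug_per_kg": conc, "censoring": censoring,
    }


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "nectar,pollen,ld50,expected",
        [
            (0.0, 0.0, 0.5, 0.0),
            (1000.0, 0.0, 0.14, 1.0),
            (50.0, 100.0, 0.5, 0.01592),
        ],
    )
    def test_acute_hand_arithmetic(self, nectar, pollen, ld50, expected):
        assert compute_rq_acute(nectar, pollen, ld50) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "nectar,pollen,endpoint,expected",
        [
            (0.0, 0.0, 0.01, 0.0),
            (10.0, 10.0, 0.01496, 0.1),
        ],
    )
    def test_chronic_hand_arithmetic(self, nectar, pollen, endpoint, expected):
        assert compute_rq_chronic(nectar, pollen, endpoint) == pytest.approx(expected, rel=1e-9)

    def test_invalid_endpoint_and_residue_rejected(self):
        with pytest.raises(ToxicityError):
            compute_rq_acute(1.0, 1.0, 0.0)
        with pytest.raises(ToxicityError):
            compute_rq_chronic(1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            compute_rq_acute(-1.0, 0.0, 0.5)

    @given(
        nectar=st.floats(0, 1e4),
        pollen=st.floats(0, 1e4),
        endpoint=st.floats(1e-4, 1e3),
        scale=st.floats(0.01, 100),
    )
    def test_homogeneous_of_degree_one_in_residues(self, nectar, pollen, endpoint, scale):
        base = compute_rq_acute(nectar, pollen, endpoint)
        scaled = compute_rq_acute(nectar * scale, pollen * scale, endpoint)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)

    @given(
        nectar=st.floats(0.1, 1e4),
        pollen=st.floats(0.1, 1e4),
        lo=st.floats(1e-4, 1e3),
        hi=st.floats(1e-4, 1e3),
    )
    def test_antitone_in_endpoint(self, nectar, pollen, lo, hi):
        lo, hi = sorted((lo, hi))
        assert compute_rq_acute(nectar, pollen, hi) <= compute_rq_acute(nectar, pollen, lo)

    def test_zero_iff_both_residues_zero(self):
        assert compute_rq_acute(0, 0, 1.0) == 0
        assert compute_rq_acute(0, 0.001, 1.0) > 0


class TestChronicEndpointSelection:
    def test_min_policy_prefers_smaller_endpoint(self):
        assert select_chronic_endpoint(0.005, 0.004) == (0.004, "ldd50")
        assert select_chronic_endpoint(0.003, 0.004) == (0.003, "lc50")

    def test_explicit_policies_and_missing(self):
        assert select_chronic_endpoint(0.005, None) == (0.005, "lc50")
        assert select_chronic_endpoint(None, None) is None
        assert select_chronic_endpoint(0.005, 0.004, policy="lc50") == (0.005, "lc50")
        assert select_chronic_endpoint(None, 0.004, policy="lc50") is None


def brute_force_rqs(residues, tox, constants=DEFAULT_CONSTANTS):
    """Independent spreadsheet-style recomputation used as oracle."""
    out = {}
    tox_idx = tox.set_index("compound")
    groups = {}
    detections = {}
    for _, row in residues.iterrows():
        key = (row.site_id, row.year, row.time_point, row.compound)
        groups.setdefault(key, {})[row.matrix] = row.concentration_ug_per_kg
        detections.setdefault(key, False)
        if row.censoring in ("detected", "below_loq"):
            detections[key] = True
    for key, mats in groups.items():
        if not detections[key]:
            continue
        compound = key[3]
        intake = (
            mats.get("nectar", 0.0) * constants.nectar_intake_kg
            + mats.get("pollen", 0.0) * constants.pollen_intake_kg
        )
        t = tox_idx.loc[compound]
        ld50 = t["acute_oral_ld50_ug_per_bee"]
        if not np.isnan(ld50):
            out[key + ("acute",)] = intake / ld50
        chronic = [
            v
            for v in (t["chronic_lc50_ug_per_bee_day"], t["chronic_ldd50_ug_per_bee_day"])
            if not np.isnan(v)
        ]
        if chronic:
            out[key + ("chronic",)] = intake / min(chronic)
    return out


class TestSiteRQs:
    def test_nectar_only_detection_treats_pollen_as_zero(self):
        residues = pd.DataFrame([residue_row(conc=10.0)])
        tox = default_toxicity_reference()
        comp = compute_site_rqs(residues, tox)
        acute = comp.of_kind("acute")
        assert len(acute) == 1
        expected = 10.0 * 140e-6 / 0.005
        assert acute["rq"].iloc[0] == pytest.approx(expected)

    def test_all_nondetect_table_is_empty_result(self):
        residues = pd.DataFrame(
            [residue_row(conc=0.0, censoring="below_lod"),
             residue_row(matrix="pollen", conc=0.0, censoring="below_lod")]
        )
        comp = compute_site_rqs(residues, default_toxicity_reference())
        assert comp.results.empty

    def test_agrees_with_brute_force_oracle(self, tiny_config):
        residues = generate_residues(tiny_config)
        assert len(residues) <= 100
        tox = default_toxicity_reference()
        comp = compute_site_rqs(residues, tox)
        oracle = brute_force_rqs(residues, tox)
        got = {
            (r.site_id, r.year, r.time_point, r.compound, r.kind): r.rq
            for r in comp.results.itertuples()
        }
        assert set(got) == set(oracle)
        for key, value in oracle.items():
            assert got[key] == pytest.approx(value, rel=1e-12), key

    def test_duplicate_matrix_record_raises(self):
        residues = pd.DataFrame([residue_row(conc=1.0), residue_row(conc=2.0)])
        with pytest.raises(DataIntegrityError):
            compute_site_rqs(residues, default_toxicity_reference())

    def test_missing_endpoint_lands_in_skipped_report(self):
        residues = pd.DataFrame([residue_row(compound="unobtainium", conc=5.0)])
        comp = compute_site_rqs(residues, default_toxicity_reference())
        assert comp.results.empty
        assert comp.skipped["compound"].tolist() == ["unobtainium"]

    def test_half_lod_policy_imputes_censored_matrix(self):
        residues = pd.DataFrame(
            [residue_row(conc=10.0),
             residue_row(matrix="pollen", conc=0.0, censoring="below_lod")]
        )
        tox = default_toxicity_reference()
        zero = compute_site_rqs(residues, tox, censoring_policy="zero")
        half = compute_site_rqs(
            residues, tox, censoring_policy="half_lod", lod_by_compound={"thiamethoxam": 0.1}
        )
        rq_zero = zero.of_kind("acute")["rq"].iloc[0]
        rq_half = half.of_kind("acute")["rq"].iloc[0]
        assert rq_half == pytest.approx(rq_zero + 0.05 * 9.6e-6 / 0.005)
        with pytest.raises(ValueError):
            compute_site_rqs(residues, tox, censoring_policy="half_lod")

    def test_exceedance_flags_match_registry(self):
        residues = pd.DataFrame([residue_row(conc=8000.0)])
        comp = compute_site_rqs(residues, default_toxicity_reference())
        acute = comp.of_kind("acute").iloc[0]
        assert acute["rq"] > 0.4
        assert bool(acute["exceeds_acute_cage"]) and bool(acute["exceeds_acute_field"])
        assert not acute["exceeds_chronic"]
        chronic = comp.of_kind("chronic").iloc[0]
        assert bool(chronic["exceeds_chronic"])
        assert not chronic["exceeds_acute_field"]


class TestTotals:
    def test_singleton_group_total_equals_member(self):
        residues = pd.DataFrame([residue_row(conc=10.0)])
        comp = compute_site_rqs(residues, default_toxicity_reference())
        totals = total_rq(comp.of_kind("acute"), "acute")
        assert len(totals) == 1
        assert totals["total_rq"].iloc[0] == pytest.approx(comp.of_kind("acute")["rq"].iloc[0])

    def test_hand_sum_and_permutation_invariance(self):
        rows = []
        for compound, rq in [("a", 0.01), ("b", 0.02), ("c", 0.03)]:
            rows.append({
                "site_id": "s1", "proximity": "near", "year": "2021", "time_point": "T2",
                "compound": compound, "kind": "acute", "rq": rq, "endpoint_used": "ld50",
                "exceeds_acute_field": False, "exceeds_acute_cage": False, "exceeds_chronic": False,
            })
        df = pd.DataFrame(rows)
        t1 = total_rq(df, "acute")
        t2 = total_rq(df.iloc[::-1].reset_index(drop=True), "acute")
        assert t1["total_rq"].iloc[0] == pytest.approx(0.06, abs=1e-12)
        pd.testing.assert_frame_equal(t1, t2)

    def test_total_at_least_max_member(self, tiny_config):
        residues = generate_residues(tiny_config)
        comp = compute_site_rqs(residues, default_toxicity_reference())
        acute = comp.of_kind("acute")
        totals = total_rq(acute, "acute").set_index(["site_id", "year", "time_point"])
        maxima = acute.groupby(["site_id", "year", "time_point"])["rq"].max()
        for key, max_rq in maxima.items():
            assert totals.loc[key, "total_rq"] >= max_rq - 1e-12

    def test_mixed_kinds_rejected(self):
        df = pd.DataFrame([
            {"site_id": "s", "proximity": "near", "year": "y", "time_point": "t",
             "compound": "a", "kind": k, "rq": 0.1, "endpoint_used": "ld50",
             "exceeds_acute_field": False, "exceeds_acute_cage": False, "exceeds_chronic": False}
            for k in ("acute", "chronic")
        ])
        with pytest.raises(ValueError):
            total_rq(df, "acute")


class TestExceedanceReport:
    def _chronic_row(self, site, compound, rq):
        return {
            "site_id": site, "proximity": "near", "year": "2021", "time_point": "T2",
            "compound": compound, "kind": "chronic", "rq": rq, "endpoint_used": "ldd50",
            "exceeds_acute_field": False, "exceeds_acute_cage": False,
            "exceeds_chronic": rq > 0.03,
        }

    def test_all_zero_rqs_no_exceedances(self):
        df = pd.DataFrame([self._chronic_row("s1", "thiamethoxam", 0.0)])
        rep = exceedance_report(df)
        assert (rep["n_sites_exceeding"] == 0).all()

    def test_boundary_equality_is_not_exceedance(self):
        df = pd.DataFrame([
            self._chronic_row("s1", "thiamethoxam", 0.03),
            self._chronic_row("s2", "thiamethoxam", 0.031),
        ])
        rep = exceedance_report(df)
        chronic = rep[rep["threshold_name"] == "chronic"].iloc[0]
        assert chronic["n_sites_exceeding"] == 1

    def test_site_counted_once_across_time_points(self):
        df = pd.DataFrame([
            self._chronic_row("s1", "thiamethoxam", 0.05),
            {**self._chronic_row("s1", "thiamethoxam", 0.06), "time_point": "T3"},
        ])
        rep = exceedance_report(df)
        assert rep[rep["threshold_name"] == "chronic"]["n_sites_exceeding"].iloc[0] == 1

    def test_planted_pattern_counts_eight_and_three_sites(self):
        """Generator planted so the focal neonicotinoids exceed the chronic
        threshold at exactly 8 and 3 of 20 sites respectively."""
        tox = default_toxicity_reference()
        # concentrations chosen so nectar alone puts chronic RQ well above 0.03
        sites8 = tuple(f"near_{i:02d}" for i in range(1, 6)) + tuple(
            f"far_{i:02d}" for i in range(1, 4)
        )
        sites3 = sites8[:3]
        cfg = SyntheticConfig(
            n_near_sites=10,
            n_far_sites=10,
            years=("2021",),
            compounds=(
                CompoundSpec(name="thiamethoxam", detection_prob=0.0),
                CompoundSpec(name="clothianidin", detection_prob=0.0),
            ),
            planted=(
                PlantedDetection(compound="thiamethoxam", site_ids=sites8,
                                 matrix="nectar", concentration_ug_per_kg=2.0),
                PlantedDetection(compound="clothianidin", site_ids=sites3,
                                 matrix="nectar", concentration_ug_per_kg=2.0),
            ),
            seed=13,
        )
        residues = generate_residues(cfg)
        comp = compute_site_rqs(residues, tox)
        rep = exceedance_report(comp.results).set_index(["compound", "threshold_name"])
        assert rep.loc[("thiamethoxam", "chronic"), "n_sites_exceeding"] == 8
        assert rep.loc[("clothianidin", "chronic"), "n_sites_exceeding"] == 3
        # recomputation is idempotent
        rep2 = exceedance_report(comp.results).set_index(["compound", "threshold_name"])
        pd.testing.assert_frame_equal(rep.reset_index(), rep2.reset_index())


def test_threshold_registry_ordering_enforced():
    with pytest.raises(ValueError):
        ThresholdRegistry(acute_cage=0.1, acute_field=0.2, chronic=0.03)
    with pytest.raises(ValueError):
        ConsumptionConstants(nectar_intake_kg=0.0)
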