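"""Modulation statistics, motif classification, cluster detection and
competition calls, checked against constructed fixtures and generator truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herbscreen import (
    APO,
    BindingPlate,
    ClusterSpec,
    CoregulatorProfileModel,
    InhibitionSpec,
    PlateError,
    PlateSpec,
    classify_motifs,
    confirm_apex,
    detect_clusters,
    generate_plate,
    inhibition_call,
    modulation,
)
from herbscreen.naping import _welch_p_rows, stars_for, unimodality_violations


def plate_from(cells, plant="p"):
    """Build a plate from {(motif, condition): [replicate values]}."""
    rows = []
    for (motif, cond), vals in cells.items():
        well = cond if cond[0] in "ABCDEFGH" and cond[1:].isdigit() else ""
        for r, v in enumerate(vals, start=1):
            rows.append((motif, cond, well, r, float(v)))
    return BindingPlate(
        plant, pd.DataFrame(rows, columns=["motif", "condition", "well", "replicate", "value"])
    )


class TestModulation:
    def test_apo_vs_apo_is_exactly_zero(self):
        plate, _ = generate_plate(PlateSpec(seed=0, n_fractions=4))
        mod = modulation(plate, APO)
        assert (mod["lfc"] == 0.0).all()

    def test_equal_means_give_zero_lfc(self):
        plate = plate_from({("m", APO): [10, 14], ("m", "cortisol"): [12, 12]})
        assert modulation(plate, "cortisol").loc["m", "lfc"] == 0.0

    def test_1024_fold_gives_lfc_10(self):
        # values large enough that the pseudo-count is negligible
        plate = plate_from({("m", APO): [1.0e6], ("m", "cortisol"): [1.024e9]})
        assert modulation(plate, "cortisol").loc["m", "lfc"] == pytest.approx(10.0, abs=1e-4)

    def test_single_replicate_has_no_p_value(self):
        plate = plate_from({("m", APO): [10.0, 11.0, 9.0], ("m", "B2"): [30.0]})
        mod = modulation(plate, "B2")
        assert np.isnan(mod.loc["m", "p_value"]) and mod.loc["m", "stars"] == ""

    def test_absent_condition_is_error(self):
        plate = plate_from({("m", APO): [1.0]})
        with pytest.raises(PlateError):
            modulation(plate, "cortisol")

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (float("nan"), "")],
    )
    def test_star_tiers(self, p, expected):
        assert stars_for(p) == expected

    def test_welch_matches_scipy(self):
        # Independent check of the vectorized Welch test against scipy's.
        rng = np.random.default_rng(42)
        a = rng.normal(10, 2, size=(50, 4))
        b = rng.normal(11, 3, size=(50, 3))
        ours = _welch_p_rows(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(ours, ref, rtol=1e-10)
        ref_less = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative="less").pvalue
        np.testing.assert_allclose(_welch_p_rows(a, b, "less"), ref_less, rtol=1e-10)


class TestClassification:
    def test_planted_classes_recovered(self):
        plate, truth = generate_plate(PlateSpec(seed=8))
        classes = classify_motifs(plate)
        # canonical coactivator induction: GC-responsive and over 1,000-fold
        assert classes.loc["NCOA1", "motif_class"] == "gc_responsive"
        assert classes.loc["NCOA1", "control_fold"] > 1000
        # cluster-only motifs are plant-exclusive; IKBB responds to both
        assert classes.loc["PELP1", "motif_class"] == "plant_exclusive"
        assert classes.loc["DHX30", "motif_class"] == "plant_exclusive"
        assert classes.loc["IKBB", "motif_class"] == "shared"

    def test_cortisol_only_motif_is_gc_responsive(self):
        cells = {
            ("g", APO): [100, 101, 99],
            ("g", "cortisol"): [400, 410, 395],
            ("g", "B2"): [100.0],
        }
        plate = plate_from(cells)
        assert classify_motifs(plate).loc["g", "motif_class"] == "gc_responsive"

    def test_quiet_motif_is_unresponsive(self):
        cells = {
            ("q", APO): [100, 101, 99],
            ("q", "cortisol"): [100, 102, 98],
            ("q", "B2"): [101.0],
        }
        plate = plate_from(cells)
        assert classify_motifs(plate).loc["q", "motif_class"] == "unresponsive"


class TestUnimodality:
    @pytest.mark.parametrize(
        "profile,violations",
        [
            ([1, 2, 3, 2, 1], 0),
            ([1, 2, 3, 4, 5], 0),  # monotone rise: peak at the end
            ([5, 4, 3, 2, 1], 0),  # monotone fall: peak at the start
            ([1, 3, 2, 3, 1], 1),  # one dip
            ([3, 1, 3, 1, 3], 2),
            ([2, 2, 2], 0),  # plateaus are neutral
        ],
    )
    def test_violation_counts(self, profile, violations):
        assert unimodality_violations(np.array(profile, dtype=float)) == violations


class TestClusterDetection:
    def test_flat_plate_yields_no_clusters(self):
        plate, _ = generate_plate(PlateSpec(seed=2, clusters=()))
        assert detect_clusters(plate) == ()

    def test_planted_bump_apex_within_one_fraction(self):
        hits = 0
        for seed in range(20):
            plate, truth = generate_plate(PlateSpec(seed=seed))
            clusters = detect_clusters(plate)
            tc = truth.clusters[0]
            ok = any(
                abs(c.apex_index - tc["apex"]) <= 1
                and abs(c.start_index - tc["start"]) <= 1
                and abs(c.end_index - tc["end"]) <= 1
                for c in clusters
            )
            hits += ok
        assert hits >= 19

    def test_two_disjoint_bumps_give_two_clusters(self):
        # One plant showing two separate activity clusters (two metabolite
        # gradients in one fraction series).
        spec = PlateSpec(
            seed=3,
            clusters=(
                ClusterSpec(("PELP1", "DHX30"), center=25.0, width=2.0, peak_lfc=2.0),
                ClusterSpec(("NCOR2",), center=60.0, width=2.0, peak_lfc=2.0),
            ),
        )
        plate, _ = generate_plate(spec)
        clusters = detect_clusters(plate)
        assert len(clusters) == 2
        spans = sorted((c.start_index, c.end_index) for c in clusters)
        assert spans[0][1] < spans[1][0]

    def test_cluster_geometry_invariants(self):
        plate, _ = generate_plate(PlateSpec(seed=4))
        for c in detect_clusters(plate):
            assert c.start_index <= c.apex_index <= c.end_index
            assert c.length >= 3
            assert set(c.profile.index) <= set(range(c.start_index, c.end_index + 1))


class TestConfirmation:
    def test_strong_apex_confirmed_weak_not(self):
        plate, truth = generate_plate(PlateSpec(seed=5))
        (cluster,) = detect_clusters(plate)
        strong, _ = generate_plate(PlateSpec(seed=6, replicates_fraction=3))
        assert confirm_apex(strong, cluster).confirmed
        null_conf, _ = generate_plate(
            PlateSpec(seed=7, clusters=(), replicates_fraction=3)
        )
        assert not confirm_apex(null_conf, cluster).confirmed

    def test_missing_apex_fraction_is_error(self):
        plate, _ = generate_plate(PlateSpec(seed=5))
        (cluster,) = detect_clusters(plate)
        tiny, _ = generate_plate(PlateSpec(seed=5, n_fractions=4, clusters=(),
                                           replicates_fraction=3))
        with pytest.raises(PlateError, match="absent"):
            confirm_apex(tiny, cluster)

    def test_significance_rises_then_falls_across_gradient(self):
        # A replicated retest across a fraction series spanning the bump:
        # the apex is the most significant, the series edges are not.
        plate, truth = generate_plate(PlateSpec(seed=9, replicates_fraction=3))
        apex = truth.clusters[0]["apex"]  # index 30 == well C6
        from herbscreen import index_to_well

        series = [index_to_well(i) for i in (24, 27, 30, 33, 36)]
        pvals = [modulation(plate, w).loc["PELP1", "p_value"] for w in series]
        assert all(p < 0.05 for p in pvals[1:4])  # inside the gradient
        assert pvals[0] > 0.05 and pvals[-1] > 0.05  # series edges quiet


class TestInhibition:
    MOTIFS8 = (
        "PELP1", "DHX30", "NCOR2", "IKBB",
        "MOTIF_030", "MOTIF_031", "MOTIF_032", "MOTIF_033",
    )

    @pytest.mark.parametrize(
        "scenario,expected", [("full", "+"), ("none", "-"), ("partial", "±")]
    )
    def test_truth_table(self, scenario, expected):
        spec = PlateSpec(
            seed=11,
            replicates_fraction=3,
            clusters=(ClusterSpec(self.MOTIFS8, 30.0, 2.0, 2.0),),
            inhibition=InhibitionSpec("C6", "PELP1", scenario),
        )
        plate, truth = generate_plate(spec)
        call = inhibition_call(plate, plate, "C6", "PELP1")
        assert call.call == expected == truth.intended_call

    def test_exact_sixty_percent_reduced_is_intermediate(self):
        # Constructed fixture: 5 responsive motifs, 3 strongly reduced,
        # 2 untouched -> reduced proportion 0.6 -> "±".
        cells = {}
        responsive = [f"m{i}" for i in range(5)]
        for i, m in enumerate(responsive):
            cells[(m, APO)] = [100, 101, 99]
            cells[(m, "C4")] = [1000, 1010, 990]
            reduced = i < 3
            cells[(m, "C4+PELP1")] = [100, 99, 101] if reduced else [1000, 995, 1005]
        plate = plate_from(cells)
        call = inhibition_call(plate, plate, "C4", "PELP1", responsive_motifs=responsive)
        assert call.reduced_proportion == 0.6
        assert call.call == "±"

    def test_no_responsive_motifs_is_error(self):
        cells = {("m", APO): [100, 101, 99], ("m", "C4"): [100, 102, 98],
                 ("m", "C4+PELP1"): [100, 101, 99]}
        plate = plate_from(cells)
        with pytest.raises(PlateError, match="nothing to inhibit"):
            inhibition_call(plate, plate, "C4", "PELP1")

    def test_missing_spiked_condition_is_error(self):
        cells = {("m", APO): [100, 101, 99], ("m", "C4"): [1000, 1010, 990]}
        plate = plate_from(cells)
        with pytest.raises(PlateError, match="spiked"):
            inhibition_call(plate, plate, "C4", "PELP1")


class TestModelResults:
    def test_fit_and_summary(self):
        plate, _ = generate_plate(PlateSpec(seed=13))
        res = CoregulatorProfileModel(plate).fit()
        assert res.class_counts()["gc_responsive"] >= 1
        assert len(res.clusters) == 1
        assert res.total_cluster_fractions() == res.clusters[0].length
        text = res.summary()
        assert "active clusters" in text and plate.plant_id in text

    def test_save_and_run_summary(self, tmp_path):
        plate, _ = generate_plate(PlateSpec(seed=13, n_fractions=12))
        res = CoregulatorProfileModel(plate).fit()
        written = res.save(tmp_path)
        assert all(p.exists() for p in written.values())
        rs = res.run_summary()
        assert rs["n_motifs"] == 101 and rs["n_clusters"] == len(res.clusters)

    def test_invalid_tiers_rejected(self):
        plate, _ = generate_plate(PlateSpec(seed=13, n_fractions=4))
        with pytest.raises(ValueError):
            CoregulatorProfileModel(plate, alpha_tiers=(0.01, 0.05, 0.001))
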