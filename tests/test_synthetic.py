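import numpy as np
import pandas as pd
import pytest

from netfp.io import load_cohort
from netfp.synthetic import (
    CohortDesign,
    GroupSpec,
    InputFunctionParams,
    example_design,
    roi_edge_signature,
    simulate_cohort,
    simulate_edge_cohort,
    simulate_input_function,
    simulate_scan,
)


class TestInputFunction:
    def test_single_peak_then_decay(self):
        grid = np.linspace(0, 90, 4000)
        c = simulate_input_function(InputFunctionParams(), grid).concentrations
        peak = int(np.argmax(c))
        assert 0 < peak < 200  # early peak
        assert np.all(np.diff(c[peak:]) <= 1e-9)  # monotone decay after the peak
        assert c[0] == 0.0

    def test_zero_amplitudes(self):
        grid = np.linspace(0, 60, 100)
        p = InputFunctionParams(a1=0.0, a2=0.0, a3=0.0)
        np.testing.assert_array_equal(simulate_input_function(p, grid).concentrations, 0.0)

    def test_amplitude_linearity(self):
        grid = np.linspace(0, 60, 500)
        p = InputFunctionParams()
        p2 = InputFunctionParams(a1=2 * p.a1, a2=2 * p.a2, a3=2 * p.a3)
        c1 = simulate_input_function(p, grid).concentrations
        c2 = simulate_input_function(p2, grid).concentrations
        np.testing.assert_allclose(c2, 2.0 * c1, atol=1e-12)


class TestSimulateScan:
    def test_zero_noise_feature_recovery(self, clean_cohort, registry):
        from netfp.kinetics import extract_features

        scans, truth = clean_cohort
        scan = scans[0]
        feats = extract_features(scan, registry=registry)
        for f in feats[:10]:
            assert f.k1 == pytest.approx(truth.scans[scan.scan_id].k1[f.roi_id], rel=2e-3)

    def test_same_seed_identical(self, registry):
        design = CohortDesign(groups=(GroupSpec("HC", 2),), noise_kappa=0.5)
        s1, t1 = simulate_cohort(design, seed=77)
        s2, t2 = simulate_cohort(design, seed=77)
        for a, b in zip(s1, s2):
            assert a.scan_id == b.scan_id
            assert a.age == b.age and a.dose_mbq == b.dose_mbq
            for roi in a.tacs:
                np.testing.assert_array_equal(a.tacs[roi].values, b.tacs[roi].values)

    def test_kappa_scaling_of_noise(self, registry):
        """Doubling kappa doubles the empirical frame-residual SD (within 10%).

        The same subject is rescanned so residuals isolate frame noise.
        """
        from netfp.synthetic import _draw_subject

        group = GroupSpec("HC", 1)
        clean_design = CohortDesign(groups=(group,), noise_kappa=0.0)
        subj = _draw_subject(clean_design, group, "p0", registry,
                             np.random.default_rng(5))
        clean_scan, _ = simulate_scan(clean_design, subj, seed=0, registry=registry)
        rois = registry.names[:20]
        clean = np.concatenate([clean_scan.tacs[r].values for r in rois])

        sds = []
        for kappa in (0.3, 0.6):
            design = CohortDesign(groups=(group,), noise_kappa=kappa)
            resid = []
            for rep in range(10):
                scan, _ = simulate_scan(design, subj, seed=1000 + rep, registry=registry)
                noisy = np.concatenate([scan.tacs[r].values for r in rois])
                resid.append(noisy - clean)
            sds.append(np.concatenate(resid).std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.1)

    def test_batch_effect_multiplicative(self, registry):
        g1 = GroupSpec("HC", 1, batch="B1")
        g2 = GroupSpec("HC", 1, batch="B2")
        d = CohortDesign(groups=(g1, g2), batch_scales={"B1": 1.0, "B2": 1.2},
                         noise_kappa=0.0)
        # same subject params: simulate one subject under both batches
        from netfp.synthetic import _draw_subject

        rng = np.random.default_rng(3)
        subj = _draw_subject(d, g1, "p0", registry, rng)
        scan1, _ = simulate_scan(d, subj, seed=1, registry=registry)
        subj2 = type(subj)(
            subject_id="p0", group=g2, k1=subj.k1, vb=subj.vb, age=subj.age,
            sex=subj.sex, genotype=subj.genotype, dose_mbq=subj.dose_mbq,
            weight_kg=subj.weight_kg,
        )
        scan2, _ = simulate_scan(d, subj2, seed=1, registry=registry)
        roi = registry.names[0]
        np.testing.assert_allclose(
            scan2.tacs[roi].values, 1.2 * scan1.tacs[roi].values, rtol=1e-10
        )


class TestSimulateCohort:
    def test_two_groups_manifest_round_trip(self, tmp_path):
        design = CohortDesign(
            groups=(GroupSpec("HC", 10), GroupSpec("DIS", 10)), noise_kappa=0.2
        )
        scans, _ = simulate_cohort(design, seed=9, out_dir=tmp_path)
        assert len(scans) == 20
        loaded = load_cohort(tmp_path / "manifest.json")
        assert len(loaded) == 20
        assert {s.scan_id for s in loaded} == {s.scan_id for s in scans}

    def test_blockade_raises_median_similarity_for_all(self):
        from netfp.network import edge_vector
        from netfp.pipeline import matrices_for_scans

        design = CohortDesign(
            groups=(GroupSpec("SCZ", 5, blockade=True),),
            noise_kappa=0.0, blockade_factor=0.5,
        )
        scans, _ = simulate_cohort(design, seed=21)
        mats, _, _ = matrices_for_scans(scans)
        med = {m.scan_id: float(np.median(edge_vector(m))) for m in mats}
        for sid in med:
            if sid.endswith("_block"):
                assert med[sid] > med[sid.replace("_block", "_baseline")]

    def test_zero_retest_noise_perfect_identification(self):
        from netfp.network import cohort_edge_table
        from netfp.pipeline import matrices_for_scans
        from netfp.reliability import identify_subjects

        design = CohortDesign(
            groups=(GroupSpec("HC", 6, retest=True),),
            noise_kappa=0.0, subject_k1_sd=0.05,
        )
        scans, _ = simulate_cohort(design, seed=33)
        mats, _, _ = matrices_for_scans(scans)
        edges = cohort_edge_table(mats)
        subjects = sorted({s.subject_id for s in scans})
        test_df = edges.loc[[f"{s}_baseline" for s in subjects]]
        retest_df = edges.loc[[f"{s}_retest" for s in subjects]]
        test_df.index = retest_df.index = subjects
        acc, _ = identify_subjects(test_df, retest_df)
        assert acc == 1.0

    def test_disease_effect_on_designated_regions(self, clean_cohort, registry):
        from netfp.kinetics import feature_frame

        scans, truth = clean_cohort
        feats = feature_frame(scans, registry=registry)
        hc_k1 = feats.xs("lh_putamen", level="roi")["k1"]
        hc = [s.scan_id for s in scans if s.diagnosis == "HC"]
        dis = [s.scan_id for s in scans if s.diagnosis == "DIS"]
        assert hc_k1.loc[dis].mean() > 1.1 * hc_k1.loc[hc].mean()

    def test_invalid_design(self):
        with pytest.raises(ValueError, match="n must be >= 1"):
            GroupSpec("HC", 0)
        with pytest.raises(ValueError, match="noise_kappa"):
            CohortDesign(groups=(GroupSpec("HC", 1),), noise_kappa=-0.1)


class TestEdgeCohort:
    def test_shapes_and_labels(self):
        df, labels = simulate_edge_cohort(
            {"A": 4, "B": 6}, n_rois=10, signatures=None, effect_size=0.0, seed=1
        )
        assert df.shape == (10, 45)
        assert list(labels.value_counts().sort_index()) == [4, 6]
        assert df.index.equals(labels.index)

    def test_determinism(self):
        a, _ = simulate_edge_cohort({"A": 5}, 8, None, 0.0, seed=4)
        b, _ = simulate_edge_cohort({"A": 5}, 8, None, 0.0, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_signature_offset_applied(self):
        sig = np.array([0, 1, 2])
        df, labels = simulate_edge_cohort(
            {"HC": 200, "DIS": 200}, n_rois=5, signatures={"DIS": sig},
            effect_size=3.0, noise_sd=1.0, seed=2,
        )
        diff = df[labels == "DIS"].mean() - df[labels == "HC"].mean()
        np.testing.assert_allclose(diff.iloc[:3], 3.0, atol=0.3)
        assert np.all(np.abs(diff.iloc[3:]) < 0.5)

    def test_roi_edge_signature_touches_affected(self):
        rng = np.random.default_rng(3)
        n_rois = 12
        sig = roi_edge_signature(n_rois, [0, 1], edges_per_roi=4, rng=rng)
        iu, ju = np.triu_indices(n_rois, 1)
        assert len(sig) == 8
        for e in sig:
            assert iu[e] in (0, 1) or ju[e] in (0, 1)


def test_example_design_loads_and_simulates(tmp_path):
    design = example_design(scale=0.3)
    scans, truth = simulate_cohort(design, seed=2, out_dir=tmp_path)
    loaded = load_cohort(tmp_path / "manifest.json")
    assert len(loaded) == len(scans)
    diagnoses = {s.diagnosis for s in scans}
    assert {"HC", "SCZ", "TBI", "MS", "DEP", "cLBP", "AD"} <= diagnoses
    tracers = {s.tracer for s in scans}
    assert len(tracers) == 3
    # genotype NA only for the genotype-independent tracer
    for s in scans:
        if s.tracer == "TRACER-C":
            assert s.genotype == "NA"
        else:
            assert s.genotype in ("HAB", "MAB")


class TestDesignSerialization:
    def test_round_trip(self, tmp_path):
        from netfp.synthetic import load_design, save_design

        design = example_design(scale=1.0)
        path = tmp_path / "design.yaml"
        save_design(design, path)
        assert load_design(path) == design

    def test_shipped_example_loads(self):
        from pathlib import Path

        from netfp.synthetic import load_design

        path = Path(__file__).resolve().parents[1] / "examples" / "design.yaml"
        design = load_design(path)
        assert len(design.groups) >= 5

    def test_bad_design_rejected(self, tmp_path):
        from netfp.synthetic import load_design

        p = tmp_path / "bad.yaml"
        p.write_text("just a string")
        with pytest.raises(ValueError, match="groups"):
            load_design(p)
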