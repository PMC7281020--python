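import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossomics import (
    ConfigurationError,
    PeakTable,
    aberrant_entities,
    annotate_peaks,
    average_patient_profiles,
    compute_zscores,
)
from crossomics.errors import InputError
from crossomics.metabolomics import ZScoreProfile, load_peak_table, load_profile, save_profile


def make_peak_table(mz, per_sample_values, controls, n_replicates=1, jitter=None):
    """per_sample_values: dict sample -> array of per-peak intensities."""
    cols, data = [], []
    for s, vals in per_sample_values.items():
        for rep in range(1, n_replicates + 1):
            cols.append((s, rep))
            v = np.asarray(vals, dtype=float)
            if jitter is not None:
                v = v + jitter[(s, rep)]
            data.append(v)
    frame = pd.DataFrame(
        np.column_stack(data), columns=pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
    )
    roles = {s: ("control" if s in controls else s) for s in per_sample_values}
    return PeakTable(np.asarray(mz, dtype=float), frame, roles)


class TestAnnotation:
    def test_exact_mass_is_annotated(self):
        pt = make_peak_table([100.0], {"c1": [1.0], "c2": [1.0]}, {"c1", "c2"})
        out = annotate_peaks(pt, {"met": 100.0})
        assert len(out) == 1 and out[0][1].annotations == {"met"}

    def test_peak_outside_scan_range_dropped(self):
        pt = make_peak_table([650.0, 65.0], {"c1": [1, 1], "c2": [1, 1]}, {"c1", "c2"})
        assert annotate_peaks(pt, {"met": 650.0, "met2": 65.0}) == []

    def test_two_ppm_window_boundary_at_300_da(self):
        # 2 ppm of ~300 Da is 0.0006 Da: 1.5 ppm matches, 3 ppm does not
        pt = make_peak_table(
            [300.00045, 300.0009], {"c1": [1, 1], "c2": [1, 1]}, {"c1", "c2"}
        )
        out = annotate_peaks(pt, {"met": 300.0})
        assert [i for i, _ in out] == [0]

    def test_isomers_collapse_into_single_entity_without_losing_annotations(self):
        pt = make_peak_table([200.0], {"c1": [1.0], "c2": [1.0]}, {"c1", "c2"})
        out = annotate_peaks(pt, {"isoA": 200.0, "isoB": 200.0, "other": 250.0})
        assert len(out) == 1
        assert out[0][1].annotations == {"isoA", "isoB"}

    def test_annotation_independent_of_peak_order(self):
        masses = {f"m{i}": 100.0 + i for i in range(5)}
        mz = [104.0, 101.0, 103.0]
        pt1 = make_peak_table(mz, {"c1": [1] * 3, "c2": [1] * 3}, {"c1", "c2"})
        pt2 = make_peak_table(mz[::-1], {"c1": [1] * 3, "c2": [1] * 3}, {"c1", "c2"})
        ann1 = {e.mz: e.annotations for _, e in annotate_peaks(pt1, masses)}
        ann2 = {e.mz: e.annotations for _, e in annotate_peaks(pt2, masses)}
        assert ann1 == ann2

    def test_empty_mass_table_warns_not_raises(self):
        pt = make_peak_table([100.0], {"c1": [1.0], "c2": [1.0]}, {"c1", "c2"})
        with pytest.warns(UserWarning, match="empty mass table"):
            assert annotate_peaks(pt, {}) == []


class TestZScores:
    def _profiles(self, control_vals, patient_val, n_replicates=1):
        per_sample = {f"c{i}": [v] for i, v in enumerate(control_vals)}
        per_sample["p"] = [patient_val]
        pt = make_peak_table([100.0], per_sample, set(per_sample) - {"p"}, n_replicates)
        annotated = annotate_peaks(pt, {"met": 100.0})
        return compute_zscores(pt, annotated)

    def test_patient_at_control_mean_scores_zero(self):
        profiles = self._profiles([1.0, 2.0, 3.0], 2.0)
        assert profiles["p"].z["E00000"] == pytest.approx(0.0)

    def test_closed_form_with_sample_sd(self):
        # controls {1,2,3}: mean 2, sd 1 (n-1 convention); patient 4 -> Z = 2
        profiles = self._profiles([1.0, 2.0, 3.0], 4.0)
        assert profiles["p"].z["E00000"] == pytest.approx(2.0)

    def test_replicates_averaged_per_sample_before_statistics(self):
        pt = make_peak_table(
            [100.0],
            {"c1": [1.0], "c2": [2.0], "c3": [3.0], "p": [4.0]},
            {"c1", "c2", "c3"},
            n_replicates=3,
            jitter={("c1", 1): 0.3, ("c1", 2): -0.3, ("c1", 3): 0.0,
                    ("c2", 1): 0.6, ("c2", 2): -0.6, ("c2", 3): 0.0,
                    ("c3", 1): 0.0, ("c3", 2): 0.0, ("c3", 3): 0.0,
                    ("p", 1): 1.5, ("p", 2): -1.5, ("p", 3): 0.0},
        )
        annotated = annotate_peaks(pt, {"met": 100.0})
        profiles = compute_zscores(pt, annotated)
        # replicate jitter cancels in per-sample means: same closed form
        assert profiles["p"].z["E00000"] == pytest.approx(2.0)

    def test_fewer_than_two_controls_is_configuration_error(self):
        pt = make_peak_table([100.0], {"c1": [1.0], "p": [2.0]}, {"c1"})
        with pytest.raises(ConfigurationError, match="control"):
            compute_zscores(pt, annotate_peaks(pt, {"met": 100.0}))

    def test_zero_control_variance_flagged_not_dropped(self):
        profiles = self._profiles([2.0, 2.0, 2.0], 5.0)
        prof = profiles["p"]
        assert "E00000" in prof.flagged
        assert np.isnan(prof.z["E00000"])
        assert prof.measured_entities() == frozenset()

    def test_control_z_distribution_is_standardized(self):
        rng = np.random.default_rng(0)
        n_controls, n_peaks = 30, 200
        per_sample = {f"c{i}": rng.normal(50, 5, size=n_peaks) for i in range(n_controls)}
        pt = make_peak_table(np.linspace(100, 400, n_peaks), per_sample, set(per_sample))
        masses = {f"m{i}": mz for i, mz in enumerate(pt.mz)}
        profiles = compute_zscores(pt, annotate_peaks(pt, masses))
        z = np.array([[p.z[e] for e in sorted(p.z)] for p in profiles.values()])
        assert abs(z.mean()) < 0.02
        assert abs(z.std(ddof=1) - 1.0) < 0.05

    @given(scale=st.floats(0.1, 100.0), shift=st.floats(-10.0, 10.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_affine_intensity_rescaling_leaves_z_invariant(self, scale, shift):
        vals = {"c1": [10.0], "c2": [14.0], "c3": [18.0], "p": [20.0]}
        shifted = {s: [scale * v[0] + shift] for s, v in vals.items()}
        # keep intensities non-negative as the container requires
        offset = min(min(v) for v in shifted.values())
        if offset < 0:
            shifted = {s: [v[0] - offset] for s, v in shifted.items()}
        z1 = self._profiles_from(vals)["p"].z["E00000"]
        z2 = self._profiles_from(shifted)["p"].z["E00000"]
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)

    def _profiles_from(self, per_sample):
        pt = make_peak_table([100.0], per_sample, set(per_sample) - {"p"})
        return compute_zscores(pt, annotate_peaks(pt, {"met": 100.0}))


class TestAveraging:
    def _profile(self, owner, zmap):
        ann = {e: frozenset({e}) for e in zmap}
        return ZScoreProfile(owner, dict(zmap), ann)

    def test_single_profile_unchanged(self):
        p = self._profile("s1", {"e1": 2.0})
        assert average_patient_profiles([p]).z == p.z

    def test_mean_of_two(self):
        avg = average_patient_profiles(
            [self._profile("s1", {"e1": 2.0}), self._profile("s2", {"e1": 0.0})]
        )
        assert avg.z["e1"] == pytest.approx(1.0)

    def test_mean_of_three(self):
        avg = average_patient_profiles(
            [self._profile(f"s{i}", {"e1": v}) for i, v in enumerate([3.0, 3.0, -3.0])]
        )
        assert avg.z["e1"] == pytest.approx(1.0)

    def test_mismatched_universes_rejected_with_difference(self):
        with pytest.raises(InputError, match="e2"):
            average_patient_profiles(
                [self._profile("s1", {"e1": 1.0}), self._profile("s2", {"e2": 1.0})]
            )


class TestAberrant:
    def _profile(self, zmap):
        return ZScoreProfile("p", dict(zmap), {e: frozenset({e}) for e in zmap})

    def test_thresholds_are_strict_inequalities(self):
        prof = self._profile({"hi": 3.0, "lo": -3.0, "past": -3.1})
        assert aberrant_entities(prof, (-3.0, 3.0)) == {"past"}

    def test_enumerated_grid(self):
        prof = self._profile({f"e{k}": k - 5.0 for k in range(10)})
        assert aberrant_entities(prof, (-3.0, 3.0)) == {"e0", "e1", "e9"}

    def test_invalid_threshold_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            aberrant_entities(self._profile({"e": 0.0}), (1.0, 3.0))


def test_profile_tsv_roundtrip(tmp_path):
    prof = ZScoreProfile(
        "p1",
        {"e1": 1.5, "e2": float("nan")},
        {"e1": frozenset({"m1", "m2"}), "e2": frozenset({"m3"})},
        frozenset({"e2"}),
    )
    path = tmp_path / "prof.tsv"
    save_profile(prof, path)
    back = load_profile(path, owner="p1")
    assert back.annotations["e1"] == {"m1", "m2"}
    assert back.flagged == {"e2"}
    assert back.z["e1"] == pytest.approx(1.5)


def test_peak_table_tsv_roundtrip(tmp_path):
    peaks = tmp_path / "peaks.tsv"
    peaks.write_text("mz\tc1#1\tc1#2\tp1#1\tp1#2\n100.0\t1.0\t1.2\t2.0\t2.2\n")
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text("sample\trole\tpatient_id\nc1\tcontrol\t\np1\tpatient\tP1\n")
    pt = load_peak_table(peaks, manifest)
    assert pt.control_samples == ["c1"]
    assert pt.patient_of == {"p1": "P1"}
    assert pt.intensities[("p1", 2)].iloc[0] == pytest.approx(2.2)
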