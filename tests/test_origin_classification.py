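"""Ratio classes, gEMSA signal definitions, k-means clustering against an
exhaustive-partition oracle, and the two classification routes."""

import itertools

import numpy as np
import pytest

from oriclass.origin_classification import (
    GemsaProfile,
    InVivoAffinity,
    best_sse,
    classify_by_emsa,
    classify_joint,
    cluster_gemsa,
    in_vivo_ratio,
    ratio_class,
    total_gemsa_signal,
)
from oriclass.peak_analysis import Peak
from oriclass.reference import load_emsa_panel, panel_with_folds
from oriclass.tracks_io import OriginAnnotation, ProbeTrack


def make_track(values, condition="x", spacing=50):
    values = np.asarray(values, dtype=float)
    t = ProbeTrack(condition)
    t.add_chromosome("chrI", np.arange(values.size) * spacing + spacing // 2, values)
    return t


class TestRatioClass:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (-0.1, "sensitive"),
            (0.3, "sensitive"),  # inclusive bound
            (0.31, "moderate"),
            (0.79, "moderate"),
            (0.8, "resistant"),  # inclusive bound
            (1.3, "resistant"),
        ],
    )
    def test_bounds_are_inclusive_as_defined(self, ratio, expected):
        assert ratio_class(ratio) == expected


class TestInVivoRatio:
    ORIGINS = [OriginAnnotation("ARS1", "chrI", 400, 700, "confirmed")]
    PEAKS = {"ARS1": Peak("chrI", 400, 700, 6.0, 1e-9, 6)}

    def test_identical_tracks_give_ratio_one(self):
        track = make_track([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0])
        (aff,) = in_vivo_ratio(track, track, self.PEAKS, self.ORIGINS)
        assert aff.ratio == pytest.approx(1.0)
        assert aff.ratio_class == "resistant"

    def test_zero_mutant_track_is_sensitive(self):
        wt = make_track([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0])
        mut = make_track(np.zeros(13))
        (aff,) = in_vivo_ratio(wt, mut, self.PEAKS, self.ORIGINS)
        assert aff.ratio == 0.0 and aff.ratio_class == "sensitive"

    def test_nonpositive_wildtype_area_flagged_unclassifiable(self):
        wt = make_track(np.zeros(13))
        (aff,) = in_vivo_ratio(wt, wt, self.PEAKS, self.ORIGINS)
        assert aff.unclassifiable


class TestGemsaSignal:
    ORIGINS = [OriginAnnotation("ARS1", "chrI", 400, 700, "confirmed")]
    PEAKS = {"ARS1": Peak("chrI", 400, 700, 5.0, 1e-9, 6)}

    def _tracks(self, values):
        return {c: make_track(values, f"gEMSA_{c}nM") for c in (0.3, 3.0, 30.0)}

    def test_total_is_sum_over_concentrations(self):
        vals = np.zeros(13)
        vals[8:11] = 5.0 / 3.0  # area 5 over the peak span
        (profile,) = total_gemsa_signal(
            self._tracks(vals), self.ORIGINS, "chip_coordinates", self.PEAKS
        )
        assert profile.total == pytest.approx(15.0)

    def test_called_peaks_mode_assigns_zero_without_a_peak(self):
        (profile,) = total_gemsa_signal(
            self._tracks(np.zeros(13)),
            self.ORIGINS,
            "called_peaks",
            gemsa_peaks={0.3: {}, 3.0: {}, 30.0: {}},
        )
        assert profile.signals == (0.0, 0.0, 0.0) and profile.total == 0.0

    def test_chip_coordinates_mode_admits_negative_totals(self):
        vals = np.zeros(13)
        vals[8:11] = -0.5
        (profile,) = total_gemsa_signal(
            self._tracks(vals), self.ORIGINS, "chip_coordinates", self.PEAKS
        )
        assert profile.total < 0

    def test_missing_concentration_track_errors(self):
        with pytest.raises(ValueError, match="missing"):
            total_gemsa_signal(
                {0.3: make_track(np.zeros(5))}, self.ORIGINS,
                "chip_coordinates", self.PEAKS,
            )


def partition_oracle_sse(X, k):
    """Exhaustive minimum SSE over all partitions into <= k nonempty sets."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        sse = 0.0
        for j in set(labels):
            pts = X[[i for i in range(n) if labels[i] == j]]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestClusterGemsa:
    def _profiles(self, X):
        return [
            GemsaProfile(f"O{i:03d}", tuple(row), "chip_coordinates")
            for i, row in enumerate(X)
        ]

    def test_separated_blobs_recovered_and_labelled_by_level(self, rng):
        X = np.concatenate(
            [
                rng.normal(0.0, 0.05, size=(15, 3)),
                rng.normal(5.0, 0.05, size=(15, 3)),
                rng.normal(10.0, 0.05, size=(15, 3)),
            ]
        )
        out = cluster_gemsa(self._profiles(X), restarts=200, seed=1)
        labels = {p.origin: p.cluster for p in out}
        assert all(labels[f"O{i:03d}"] == "Weak" for i in range(15))
        assert all(labels[f"O{i:03d}"] == "Moderate" for i in range(15, 30))
        assert all(labels[f"O{i:03d}"] == "Strong" for i in range(30, 45))

    def test_best_sse_matches_exhaustive_partition_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        sse = best_sse(self._profiles(X), k=3, restarts=500, seed=3)
        assert sse == pytest.approx(partition_oracle_sse(X, 3), rel=1e-9)

    def test_permuting_input_order_leaves_assignment_unchanged(self, rng):
        X = rng.normal(size=(20, 3)) * [1, 2, 5]
        profiles = self._profiles(X)
        out_a = cluster_gemsa(profiles, restarts=100, seed=7)
        out_b = cluster_gemsa(list(reversed(profiles)), restarts=100, seed=7)
        assert {p.origin: p.cluster for p in out_a} == {
            p.origin: p.cluster for p in out_b
        }

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_gemsa(self._profiles(np.zeros((2, 3))), k=3)

    def test_best_sse_non_increasing_in_restart_budget(self, rng):
        X = rng.normal(size=(30, 3))
        profiles = self._profiles(X)
        sses = [best_sse(profiles, restarts=r, seed=5) for r in (1, 10, 100)]
        assert sses[0] >= sses[1] >= sses[2]

    def test_agrees_with_sklearn_on_well_separated_data(self, rng):
        """Independent cross-check: scikit-learn's k-means reaches the same
        partition on data with unambiguous structure."""
        from sklearn.cluster import KMeans

        X = np.concatenate(
            [rng.normal(m, 0.1, size=(12, 3)) for m in (0.0, 4.0, 9.0)]
        )
        ours = cluster_gemsa(self._profiles(X), restarts=200, seed=2)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        # compare partitions, not label names
        ours_labels = np.array(
            [{"Weak": 0, "Moderate": 1, "Strong": 2}[p.cluster] for p in ours]
        )
        for a in range(3):
            for b in range(3):
                same_ours = ours_labels[a * 12] == ours_labels[b * 12]
                same_sk = sk.labels_[a * 12] == sk.labels_[b * 12]
                assert same_ours == same_sk


class TestJointClassification:
    def _affinity(self, origin, ratio):
        return InVivoAffinity(origin, 1.0, ratio, ratio, ratio_class(ratio))

    def _profile(self, origin, cluster):
        return GemsaProfile(origin, (0, 0, 0), "chip_coordinates", cluster)

    @pytest.mark.parametrize(
        "ratio,cluster,call",
        [
            (0.9, "Weak", "chromatin_dependent"),
            (0.9, "Strong", "dna_dependent"),
            (0.9, "Moderate", "dna_dependent"),
            (0.1, "Weak", "weak"),
            (0.5, "Weak", "unclassified"),
            (0.1, "Strong", "unclassified"),
        ],
    )
    def test_cluster_route_rules(self, ratio, cluster, call):
        (res,) = classify_joint(
            [self._affinity("o", ratio)], [self._profile("o", cluster)]
        )
        assert res.call == call and res.route == "gemsa_clusters"

    def test_exclusion_list_drops_origins(self):
        res = classify_joint(
            [self._affinity("telo", 0.9)], [self._profile("telo", "Weak")],
            exclusions=["telo"],
        )
        assert res == []

    def test_every_origin_gets_exactly_one_call(self, rng):
        affs = [self._affinity(f"o{i}", float(rng.uniform(-0.2, 1.3))) for i in range(50)]
        profs = [
            self._profile(f"o{i}", rng.choice(["Weak", "Moderate", "Strong"]))
            for i in range(50)
        ]
        calls = classify_joint(affs, profs)
        assert sorted(c.origin for c in calls) == sorted(a.origin for a in affs)


class TestEmsaRoute:
    def test_reference_panel_exemplars(self):
        """The canonical panel origins classify as published: the reference
        origin ARS317 is DNA-dependent, the ND origin ARS1528 is
        chromatin-dependent and ARS1332 (fold ~4.9) is complex."""
        panel = panel_with_folds(load_emsa_panel())
        affs = [
            InVivoAffinity(o, 1.0, r, r, ratio_class(r))
            for o, r in zip(panel["origin"], panel["orc21_orc2_ratio"])
        ]
        folds = dict(zip(panel["origin"], panel["fold_vs_reference"]))
        calls = {c.origin: c.call for c in classify_by_emsa(affs, folds)}
        assert calls["ARS317"] == "dna_dependent"
        assert calls["ARS1528"] == "chromatin_dependent"
        assert calls["ARS1332"] == "complex"
        assert calls["ARS1413"] == "weak"  # sensitive, fold 58x
        assert calls["ARS416"] == "unclassified"  # moderate band never forced
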