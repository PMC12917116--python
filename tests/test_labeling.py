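"""Disc labeling: reference anchoring, template matching vs exhaustive
enumeration, label fusion, identification rate."""

import itertools

import numpy as np
import pytest

from spineplan.errors import (NoCandidatesError, NoReferenceFoundError,
                              InvalidSpecError)
from spineplan.geometry import rotation_xyz
from spineplan.heatmaps import Candidate
from spineplan.labeling import (DiscTemplate, fuse_labels,
                                find_reference_disc, identification_rate,
                                label_discs, match_template)
from spineplan.volume import LabelVolume


def _cand(pos, heat=200.0, channel="c"):
    return Candidate(np.asarray(pos, dtype=float), heat, channel)


def _straight_template(n=5, spacing=35.0):
    pts = [(0.0, 0.0, -spacing * i) for i in range(n)]
    labels = tuple(f"D{i}" for i in range(n))
    return DiscTemplate.from_positions(labels, pts), pts, labels


def brute_force_match(candidates, template):
    """Enumeration oracle: best order-preserving injective assignment of
    the Z-sorted candidate pool to labels (max assigned, then min
    matching error)."""
    pool = sorted((c for lst in candidates.values() for c in lst),
                  key=lambda c: (-c.position[2], -c.heat))
    d = len(template.labels)
    k = min(d, len(pool))
    if k == 0:
        raise NoCandidatesError("empty")
    dist = np.linalg.norm(
        np.stack([c.position for c in pool])[:, None, :]
        - np.stack([c.position for c in pool])[None, :, :], axis=-1)
    best_cost, best_assign = np.inf, None
    for label_set in itertools.combinations(range(d), k):
        for cand_set in itertools.combinations(range(len(pool)), k):
            cost = 0.0
            for (li, pi), (lj, pj) in itertools.combinations(
                    zip(label_set, cand_set), 2):
                cost += abs(dist[pi, pj] - template.distances[li, lj])
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_assign = dict(zip(label_set, cand_set))
    return best_cost, best_assign, pool


class TestDiscTemplate:
    def test_symmetry_and_triangle_validated(self):
        with pytest.raises(InvalidSpecError):
            DiscTemplate(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_default_template_adjacent_spacing(self):
        t = DiscTemplate.default(5, adjacent_spacing=35.0)
        for i in range(4):
            assert t.distances[i, i + 1] == pytest.approx(35.0, abs=0.5)

    def test_from_positions_round_trip(self):
        t, pts, labels = _straight_template()
        assert t.distances[0, 4] == pytest.approx(140.0)
        t2 = DiscTemplate.from_dict(t.to_dict())
        np.testing.assert_allclose(t2.distances, t.distances)


class TestFindReference:
    def test_most_caudal_selected(self):
        cands = {"c": [_cand((0, 0, 200)), _cand((0, 0, 160)),
                       _cand((0, 0, 120))]}
        ref = find_reference_disc(cands)
        assert ref.position[2] == 120

    def test_single_candidate_is_reference(self):
        c = _cand((1, 2, 3))
        assert find_reference_disc({"c": [c]}) is c

    def test_z_tie_broken_by_heat(self):
        a = _cand((0, 0, 50.0), heat=200)
        b = _cand((5, 0, 50.0), heat=150)
        assert find_reference_disc({"c": [b, a]}) is a

    def test_threshold_filters_all_raises(self):
        with pytest.raises(NoReferenceFoundError):
            find_reference_disc({"c": [_cand((0, 0, 0), heat=10)]},
                                threshold=100)


class TestMatchTemplate:
    def test_perfect_geometry_zero_error(self):
        t, pts, labels = _straight_template()
        cands = {lab: [_cand(p, channel=lab)]
                 for lab, p in zip(labels, pts)}
        out = match_template(cands, t)
        assert out.matching_error == pytest.approx(0.0, abs=1e-9)
        for lab, p in zip(labels, pts):
            np.testing.assert_allclose(out.mapping[lab].position, p)

    def test_spurious_candidate_rejected(self):
        t, pts, labels = _straight_template()
        cands = {lab: [_cand(p, channel=lab)]
                 for lab, p in zip(labels, pts)}
        cands[labels[2]].append(_cand((20.0, 0.0, -70.0), heat=150))
        out = match_template(cands, t)
        np.testing.assert_allclose(out.mapping[labels[2]].position, pts[2])
        cost, _, _ = brute_force_match(cands, t)
        assert out.matching_error == pytest.approx(cost, abs=1e-9)

    def test_swapped_channels_follow_spatial_order(self):
        t, pts, labels = _straight_template()
        cands = {lab: [] for lab in labels}
        # the network put D1's peak in D2's channel and vice versa
        cands[labels[1]] = [_cand(pts[2], channel=labels[1])]
        cands[labels[2]] = [_cand(pts[1], channel=labels[2])]
        for i in (0, 3, 4):
            cands[labels[i]] = [_cand(pts[i], channel=labels[i])]
        out = match_template(cands, t)
        for lab, p in zip(labels, pts):
            np.testing.assert_allclose(out.mapping[lab].position, p)
        assert out.matching_error == pytest.approx(0.0, abs=1e-9)

    def test_missing_channel_marked_missing(self):
        t, pts, labels = _straight_template()
        cands = {lab: [_cand(p, channel=lab)]
                 for lab, p in zip(labels[:-1], pts[:-1])}
        out = match_template(cands, t)
        assert out.mapping[labels[-1]] is None
        assert out.n_assigned() == 4

    def test_all_empty_raises(self):
        t, _, labels = _straight_template()
        with pytest.raises(NoCandidatesError):
            match_template({lab: [] for lab in labels}, t)

    @pytest.mark.parametrize("trial", range(60))
    def test_equals_enumeration_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        d = int(rng.integers(2, 7))
        labels = tuple(f"D{i}" for i in range(d))
        pts = np.stack([[rng.normal(0, 5), rng.normal(0, 5), -35.0 * i]
                        for i in range(d)])
        template = DiscTemplate.from_positions(labels, pts)
        cands = {}
        for i, lab in enumerate(labels):
            k = int(rng.integers(0, 4))
            cands[lab] = [
                _cand(pts[i] + rng.normal(0, 8, 3),
                      heat=float(rng.uniform(129, 256)), channel=lab)
                for _ in range(k)]
        if not any(cands.values()):
            cands[labels[0]] = [_cand(pts[0], channel=labels[0])]
        got = match_template(cands, template)
        cost, assign, pool = brute_force_match(cands, template)
        assert got.matching_error == pytest.approx(cost, abs=1e-9)

    def test_rigid_transform_leaves_error_invariant(self):
        t, pts, labels = _straight_template()
        rng = np.random.default_rng(9)
        cands = {lab: [_cand(p + rng.normal(0, 3, 3), channel=lab)]
                 for lab, p in zip(labels, pts)}
        base = match_template(cands, t).matching_error
        rot = rotation_xyz(12.0, -7.0, 30.0)
        shift = np.array([10.0, -4.0, 6.0])
        moved = {lab: [_cand(rot @ c[0].position + shift, channel=lab)]
                 for lab, c in cands.items()}
        assert match_template(moved, t).matching_error == \
               pytest.approx(base, abs=1e-9)

    def test_anchor_constrains_most_caudal_label(self):
        t, pts, labels = _straight_template()
        cands = {lab: [_cand(p, channel=lab)]
                 for lab, p in zip(labels, pts)}
        spurious = _cand((0.0, 0.0, -150.0), heat=255)
        cands[labels[-1]].append(spurious)
        ref = find_reference_disc(cands)
        assert ref is spurious  # most caudal wins the anchor rule
        out = match_template(cands, t, anchor=ref)
        assert out.mapping[labels[-1]] is spurious


class TestFuseLabels:
    def _generic_segmentation(self, label_volume):
        """Collapse per-level labels to generic disc/vertebra classes."""
        vox = np.zeros_like(label_volume.voxels)
        lm = {"disc": 1, "vertebra": 2}
        for name, code in label_volume.label_map.items():
            if name.startswith("disc_"):
                vox[label_volume.voxels == code] = 1
            elif name.startswith("vertebra_"):
                vox[label_volume.voxels == code] = 2
        return LabelVolume(vox, label_volume.spacing.copy(),
                           label_volume.origin.copy(), lm)

    def test_five_components_all_labeled(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        seg = self._generic_segmentation(label_vol)
        cands = {lv: [_cand(truth.disc_centers[lv], channel=lv)]
                 for lv in truth.disc_labels}
        template = DiscTemplate.from_positions(
            truth.disc_labels,
            [truth.disc_centers[lv] for lv in truth.disc_labels])
        assignment = match_template(cands, template)
        fused = fuse_labels(seg, assignment)
        for lv in truth.disc_labels:
            assert f"disc_{lv}" in fused.label_map
            c = fused.centroid_world(f"disc_{lv}")
            assert np.linalg.norm(c - truth.disc_centers[lv]) < 3.0

    def test_vertebra_named_from_flanking_discs(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        seg = self._generic_segmentation(label_vol)
        cands = {lv: [_cand(truth.disc_centers[lv], channel=lv)]
                 for lv in truth.disc_labels}
        template = DiscTemplate.from_positions(
            truth.disc_labels,
            [truth.disc_centers[lv] for lv in truth.disc_labels])
        fused = fuse_labels(seg, match_template(cands, template))
        # vertebra between L4/5 and L5/S1 must be L5
        assert "vertebra_L5" in fused.label_map
        c5 = fused.centroid_world("vertebra_L5")
        z45 = truth.disc_centers["L4/5"][2]
        z51 = truth.disc_centers["L5/S1"][2]
        assert z51 < c5[2] < z45

    def test_component_outside_gate_stays_unlabeled(self):
        vox = np.zeros((40, 10, 60), dtype=np.int16)
        vox[4:8, 4:7, 10:14] = 1      # genuine disc component
        vox[30:34, 4:7, 50:54] = 1    # spurious blob far away
        seg = LabelVolume(vox, (1.5, 1.5, 1.5), (0.0, 0.0, 0.0), {"disc": 1})
        c = _cand(seg.index_to_world([5.5, 5.0, 11.5]), channel="L4/5")
        template = DiscTemplate(("L4/5",), np.zeros((1, 1)))
        assignment = match_template({"L4/5": [c]}, template)
        fused = fuse_labels(seg, assignment, gate_mm=15.0)
        assert "disc_L4/5" in fused.label_map
        # the far blob keeps the generic disc code
        assert np.any(fused.voxels == 1)


class TestIdentificationRate:
    TRUTH = {f"D{i}": np.array([0.0, 0.0, -38.0 * i]) for i in range(5)}

    def test_exact_predictions_full_rate(self):
        assert identification_rate(dict(self.TRUTH), self.TRUTH) == 1.0

    def test_one_disc_displaced_beyond_tolerance(self):
        pred = {k: v.copy() for k, v in self.TRUTH.items()}
        pred["D2"] = pred["D2"] + np.array([7.0, 0.0, 0.0])
        assert identification_rate(pred, self.TRUTH) == 0.8

    def test_per_axis_rule_is_strict(self):
        pred = {k: v.copy() for k, v in self.TRUTH.items()}
        pred["D2"] = pred["D2"] + np.array([6.0, 0.0, 0.0])
        assert identification_rate(pred, self.TRUTH) == 0.8
        pred["D2"] = self.TRUTH["D2"] + np.array([5.9, 0.0, 0.0])
        assert identification_rate(pred, self.TRUTH) == 1.0

    def test_closest_centroid_must_carry_same_label(self):
        pred = {k: v.copy() for k, v in self.TRUTH.items()}
        # D1's prediction lands 2 mm from D2's centroid: nearest truth
        # centroid has the wrong label, so D1 is not identified even
        # though some truth point is within tolerance
        pred["D1"] = self.TRUTH["D2"] + np.array([0.0, 0.0, 2.0])
        assert identification_rate(pred, self.TRUTH) == 0.8

    def test_missing_prediction_counts_as_not_identified(self):
        pred = {k: v for k, v in self.TRUTH.items() if k != "D0"}
        assert identification_rate(pred, self.TRUTH) == 0.8

    def test_monotone_degradation_with_displacement(self):
        rates = []
        for amp in (0.0, 2.0, 4.0, 5.9, 6.0, 8.0, 10.0):
            pred = {k: v + np.array([amp, 0.0, 0.0])
                    for k, v in self.TRUTH.items()}
            rates.append(identification_rate(pred, self.TRUTH))
        assert rates == sorted(rates, reverse=True)
        assert rates[3] == 1.0 and rates[4] == 0.0


class TestPipelineIntegration:
    def test_clean_phantom_identified_perfectly(self, default_phantom):
        from spineplan import heatmaps
        spec, (label_vol, _, truth) = default_phantom
        hm = heatmaps.heatmap_from_truth(truth, label_vol, sigma=6.0)
        cands = heatmaps.extract_candidates(hm, 128.0)
        template = DiscTemplate.from_spec(spec)
        assignment = label_discs(cands, template)
        rate = identification_rate(assignment.points, truth.disc_centers)
        assert rate == 1.0
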