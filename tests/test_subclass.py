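import numpy as np
import pytest

from actiseg.quantize import PrimitiveSequence
from actiseg.subclass import (
    apply_and_mapback,
    extract_instances,
    find_subclasses,
    fixed_subclasses,
    gdi33_index,
    histogram,
    loio_nb_accuracy,
    pbm_index,
    relabel_windows,
    silhouette_index,
)

FOUR_POINTS = np.array([[0.0], [1.0], [10.0], [11.0]])
FOUR_SPLIT = np.array([0, 0, 1, 1])


class TestHistogram:
    def test_relative_frequencies(self):
        assert histogram([1, 1, 2], 3).tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_constant_list_one_hot(self):
        h = histogram([4] * 7, 5)
        assert h.tolist() == [0, 0, 0, 1, 0]

    def test_matches_counting_oracle_and_sums_to_one(self):
        rng = np.random.default_rng(0)
        prims = rng.integers(1, 9, size=57)
        h = histogram(prims, 8)
        assert h.sum() == pytest.approx(1.0)
        for k in range(1, 9):
            assert h[k - 1] == pytest.approx((prims == k).sum() / 57)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty input"):
            histogram([], 4)


class TestValidityIndices:
    def test_silhouette_hand_value(self):
        # per-point widths: (10.5-1)/10.5, (9.5-1)/9.5 and symmetric
        expected = np.mean([9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5])
        got = silhouette_index(FOUR_POINTS, FOUR_SPLIT)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.8997, abs=5e-5)

    def test_silhouette_perfect_separation(self):
        pts = np.array([[0.0], [0.0], [9.0], [9.0]])
        assert silhouette_index(pts, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_silhouette_near_zero_for_random_split_of_one_blob(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(200, 2))
        s = silhouette_index(pts, rng.integers(0, 2, size=200))
        assert abs(s) < 0.2

    def test_pbm_hand_value(self):
        # E1=20, EK=2, DK=10 -> ((1/2)(20/2)(10))^2 = 2500
        assert pbm_index(FOUR_POINTS, FOUR_SPLIT) == pytest.approx(2500.0)

    def test_pbm_compact_sentinel(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert pbm_index(pts, [0, 0, 1, 1]) == np.inf

    def test_pbm_ranking_is_scale_invariant(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(6, 1, (20, 2))])
        good = np.repeat([0, 1], 20)
        bad = rng.integers(0, 2, size=40)
        for c in (1.0, 0.1, 25.0):
            assert pbm_index(c * pts, good) > pbm_index(c * pts, bad)

    def test_gdi33_hand_value(self):
        # delta3 = mean{10,11,9,10} = 10, Delta3 = 2*0.5 = 1
        assert gdi33_index(FOUR_POINTS, FOUR_SPLIT) == pytest.approx(10.0)

    def test_gdi33_sentinel_and_merge_penalty(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert gdi33_index(pts, [0, 0, 1, 1]) == np.inf
        rng = np.random.default_rng(4)
        blobs = np.vstack(
            [rng.normal(0, 0.5, (15, 2)), rng.normal(8, 0.5, (15, 2)),
             rng.normal((0, 8), 0.5, (15, 2))]
        )
        true = np.repeat([0, 1, 2], 15)
        merged = np.where(true == 2, 1, true)  # fuse two separated blobs
        assert gdi33_index(blobs, true) > gdi33_index(blobs, merged)

    @pytest.mark.parametrize("index", [silhouette_index, pbm_index, gdi33_index])
    def test_indices_invariant_to_point_reordering(self, index):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(5, 1, (12, 3))])
        lab = np.repeat([0, 1], 12)
        perm = rng.permutation(24)
        assert index(pts, lab) == pytest.approx(index(pts[perm], lab[perm]))

    @pytest.mark.parametrize("index", [silhouette_index, pbm_index, gdi33_index])
    def test_single_cluster_rejected(self, index):
        with pytest.raises(ValueError, match="2 clusters"):
            index(FOUR_POINTS, np.zeros(4, dtype=int))


def _instances_from_modes(rng, spec):
    """Build instances whose histograms follow per-(class, mode) supports.

    ``spec`` maps class name -> list of primitive-ID lists (one per mode).
    """
    seqs = []
    for i, (cls, modes) in enumerate(
        (c, m) for c, mode_list in spec.items() for m in mode_list
    ):
        prims = rng.choice(modes, size=60)
        seqs.append(
            PrimitiveSequence(f"r{i}", prims, np.array([cls] * 60, dtype=object))
        )
    return extract_instances(seqs, 12)


class TestSubclassSearch:
    def test_uniform_class_is_not_split(self):
        rng = np.random.default_rng(0)
        spec = {
            "a": [[1, 2, 3]] * 8,
            "b": [[7, 8, 9]] * 8,
        }
        sm = find_subclasses(_instances_from_modes(rng, spec), max_k=4, seed=0)
        assert sm.fragment_counts == {"a": 1, "b": 1}

    @pytest.mark.parametrize("index", ["silhouette", "pbm", "gdi33"])
    def test_two_mode_class_split_matches_generating_mode(self, index):
        rng = np.random.default_rng(1)
        # class "frag" mixes two disjoint supports; one of them shadows "b"
        spec = {
            "frag": [[1, 2, 3]] * 5 + [[7, 8]] * 5,
            "b": [[7, 8, 9]] * 8,
        }
        instances = _instances_from_modes(rng, spec)
        sm = find_subclasses(instances, index=index, max_k=4, seed=1)
        assert sm.fragment_counts["frag"] == 2
        assert sm.fragment_counts["b"] == 1
        # assignment must follow the generating mode up to label permutation
        frag_labels = [
            lab
            for lab, inst in zip(sm.instance_labels, instances)
            if inst.original_class == "frag"
        ]
        modes = [tuple(sorted(set(frag_labels[:5]))), tuple(sorted(set(frag_labels[5:])))]
        assert all(len(m) == 1 for m in modes) and modes[0] != modes[1]

    def test_max_k_one_gives_identity_map(self):
        rng = np.random.default_rng(2)
        spec = {"a": [[1, 2], [5, 6]] * 3}
        sm = find_subclasses(_instances_from_modes(rng, spec), max_k=1, seed=0)
        assert sm.fragment_counts == {"a": 1}
        assert all(lab == "a" for lab in sm.instance_labels)

    def test_accuracy_gate_never_decreases_cv_accuracy(self):
        rng = np.random.default_rng(3)
        spec = {
            "frag": [[1, 2, 3]] * 5 + [[7, 8]] * 5,
            "b": [[7, 8, 9]] * 8,
            "c": [[11, 12]] * 6,
        }
        instances = _instances_from_modes(rng, spec)
        counts = np.stack([inst.counts for inst in instances])
        orig = np.array([inst.original_class for inst in instances], dtype=object)
        identity = {c: c for c in set(orig)}
        baseline = loio_nb_accuracy(counts, orig, orig, identity)
        sm = find_subclasses(instances, max_k=4, seed=3)
        after = loio_nb_accuracy(counts, sm.instance_labels, orig, sm.mapping)
        assert after >= baseline

    def test_fixed_subclassing_bypasses_the_gate(self):
        rng = np.random.default_rng(4)
        spec = {"a": [[1, 2]] * 4 + [[5, 6]] * 4, "b": [[9, 10]] * 4}
        instances = _instances_from_modes(rng, spec)
        sm = fixed_subclasses(instances, {"a": 2}, seed=0)
        assert sm.fragment_counts == {"a": 2, "b": 1}
        assert set(sm.mapping.values()) == {"a", "b"}


class TestMapBack:
    def test_identity_map(self):
        preds = ["a", "b", "a"]
        assert apply_and_mapback({"a": "a", "b": "b"}, preds).tolist() == preds

    def test_subclass_labels_replaced(self):
        mapping = {"A1": "A", "A2": "A", "B1": "B"}
        got = apply_and_mapback(mapping, ["A2", "B1", "A1"])
        assert got.tolist() == ["A", "B", "A"]

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="mystery"):
            apply_and_mapback({"a": "a"}, ["mystery"])

    def test_relabel_then_mapback_round_trip(self):
        rng = np.random.default_rng(5)
        spec = {"a": [[1, 2]] * 4 + [[5, 6]] * 4, "b": [[9, 10]] * 5}
        instances = _instances_from_modes(rng, spec)
        seqs = [
            PrimitiveSequence(
                f"r{i}", rng.integers(1, 13, 60),
                np.array([inst.original_class] * 60, dtype=object),
            )
            for i, inst in enumerate(instances)
        ]
        instances = extract_instances(seqs, 12)
        sm = fixed_subclasses(instances, {"a": 2}, seed=0)
        relabeled = relabel_windows(seqs, instances, sm)
        for seq, newlab in zip(seqs, relabeled):
            back = apply_and_mapback(sm.mapping, newlab)
            assert back.tolist() == seq.labels.tolist()
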