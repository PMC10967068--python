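import numpy as np
import pandas as pd
import pytest

from histotile.errors import BalancingError, DuplicateRecordError, SchemaError
from histotile.store import (
    TileRecord,
    augment_image,
    balanced_batches,
    decode_tile,
    encode_tile,
    epoch_length,
    iter_records,
    join_labels,
    load_index,
    read_tiles,
    standardize,
    write_store,
)


def make_records(rng, n=10, slide="s1", codec="png", offset=0):
    recs = []
    for i in range(n):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        recs.append(TileRecord(slide, (i + offset) * 16, 0, codec, encode_tile(img, codec)))
    return recs


class TestStoreRoundtrip:
    def test_write_read_preserves_order_and_fields(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = make_records(rng, 10)
        index = write_store(recs, tmp_path / "a.tiles", tile_px=16, tile_um=64)
        assert index.n_records == 10
        back = list(iter_records(tmp_path / "a.tiles"))
        assert [r.key for r in back] == [r.key for r in recs]
        assert [r.payload for r in back] == [r.payload for r in recs]

    def test_png_pixel_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        rec = TileRecord("s", 0, 0, "png", encode_tile(img, "png"))
        write_store([rec], tmp_path / "b.tiles")
        decoded, *_ = next(read_tiles(tmp_path / "b.tiles"))
        assert np.array_equal(decoded, img)

    def test_duplicate_key_rejected(self, tmp_path):
        rng = np.random.default_rng(2)
        recs = make_records(rng, 2)
        recs.append(recs[0])
        with pytest.raises(DuplicateRecordError):
            write_store(recs, tmp_path / "c.tiles")

    def test_slide_filter_and_shuffle(self, tmp_path):
        rng = np.random.default_rng(3)
        recs = make_records(rng, 6, "s1") + make_records(rng, 4, "s2")
        index = write_store(recs, tmp_path / "d.tiles")
        assert index.slide_counts == {"s1": 6, "s2": 4}
        only_s2 = list(iter_records(tmp_path / "d.tiles", slides=["s2"]))
        assert len(only_s2) == 4
        o1 = [r.key for r in iter_records(tmp_path / "d.tiles", shuffle_seed=9)]
        o2 = [r.key for r in iter_records(tmp_path / "d.tiles", shuffle_seed=9)]
        o3 = [r.key for r in iter_records(tmp_path / "d.tiles", shuffle_seed=10)]
        assert o1 == o2 != o3
        assert sorted(o1) == sorted(r.key for r in recs)

    def test_index_sidecar_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        index = write_store(make_records(rng, 5), tmp_path / "e.tiles", tile_px=16)
        again = load_index(tmp_path / "e.tiles")
        assert again.offsets == index.offsets
        assert again.slide_counts == index.slide_counts
        assert again.tile_px == 16
        assert all(a < b for a, b in zip(index.offsets, index.offsets[1:]))


class TestAugment:
    def test_no_ops_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        assert np.array_equal(augment_image(img, ops=()), img)

    def test_rot180_twice_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        once = np.rot90(img, 2)
        assert np.array_equal(np.rot90(once, 2), img)

    def test_dihedral_covers_all_eight(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)[..., None].repeat(3, -1)
        seen = set()
        rng = np.random.default_rng(2)
        for _ in range(200):
            seen.add(augment_image(img, ("flip-rotate",), rng).tobytes())
        assert len(seen) == 8

    def test_fixed_seed_deterministic(self):
        rng_img = np.random.default_rng(3)
        img = rng_img.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        a = augment_image(img, ("flip-rotate", "jpeg", "blur"),
                          np.random.default_rng(7), p_jpeg=1.0, p_blur=1.0)
        b = augment_image(img, ("flip-rotate", "jpeg", "blur"),
                          np.random.default_rng(7), p_jpeg=1.0, p_blur=1.0)
        assert np.array_equal(a, b)


class TestStandardize:
    def test_zscore_moments(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        out = standardize(img, "zscore")
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_unit_range(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert standardize(img, "unit").max() == 1.0

    def test_constant_zscore_guard(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert np.all(standardize(img, "zscore") == 0.0)


class TestJoinLabels:
    def _store(self, tmp_path, slides=("s1", "s2", "s3"), n=3):
        rng = np.random.default_rng(6)
        recs = []
        for s in slides:
            recs += make_records(rng, n, s)
        return write_store(recs, tmp_path / "j.tiles")

    def test_full_join(self, tmp_path):
        index = self._store(tmp_path)
        ann = pd.DataFrame({
            "patient": ["p1", "p1", "p2"],
            "slide": ["s1", "s2", "s3"],
            "outcome": ["pos", "neg", "pos"],
        })
        ds = join_labels(index, ann)
        assert ds.n_tiles == 9
        assert ds.missing == []
        assert ds.outcome_type == "categorical"
        assert ds.patients["s2"] == "p1"

    def test_missing_slide_reported(self, tmp_path):
        index = self._store(tmp_path)
        ann = pd.DataFrame({
            "patient": ["p1", "p2"],
            "slide": ["s1", "s3"],
            "outcome": [0, 1],
        })
        ds = join_labels(index, ann)
        assert ds.missing == ["s2"]
        assert ds.n_tiles == 6

    def test_numeric_flagged_categorical(self, tmp_path):
        index = self._store(tmp_path)
        ann = pd.DataFrame({
            "patient": ["p1", "p1", "p2"],
            "slide": ["s1", "s2", "s3"],
            "outcome": [0, 1, 0],
        })
        assert join_labels(index, ann).outcome_type == "continuous"
        assert join_labels(index, ann, categorical=True).outcome_type == "categorical"

    def test_missing_outcome_column(self, tmp_path):
        index = self._store(tmp_path)
        ann = pd.DataFrame({"patient": ["p"], "slide": ["s1"]})
        with pytest.raises(SchemaError):
            join_labels(index, ann)

    def test_csv_path_input(self, tmp_path):
        index = self._store(tmp_path)
        csv = tmp_path / "ann.csv"
        csv.write_text("patient,slide,outcome\np1,s1,a\np1,s2,b\np2,s3,a\n")
        assert join_labels(index, csv).n_tiles == 9


def imbalanced_dataset(tmp_path, n_a=100, n_b=10):
    """Two classes, 10:1 tile imbalance across four slides."""
    rng = np.random.default_rng(7)
    recs = (
        make_records(rng, n_a // 2, "a1") + make_records(rng, n_a // 2, "a2")
        + make_records(rng, n_b // 2, "b1") + make_records(rng, n_b // 2, "b2")
    )
    index = write_store(recs, tmp_path / "bal.tiles")
    ann = pd.DataFrame({
        "patient": ["pa", "pa", "pb", "pb"],
        "slide": ["a1", "a2", "b1", "b2"],
        "outcome": ["A", "A", "B", "B"],
    })
    return join_labels(index, ann)


class TestBalancedBatches:
    def test_category_balance_exact_split(self, tmp_path):
        ds = imbalanced_dataset(tmp_path)
        labels = ds.tile_labels()
        for batch in balanced_batches(ds, 10, "category", rng=1):
            counts = pd.Series(labels[batch]).value_counts()
            assert counts["A"] == 5 and counts["B"] == 5

    def test_none_mode_matches_empirical_frequency(self, tmp_path):
        """Unbalanced sampling reproduces the 10:1 tile frequency."""
        ds = imbalanced_dataset(tmp_path)
        labels = ds.tile_labels()
        n_b = 0
        total = 0
        for batch in balanced_batches(ds, 10, "none", rng=2, n_batches=500):
            n_b += (labels[batch] == "B").sum()
            total += len(batch)
        p = n_b / total
        # expected 10/110 = 0.0909, binomial sd ~ 0.004
        assert abs(p - 10 / 110) < 0.02

    def test_slide_balance_covers_every_slide(self, tmp_path):
        ds = imbalanced_dataset(tmp_path)
        slides = ds.tiles["slide_id"].to_numpy()
        seen = set()
        for batch in balanced_batches(ds, 8, "slide", rng=3):
            counts = pd.Series(slides[batch]).value_counts()
            assert counts.max() - counts.min() <= 1
            seen.update(counts.index)
        assert seen == {"a1", "a2", "b1", "b2"}

    def test_both_mode_balances_class_then_slide(self, tmp_path):
        ds = imbalanced_dataset(tmp_path)
        labels = ds.tile_labels()
        slides = ds.tiles["slide_id"].to_numpy()
        for batch in balanced_batches(ds, 12, "both", rng=4, n_batches=20):
            lab = pd.Series(labels[batch]).value_counts()
            assert abs(lab["A"] - lab["B"]) <= 1
            for cls in "AB":
                sl = pd.Series(slides[batch][labels[batch] == cls]).value_counts()
                assert sl.max() - sl.min() <= 1

    def test_epoch_length(self, tmp_path):
        assert epoch_length(110, 10) == 11
        ds = imbalanced_dataset(tmp_path)
        assert len(list(balanced_batches(ds, 10, "none", rng=0))) == 11

    def test_seeded_reproducibility(self, tmp_path):
        ds = imbalanced_dataset(tmp_path)
        a = [b.tolist() for b in balanced_batches(ds, 10, "category", rng=5)]
        b = [b.tolist() for b in balanced_batches(ds, 10, "category", rng=5)]
        assert a == b

    def test_empty_class_raises(self, tmp_path):
        ds = imbalanced_dataset(tmp_path)
        ds.tiles = ds.tiles[ds.tiles["slide_id"].isin(["a1", "a2"])].reset_index(drop=True)
        labels = ds.tile_labels()
        assert set(labels) == {"A"}  # class B now empty among tiles
        # single remaining class balances trivially
        batch = next(balanced_batches(ds, 10, "category", rng=6))
        assert len(batch) == 10

    def test_category_frequency_over_many_batches(self, tmp_path):
        """Per-class frequency within 2% of uniform over 1,000 batches."""
        ds = imbalanced_dataset(tmp_path)
        labels = ds.tile_labels()
        counts = {"A": 0, "B": 0}
        for batch in balanced_batches(ds, 10, "category", rng=8, n_batches=1000):
            for c in counts:
                counts[c] += (labels[batch] == c).sum()
        total = sum(counts.values())
        assert abs(counts["A"] / total - 0.5) < 0.02
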