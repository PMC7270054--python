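"""Decile partitioning, volume masks and term decoding."""

import numpy as np
import pytest

from connectopy.connectopic_mapping import ConnectopicMap, normalize_map
from connectopy.functional_decoding import (
    TermMapLibrary,
    decile_partition,
    decode_decile,
    decoding_table,
    mask_to_volume,
    rank_deciles,
)


def cmap_of(values):
    return ConnectopicMap(values=normalize_map(values), eigenvalues=[1.0])


class TestDecilePartition:
    def test_hundred_distinct_values_make_equal_bins(self):
        masks = rank_deciles(np.random.default_rng(0).permutation(np.arange(100.0)))
        assert [m.sum() for m in masks] == [10] * 10

    def test_ten_values_make_singletons_in_value_order(self):
        values = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0, 4.0, 6.0, 0.0])
        masks = rank_deciles(values)
        order = [int(np.flatnonzero(m)[0]) for m in masks]
        assert [values[i] for i in order] == sorted(values)

    def test_remainder_spread_to_lowest_bins(self):
        masks = rank_deciles(np.random.default_rng(1).permutation(np.arange(105.0)))
        assert [m.sum() for m in masks] == [11] * 5 + [10] * 5

    def test_masks_partition_all_vertices(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=73)
        masks = rank_deciles(values)
        total = np.sum(masks, axis=0)
        assert np.all(total == 1)
        sizes = [m.sum() for m in masks]
        assert max(sizes) - min(sizes) <= 1

    def test_ties_broken_by_vertex_index(self):
        values = np.zeros(20)
        values[10:] = 1.0
        masks = rank_deciles(values)
        # first five bins take the tied zeros in index order
        assert np.flatnonzero(masks[0]).tolist() == [0, 1]
        assert np.flatnonzero(masks[1]).tolist() == [2, 3]

    def test_small_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_deciles(np.arange(9.0))
        with pytest.raises(ValueError):
            rank_deciles(np.ones(20))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=50)
        a = rank_deciles(values)
        b = rank_deciles(np.exp(values))
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_partition_from_map(self):
        masks = decile_partition(cmap_of(np.arange(40.0)), 0)
        assert np.flatnonzero(masks[0]).tolist() == [0, 1, 2, 3]


class TestMaskToVolume:
    def test_empty_mask_all_zero(self):
        v2v = np.zeros((5, 3), dtype=int)
        vol = mask_to_volume(np.zeros(5, bool), v2v, (2, 2, 2))
        assert not vol.any()

    def test_two_vertices_same_voxel(self):
        v2v = np.array([[1, 1, 0], [1, 1, 0]])
        vol = mask_to_volume(np.ones(2, bool), v2v, (2, 2, 1))
        assert vol.sum() == 1
        assert vol[1, 1, 0]

    def test_decile_union_covers_exactly_seed_voxels(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=60)
        v2v = np.column_stack(
            [np.arange(60) % 6, (np.arange(60) // 6) % 5, np.arange(60) // 30]
        )
        masks = rank_deciles(values)
        union = np.zeros((6, 5, 2), bool)
        for m in masks:
            union |= mask_to_volume(m, v2v, (6, 5, 2))
        expected = np.zeros((6, 5, 2), bool)
        expected[v2v[:, 0], v2v[:, 1], v2v[:, 2]] = True
        np.testing.assert_array_equal(union, expected)

    def test_out_of_grid_rejected(self):
        v2v = np.array([[5, 0, 0]])
        with pytest.raises(ValueError, match="outside"):
            mask_to_volume(np.ones(1, bool), v2v, (4, 4, 4))


def library_on(grid, entries, synonyms=None):
    terms = [t for t, _, _ in entries]
    return TermMapLibrary(
        terms=terms,
        maps={t: m for t, m, _ in entries},
        is_anatomical={t: anat for t, _, anat in entries},
        synonym_groups=synonyms or {},
    )


class TestDecodeDecile:
    def grid(self):
        return (6, 6, 2)

    def decile_vol(self):
        vol = np.zeros(self.grid(), bool)
        vol[:2, :2, 0] = True
        return vol

    def test_exact_match_ranks_first_with_r_one(self):
        vol = self.decile_vol()
        rng = np.random.default_rng(0)
        lib = library_on(
            self.grid(),
            [
                ("exact", vol.astype(float), False),
                ("noise", rng.normal(size=self.grid()), False),
            ],
        )
        ranked = decode_decile(vol, lib)
        assert ranked[0][0] == "exact"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_anatomical_terms_never_reported(self):
        vol = self.decile_vol()
        lib = library_on(
            self.grid(),
            [
                ("anat term", vol.astype(float), True),
                ("weak", vol.astype(float) * 0.5 + 0.1, False),
            ],
        )
        ranked = decode_decile(vol, lib)
        assert all(t != "anat term" for t, _ in ranked)

    def test_non_positive_correlations_dropped(self):
        vol = self.decile_vol()
        lib = library_on(self.grid(), [("anti", 1.0 - vol.astype(float), False)])
        assert decode_decile(vol, lib) == []

    def test_synonym_group_keeps_best_member(self):
        vol = self.decile_vol()
        rng = np.random.default_rng(1)
        good = vol.astype(float) + rng.normal(0, 0.05, self.grid())
        worse = vol.astype(float) + rng.normal(0, 0.5, self.grid())
        lib = library_on(
            self.grid(),
            [("objects", good, False), ("object", worse, False)],
            synonyms={"objects": "object", "object": "object"},
        )
        ranked = decode_decile(vol, lib)
        assert len(ranked) == 1
        assert ranked[0][0] == "objects"

    def test_at_most_three_terms(self):
        vol = self.decile_vol()
        entries = [
            (f"t{i}", vol.astype(float) * (1 - 0.1 * i) + 0.01 * i, False)
            for i in range(6)
        ]
        assert len(decode_decile(vol, library_on(self.grid(), entries))) == 3

    def test_constant_term_skipped_with_warning(self):
        vol = self.decile_vol()
        lib = library_on(
            self.grid(),
            [("flat", np.ones(self.grid()), False), ("ok", vol.astype(float), False)],
        )
        with pytest.warns(RuntimeWarning, match="constant"):
            ranked = decode_decile(vol, lib)
        assert [t for t, _ in ranked] == ["ok"]


class TestDecodingTable:
    def planted_setup(self, noise_sigma, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        values = rng.permutation(n).astype(float)
        v2v = np.column_stack(
            [np.arange(n) % 8, (np.arange(n) // 8) % 5, np.arange(n) // 40]
        )
        grid = (8, 5, 3)
        masks = rank_deciles(values)
        entries = []
        for d, mask in enumerate(masks, start=1):
            m = mask_to_volume(mask, v2v, grid).astype(float)
            m += rng.normal(0, noise_sigma, grid)
            entries.append((f"planted_d{d}", m, False))
        for t in range(8):
            entries.append((f"noise_{t}", rng.normal(size=grid), False))
        entries.append(("anatomy", np.ones(grid) * 0.5, True))
        lib = library_on(grid, entries)
        return cmap_of(values), lib, v2v

    def test_planted_terms_dominate_their_deciles(self):
        cmap, lib, v2v = self.planted_setup(noise_sigma=0.2)
        table = decoding_table(cmap, 0, lib, v2v)
        hits = sum(
            bool(table.top3[d]) and table.top3[d][0][0] == f"planted_d{d}"
            for d in range(1, 11)
        )
        assert hits >= 9

    def test_all_noise_library_keeps_correlations_small(self):
        rng = np.random.default_rng(4)
        n = 100
        values = rng.permutation(n).astype(float)
        v2v = np.column_stack(
            [np.arange(n) % 10, (np.arange(n) // 10) % 10, np.zeros(n, int)]
        )
        grid = (10, 10, 10)  # 10^3 voxels
        entries = [(f"noise_{t}", rng.normal(size=grid), False) for t in range(15)]
        table = decoding_table(cmap_of(values), 0, library_on(grid, entries), v2v)
        assert np.nanmax(np.abs(table.table.values)) < 0.2
        assert all(len(table.top3[d]) <= 3 for d in range(1, 11))

    def test_rerun_is_identical(self):
        cmap, lib, v2v = self.planted_setup(noise_sigma=0.3, seed=5)
        a = decoding_table(cmap, 0, lib, v2v)
        b = decoding_table(cmap, 0, lib, v2v)
        assert a.table.equals(b.table)
        assert a.top3 == b.top3

    def test_table_rows_are_union_of_top3(self):
        cmap, lib, v2v = self.planted_setup(noise_sigma=0.2, seed=6)
        table = decoding_table(cmap, 0, lib, v2v)
        union = sorted({t for ranked in table.top3.values() for t, _ in ranked})
        assert list(table.table.index) == union
        positive = table.table.values[np.isfinite(table.table.values)]
        assert np.all(positive > 0)
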