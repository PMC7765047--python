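"""Combinatorial barcoding and slice debarcoding rules."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import spherovar as sv
from spherovar.barcoding import (
    UNASSIGNED,
    assign_slice,
    binarize_channels,
    call_pt_label,
    combine_cisplatin,
    enumerate_codes,
)


class TestEnumerateCodes:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(9, 4, 126), (8, 4, 70), (5, 0, 1), (6, 6, 1), (10, 3, comb(10, 3))],
    )
    def test_counts(self, n, k, expected):
        assert len(enumerate_codes(n, k)) == expected

    def test_lexicographic_and_weight(self):
        cs = enumerate_codes(6, 2)
        words = cs.codewords
        assert all(sum(w) == 2 for w in words)
        assert list(words) == sorted(words)
        assert len(set(words)) == len(words)

    @pytest.mark.parametrize("n,k", [(6, 3), (8, 4), (10, 5)])
    def test_min_hamming_distance_two(self, n, k):
        words = enumerate_codes(n, k).codewords
        for a, b in itertools.combinations(words, 2):
            assert sum(x != y for x, y in zip(a, b)) >= 2

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            enumerate_codes(4, 5)


class TestBinarize:
    def test_mean_threshold(self):
        # channel values {0,0,10,10}: threshold 5, so cells 3,4 are positive
        df = pd.DataFrame({"bc_0": [0.0, 0.0, 10.0, 10.0]})
        bits = binarize_channels(df)
        assert bits["bc_0"].tolist() == [0, 0, 1, 1]

    def test_border_eligibility(self):
        df = pd.DataFrame({"bc_0": [10.0, 0.0, 0.0, 10.0]})
        bits = binarize_channels(df, border_distance=np.array([5.0, 10.0, 20.0, 40.0]))
        # the 40 µm cell is beyond the 30 µm debarcoding band
        assert bits["eligible"].tolist() == [True, True, True, False]

    def test_constant_channel_warns(self):
        df = pd.DataFrame({"bc_0": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning):
            bits = binarize_channels(df)
        assert bits["bc_0"].tolist() == [0, 0, 0]

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            binarize_channels(pd.DataFrame({"bc_0": [1.0]}))


class TestAssignSlice:
    def setup_method(self):
        self.cs = enumerate_codes(4, 2)
        self.A = self.cs.codewords[0]
        self.B = self.cs.codewords[1]

    def _codes(self, counts):
        rows = []
        for word, cnt in counts.items():
            rows.extend([list(word)] * cnt)
        return np.array(rows)

    def test_clear_majority(self):
        a = assign_slice(self._codes({self.A: 25, self.B: 5}), self.cs)
        assert a.assigned and a.well == self.cs.well_map[self.A]

    def test_dominance_rule(self):
        a = assign_slice(self._codes({self.A: 12, self.B: 7}), self.cs)
        assert a.well == UNASSIGNED  # 12 < 2×7

    def test_min_count_rule(self):
        a = assign_slice(self._codes({self.A: 9}), self.cs)
        assert a.well == UNASSIGNED  # 9 < 10

    def test_invalid_weight_discarded(self):
        codes = np.vstack([self._codes({self.A: 12}), np.ones((50, 4), dtype=int)])
        a = assign_slice(codes, self.cs)
        assert a.well == self.cs.well_map[self.A]

    def test_no_valid_codes(self):
        a = assign_slice(np.ones((30, 4), dtype=int), self.cs)
        assert a.well == UNASSIGNED and a.reason == "no valid codewords"


class TestCisplatin:
    def test_capacity_offsets(self):
        cs = enumerate_codes(4, 2)
        base = assign_slice(np.array([list(cs.codewords[0])] * 20), cs)
        w7 = base.well
        assert combine_cisplatin(base, "Pt194", layout_size=120) == w7
        assert combine_cisplatin(base, "Pt198", layout_size=120) == w7 + 120

    def test_pt_tie_unassigned(self):
        assert call_pt_label(0.5, 0.5) == UNASSIGNED
        assert call_pt_label(0.9, 0.1) == "Pt194"
        assert call_pt_label(0.1, 0.9) == "Pt198"
        cs = enumerate_codes(4, 2)
        base = assign_slice(np.array([list(cs.codewords[0])] * 20), cs)
        assert combine_cisplatin(base, UNASSIGNED, 120) == UNASSIGNED


def _debarcode_accuracy(seed: int) -> float:
    cfg = sv.SyntheticConfig(
        n_spheres=6, slices_per_sphere=2, sphere_radius_mean=60.0, sphere_radius_sd=3.0
    )
    cells, truth = sv.generate_condition(cfg, seed)
    n_ch, k_on = cfg.barcode_scheme
    code_set = enumerate_codes(n_ch, k_on)
    bc_cols = [f"bc_{c}" for c in range(n_ch)]
    bits = binarize_channels(cells[bc_cols], border_distance=cells["dist_border"])
    ok = 0
    images = cells.groupby("image_id", sort=False)
    for img, grp in images:
        sub = bits.loc[grp.index]
        sub = sub[sub["eligible"]]
        a = assign_slice(sub[bc_cols].to_numpy(), code_set, img)
        expected = truth.sphere_wells[grp["sphere_id"].iloc[0]]
        ok += a.well == expected
    return ok / len(images)


def test_debarcoding_recovers_wells_on_synthetic_plug():
    assert _debarcode_accuracy(3) == 1.0


def test_per_cell_code_accuracy_at_default_separation():
    # a plug needs every barcode channel represented in both states for the
    # mean-intensity threshold to separate; 12 wells of the 8-choose-4
    # scheme make a constant channel essentially impossible
    cfg = sv.SyntheticConfig(n_spheres=12, slices_per_sphere=2, sphere_radius_mean=60.0)
    cells, truth = sv.generate_condition(cfg, 2)
    n_ch, k_on = cfg.barcode_scheme
    code_set = enumerate_codes(n_ch, k_on)
    bc_cols = [f"bc_{c}" for c in range(n_ch)]
    bits = binarize_channels(cells[bc_cols], border_distance=cells["dist_border"])
    eligible = bits["eligible"]
    inv_map = {v: k for k, v in code_set.well_map.items()}
    expected_words = cells["sphere_id"].map(
        {s: inv_map[w] for s, w in truth.sphere_wells.items()}
    )
    got = [tuple(r) for r in bits.loc[eligible, bc_cols].to_numpy()]
    want = list(expected_words[eligible])
    acc = np.mean([g == w for g, w in zip(got, want)])
    assert acc == 1.0


def test_accuracy_degrades_with_separation():
    cfg_kw = dict(n_spheres=6, slices_per_sphere=2, sphere_radius_mean=60.0)
    accs = []
    for sep in (1.5, 0.2, 0.05):
        acc = []
        for seed in range(3):
            cfg = sv.SyntheticConfig(barcode_separation=sep, **cfg_kw)
            cells, truth = sv.generate_condition(cfg, seed)
            n_ch, k_on = cfg.barcode_scheme
            code_set = enumerate_codes(n_ch, k_on)
            bc_cols = [f"bc_{c}" for c in range(n_ch)]
            bits = binarize_channels(cells[bc_cols], border_distance=cells["dist_border"])
            ok = 0
            images = cells.groupby("image_id", sort=False)
            for img, grp in images:
                sub = bits.loc[grp.index]
                sub = sub[sub["eligible"]]
                a = assign_slice(sub[bc_cols].to_numpy(), code_set, img)
                ok += a.well == truth.sphere_wells[grp["sphere_id"].iloc[0]]
            acc.append(ok / len(images))
        accs.append(np.mean(acc))
    assert accs[0] >= accs[1] >= accs[2]
    assert accs[0] == 1.0
    assert accs[0] > accs[2]
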