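"""Object-based colocalization: overlap rule, counts, summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleopunct.coloc import (
    ColocRecord,
    build_coloc_records,
    coloc_fraction_summary,
    overlap_fraction,
    per_cell_coloc_fractions,
    per_nucleus_counts,
    score_colocalization,
)
from nucleopunct.puncta import Punctum
from nucleopunct.segmentation import NucleusRecord, partition_rings

from conftest import make_disk


def punctum_from_mask(mask, pid=1, nucleus=None, region="inner",
                      channel="gal9"):
    rr, cc = np.nonzero(mask)
    r0, c0, r1, c1 = rr.min(), cc.min(), rr.max() + 1, cc.max() + 1
    local = mask[r0:r1, c0:c1]
    return Punctum(
        id=pid, channel=channel, bbox=(int(r0), int(c0), int(r1), int(c1)),
        mask=local, centroid=(float(rr.mean()), float(cc.mean())),
        area_px=int(mask.sum()),
        equiv_diameter_px=2 * np.sqrt(mask.sum() / np.pi),
        equiv_diameter_um=0.5, mean_intensity=200.0,
        nucleus_label=nucleus, region=region)


def engineered_pair(n_pixels: int, n_overlap: int):
    """A punctum of exactly `n_pixels` pixels and a partner mask
    covering exactly `n_overlap` of them."""
    shape = (40, max(50, n_pixels // 20 + 10))
    mask = np.zeros(shape, bool)
    flat = np.arange(n_pixels)
    mask[5 + flat // (shape[1] - 10), 5 + flat % (shape[1] - 10)] = True
    assert mask.sum() == n_pixels
    partner = np.zeros(shape, bool)
    rr, cc = np.nonzero(mask)
    partner[rr[:n_overlap], cc[:n_overlap]] = True
    return mask, partner


class TestOverlapFraction:
    def test_identical_masks(self):
        m = make_disk(10)
        assert overlap_fraction(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((20, 20), bool); a[2:5, 2:5] = True
        b = np.zeros((20, 20), bool); b[10:15, 10:15] = True
        assert overlap_fraction(a, b) == 0.0

    def test_disk_on_half_plane_boundary(self):
        a = make_disk(20, pad=5)
        b = np.zeros_like(a)
        b[:, a.shape[1] // 2:] = True       # half-plane through the centre
        assert overlap_fraction(a, b) == pytest.approx(0.5, abs=0.02)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(np.zeros((5, 5), bool), np.ones((5, 5), bool))


class TestThirtyPercentRule:
    @pytest.mark.parametrize("n_overlap,expected", [
        (299, False),   # 0.299: below the rule
        (300, True),    # exactly 30 %: inclusive
        (301, True),
    ])
    def test_boundary_classification(self, n_overlap, expected):
        mask, partner = engineered_pair(1000, n_overlap)
        p = punctum_from_mask(mask)
        [(pid, frac, called)] = score_colocalization([p], partner,
                                                     threshold=0.30)
        assert frac == pytest.approx(n_overlap / 1000)
        assert called is expected

    def test_zero_threshold_calls_everything(self):
        mask, partner = engineered_pair(100, 0)
        p = punctum_from_mask(mask)
        [(_, frac, called)] = score_colocalization([p], partner, threshold=0.0)
        assert frac == 0.0 and called

    def test_call_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        puncta, partner = [], np.zeros((200, 200), bool)
        for i in range(12):
            r0, c0 = rng.integers(10, 180, 2)
            m = np.zeros((200, 200), bool)
            m[r0:r0 + 8, c0:c0 + 8] = True
            puncta.append(punctum_from_mask(m, pid=i))
            k = rng.integers(0, 9)
            partner[r0:r0 + k, c0:c0 + 8] = True
        counts = [sum(c for _, _, c in
                      score_colocalization(puncta, partner, threshold=t))
                  for t in np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(f_pdna=st.floats(0, 1), f_sc35=st.floats(0, 1),
           thr=st.floats(0, 1))
    def test_triple_implies_both_pairwise(self, f_pdna, f_sc35, thr):
        rec = ColocRecord(1, None, f_pdna, f_sc35,
                          f_pdna >= thr, f_sc35 >= thr)
        assert rec.triple == (rec.coloc_pdna and rec.coloc_sc35)


class TestPerNucleusCounts:
    def nucleus(self, label=1):
        mask = make_disk(30)
        rec = NucleusRecord(
            label=label, bbox=(0, 0, *mask.shape), mask=mask,
            area_px=int(mask.sum()), equiv_diameter_px=60.0, form_factor=1.0,
            centroid=(34.0, 34.0), touches_border=False, passed_filters=True)
        return partition_rings(rec, 0.2)

    def test_no_puncta_gives_zero_counts(self):
        counts = per_nucleus_counts([self.nucleus()], {"gal9": []}, [])
        assert counts[0].counts["gal9"] == {"edge": 0, "inner": 0, "total": 0}
        assert counts[0].n_gal9_coloc_pdna == 0

    def test_edge_plus_inner_equals_total(self):
        nuc = self.nucleus()
        puncta = []
        for i, (region) in enumerate(["edge", "inner", "inner"]):
            m = np.zeros((70, 70), bool)
            m[10 + i * 15: 14 + i * 15, 30:34] = True
            puncta.append(punctum_from_mask(m, pid=i, nucleus=1,
                                            region=region))
        counts = per_nucleus_counts([nuc], {"gal9": puncta}, [])
        c = counts[0].counts["gal9"]
        assert c["edge"] + c["inner"] == c["total"] == 3

    def test_coloc_counts_bounded_by_gal9_total(self):
        nuc = self.nucleus()
        m = np.zeros((70, 70), bool)
        m[30:35, 30:35] = True
        puncta = [punctum_from_mask(m, pid=1, nucleus=1)]
        records = [ColocRecord(1, 1, 0.9, 0.9, True, True),
                   ColocRecord(2, 1, 0.9, 0.0, True, False)]  # stray record
        counts = per_nucleus_counts([nuc], {"gal9": puncta}, records)
        assert counts[0].n_gal9_coloc_pdna <= 2
        assert counts[0].n_triple <= counts[0].n_gal9_coloc_pdna

    def test_unfiltered_nuclei_excluded(self):
        good, bad = self.nucleus(1), self.nucleus(2)
        bad.passed_filters = False
        counts = per_nucleus_counts([good, bad], {"gal9": []}, [])
        assert [c.nucleus_label for c in counts] == [1]


class TestColocSummary:
    def test_fully_colocalized_cells(self):
        table = coloc_fraction_summary({"t3h": [1.0, 1.0, 1.0]})
        row = table.iloc[0]
        assert row["mean_fraction"] == 1.0
        assert row["sem"] == 0.0
        assert row["n"] == 3

    def test_two_cell_example(self):
        table = coloc_fraction_summary({"g": [0.2, 0.4]})
        row = table.iloc[0]
        assert row["mean_fraction"] == pytest.approx(0.3)
        assert row["sem"] == pytest.approx(0.1)

    def test_empty_group_reports_n_zero(self):
        table = coloc_fraction_summary({"empty": []})
        row = table.iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["mean_fraction"])

    def test_cells_without_gal9_are_skipped_and_counted(self):
        from nucleopunct.coloc import NucleusCounts
        counts = [
            NucleusCounts(1, {"gal9": {"edge": 0, "inner": 2, "total": 2}},
                          n_gal9_coloc_pdna=1),
            NucleusCounts(2, {"gal9": {"edge": 0, "inner": 0, "total": 0}}),
        ]
        fractions, skipped = per_cell_coloc_fractions(counts, "pdna")
        assert fractions == [0.5]
        assert skipped == 1
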