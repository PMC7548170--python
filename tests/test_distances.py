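"""K2P distances, haversine geography, populations and contrasts."""

import itertools
import math

import numpy as np
import pytest

from barcodescope.distances import (
    SaturationError,
    UndefinedDistanceError,
    assign_populations,
    contrast_label,
    contrast_table,
    contrasts_to_frame,
    count_site_patterns,
    distance_matrix,
    haversine_km,
    k2p_distance,
    k2p_from_pq,
)
from barcodescope.seqio import AlignedSeqSet, SpecimenRecord


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    @pytest.mark.parametrize(
        "p,q,expected",
        [(0.1, 0.05, 0.170182), (0.25, 0.25, 0.866434)],
    )
    def test_hand_evaluated_formula(self, p, q, expected):
        assert k2p_from_pq(p, q) == pytest.approx(expected, abs=1e-6)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p_from_pq(0.4, 0.3)

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            k2p_distance("NN--", "AC--")

    def test_pairwise_deletion_bookkeeping(self):
        # 10 bp, 2 gapped sites, 1 transition among the remaining 8
        a = "A-GTACGTAC"
        b = "AC-TACGTAT"  # site 10: C->T transition
        n, ts, tv = count_site_patterns(a, b)
        assert (n, ts, tv) == (8, 1, 0)
        assert k2p_distance(a, b) == pytest.approx(k2p_from_pq(1 / 8, 0))


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, small_alignment):
        dm = distance_matrix(small_alignment)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_k2p_dominates_p_distance(self, rng):
        for _ in range(10):
            seqs = tuple(
                "".join(rng.choice(list("ACGT"), size=100)) for _ in range(4)
            )
            aln = AlignedSeqSet(ids=("a", "b", "c", "d"), seqs=seqs)
            try:
                k2p = distance_matrix(aln, model="k2p").values
            except SaturationError:
                continue
            p = distance_matrix(aln, model="p").values
            assert (k2p >= p - 1e-12).all()

    def test_bp_model_equals_hamming_loop(self, rng):
        seqs = tuple("".join(rng.choice(list("ACGT"), size=60)) for _ in range(5))
        aln = AlignedSeqSet(ids=tuple("abcde"), seqs=seqs)
        dm = distance_matrix(aln, model="bp")
        for i, j in itertools.combinations(range(5), 2):
            hamming = sum(x != y for x, y in zip(seqs[i], seqs[j]))
            assert dm.values[i, j] == hamming

    def test_percent_scale(self, small_alignment):
        prop = distance_matrix(small_alignment, scale="proportion").values
        pct = distance_matrix(small_alignment, scale="percent").values
        assert np.allclose(pct, 100 * prop)

    def test_complete_deletion_drops_gapped_columns(self):
        aln = AlignedSeqSet(ids=("a", "b", "c"), seqs=("ACGT", "AC-T", "ACGA"))
        dm = distance_matrix(aln, model="bp", deletion="complete")
        # column 3 (gap in b) removed for all pairs: a vs c differ at last col
        assert dm.get("a", "c") == 1.0
        assert dm.get("a", "b") == 0.0


class TestHaversine:
    def test_closed_forms(self):
        assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0
        assert haversine_km((0, 0), (0, 1)) == pytest.approx(111.195, abs=1e-3)
        assert haversine_km((0, 0), (0, 180)) == pytest.approx(20015.087, abs=1e-3)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(200):
            pts = [(float(rng.uniform(-89, 89)), float(rng.uniform(-180, 180)))
                   for _ in range(3)]
            d01 = haversine_km(pts[0], pts[1])
            d10 = haversine_km(pts[1], pts[0])
            d02 = haversine_km(pts[0], pts[2])
            d12 = haversine_km(pts[1], pts[2])
            assert d01 == pytest.approx(d10, rel=1e-12)
            assert d01 >= 0
            assert d02 <= d01 + d12 + 1e-9


def _spec(i, site, lat, lon, species="spA", region="EU", country="Germany"):
    return SpecimenRecord(
        seq_id=i, species=species, site_name=site, country=country,
        region=region, lat=lat, lon=lon,
    )


class TestAssignPopulations:
    def test_shared_site_name_without_coordinates(self):
        specs = [
            SpecimenRecord(seq_id="a", species="s", site_name="X",
                           country="Spain", region="IB"),
            SpecimenRecord(seq_id="b", species="s", site_name="X",
                           country="Spain", region="IB"),
        ]
        pops = assign_populations(specs)
        assert len(pops) == 1

    def test_five_km_threshold_boundary(self):
        # ~0.009 deg lat = 1 km: two sites 4.9 km apart merge, 5.1 km do not
        near = [_spec("a", "p", 50.0, 10.0), _spec("b", "q", 50.0 + 4.9 / 111.195, 10.0)]
        far = [_spec("a", "p", 50.0, 10.0), _spec("b", "q", 50.0 + 5.1 / 111.195, 10.0)]
        assert len(assign_populations(near)) == 1
        assert len(assign_populations(far)) == 2

    def test_single_linkage_chain_closure(self):
        km = 1 / 111.195
        specs = [
            _spec("a", "p", 50.0, 10.0),
            _spec("b", "q", 50.0 + 4 * km, 10.0),
            _spec("c", "r", 50.0 + 8 * km, 10.0),
        ]
        assert len(assign_populations(specs)) == 1
        assert len(assign_populations(specs, single_linkage=False)) == 2

    def test_order_invariance(self, located_specimens):
        fwd = assign_populations(located_specimens)
        rev = assign_populations(list(reversed(located_specimens)))
        blocks = lambda pm: {frozenset(p.member_ids) for p in pm.populations}
        assert blocks(fwd) == blocks(rev)

    def test_unlocated_without_site_excluded(self):
        specs = [
            SpecimenRecord(seq_id="a", species="s", site_name="",
                           country="Spain", region="IB"),
            _spec("b", "p", 50.0, 10.0),
        ]
        pops = assign_populations(specs)
        assert pops.excluded_ids == ("a",)


class TestContrasts:
    @pytest.mark.parametrize(
        "pair,label",
        [
            (("EU", "EU"), "EUEU"), (("EU", "IB"), "EUIB"), (("IB", "EU"), "EUIB"),
            (("EU", "IT"), "EUIT"), (("IB", "IB"), "IBIB"), (("IT", "IT"), "other"),
            (("IB", "IT"), "other"),
        ],
    )
    def test_contrast_from_unordered_region_pair(self, pair, label):
        assert contrast_label(*pair) == label

    def _setup(self, seqs, specimens):
        aln = AlignedSeqSet(ids=tuple(s.seq_id for s in specimens), seqs=tuple(seqs))
        dm = distance_matrix(aln, scale="percent")
        pops = assign_populations(specimens)
        return {"spA": dm}, pops

    def test_max_divergence_is_max_over_cross_pairs(self, located_specimens):
        seqs = ["ACGTACGTACGT", "ACGTACGTACGT", "ACGAACGTACGT",
                "TTTTACGTACGT", "ACGTACGTACGA"]
        dms, pops = self._setup(seqs, located_specimens)
        rows = contrast_table(dms, pops, located_specimens)
        df = contrasts_to_frame(rows)
        dm = dms["spA"]
        for _, row in df.iterrows():
            ids_a = next(p.member_ids for p in pops.populations if p.pop_id == row.pop_a)
            ids_b = next(p.member_ids for p in pops.populations if p.pop_id == row.pop_b)
            expected = max(dm.get(i, j) for i in ids_a for j in ids_b)
            assert row.max_div_pct == pytest.approx(expected)

    def test_max_div_monotone_under_added_sequence(self):
        # two fixed populations; adding a sequence to one never lowers max_div
        def specs(with_extra):
            out = [
                _spec("a1", "siteA", 50.0, 10.0),
                _spec("a2", "siteA", 50.0, 10.0),
                _spec("b1", "siteB", 52.0, 12.0),
            ]
            if with_extra:
                out.append(_spec("a3", "siteA", 50.0, 10.0))
            return out

        seq_of = {
            "a1": "ACGTACGTACGT", "a2": "ACGAACGTACGT",
            "b1": "TTGTACGTACGT", "a3": "ACGTACGTTTTT",
        }
        results = {}
        for with_extra in (False, True):
            sp = specs(with_extra)
            aln = AlignedSeqSet(
                ids=tuple(s.seq_id for s in sp),
                seqs=tuple(seq_of[s.seq_id] for s in sp),
            )
            dm = distance_matrix(aln, scale="percent")
            rows = contrast_table({"spA": dm}, assign_populations(sp), sp)
            (row,) = rows
            results[with_extra] = row.max_div
        assert results[True] >= results[False] - 1e-12
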