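import numpy as np
import pytest

from cyclepeaks.classify import classify_sites
from cyclepeaks.intervals import GenomeTable, GenomicInterval, PeakSet, ValidationError
from cyclepeaks.spatial import (
    DomainSet,
    LabeledBoundary,
    boundary_enrichment_profile,
    boundary_spacing_permutation_test,
    label_boundaries,
    nearest_neighbor_permutation_test,
    _domains_between,
    _spacing_statistics,
)
from .conftest import make_peaks


def tiled_domains(genome, chrom="chr2L", start=100_000, widths=(50_000,) * 5):
    """Contiguous domains sharing boundaries (B0..Bn for D1..Dn)."""
    ds, pos = [], start
    for i, w in enumerate(widths):
        ds.append(GenomicInterval(chrom, pos, pos + w, f"d{i}"))
        pos += w
    return DomainSet(ds, genome)


def spacing_oracle(positions, labeled_idx, domains):
    """Exhaustive pairwise scan for minimum-domain-number spacing."""
    out = []
    for i in labeled_idx:
        best = None
        for j in labeled_idx:
            if i == j:
                continue
            lo = min(positions[i], positions[j])
            hi = max(positions[i], positions[j])
            n = sum(1 for d in domains if lo <= d.start and d.end <= hi)
            best = n if best is None else min(best, n)
        out.append(best)
    return out


class TestDomainSet:
    def test_rejects_overlapping_domains(self, genome):
        with pytest.raises(ValidationError):
            DomainSet(
                [GenomicInterval("chr2L", 0, 100), GenomicInterval("chr2L", 50, 150)],
                genome,
            )

    def test_rejects_unknown_kind(self, genome):
        with pytest.raises(ValidationError):
            DomainSet([], genome, kind="nope")

    def test_boundary_positions_unique_sorted(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 3)
        pos = ds.boundary_positions("chr2L")
        assert list(pos) == [100_000, 150_000, 200_000, 250_000]


class TestNearestNeighborPermutationTest:
    def build_uniform(self, genome, n, seed, chrom="chr2L"):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 990_000, size=n)
        return make_peaks(genome, [(chrom, int(s), int(s) + 100, f"p{k}")
                                   for k, s in enumerate(starts)])

    def test_deterministic_under_seed(self, genome):
        peaks = self.build_uniform(genome, 30, seed=1)
        r1 = nearest_neighbor_permutation_test(peaks, peaks, n_perm=50, seed=9)
        r2 = nearest_neighbor_permutation_test(peaks, peaks, n_perm=50, seed=9)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null, r2.null)

    def test_two_baits_deterministic_recomputable(self):
        genome = GenomeTable({"c": 100_000})
        peaks = make_peaks(genome, [("c", 1000, 1100, "a"), ("c", 5000, 5100, "b")])
        res = nearest_neighbor_permutation_test(peaks, peaks, n_perm=20, seed=5)
        assert np.array_equal(res.observed, [4000, 4000])
        assert len(res.null) == 20 * 2
        # recompute the null from scratch with the same draw sequence
        rng = np.random.default_rng(5)
        expected_null = []
        for _ in range(20):
            starts = rng.integers(0, 100_000 - 100 + 1, size=2)
            anchors = np.sort(starts + 50)
            d = anchors[1] - anchors[0]
            expected_null.extend([d, d])
        assert np.array_equal(res.null, expected_null)

    def test_insufficient_sites_error(self, genome):
        peaks = make_peaks(genome, [("chr2L", 0, 100, "only")])
        with pytest.raises(ValidationError, match="insufficient"):
            nearest_neighbor_permutation_test(peaks, peaks, n_perm=10, seed=0)

    def test_null_pools_equal_weight(self, genome):
        peaks = self.build_uniform(genome, 25, seed=3)
        res = nearest_neighbor_permutation_test(peaks, peaks, n_perm=40, seed=0)
        assert len(res.null) == 40 * 25
        assert len(res.perm_medians) == 40

    def test_planted_clusters_significant(self):
        genome = GenomeTable({"c": 20_000_000})
        rng = np.random.default_rng(7)
        centers = rng.integers(100_000, 19_900_000, size=10)
        ivs = []
        for k in range(200):
            c = centers[k % len(centers)]
            pos = int(c + rng.integers(-5000, 5001))
            ivs.append(GenomicInterval("c", pos, pos + 100, f"p{k}"))
        peaks = PeakSet(ivs, genome)
        res = nearest_neighbor_permutation_test(peaks, peaks, n_perm=100, seed=1)
        assert res.observed_median < res.null_median
        assert res.p_value < 1e-4

    def test_distinct_target_set_shuffles_targets_only(self, genome):
        baits = self.build_uniform(genome, 20, seed=1)
        targets = self.build_uniform(genome, 30, seed=2)
        res = nearest_neighbor_permutation_test(baits, targets, n_perm=30, seed=4)
        assert len(res.observed) == 20
        assert len(res.null) == 30 * 20

    def test_invariant_to_chromosome_relabeling_and_shift(self):
        g1 = GenomeTable({"alpha": 1_000_000})
        g2 = GenomeTable({"beta": 1_000_000})
        rng = np.random.default_rng(11)
        starts = rng.integers(10_000, 900_000, size=40)
        p1 = PeakSet(
            [GenomicInterval("alpha", int(s), int(s) + 100, f"p{k}")
             for k, s in enumerate(starts)], g1
        )
        p2 = PeakSet(
            [GenomicInterval("beta", int(s) + 777, int(s) + 877, f"p{k}")
             for k, s in enumerate(starts)], g2
        )
        r1 = nearest_neighbor_permutation_test(p1, p1, n_perm=25, seed=3)
        r2 = nearest_neighbor_permutation_test(p2, p2, n_perm=25, seed=3)
        assert np.array_equal(np.sort(r1.observed), np.sort(r2.observed))
        assert r1.p_value == r2.p_value

    def test_mismatched_genomes_error(self, genome):
        other = GenomeTable({"chr2L": 999_999})
        baits = self.build_uniform(genome, 5, seed=0)
        targets = make_peaks(other, [("chr2L", 0, 100)])
        with pytest.raises(ValidationError):
            nearest_neighbor_permutation_test(baits, targets, n_perm=5, seed=0)


class TestBoundaryEnrichmentProfile:
    def test_sites_at_boundaries_all_mass_at_zero(self, genome):
        ds = tiled_domains(genome)
        positions = ds.boundary_positions("chr2L")
        sites = make_peaks(
            genome, [("chr2L", int(p) - 50, int(p) + 50, f"b{k}")
                     for k, p in enumerate(positions)]
        )
        prof = boundary_enrichment_profile(sites, ds, flank=10_000, bin=1000)
        center = np.flatnonzero(prof.offsets == 0)[0]
        assert prof.mean[center] > 0
        mask = np.ones(len(prof.mean), dtype=bool)
        mask[center] = False
        assert np.allclose(prof.mean[mask], 0.0)

    def test_sites_at_domain_centers_empty_profile(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 4)
        sites = make_peaks(
            genome,
            [("chr2L", 100_000 + 50_000 * i + 24_950, 100_000 + 50_000 * i + 25_050,
              f"c{i}") for i in range(4)],
        )
        prof = boundary_enrichment_profile(sites, ds, flank=10_000, bin=1000)
        assert np.allclose(prof.mean, 0.0)

    def test_interior_sites_get_negative_offsets(self, genome):
        ds = tiled_domains(genome, widths=(50_000,))
        # site 5 kb inside the left edge
        sites = make_peaks(genome, [("chr2L", 104_950, 105_050, "s")])
        prof = boundary_enrichment_profile(sites, ds, flank=10_000, bin=1000)
        hit_offsets = prof.offsets[prof.mean > 0]
        assert (hit_offsets < 0).all()

    def test_outside_sites_get_positive_offsets(self, genome):
        ds = tiled_domains(genome, widths=(50_000,))
        sites = make_peaks(genome, [("chr2L", 94_950, 95_050, "s")])  # 5 kb left of start
        prof = boundary_enrichment_profile(sites, ds, flank=10_000, bin=1000)
        hit_offsets = prof.offsets[prof.mean > 0]
        assert (hit_offsets > 0).all()

    def test_empty_domains_error(self, genome):
        sites = make_peaks(genome, [("chr2L", 0, 100)])
        with pytest.raises(ValidationError):
            boundary_enrichment_profile(sites, DomainSet([], genome), 1000, 100)


class TestLabelBoundaries:
    def classified(self, genome, im_spec, io_spec=(), mo_spec=()):
        inter, mito = [], []
        for k, (c, s, e) in enumerate(im_spec):
            inter.append(GenomicInterval(c, s, e, f"im{k}"))
            mito.append(GenomicInterval(c, s + 1, e + 1, f"im{k}_m"))
        for k, (c, s, e) in enumerate(io_spec):
            inter.append(GenomicInterval(c, s, e, f"io{k}"))
        for k, (c, s, e) in enumerate(mo_spec):
            mito.append(GenomicInterval(c, s, e, f"mo{k}"))
        return classify_sites(PeakSet(inter, genome), PeakSet(mito, genome))

    def test_single_class_label(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 2)
        c = self.classified(genome, [("chr2L", 149_900, 150_000)])
        labeled = label_boundaries(ds, c, boundary_window=500)
        by_pos = {b.position: b.labels for b in labeled}
        assert by_pos[150_000] == {"IM"}
        assert by_pos[100_000] == set()

    def test_multiple_labels_on_one_boundary(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 2)
        c = self.classified(
            genome,
            im_spec=[("chr2L", 149_900, 150_000)],
            io_spec=[("chr2L", 150_100, 150_200)],
        )
        labeled = label_boundaries(ds, c, boundary_window=500)
        by_pos = {b.position: b.labels for b in labeled}
        assert by_pos[150_000] == {"IM", "IO"}

    def test_unlabeled_boundaries_retained_with_index(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 3)
        c = self.classified(genome, [("chr2L", 500_000, 500_100)])
        labeled = label_boundaries(ds, c)
        assert len(labeled) == 4
        assert [b.index for b in labeled] == [0, 1, 2, 3]


class TestBoundarySpacing:
    def test_observed_example_b1_b4(self, genome):
        # domains D1..D5, boundaries B0..B5; labels at B1 and B4 -> {3, 3}
        ds = tiled_domains(genome, widths=(50_000,) * 5)
        positions = ds.boundary_positions("chr2L")
        boundaries = [
            LabeledBoundary("chr2L", int(p), int(p), i,
                            {"IM"} if i in (1, 4) else set())
            for i, p in enumerate(positions)
        ]
        res = boundary_spacing_permutation_test(ds, boundaries, "IM", n_perm=10, seed=0)
        assert sorted(res.observed) == [3, 3]

    def test_adjacent_boundaries_one_domain_apart(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 5)
        positions = ds.boundary_positions("chr2L")
        boundaries = [
            LabeledBoundary("chr2L", int(p), int(p), i,
                            {"IM"} if i in (2, 3) else set())
            for i, p in enumerate(positions)
        ]
        res = boundary_spacing_permutation_test(ds, boundaries, "IM", n_perm=10, seed=0)
        assert sorted(res.observed) == [1, 1]

    def test_error_when_no_chromosome_has_two_labels(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 5)
        positions = ds.boundary_positions("chr2L")
        boundaries = [
            LabeledBoundary("chr2L", int(p), int(p), i, {"IM"} if i == 0 else set())
            for i, p in enumerate(positions)
        ]
        with pytest.raises(ValidationError):
            boundary_spacing_permutation_test(ds, boundaries, "IM", n_perm=5, seed=0)

    def test_null_size_conserves_label_counts(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 8)
        positions = ds.boundary_positions("chr2L")
        k = 4
        boundaries = [
            LabeledBoundary("chr2L", int(p), int(p), i,
                            {"IM"} if i < k else set())
            for i, p in enumerate(positions)
        ]
        res = boundary_spacing_permutation_test(ds, boundaries, "IM", n_perm=33, seed=0)
        # each permutation keeps exactly k labeled boundaries
        assert len(res.null) == 33 * k

    def test_statistic_symmetry(self, genome):
        ds = tiled_domains(genome, widths=(50_000,) * 6)
        positions = ds.boundary_positions("chr2L")
        starts = np.array([d.start for d in ds.domains("chr2L")])
        ends = np.array([d.end for d in ds.domains("chr2L")])
        stats = _spacing_statistics(positions, np.array([1, 5]), starts, ends)
        assert stats[0] == stats[1]

    def test_oracle_equivalence_random_configs(self, rng):
        genome = GenomeTable({"c": 10_000_000})
        for _ in range(100):
            n_dom = int(rng.integers(3, 15))
            widths = rng.integers(20_000, 100_000, size=n_dom)
            ds, pos = [], int(rng.integers(0, 100_000))
            for i, w in enumerate(widths):
                ds.append(GenomicInterval("c", pos, pos + int(w), f"d{i}"))
                pos += int(w) + int(rng.integers(0, 2) * rng.integers(0, 10_000))
            domains = DomainSet(ds, genome)
            positions = domains.boundary_positions("c")
            n_b = len(positions)
            k = int(rng.integers(2, max(3, n_b)))
            k = min(k, n_b)
            labeled_idx = np.sort(rng.choice(n_b, size=k, replace=False))
            starts = np.array([d.start for d in domains.domains("c")])
            ends = np.array([d.end for d in domains.domains("c")])
            got = _spacing_statistics(positions, labeled_idx, starts, ends)
            want = spacing_oracle(list(positions), list(labeled_idx), domains.domains("c"))
            assert list(got) == want

    def test_clustered_labels_significant(self, genome):
        ds = tiled_domains(genome, chrom="chr2L", start=0, widths=(10_000,) * 90)
        positions = ds.boundary_positions("chr2L")
        # labels in two tight runs
        labeled = set(range(10, 20)) | set(range(60, 70))
        boundaries = [
            LabeledBoundary("chr2L", int(p), int(p), i,
                            {"IM"} if i in labeled else set())
            for i, p in enumerate(positions)
        ]
        res = boundary_spacing_permutation_test(ds, boundaries, "IM", n_perm=200, seed=2)
        assert res.observed_median < res.null_median
        assert res.p_value < 0.05


class TestDomainsBetween:
    def test_partial_domains_excluded(self):
        starts = np.array([0, 100, 200])
        ends = np.array([50, 150, 250])
        assert _domains_between(starts, ends, 0, 250) == 3
        assert _domains_between(starts, ends, 10, 250) == 2
        assert _domains_between(starts, ends, 0, 240) == 2
        assert _domains_between(starts, ends, 60, 90) == 0
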