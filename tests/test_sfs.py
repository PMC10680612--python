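"""Site frequency spectra, pooling, folding, the .fs format, and
windowed summary statistics."""

import numpy as np
import pytest

import ratehet as rh
from ratehet.sfs import (SFS, fold, pi_from_haplotypes, pool_sfs, read_fs,
                         sfs_from_replicates, tajimas_d_constants,
                         window_summaries, write_fs)
from ratehet.simulate import ReplicateResult


def make_rep(hap, positions=None, L=1000, classes=None):
    hap = np.asarray(hap, dtype=np.uint8)
    S = hap.shape[1]
    if positions is None:
        positions = np.arange(S, dtype=np.int64) * (L // max(S, 1))
    if classes is None:
        classes = np.full(S, 3, dtype=np.uint8)  # intergenic
    return ReplicateResult(np.asarray(positions, dtype=np.int64), hap,
                           classes, np.zeros(S), L, seed=None, Q=1.0)


class TestTally:
    def test_simple_counts(self):
        n = 100
        hap = np.zeros((n, 3), dtype=np.uint8)
        hap[:1, 0] = 1
        hap[:1, 1] = 1
        hap[:99, 2] = 1
        sfs = sfs_from_replicates(make_rep(hap))
        assert sfs.counts[1] == 2
        assert sfs.counts[99] == 1
        assert sfs.segregating == 3

    def test_exon_mask_span(self, paper_layout):
        hap = np.zeros((4, 1), dtype=np.uint8)
        hap[0, 0] = 1
        rep = make_rep(hap, positions=[500_000], L=997_204)
        sfs = sfs_from_replicates(rep, mask=rh.exon_mask(paper_layout))
        assert sfs.span_bp == 997_204 - 298_704 == 698_500
        assert sfs.masked

    def test_masked_site_excluded(self, paper_layout):
        hap = np.ones((4, 1), dtype=np.uint8)
        hap[2:, 0] = 0
        rep = make_rep(hap, positions=[0], L=997_204)  # first exon base
        sfs = sfs_from_replicates(rep, mask=rh.exon_mask(paper_layout))
        assert sfs.segregating == 0

    def test_pooling_batches(self):
        reps = []
        rng = np.random.default_rng(0)
        for _ in range(10):
            hap = (rng.random((10, 5)) < 0.3).astype(np.uint8)
            hap[0] = 1  # keep all columns segregating-ish
            hap[1] = 0
            reps.append(make_rep(hap))
        pooled = sfs_from_replicates(reps)
        singles = [sfs_from_replicates(r) for r in reps]
        np.testing.assert_array_equal(
            pooled.counts, pool_sfs(singles).counts)
        np.testing.assert_array_equal(
            pool_sfs(singles).counts, pool_sfs(singles[::-1]).counts)
        assert pooled.span_bp == 10 * 1000

    def test_inconsistent_sample_sizes_rejected(self):
        a = make_rep(np.ones((4, 1), dtype=np.uint8))
        b = make_rep(np.ones((6, 1), dtype=np.uint8))
        with pytest.raises(ValueError):
            sfs_from_replicates([a, b])

    def test_sfs_and_pairwise_pi_identical(self):
        rng = np.random.default_rng(3)
        hap = (rng.random((20, 40)) < rng.random(40)).astype(np.uint8)
        rep = make_rep(hap, L=500)
        sfs = sfs_from_replicates(rep)
        direct = pi_from_haplotypes(hap) / sfs.span_bp
        assert sfs.pi_per_site() == pytest.approx(direct, rel=1e-12)


class TestFold:
    def test_total_conserved(self):
        counts = np.array([0, 5, 3, 2, 1, 4, 0, 1, 2, 3, 0.0])
        sfs = SFS(10, counts, span_bp=100)
        assert fold(sfs).counts.sum() == counts.sum()

    def test_n4_mapping(self):
        sfs = SFS(4, np.array([0, 10.0, 5.0, 3.0, 0]), span_bp=10)
        f = fold(sfs)
        np.testing.assert_array_equal(f.counts, [0, 13, 5])

    def test_fold_idempotent_in_content(self):
        sfs = SFS(4, np.array([0, 7.0, 5.0, 7.0, 0]), span_bp=10)
        f = fold(sfs)
        assert fold(f) is f
        np.testing.assert_array_equal(f.counts, [0, 14, 5])


class TestFsFormat:
    def test_round_trip(self, tmp_path):
        sfs = SFS(100, np.arange(101, dtype=float))
        path = tmp_path / "spec.fs"
        write_fs(sfs, path)
        back = read_fs(path)
        assert back.n == 100
        np.testing.assert_allclose(back.counts, sfs.counts)

    def test_header_text(self):
        text = write_fs(SFS(100, np.zeros(101)))
        lines = text.splitlines()
        assert lines[0] == "101 unfolded"
        mask = lines[2].split()
        assert mask[0] == "1" and mask[-1] == "1"
        assert set(mask[1:-1]) == {"0"}

    def test_folded_header(self):
        f = fold(SFS(10, np.zeros(11)))
        text = write_fs(f)
        assert text.splitlines()[0] == "6 folded"
        assert read_fs(text).n == 10


def brute_force_tajimas_d(hap):
    """Independent from-first-principles D (pairwise loops)."""
    n, S = hap.shape
    pi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi += np.sum(hap[i] != hap[j])
    pi /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestWindows:
    def test_single_site_pi(self):
        hap = np.zeros((4, 1), dtype=np.uint8)
        hap[:2, 0] = 1
        rep = make_rep(hap, positions=[0], L=1)
        w = window_summaries(rep, window_len=1, step=1)
        assert len(w) == 1
        assert w[0].pi == pytest.approx(2 * 0.5 * 0.5 * 4 / 3, rel=1e-12)

    def test_empty_window_has_undefined_d(self):
        hap = np.ones((4, 1), dtype=np.uint8)
        hap[0, 0] = 0
        rep = make_rep(hap, positions=[9000], L=10_000)
        w = window_summaries(rep, window_len=5000, step=2500)
        assert not w[0].d_defined
        assert w[0].S == 0

    def test_d_matches_brute_force(self):
        rng = np.random.default_rng(7)
        hap = (rng.random((12, 30)) < 0.3).astype(np.uint8)
        dac = hap.sum(axis=0)
        hap = hap[:, (dac > 0) & (dac < 12)]
        rep = make_rep(hap, positions=np.arange(hap.shape[1]),
                       L=hap.shape[1])
        w = window_summaries(rep, window_len=hap.shape[1],
                             step=hap.shape[1])
        assert w[0].tajimas_d == pytest.approx(
            brute_force_tajimas_d(hap), rel=1e-12)

    def test_window_tiling_and_truncation(self):
        hap = np.ones((4, 2), dtype=np.uint8)
        hap[0] = 0
        rep = make_rep(hap, positions=[100, 11_000], L=12_000)
        w = window_summaries(rep, window_len=5000, step=2500)
        assert w[0].start == 0 and w[0].end == 5000
        assert w[-1].end == 12_000
        assert w[-1].truncated
        assert sum(x.S for x in w if x.start % 5000 == 0) == 2

    def test_constants_against_reference_n10(self):
        c = tajimas_d_constants(10)
        assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert c["b1"] == pytest.approx(11 / 27)
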