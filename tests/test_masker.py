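"""Three-pass k-mer masking: parameter derivation, window and local passes."""

import numpy as np
import pytest

from snpdiscover import masker
from snpdiscover.records import Cutoffs, KmerSpectrum, Read


def _read(bases, id="r0"):
    return Read(id=id, bases=bases, quals=np.full(len(bases), 40))


class TestChooseK:
    def test_million_bases(self):
        # 10^6/4^8 ≈ 15.3 > 5 while 10^6/4^9 ≈ 3.8 ≤ 5
        assert masker.choose_k(1_000_000) == 8

    def test_smallest_valid(self):
        assert masker.choose_k(21) == 1  # 21/4 = 5.25 > 5, 21/16 ≤ 5

    def test_boundary_error(self):
        with pytest.raises(ValueError):
            masker.choose_k(20)  # 20/4 = 5 is not > 5


class TestSpectrum:
    def test_overlapping_windows(self):
        spec = masker.build_spectrum([_read("AAAA")], K=2)
        assert spec.counts == {"AA": 3}

    def test_canonicalization_merges_strands(self):
        spec = masker.build_spectrum([_read("AC"), _read("GT", id="r1")], K=2)
        assert spec.counts == {"AC": 2}  # GT is the reverse complement of AC

    def test_n_windows_skipped(self):
        spec = masker.build_spectrum([_read("ANA")], K=2)
        assert spec.counts == {}

    def test_short_reads_contribute_nothing(self):
        spec = masker.build_spectrum([_read("ACGTA"), _read("AC", id="r1")], K=3)
        assert sum(spec.freqs) == 3


class TestCutoffs:
    def test_all_singletons(self):
        spec = KmerSpectrum(K=5, codes=np.arange(1000),
                            freqs=np.ones(1000, dtype=np.int64))
        c = masker.compute_cutoffs(spec, n_total=5000)
        assert (c.T_low, c.T_extend, c.T_threshold, c.T_high) == (2, 2, 2, 2)

    def test_direct_percentile_indexing(self):
        freqs = np.concatenate([np.ones(900), np.full(100, 10)]).astype(np.int64)
        spec = KmerSpectrum(K=5, codes=np.arange(1000), freqs=freqs)
        c = masker.compute_cutoffs(spec, n_total=5000)
        # F[900]=10, F[990]=10, F[995]=10, F[998]=10, each + 1
        assert (c.T_low, c.T_extend, c.T_threshold, c.T_high) == (11, 11, 11, 11)

    def test_tiny_spectrum_collapses(self):
        spec = KmerSpectrum(K=3, codes=np.arange(10),
                            freqs=np.arange(1, 11).astype(np.int64))
        c = masker.compute_cutoffs(spec, n_total=100)
        # int(0.9*10)=9 and int(0.998*10)=9: all cutoffs coincide at F[9]+1
        assert (c.T_low, c.T_extend, c.T_threshold, c.T_high) == (11, 11, 11, 11)


class TestScoreKmer:
    cut = Cutoffs(K=5, T_low=2, T_extend=5, T_threshold=8, T_high=10,
                  N_total=1000, C_unique=100)

    def test_pass_through_band(self):
        assert masker.score_kmer(5, self.cut) == 5

    def test_upper_clamp(self):
        assert masker.score_kmer(1_000_000, self.cut) == 10

    def test_lower_clamp(self):
        assert masker.score_kmer(1, self.cut) == 2


def _uniform_cutoffs(K, t):
    return Cutoffs(K=K, T_low=t, T_extend=t, T_threshold=t, T_high=t + 5,
                   N_total=10_000, C_unique=100)


class TestMaskWindows:
    def test_high_frequency_read_fully_masked(self):
        # every k-mer of a poly-A read has huge frequency
        r = _read("A" * 60)
        spec = masker.build_spectrum([_read("A" * 2000, id="bg")], K=5)
        cut = _uniform_cutoffs(5, 3)
        masker.mask_windows(r, spec, cut)
        assert r.mask.all()

    def test_unique_kmers_untouched(self, random_dna):
        r = _read(random_dna(80))
        spec = masker.build_spectrum([r], K=8)
        cut = Cutoffs(K=8, T_low=2, T_extend=2, T_threshold=2, T_high=3,
                      N_total=80, C_unique=spec.C_unique)
        masker.mask_windows(r, spec, cut)
        assert not r.mask.any()

    def test_bridge_between_masked_windows(self):
        # hand-built spectrum: hot k-mers at both ends of a read, a warm
        # (T_extend < score <= T_threshold) stretch in between
        K = 4
        hot1, mid, hot2 = "ACAC", "GGTA", "TCTC"
        bases = hot1 * 3 + mid * 3 + hot2 * 3
        r = _read(bases)
        from snpdiscover.masker import _kmer_codes

        codes, _ = _kmer_codes(r, K)
        uniq = np.unique(codes)
        hotset = {c for c, ok in zip(
            *_kmer_codes(_read(hot1 * 2 + "T" + hot2 * 2, id="h"), K)) if True}
        freqs = []
        hot_codes = set(np.unique(_kmer_codes(_read(hot1 * 3, id="x"), K)[0])) | set(
            np.unique(_kmer_codes(_read(hot2 * 3, id="y"), K)[0]))
        for c in uniq:
            freqs.append(50 if c in hot_codes else 10)
        spec = KmerSpectrum(K=K, codes=uniq, freqs=np.array(freqs, dtype=np.int64))
        cut = Cutoffs(K=K, T_low=1, T_extend=5, T_threshold=20, T_high=60,
                      N_total=100, C_unique=len(uniq))
        masker.mask_windows(r, spec, cut)
        # middle windows score 10 ∈ (T_extend, T_threshold]: bridged
        assert r.mask.all()


class TestLocalRepeatPass:
    def test_local_repeat_masks_whole_read(self):
        r = _read("ACGTG" * 12)  # the 5-mer ACGTG occurs 12 times
        cut = _uniform_cutoffs(5, 10)
        _, fully = masker.local_repeat_pass(r, 5, cut)
        assert fully and r.mask.all() and r.fully_masked

    def test_short_masked_run_unmasked(self, random_dna):
        r = _read(random_dna(120))
        r.mask[10:49] = True  # 39 bp < 40
        cut = _uniform_cutoffs(5, 100)
        _, fully = masker.local_repeat_pass(r, 5, cut)
        assert not fully and not r.mask.any()

    def test_forty_bp_run_stays(self, random_dna):
        r = _read(random_dna(120))
        r.mask[10:50] = True  # exactly 40 bp
        cut = _uniform_cutoffs(5, 100)
        masker.local_repeat_pass(r, 5, cut)
        assert r.mask[10:50].all() and r.mask.sum() == 40


def test_masking_never_edits_bases(random_dna):
    bases = random_dna(400)
    reads = [_read(bases[i:i + 100], id=f"r{i}") for i in range(0, 300, 50)]
    masker.mask_set(reads, K=8)
    for i, r in enumerate(reads):
        assert r.bases == bases[i * 50:i * 50 + 100].upper()


def test_freq1_spectrum_masks_nothing(random_dna, rng):
    reads = [_read(random_dna(150), id=f"r{i}") for i in range(20)]
    spec = masker.build_spectrum(reads, K=10)
    cut = Cutoffs(K=10, T_low=2, T_extend=2, T_threshold=2, T_high=3,
                  N_total=3000, C_unique=spec.C_unique)
    for r in reads:
        masker.mask_windows(r, spec, cut)
    assert not any(r.mask.any() for r in reads)


def test_planted_repeat_family_masked_background_untouched(rng):
    """A 500-copy interspersed repeat is masked; unique background is not."""
    from snpdiscover.simulate import SimConfig, sample_reads, simulate_genome

    cfg = SimConfig(genome_length=3_000_000, het_density=0.0, coverage=2.0,
                    read_length=250, seed=5,
                    interspersed_repeat=(250, 500))
    truth = simulate_genome(cfg)
    reads = sample_reads(truth, cfg)
    masker.mask_set(reads)
    in_rep = np.zeros(cfg.genome_length, dtype=bool)
    for b, e in truth.dup_regions:
        in_rep[b:e] = True
    rep_tot = rep_masked = uniq_tot = uniq_masked = 0
    # reads are error-free so locating them by exact search is reliable
    for r in reads[:2500]:
        hit = truth.haplotypes[0].find(r.bases)
        if hit < 0:
            continue  # reverse-complement sampled; orientation is symmetric
        flags = in_rep[hit:hit + len(r)]
        rep_tot += int(flags.sum())
        uniq_tot += int((~flags).sum())
        rep_masked += int(r.mask[flags].sum())
        uniq_masked += int(r.mask[~flags].sum())
    assert rep_tot > 5_000
    assert rep_masked / rep_tot >= 0.95
    assert uniq_masked / uniq_tot <= 0.01
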