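"""Genotype reading, the filtering cascade, clone detection, VIF pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispersalkit import genotype_io as gio
from dispersalkit.genotype_io import MISSING, GenotypeMatrix

from conftest import make_gm, write_minimal_vcf


class TestReadGenotypes:
    def test_biallelic_snps_parse(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "t.vcf",
            [
                ("chr1", 10, "A", "T", ["0/0", "0/1"]),
                ("chr1", 20, "C", "G", ["1/1", "./."]),
                ("chr2", 5, "G", "A", ["0/1", "0/1"]),
            ],
        )
        gm = gio.read_genotypes(path, mode="variant")
        assert gm.n_samples == 2 and gm.n_loci == 3
        assert gm.calls.tolist() == [[0, 2, 1], [1, MISSING, 1]]
        assert not gm.invariant_flag.any()

    def test_allsites_flags_invariant(self, tmp_path):
        records = [("chr1", p, "A", ".", ["0/0", "0/0"]) for p in range(1, 9)]
        records += [
            ("chr1", 100, "A", "T", ["0/1", "0/0"]),
            ("chr1", 101, "C", "G", ["1/1", "0/1"]),
        ]
        path = write_minimal_vcf(tmp_path / "t.vcf", records)
        gm = gio.read_genotypes(path, mode="all-sites")
        assert gm.n_loci == 10
        assert int(gm.invariant_flag.sum()) == 8
        # variant-only mode drops the monomorphic records
        gmv = gio.read_genotypes(path, mode="variant")
        assert gmv.n_loci == 2

    def test_indels_and_multiallelics_excluded(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "t.vcf",
            [
                ("chr1", 10, "A", "T", ["0/0", "0/1"]),
                ("chr1", 20, "AT", "A", ["0/1", "0/0"]),  # indel
                ("chr1", 30, "C", "G,T", ["1/2", "0/0"]),  # multiallelic
                ("chr1", 40, "G", "C", ["0/1", "1/1"]),
                ("chr1", 50, "T", "TA", ["0/0", "0/1"]),  # insertion
            ],
        )
        gm = gio.read_genotypes(path)
        assert gm.n_loci == 2
        assert [l[1] for l in gm.loci] == [10, 40]

    def test_haploid_call_raises(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "t.vcf", [("chr1", 10, "A", "T", ["0", "0/1"])]
        )
        with pytest.raises(ValueError, match="chr1:10"):
            gio.read_genotypes(path)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(IOError):
            gio.read_genotypes(tmp_path / "nope.vcf")

    def test_vcf_round_trip(self, tmp_path):
        gm = make_gm([[0, 1, 2, MISSING], [2, 1, 0, 0], [1, MISSING, 2, 1]])
        gio.write_vcf(gm, tmp_path / "rt.vcf")
        back = gio.read_genotypes(tmp_path / "rt.vcf")
        assert back.samples == gm.samples
        assert back.loci == gm.loci
        assert np.array_equal(back.calls, gm.calls)

    def test_tsv_round_trip(self, tmp_path):
        gm = make_gm([[0, 1, MISSING], [2, 0, 1]])
        gm.to_tsv(tmp_path / "g.tsv")
        back = GenotypeMatrix.from_tsv(tmp_path / "g.tsv")
        assert back.samples == gm.samples and back.loci == gm.loci
        assert np.array_equal(back.calls, gm.calls)


class TestFilterSites:
    def test_mac_boundary(self):
        # alt count 2 < mac_min 3 -> dropped; need a passing site to survive
        calls = [[1, 1], [1, 1], [0, 1], [0, 1], [0, 0], [0, 0]]
        gm = make_gm(calls)
        out = gio.filter_sites(gm, mac_min=3, depth_min=0, depth_max=10**9,
                               max_site_missing=1.0, maf_min=0.0)
        assert out.n_loci == 1 and out.loci[0] == gm.loci[1]

    def test_site_missingness(self):
        col_bad = [MISSING] * 6 + [0, 1, 0, 1]  # 60% missing
        col_ok = [0, 1] * 5
        gm = make_gm(np.array([col_bad, col_ok]).T)
        out = gio.filter_sites(gm, mac_min=0, depth_min=0, depth_max=10**9,
                               max_site_missing=0.5, maf_min=0.0)
        assert out.n_loci == 1

    def test_planted_violations_counted(self, rng):
        """20 sites: 4 fail MAC, 3 fail MAF only, 2 fail missingness -> 11 left.

        With 60 samples: MAC sites carry 2 alt copies; MAF-only sites carry
        3 alt copies (freq 3/120 = 0.025 < 0.05 but MAC passes at 3); clean
        sites carry 30 alt copies.
        """
        n = 60
        cols = []
        for _ in range(11):
            c = np.zeros(n, int); c[:15] = 1; cols.append(c)
        for _ in range(4):  # MAC failures (2 copies)
            c = np.zeros(n, int); c[0] = 2; cols.append(c)
        for _ in range(3):  # MAF failures (3 copies, freq 0.025)
            c = np.zeros(n, int); c[:3] = 1; cols.append(c)
        for _ in range(2):  # missingness failures
            c = np.zeros(n, int); c[:15] = 1; c[15:] = MISSING; cols.append(c)
        gm = make_gm(np.array(cols).T)
        out = gio.filter_sites(gm, mac_min=3, depth_min=0, depth_max=10**9,
                               max_site_missing=0.5, maf_min=0.05)
        assert out.n_loci == 11

    def test_depth_masks_calls_before_site_filters(self):
        calls = np.array([[1, 1], [1, 1], [0, 1], [0, 1]], dtype=np.int8)
        depths = np.array([[2, 50], [200, 50], [50, 50], [50, 50]], dtype=np.int32)
        gm = make_gm(calls, depths=depths)
        # depth bounds knock out 2 of 4 calls at site 0 -> 50% missing passes,
        # but MAC drops to 0+0+0 = 0 there
        out = gio.filter_sites(gm, mac_min=2, depth_min=5, depth_max=100,
                               max_site_missing=0.5, maf_min=0.0)
        assert out.n_loci == 1

    def test_empty_output_raises(self):
        gm = make_gm([[1, 1], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="no sites survive"):
            gio.filter_sites(gm, mac_min=5, depth_min=0, depth_max=10**9,
                             max_site_missing=1.0, maf_min=0.0)

    def test_idempotent(self, rng):
        calls = rng.integers(0, 3, size=(30, 50))
        calls[rng.random((30, 50)) < 0.2] = MISSING
        gm = make_gm(calls)
        kw = dict(mac_min=3, depth_min=0, depth_max=10**9,
                  max_site_missing=0.3, maf_min=0.05)
        once = gio.filter_sites(gm, **kw)
        twice = gio.filter_sites(once, **kw)
        assert twice.loci == once.loci
        assert np.array_equal(twice.calls, once.calls)


class TestFilterSamples:
    def test_threshold_is_strict_exceed(self):
        n_loci = 100
        rates = [0.0, 0.1, 0.3, 0.5, 0.9]
        calls = np.ones((5, n_loci), dtype=np.int8)
        for i, r in enumerate(rates):
            calls[i, : int(r * n_loci)] = MISSING
        gm = make_gm(calls)
        out = gio.filter_samples(gm, 0.3)
        assert out.samples == ["s0", "s1", "s2"]  # 0.30 retained, 0.31+ removed

    def test_sample_at_31pct_removed(self):
        calls = np.ones((2, 100), dtype=np.int8)
        calls[0, :31] = MISSING
        out = gio.filter_samples(make_gm(calls), 0.30)
        assert out.samples == ["s1"]

    def test_all_removed_raises(self):
        calls = np.full((2, 10), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="all samples"):
            gio.filter_samples(make_gm(calls), 0.3)


class TestAllelicSimilarity:
    def test_hand_cases(self):
        gm = make_gm([[0, 1, 2, 0], [1, 1, 2, 0]])
        sim = gio.allelic_similarity(gm)
        assert sim[0, 1] == pytest.approx((0.5 + 3) / 4)
        gm2 = make_gm([[0, 0, 0], [2, 2, 2]])
        assert gio.allelic_similarity(gm2)[0, 1] == 0.0
        gm3 = make_gm([[0, 1, 2], [0, 1, 2]])
        assert gio.allelic_similarity(gm3)[0, 1] == 1.0

    def test_no_shared_loci_is_nan(self):
        gm = make_gm([[0, MISSING], [MISSING, 1]])
        assert np.isnan(gio.allelic_similarity(gm)[0, 1])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_locus_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        calls[rng.random((5, 20)) < 0.2] = MISSING
        gm = make_gm(calls)
        sim = gio.allelic_similarity(gm)
        for i in range(5):
            for j in range(i + 1, 5):
                scores = []
                for l in range(20):
                    a, b = calls[i, l], calls[j, l]
                    if a == MISSING or b == MISSING:
                        continue
                    scores.append(1.0 if a == b else (0.5 if abs(a - b) == 1 else 0.0))
                expected = np.mean(scores) if scores else np.nan
                if np.isnan(expected):
                    assert np.isnan(sim[i, j])
                else:
                    assert sim[i, j] == pytest.approx(expected, abs=1e-12)


class TestDetectClones:
    def test_empty_report(self, rng):
        calls = rng.integers(0, 3, size=(6, 200)).astype(np.int8)
        gm = make_gm(calls)
        sim = gio.allelic_similarity(gm)
        rep = gio.detect_clones(sim, gm.samples, gm.sample_missingness(), 0.99)
        assert rep.pairs == [] and rep.removed == []

    def test_planted_duplicate_detected_higher_missing_removed(self, rng):
        base = rng.integers(0, 3, size=(4, 1000)).astype(np.int8)
        dup = base[0].copy()
        flip = rng.choice(1000, size=5, replace=False)  # 0.5% discordance
        dup[flip] = (dup[flip] + 1) % 3
        dup[:50] = MISSING  # duplicate has more missing data
        calls = np.vstack([base, dup[None, :]])
        gm = make_gm(calls, samples=["a", "b", "c", "d", "a_dup"])
        sim = gio.allelic_similarity(gm)
        rep = gio.detect_clones(sim, gm.samples, gm.sample_missingness(), 0.99)
        assert [tuple(p[:2]) for p in rep.pairs] == [("a", "a_dup")]
        assert rep.removed == ["a_dup"]

    def test_triplet_keeps_least_missing(self, rng):
        base = rng.integers(0, 3, size=(1, 1000)).astype(np.int8)[0]
        a, b, c = base.copy(), base.copy(), base.copy()
        b[:3] = (b[:3] + 1) % 3
        c[:4] = (c[:4] + 1) % 3
        a[:20] = MISSING  # A most missing; B next; C least
        b[:10] = MISSING
        calls = np.vstack([a, b, c, base * 0])
        gm = make_gm(calls, samples=["A", "B", "C", "other"])
        sim = gio.allelic_similarity(gm)
        rep = gio.detect_clones(sim, gm.samples, gm.sample_missingness(), 0.99)
        assert sorted(rep.removed) == ["A", "B"]

    def test_never_removes_both_members_of_pair(self, rng):
        calls = rng.integers(0, 3, size=(3, 500)).astype(np.int8)
        calls[1] = calls[0]
        gm = make_gm(calls)
        sim = gio.allelic_similarity(gm)
        rep = gio.detect_clones(sim, gm.samples, gm.sample_missingness(), 0.99)
        assert len(rep.removed) == 1


class TestPruneLinked:
    def test_duplicated_locus_removed(self, rng):
        calls = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        calls[:, 3] = calls[:, 2]  # perfect collinearity
        gm = make_gm(calls)
        out = gio.prune_linked(gm, window=6, step=3, vif_max=2)
        dropped = set(gm.loci) - set(out.loci)
        assert len(dropped & {gm.loci[2], gm.loci[3]}) == 1

    def test_independent_loci_all_retained(self, rng):
        calls = rng.binomial(2, 0.5, size=(200, 20)).astype(np.int8)
        gm = make_gm(calls)
        out = gio.prune_linked(gm, window=10, step=5, vif_max=2)
        assert out.n_loci == 20

    def test_correlated_triple_pruned_against_bruteforce_vif(self, rng):
        # three strongly correlated loci -> regression R^2 > 0.5, VIF > 2
        n = 400
        z = rng.normal(size=n)
        cols = []
        for _ in range(3):
            x = 0.95 * z + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
            cols.append(np.clip(np.round(x + 1), 0, 2))
        calls = np.array(cols).T.astype(np.int8)
        gm = make_gm(calls)

        # brute-force VIF of locus 0 given 1, 2
        x = calls.astype(float)
        xc = x - x.mean(axis=0)
        beta, *_ = np.linalg.lstsq(xc[:, 1:], xc[:, 0], rcond=None)
        r2 = 1 - ((xc[:, 0] - xc[:, 1:] @ beta) ** 2).sum() / (xc[:, 0] ** 2).sum()
        assert 1 / (1 - r2) > 2

        out = gio.prune_linked(gm, window=3, step=1, vif_max=2)
        assert out.n_loci < 3

    def test_no_window_exceeds_vif_after_prune(self, rng):
        n, L = 150, 40
        base = rng.binomial(2, 0.5, size=(n, L)).astype(np.int8)
        # plant correlated blocks
        for j in range(0, L, 7):
            base[:, j + 1] = np.clip(base[:, j] + rng.integers(-1, 1, n), 0, 2)
        gm = make_gm(base)
        out = gio.prune_linked(gm, window=10, step=5, vif_max=2)
        from dispersalkit.genotype_io import _vif_scores

        g = out.calls.astype(float)
        for start in range(0, out.n_loci - 1, 5):
            block = g[:, start : start + 10]
            vif = _vif_scores(block)
            assert (vif <= 2 + 1e-9).all()
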