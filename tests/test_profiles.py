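import numpy as np
import pandas as pd
import pytest

from tilemark.profiles import (
    BIN_LABELS,
    decile_profiles,
    gene_windows,
    group_mean_profile,
    positional_profile,
    profile_matrix,
    relative_profile,
    select_spaced_genes,
)
from tilemark.types import EnrichmentTrack, GeneModel


def gene(gid="g1", start=1000, end=2000, strand="+", gene_type="protein_coding", chrom="chr1"):
    return GeneModel(gid, chrom, start, end, strand, gene_type)


def track(positions, values, chrom="chr1"):
    return EnrichmentTrack(chrom, np.asarray(positions), np.asarray(values, dtype=float))


class TestGeneWindows:
    def test_fifteen_bins(self):
        assert len(gene_windows(gene())) == 15
        assert len(BIN_LABELS) == 15

    def test_plus_strand_layout_1kb_gene(self):
        w = gene_windows(gene(start=1000, end=2000))
        assert w[0] == (650, 750)        # promoter -350..-250
        assert w[1] == (750, 850)
        assert w[2] == (850, 950)
        assert w[3] == (950, 1050)       # TSS window: -50 bp to 5% of 1000
        assert w[4] == (1050, 1150)      # body 5-15%
        assert w[12] == (1850, 1950)     # body 85-95%
        assert w[13] == (1950, 2050)     # 3' end: 95% to +50
        assert w[14] == (2050, 2150)     # 3' flank: +50..+150

    def test_minus_strand_mirror(self):
        plus = gene_windows(gene(start=1000, end=2000, strand="+"))
        minus = gene_windows(gene(start=1000, end=2000, strand="-"))
        # bin i of the minus gene is the mirror image of bin i of the plus gene
        for (a, b), (c, d) in zip(plus, minus):
            assert (c, d) == (3000 - b, 3000 - a)

    def test_windows_tile_without_gaps(self):
        w = gene_windows(gene(start=5000, end=6237))
        for (_, b), (c, _) in zip(w, w[1:]):
            assert b == c

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError):
            gene_windows(gene(start=100, end=110))


class TestSelectSpacedGenes:
    def test_single_gene_included(self):
        assert select_spaced_genes([gene()]) == [gene()]

    def test_two_plus_genes_100bp_gap(self):
        g1 = gene("g1", 0, 1000)
        g2 = gene("g2", 1100, 2000)
        kept = select_spaced_genes([g1, g2])
        # downstream gene fails the 5' rule (100 < 350); upstream gene's 3'
        # side needs >= 150, so it fails too
        assert kept == []

    def test_two_plus_genes_200bp_gap(self):
        g1 = gene("g1", 0, 1000)
        g2 = gene("g2", 1200, 2000)
        kept = select_spaced_genes([g1, g2])
        assert [g.gene_id for g in kept] == ["g1"]  # 3' gap 200 >= 150; g2 5' gap 200 < 350

    def test_quadratic_all_pairs_oracle(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            genes, pos = [], 0
            for i in range(int(rng.integers(1, 12))):
                pos += int(rng.integers(50, 600))
                L = int(rng.integers(100, 800))
                genes.append(gene(f"g{i}", pos, pos + L, strand=str(rng.choice(["+", "-"]))))
                pos += L
            kept = {g.gene_id for g in select_spaced_genes(genes)}
            for g in genes:
                up_ds = [o for o in genes if o.gene_id != g.gene_id]
                left = max((o.end for o in up_ds if o.end <= g.start), default=None)
                right = min((o.start for o in up_ds if o.start >= g.end), default=None)
                d_left = g.start - left if left is not None else None
                d_right = right - g.end if right is not None else None
                d5, d3 = (d_left, d_right) if g.strand == "+" else (d_right, d_left)
                expected = (d5 is None or d5 >= 350) and (d3 is None or d3 >= 150)
                assert (g.gene_id in kept) == expected, (seed, g.gene_id)


class TestPositionalProfile:
    def test_constant_track(self):
        pos = np.arange(0, 3000, 35)
        prof = positional_profile(track(pos, np.full(pos.size, 2.5)), gene())
        filled = prof.bins[~np.isnan(prof.bins)]
        assert filled.size > 0
        np.testing.assert_allclose(filled, 2.5)

    def test_hand_binning_oracle(self):
        rng = np.random.default_rng(3)
        pos = np.arange(400, 2400, 35)
        vals = rng.normal(size=pos.size)
        g = gene(start=1000, end=2000)
        prof = positional_profile(track(pos, vals), g)
        for i, (a, b) in enumerate(gene_windows(g)):
            member_vals = [v for p, v in zip(pos, vals) if a <= p < b]
            if member_vals:
                assert prof.bins[i] == pytest.approx(np.mean(member_vals))
            else:
                assert np.isnan(prof.bins[i])

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        # probes at 501, 511, ... never hit window boundaries (multiples of 50)
        pos = np.arange(501, 2500, 10)
        vals = rng.normal(size=pos.size)
        g_plus = gene("g1", 1000, 2000, strand="+")
        prof_plus = positional_profile(track(pos, vals), g_plus)
        # reflect the genome about R=3000: probe p -> 3000 - p
        refl_pos = 3000 - pos[::-1]
        refl_vals = vals[::-1]
        g_minus = gene("g1", 1000, 2000, strand="-")
        prof_minus = positional_profile(track(refl_pos, refl_vals), g_minus)
        np.testing.assert_allclose(prof_minus.bins, prof_plus.bins)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        pos = np.arange(0, 3000, 35)
        vals = rng.normal(size=pos.size)
        shift = 70_000
        a = positional_profile(track(pos, vals), gene())
        b = positional_profile(track(pos + shift, vals), gene(start=1000 + shift, end=2000 + shift))
        np.testing.assert_allclose(a.bins, b.bins)

    def test_profile_has_15_bins(self):
        pos = np.arange(0, 3000, 35)
        prof = positional_profile(track(pos, np.zeros(pos.size)), gene())
        assert prof.bins.size == 15

    def test_short_gene_skipped(self, caplog):
        pos = np.arange(0, 3000, 35)
        assert positional_profile(track(pos, np.zeros(pos.size)), gene(start=100, end=110)) is None


class TestGroupMeanProfile:
    def _profiles(self, rng, n=6):
        return pd.DataFrame(rng.normal(size=(n, 15)), index=[f"g{i}" for i in range(n)],
                            columns=list(BIN_LABELS))

    def test_identical_profiles(self):
        profs = pd.DataFrame(np.tile(np.arange(15.0), (4, 1)), index=list("abcd"),
                             columns=list(BIN_LABELS))
        out = group_mean_profile(profs, {g: "x" for g in "abcd"})
        np.testing.assert_allclose(out.loc["x"], np.arange(15.0))

    def test_missing_bin_excluded_from_mean(self):
        profs = pd.DataFrame(np.ones((3, 15)), index=list("abc"), columns=list(BIN_LABELS))
        profs.iloc[0, 6] = np.nan
        profs.iloc[1, 6] = 3.0
        out = group_mean_profile(profs, {g: "x" for g in "abc"})
        assert out.loc["x"].iloc[6] == pytest.approx(2.0)

    def test_direct_arithmetic_oracle(self, rng):
        profs = self._profiles(rng)
        groups = {f"g{i}": i % 2 for i in range(6)}
        out = group_mean_profile(profs, groups)
        for label in (0, 1):
            members = [f"g{i}" for i in range(6) if i % 2 == label]
            np.testing.assert_allclose(out.loc[label], profs.loc[members].mean(axis=0))

    def test_empty_group_rejected(self, rng):
        profs = self._profiles(rng, 2)
        with pytest.raises(ValueError, match="empty"):
            group_mean_profile(profs.iloc[:0], {})


class TestDecileProfiles:
    def test_twenty_genes_two_per_decile(self, rng):
        profs = pd.DataFrame(rng.normal(size=(20, 15)),
                             index=[f"g{i:02d}" for i in range(20)], columns=list(BIN_LABELS))
        expr = {f"g{i:02d}": float(i) for i in range(20)}
        out = decile_profiles(profs, expr)
        assert len(out) == 10
        # decile 1 holds the two lowest-expression genes
        np.testing.assert_allclose(out.loc[1], profs.loc[["g00", "g01"]].mean(axis=0))

    def test_tie_break_by_gene_id(self, rng):
        profs = pd.DataFrame(rng.normal(size=(10, 15)),
                             index=[f"g{i}" for i in range(10)], columns=list(BIN_LABELS))
        expr = {f"g{i}": 1.0 for i in range(10)}  # all tied
        out1 = decile_profiles(profs, expr)
        out2 = decile_profiles(profs.iloc[::-1], expr)
        np.testing.assert_allclose(out1.values, out2.values)

    def test_too_few_genes_rejected(self, rng):
        profs = pd.DataFrame(rng.normal(size=(5, 15)),
                             index=[f"g{i}" for i in range(5)], columns=list(BIN_LABELS))
        with pytest.raises(ValueError):
            decile_profiles(profs, {f"g{i}": float(i) for i in range(5)})

    def test_planted_monotone_depletion(self):
        # higher expression -> deeper gene-body depletion
        rng = np.random.default_rng(11)
        n = 100
        ids = [f"g{i:03d}" for i in range(n)]
        expr = {gid: float(i) for i, gid in enumerate(ids)}
        body = np.zeros((n, 15))
        for i in range(n):
            body[i, 4:13] = -0.03 * i + rng.normal(0, 0.1, size=9)
        profs = pd.DataFrame(body, index=ids, columns=list(BIN_LABELS))
        out = decile_profiles(profs, expr)
        body_mean = out[[f"B{k}" for k in range(1, 10)]].mean(axis=1)
        assert body_mean.loc[10] < body_mean.loc[1]


class TestRelativeProfile:
    def test_equal_profiles_zero(self, rng):
        profs = pd.DataFrame(rng.normal(size=(4, 15)), index=list("abcd"), columns=list(BIN_LABELS))
        np.testing.assert_allclose(relative_profile(profs, profs.copy()).values, 0.0)

    def test_all_missing_propagates(self, rng):
        a = pd.DataFrame(rng.normal(size=(2, 15)), index=list("ab"), columns=list(BIN_LABELS))
        b = pd.DataFrame(np.nan, index=list("ab"), columns=list(BIN_LABELS))
        assert relative_profile(a, b).isna().all().all()

    def test_elementwise_oracle(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 15)), index=list("abc"), columns=list(BIN_LABELS))
        b = pd.DataFrame(rng.normal(size=(3, 15)), index=list("abc"), columns=list(BIN_LABELS))
        np.testing.assert_allclose(relative_profile(a, b).values, a.values - b.values)

    def test_schema_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(2, 15)), index=list("ab"), columns=list(BIN_LABELS))
        b = a.iloc[::-1]
        with pytest.raises(ValueError):
            relative_profile(a, b)


class TestProfileMatrix:
    def test_uniform_track_constant_group_means(self, rng):
        pos = np.arange(0, 50_000, 35)
        tr = track(pos, np.full(pos.size, 1.7))
        genes = [gene(f"g{i}", 2000 + i * 5000, 2000 + i * 5000 + 1500,
                      strand=str(rng.choice(["+", "-"]))) for i in range(8)]
        mat = profile_matrix(tr, genes)
        means = group_mean_profile(mat, {g.gene_id: g.gene_id < "g4" for g in genes})
        filled = means.values[~np.isnan(means.values)]
        np.testing.assert_allclose(filled, 1.7)
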