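"""ABBA-BABA polarization, pattern weights, D, and block jackknife.

The exhaustive oracle used throughout: for haploid-coded single-individual
populations (every dosage 0 or 2), each retained site is literally one of the
four-taxon patterns, so ABBA/BABA sums must equal direct pattern counts.
"""

import numpy as np
import pandas as pd
import pytest

from introkit import abbababa, simdata
from introkit.abbababa import (
    DStatError,
    assign_blocks,
    block_jackknife,
    dstat,
    polarize,
    qp_dstat_table,
    site_patterns,
)
from conftest import make_matrix


def count_patterns_oracle(g1, g2, g3):
    """Exhaustive ABBA/BABA counting for haploid-coded trios (0 = ancestral
    allele A, 1 = derived allele B); outgroup is ancestral by construction.

    With taxon order (P1, P2, Test, Outgroup): ABBA = sites where the Test
    individual shares the derived allele with P1 against P2; BABA = P1 with
    P2 against Test.
    """
    abba = baba = 0
    for a, b, c in zip(g1, g2, g3):
        if (a, b, c) == (1, 0, 1):
            abba += 1
        elif (a, b, c) == (1, 1, 0):
            baba += 1
    return abba, baba


def pf_frame(p1, p2, p3, blocks=None):
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(p1),
            "pos": np.arange(1, len(p1) + 1),
            "p1": p1,
            "p2": p2,
            "p3": p3,
        }
    )
    if blocks is not None:
        df["block"] = blocks
    return df


class TestPolarize:
    def test_outgroup_ref_homozygote_defines_derived_freq(self):
        # samples: p1, p2, p3, outgroup; one locus each
        m = make_matrix([[1], [2], [0], [0]])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        assert len(pf) == 1
        assert pf.iloc[0][["p1", "p2", "p3"]].tolist() == [0.5, 1.0, 0.0]

    def test_alt_homozygous_outgroup_flips_polarity(self):
        m = make_matrix([[1], [2], [0], [2]])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        assert pf.iloc[0][["p1", "p2", "p3"]].tolist() == [0.5, 0.0, 1.0]

    def test_heterozygous_outgroup_site_dropped(self):
        m = make_matrix([[1, 1], [2, 2], [0, 0], [1, 0]])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        assert list(pf["pos"]) == [20]

    def test_polymorphic_outgroup_pair_dropped(self):
        m = make_matrix([[1, 1], [2, 2], [0, 0], [0, 0], [2, 0]])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4", "s5"])
        assert list(pf["pos"]) == [20]

    def test_missing_in_involved_sample_drops_site(self):
        m = make_matrix([[1, 1], [2, 2], [0, 1], [0, 0]], missing=[(0, 0)])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        assert list(pf["pos"]) == [20]

    def test_sites_with_no_derived_variation_dropped(self):
        m = make_matrix([[0, 1], [0, 2], [0, 0], [0, 0]])
        pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        assert list(pf["pos"]) == [20]

    def test_reference_allele_column_mode_matches_sample_mode(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(3, 40))
        m_og = make_matrix(np.vstack([dos, np.zeros((1, 40), dtype=int)]))
        pf_sample = polarize(m_og, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
        m = make_matrix(dos)
        pf_ref = polarize(
            m, ["s1"], ["s2"], ["s3"], ancestral_alleles=np.zeros(40, dtype=int)
        )
        pd.testing.assert_frame_equal(pf_sample, pf_ref)

    def test_injected_outgroup_heterozygosity_drops_those_sites(self):
        cfg = simdata.SimulationConfig(n_loci=300, seed=8)
        matrix, _ = simdata.simulate_dataset(cfg)
        het_sites = [5, 17, 100]
        gt = matrix.gt.copy()
        out_row = matrix.sample_ids.index("OUT1")
        gt[out_row, het_sites] = [0, 1]
        from introkit.genio import GenotypeMatrix

        m = GenotypeMatrix(matrix.sample_ids, matrix.loci, gt, matrix.populations)
        pf_all = polarize(
            matrix, ["A1"], ["B2"], ["B1"], outgroup_samples=["OUT1"]
        )
        pf_het = polarize(m, ["A1"], ["B2"], ["B1"], outgroup_samples=["OUT1"])
        key = lambda df: set(zip(df["chrom"], df["pos"]))
        injected = key(matrix.loci.iloc[het_sites].assign(chrom=matrix.loci["chrom"].iloc[het_sites]))
        assert key(pf_all) - key(pf_het) == injected & key(pf_all)

    def test_multiallelic_input_rejected(self):
        m = make_matrix([[0], [1], [2], [0]], alt_counts=[2])
        with pytest.raises(DStatError, match="multiallelic"):
            polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])


class TestSitePatterns:
    def test_pure_abba_site(self):
        abba, baba = site_patterns(pf_frame([1.0], [0.0], [1.0]))
        assert (abba[0], baba[0]) == (1.0, 0.0)

    def test_pure_baba_site(self):
        abba, baba = site_patterns(pf_frame([1.0], [1.0], [0.0]))
        assert (abba[0], baba[0]) == (0.0, 1.0)

    def test_haploid_toy_equals_pattern_counting(self):
        rng = np.random.default_rng(3)
        g1, g2, g3 = rng.integers(0, 2, size=(3, 12))
        abba_o, baba_o = count_patterns_oracle(g1, g2, g3)
        abba, baba = site_patterns(pf_frame(g1, g2, g3))
        assert abba.sum() == abba_o
        assert baba.sum() == baba_o


class TestDstat:
    def test_equal_sums_give_zero(self):
        res = dstat(pf_frame([1, 1], [0, 1], [1, 0]))
        assert res.d == 0.0

    def test_all_abba_gives_one(self):
        res = dstat(pf_frame([1, 1], [0, 0], [1, 1]))
        assert res.d == 1.0
        assert res.n_snps == 2

    def test_zero_denominator_raises(self):
        with pytest.raises(DStatError, match="undefined"):
            dstat(pf_frame([0.0], [1.0], [1.0]))

    def test_swapping_sister_pair_negates_d(self):
        rng = np.random.default_rng(1)
        p1, p2, p3 = rng.uniform(size=(3, 50))
        d_fwd = dstat(pf_frame(p1, p2, p3)).d
        d_rev = dstat(pf_frame(p1, p3, p2)).d
        assert d_fwd == pytest.approx(-d_rev, abs=1e-12)


def naive_jackknife(pf):
    """Independent delete-one-block reimplementation (plain loops)."""
    abba, baba = site_patterns(pf)
    d_full = (abba.sum() - baba.sum()) / (abba.sum() + baba.sum())
    loo = []
    for b in sorted(set(pf["block"])):
        keep = (pf["block"] != b).to_numpy()
        if (abba[~keep].sum() + baba[~keep].sum()) == 0:
            continue
        loo.append(
            (abba[keep].sum() - baba[keep].sum()) / (abba[keep].sum() + baba[keep].sum())
        )
    loo = np.array(loo)
    m = len(loo)
    se = np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())
    return se, d_full / se if se > 0 else np.inf, m


class TestBlockJackknife:
    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(7)
        pf = pf_frame(*rng.uniform(size=(3, 40)), blocks=np.repeat([0, 1, 2, 3], 10))
        se, z, m = block_jackknife(pf)
        se_o, z_o, m_o = naive_jackknife(pf)
        assert se == pytest.approx(se_o, abs=1e-12)
        assert z == pytest.approx(z_o, abs=1e-9)
        assert m == m_o == 4

    def test_identical_blocks_degenerate_se(self):
        # each block holds one ABBA and one BABA site -> D = 0 everywhere
        pf = pf_frame([1, 1, 1, 1], [0, 1, 0, 1], [1, 0, 1, 0], blocks=[0, 0, 1, 1])
        se, z, m = block_jackknife(pf)
        assert se == 0.0
        assert z == 0.0

    def test_degenerate_se_with_nonzero_d_flags_infinite_z(self):
        pf = pf_frame([1, 1], [0, 0], [1, 1], blocks=[0, 1])
        se, z, m = block_jackknife(pf)
        assert se == 0.0 and np.isinf(z) and z > 0

    def test_uninformative_blocks_skipped(self):
        pf = pf_frame([1, 0, 1], [0, 0, 0], [1, 0, 1], blocks=[0, 1, 2])
        _, _, m = block_jackknife(pf)
        assert m == 2

    def test_single_block_rejected(self):
        pf = pf_frame([1, 1], [0, 0], [1, 1], blocks=[0, 0])
        with pytest.raises(DStatError, match="blocks"):
            block_jackknife(pf)

    def test_equal_count_block_assignment(self):
        pf = assign_blocks(pf_frame([1.0] * 100, [0.0] * 100, [1.0] * 100), n_blocks=10)
        counts = pf.groupby("block").size()
        assert len(counts) == 10
        assert counts.min() == counts.max() == 10


class TestQpDstatTable:
    def test_unknown_names_listed(self, sim_separated):
        _, matrix, _ = sim_separated
        with pytest.raises(DStatError, match="ghost"):
            qp_dstat_table(matrix, "outgroup", [("speciesA", "ghost", "B1")])

    def test_empty_trio_list_gives_empty_table(self, sim_separated):
        _, matrix, _ = sim_separated
        table = qp_dstat_table(matrix, "outgroup", [])
        assert len(table) == 0
        assert list(table.columns)[:4] == ["Outgroup", "Pop1", "Pop2", "Pop3"]

    def test_design_with_varying_test_sample(self, sim_separated):
        # the study design: same P1/P2, each remaining conspecific as Test
        _, matrix, _ = sim_separated
        trios = [("A1", "B1", t) for t in ("B2", "B3", "B4")]
        table = qp_dstat_table(matrix, "outgroup", trios, n_blocks=20)
        assert list(table["Pop3"]) == ["B2", "B3", "B4"]
        assert (table["nSNPs"] > 0).all()

    def test_introgression_yields_positive_d(self):
        cfg = simdata.SimulationConfig(n_loci=10_000, introgression_alpha=0.05, seed=3)
        matrix, _ = simdata.simulate_dataset(cfg)
        pops = dict(matrix.populations)
        pops["B1"] = "focal"
        from introkit.genio import GenotypeMatrix

        m = GenotypeMatrix(matrix.sample_ids, matrix.loci, matrix.gt, pops)
        table = qp_dstat_table(m, "outgroup", [("speciesA", "speciesB", "B1")])
        assert table["D"][0] > 0


class TestExactOracleEquivalence:
    def test_haploid_instances_match_exhaustive_counting(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = rng.integers(4, 21)
            g = rng.integers(0, 2, size=(3, n))
            if not (g[0] & (g[1] ^ g[2])).any():
                continue  # no informative site; D undefined
            m = make_matrix(np.vstack([2 * g, np.zeros((1, n), dtype=int)]))
            pf = polarize(m, ["s1"], ["s2"], ["s3"], outgroup_samples=["s4"])
            res = dstat(pf) if len(pf) else None
            abba_o, baba_o = count_patterns_oracle(*g)
            if abba_o + baba_o == 0:
                assert res is None or res.abba + res.baba == 0
                continue
            assert res.abba == abba_o
            assert res.baba == baba_o
            assert res.d == pytest.approx(
                (abba_o - baba_o) / (abba_o + baba_o), abs=1e-12
            )


def test_null_simulation_mean_d_near_zero():
    """With no introgression the sister pair is exchangeable: E[D] = 0."""
    ds = []
    for seed in range(30):
        cfg = simdata.SimulationConfig(n_loci=4000, introgression_alpha=0.0, seed=seed)
        matrix, _ = simdata.simulate_dataset(cfg)
        pf = polarize(
            matrix, ["A1", "A2", "A3"], ["B2", "B3", "B4", "B5"], ["B1"],
            outgroup_samples=["OUT1"],
        )
        ds.append(dstat(pf).d)
    ds = np.array(ds)
    assert abs(ds.mean()) < 3 * ds.std(ddof=1) / np.sqrt(len(ds))
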