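"""Genotype I/O, QC filters and the exact HWE mid-p test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dhdrift.genotype_io import (
    apply_exclusion_list,
    MISSING,
    GenotypeMatrix,
    SampleSheet,
    SiteCounts,
    define_alternative_allele,
    filter_hwe,
    filter_missingness,
    filter_monomorphic,
    hwe_exact_midp,
    imputation_error_rate,
    intersect_panels,
    mask_dh_heterozygotes,
    read_genotypes,
    site_counts,
    write_vcf,
)
from conftest import make_matrix


def write_tiny_vcf(path, records, samples=("A", "B")):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            fh.write(rec + "\n")


class TestReadGenotypes:
    @pytest.mark.parametrize(
        "gt,expected",
        [("0/1", 1), ("./.", MISSING), ("1|0", 1), ("1/1", 2), ("0|0", 0)],
    )
    def test_dosage_coding(self, tmp_path, gt, expected):
        p = tmp_path / "t.vcf"
        write_tiny_vcf(p, [f"1\t100\trs1\tA\tG\t.\t.\t.\tGT\t{gt}\t0/0"])
        gm = read_genotypes(p)
        assert gm.dosages[0, 0] == expected

    def test_phase_retained(self, tmp_path):
        p = tmp_path / "t.vcf"
        write_tiny_vcf(p, ["1\t100\trs1\tA\tG\t.\t.\t.\tGT\t1|0\t0/1"])
        gm = read_genotypes(p)
        assert tuple(gm.haplotypes[0, 0]) == (1, 0)
        # unphased het carries no haplotype information
        assert tuple(gm.haplotypes[1, 0]) == (MISSING, MISSING)
        assert gm.dosages[1, 0] == 1

    def test_multiallelic_rejected_with_locus(self, tmp_path):
        p = tmp_path / "t.vcf"
        write_tiny_vcf(p, ["1\t123\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0"])
        with pytest.raises(ValueError, match="1:123"):
            read_genotypes(p)

    def test_indel_rejected(self, tmp_path):
        p = tmp_path / "t.vcf"
        write_tiny_vcf(p, ["1\t55\trs1\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0"])
        with pytest.raises(ValueError, match="1:55"):
            read_genotypes(p)

    def test_unknown_sample_named_in_error(self, tmp_path):
        p = tmp_path / "t.vcf"
        write_tiny_vcf(p, ["1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t0/0"])
        sheet = SampleSheet(
            pd.DataFrame({"sample": ["A"], "accession": ["X"], "population": ["LR"]})
        )
        with pytest.raises(ValueError, match="B"):
            read_genotypes(p, sheet)

    def test_round_trip_preserves_everything(self, tmp_path, small_sim):
        p = tmp_path / "rt.vcf"
        write_vcf(small_sim.lr, p)
        back = read_genotypes(p)
        assert back.samples == small_sim.lr.samples
        np.testing.assert_array_equal(back.dosages, small_sim.lr.dosages)
        np.testing.assert_array_equal(back.haplotypes, small_sim.lr.haplotypes)
        pd.testing.assert_frame_equal(back.sites, small_sim.lr.sites)


class TestAlleleHarmonization:
    def test_major_alt_flipped(self):
        gm = make_matrix([[2, 0], [2, 1], [1, 0]])  # site0 freq 5/6, site1 freq 1/6
        (out,) = define_alternative_allele([gm])
        np.testing.assert_array_equal(out.dosages[:, 0], [0, 0, 1])
        np.testing.assert_array_equal(out.dosages[:, 1], [0, 1, 0])
        assert out.sites["ref"].iat[0] == "T" and out.sites["alt"].iat[0] == "A"

    def test_tie_keeps_input_coding(self):
        gm = make_matrix([[2], [0]])  # pooled frequency exactly 0.5
        (out,) = define_alternative_allele([gm])
        np.testing.assert_array_equal(out.dosages, gm.dosages)

    def test_pooled_across_panels(self):
        a = make_matrix([[0]])
        b = make_matrix([[2], [2]])  # pooled freq 4/6 -> flip both panels
        a2, b2 = define_alternative_allele([a, b])
        assert a2.dosages[0, 0] == 2 and b2.dosages[0, 0] == 0

    def test_missing_untouched(self):
        gm = make_matrix([[2, MISSING], [2, 2], [2, 2]])
        (out,) = define_alternative_allele([gm])
        assert out.dosages[0, 1] == MISSING


class TestMaskDhHeterozygotes:
    def test_counts_and_masks_hets(self):
        gm = make_matrix([[0, 1, 2], [1, 1, 0]])
        out, n = mask_dh_heterozygotes(gm)
        assert n == 3
        np.testing.assert_array_equal(out.dosages, [[0, MISSING, 2], [MISSING, MISSING, 0]])

    def test_homozygous_matrix_unchanged(self):
        gm = make_matrix([[0, 2], [2, 0]])
        out, n = mask_dh_heterozygotes(gm)
        assert n == 0
        np.testing.assert_array_equal(out.dosages, gm.dosages)

    def test_count_matches_brute_force_scan(self, rng):
        d = rng.integers(0, 3, size=(10, 10))
        gm = make_matrix(d)
        _, n = mask_dh_heterozygotes(gm)
        assert n == sum(
            1 for i in range(10) for j in range(10) if d[i, j] == 1
        )


class TestFilterMonomorphic:
    def test_fixed_zero_removed_and_cross_panel_polymorphism_kept(self):
        lr = make_matrix([[0, 0], [0, 0]])
        dh = make_matrix([[0, 2], [0, 0]])
        lr2, dh2 = filter_monomorphic([lr, dh])
        assert list(lr2.site_ids) == ["1_101"]  # site 0 (all zero) removed

    def test_matches_brute_force_tally(self, rng):
        d1 = rng.integers(-1, 3, size=(8, 40))
        d2 = rng.integers(-1, 3, size=(6, 40))
        lr, dh = make_matrix(d1), make_matrix(d2)
        lr2, _ = filter_monomorphic([lr, dh])
        kept = set(lr2.site_ids)
        for j in range(40):
            alleles = set()
            for d in (d1, d2):
                for x in d[:, j]:
                    if x == 0:
                        alleles.add("r")
                    elif x == 2:
                        alleles.add("a")
                    elif x == 1:
                        alleles.update("ra")
            expect_kept = len(alleles) != 1
            assert (lr.site_ids[j] in kept) == expect_kept


def hwe_midp_oracle(n_AA, n_Aa, n_aa):
    """Exhaustive mid-p with exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        AA = n - het - aa
        probs[het] = Fraction(
            math.factorial(n) * 2**het,
            math.factorial(AA) * math.factorial(het) * math.factorial(aa),
        )
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_Aa]
    return float(
        sum(p for p in probs.values() if p < p_obs)
        + Fraction(1, 2) * sum(p for p in probs.values() if p == p_obs)
    )


class TestHweExactMidp:
    def test_single_configuration_gives_half(self):
        assert hwe_exact_midp(0, 1, 0) == pytest.approx(0.5)

    def test_matches_enumeration_oracle_at_mode(self):
        assert hwe_exact_midp(25, 50, 25) == pytest.approx(
            hwe_midp_oracle(25, 50, 25), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_counts(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 26))
        geno = r.multinomial(n, [0.3, 0.4, 0.3])
        got = hwe_exact_midp(*geno)
        assert got == pytest.approx(hwe_midp_oracle(*geno), abs=1e-12)
        assert 0 < got <= 1

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_midp(0, 0, 0)


class TestFilterHwe:
    def _panel_with_midp(self, midp_low: bool):
        # all-het panels violate HWE strongly; balanced panels do not
        if midp_low:
            return make_matrix([[1]] * 40)
        return make_matrix([[0]] * 10 + [[1]] * 20 + [[2]] * 10)

    def test_removed_only_when_all_accessions_violate(self):
        all_bad = {f"acc{k}": self._panel_with_midp(True) for k in range(5)}
        assert filter_hwe(all_bad)[0]
        one_good = dict(all_bad)
        one_good["acc3"] = self._panel_with_midp(False)
        assert not filter_hwe(one_good)[0]

    def test_conjunction_matches_per_site_scan(self, rng):
        panels = {
            f"a{k}": make_matrix(rng.integers(0, 3, size=(30, 50))) for k in range(3)
        }
        remove = filter_hwe(panels, alpha=0.5)  # large alpha so both outcomes occur
        for j in range(50):
            ps = []
            for gm in panels.values():
                col = gm.dosages[:, j]
                ps.append(
                    hwe_exact_midp(
                        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
                    )
                )
            assert remove[j] == all(p < 0.5 for p in ps)
        assert remove.sum() > 0 and (~remove).sum() > 0


class TestFilterMissingness:
    def test_all_missing_removed_half_kept(self):
        gm = make_matrix([[MISSING, MISSING], [MISSING, 1]])
        out = filter_missingness(gm, 0.99)
        assert list(out.site_ids) == ["1_101"]

    def test_strict_inequality_at_threshold(self):
        gm = make_matrix([[MISSING, 0], [1, 0]])  # site0 missing fraction exactly 0.5
        assert filter_missingness(gm, 0.5).n_sites == 2
        assert filter_missingness(gm, 0.4).n_sites == 1

    def test_idempotent(self, small_sim):
        once = filter_missingness(small_sim.lr, 0.5)
        twice = filter_missingness(once, 0.5)
        np.testing.assert_array_equal(once.dosages, twice.dosages)


def test_exclusion_list_drops_named_sites():
    gm = make_matrix([[0, 1, 2]])
    out = apply_exclusion_list(gm, {gm.site_ids[1]})
    assert list(out.site_ids) == [gm.site_ids[0], gm.site_ids[2]]
    table = pd.DataFrame({"site_id": [gm.site_ids[0]], "reason": ["off-target"]})
    assert apply_exclusion_list(gm, table).n_sites == 2


class TestIntersectPanels:
    def _panel(self, positions, ref="A", alt="G", dos=None):
        n = len(positions)
        d = dos if dos is not None else [[1] * n]
        sites = pd.DataFrame(
            {
                "chrom": "1",
                "pos": positions,
                "ref": ref,
                "alt": alt,
                "site_id": [f"p{p}" for p in positions],
            }
        )
        return GenotypeMatrix(["S0"], sites, np.asarray(d, dtype=np.int16))

    def test_common_positions_matched(self):
        a = self._panel(list(range(100, 1100, 100)))
        b = self._panel(list(range(100, 600, 100)))
        res = intersect_panels(a, b)
        assert res.a.n_sites == res.b.n_sites == 5

    def test_ref_alt_swap_flips_dosage(self):
        a = self._panel([100], ref="A", alt="G", dos=[[0]])
        b = self._panel([100], ref="G", alt="A", dos=[[0]])
        res = intersect_panels(a, b)
        assert res.flipped_b[0]
        assert res.b.dosages[0, 0] == 2
        assert res.b.sites["ref"].iat[0] == "A"

    def test_incompatible_alleles_dropped_not_fatal(self):
        a = self._panel([100], ref="A", alt="G")
        b = self._panel([100], ref="A", alt="T")
        with pytest.warns(UserWarning, match="1:100"):
            res = intersect_panels(a, b)
        assert res.a.n_sites == 0 and res.dropped == [("1", 100)]


class TestImputationErrorRate:
    def test_formula_plug_in(self):
        truth = make_matrix([[0]] * 50)
        imputed = make_matrix([[0]] * 45 + [[1]] * 5)
        qc = imputation_error_rate(truth, imputed, [truth.site_ids[0]])
        row = qc.per_site.iloc[0]
        assert (row.z, row.k, row.m) == (45, 50, 0)
        assert row.E == pytest.approx(0.1)

    def test_identical_panels_zero_error(self, small_sim):
        ids = list(small_sim.dh.site_ids[:20])
        qc = imputation_error_rate(small_sim.dh, small_sim.dh, ids)
        assert (qc.per_site["E"] == 0).all() and qc.mean_error == 0

    def test_total_mismatch_with_missing(self):
        truth = make_matrix([[0]] * 8 + [[MISSING]] * 2)
        imputed = make_matrix([[2]] * 10)
        qc = imputation_error_rate(truth, imputed, [truth.site_ids[0]])
        assert qc.per_site["E"].iat[0] == pytest.approx(1.0)
        assert qc.per_site["m"].iat[0] == 2

    def test_absent_masked_site_errors(self, small_sim):
        with pytest.raises(KeyError):
            imputation_error_rate(small_sim.dh, small_sim.dh, ["nope"])


def test_site_counts_bounds_and_missing_handling(small_sim):
    counts = site_counts(small_sim.lr, small_sim.dh)
    assert ((counts["l"] >= 0) & (counts["l"] <= counts["n_L"])).all()
    assert ((counts["d"] >= 0) & (counts["d"] <= counts["n_D"])).all()
    assert (counts["n_L"] == 2 * small_sim.lr.n_samples).all()


def test_site_counts_invalid_rejected():
    with pytest.raises(ValueError):
        SiteCounts("x", 5, 4, 0, 10)


def test_filter_chain_idempotent(small_sim):
    lr, dh = small_sim.lr, small_sim.dh
    dh, _ = mask_dh_heterozygotes(dh)
    lr, dh = define_alternative_allele([lr, dh])
    lr, dh = filter_monomorphic([lr, dh])
    remove = filter_hwe({"a": lr})
    lr, dh = lr.take_sites(np.flatnonzero(~remove)), dh.take_sites(np.flatnonzero(~remove))
    lr = filter_missingness(lr)
    # re-running the chain changes nothing
    lr2, dh2 = filter_monomorphic([lr, dh])
    assert lr2.n_sites == lr.n_sites
    assert not filter_hwe({"a": lr2}).any()
    assert filter_missingness(lr2).n_sites == lr2.n_sites
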