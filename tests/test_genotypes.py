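"""PED/MAP round-trips, genotype coding, HWE exact test, and QC filters."""

from math import exp, lgamma, log

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgs.genotypes import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    GenotypeMatrix,
    QcThresholds,
    filter_snps,
    hwe_chisq,
    hwe_test,
    read_ped_map,
    write_ped_map,
)


def make_matrix(codes, chrom="1", bp=None, cm=None):
    codes = np.asarray(codes, dtype=np.int8)
    m, n = codes.shape
    return GenotypeMatrix(
        snps=pd.DataFrame(
            {
                "chrom": chrom,
                "snp_id": [f"s{i}" for i in range(m)],
                "cm": cm if cm is not None else np.arange(m, dtype=float),
                "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
                "a1": "A",
                "a2": "G",
            }
        ),
        samples=[f"x{j}" for j in range(n)],
        codes=codes,
    )


class TestPedMapIO:
    def test_handwritten_round_trip(self, tmp_path):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        ped.write_text(
            "1 s1 0 0 0 0 A A A G 0 0\n"
            "1 s2 0 0 0 0 A G G G C C\n"
        )
        mp.write_text("1 rs1 0.0 100\n1 rs2 0.1 200\n2 rs3 0.0 50\n")
        genos = read_ped_map(ped, mp)
        assert genos.samples == ["s1", "s2"]
        assert genos.codes.tolist() == [[HOM1, HET], [HET, HOM2], [MISSING, HOM1]]
        out_ped, out_map = tmp_path / "o.ped", tmp_path / "o.map"
        write_ped_map(genos, out_ped, out_map)
        again = read_ped_map(out_ped, out_map)
        assert again.codes.tolist() == genos.codes.tolist()
        assert list(again.snps["snp_id"]) == list(genos.snps["snp_id"])

    def test_het_and_missing_coding(self, tmp_path):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        ped.write_text("1 a 0 0 0 0 G A\n1 b 0 0 0 0 0 0\n")
        mp.write_text("1 rs1 0.0 100\n")
        genos = read_ped_map(ped, mp)
        # allele 1 is the lexicographically smaller label
        assert genos.snps["a1"][0] == "A" and genos.snps["a2"][0] == "G"
        assert genos.codes[0, 0] == HET
        assert genos.codes[0, 1] == MISSING

    def test_triallelic_rejected(self, tmp_path):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        ped.write_text("1 a 0 0 0 0 A G\n1 b 0 0 0 0 C C\n")
        mp.write_text("1 rs1 0.0 100\n")
        with pytest.raises(ValueError, match="alleles"):
            read_ped_map(ped, mp)

    def test_row_length_mismatch_rejected(self, tmp_path):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        ped.write_text("1 a 0 0 0 0 A G C\n")
        mp.write_text("1 rs1 0.0 100\n")
        with pytest.raises(ValueError, match="columns"):
            read_ped_map(ped, mp)

    def test_unsorted_map_rejected(self, tmp_path):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        mp.write_text("1 rs1 0.0 200\n1 rs2 0.1 100\n")
        ped.write_text("1 a 0 0 0 0 A A G G\n")
        with pytest.raises(ValueError, match="sorted"):
            read_ped_map(ped, mp)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_round_trip_random_matrices(self, tmp_path_factory, data):
        """Write/read is lossless for arbitrary valid matrices."""
        m = data.draw(st.integers(1, 12))
        n = data.draw(st.integers(1, 6))
        codes = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 3), min_size=n, max_size=n),
                    min_size=m,
                    max_size=m,
                )
            ),
            dtype=np.int8,
        )
        genos = make_matrix(codes)
        d = tmp_path_factory.mktemp("rt")
        write_ped_map(genos, d / "x.ped", d / "x.map")
        again = read_ped_map(d / "x.ped", d / "x.map")
        # allele labels are inferred from the data, so a SNP where allele A
        # was never written anchors its codes to the observed allele; the
        # files themselves round-trip bit-identically
        write_ped_map(again, d / "y.ped", d / "y.map")
        assert (d / "y.ped").read_text() == (d / "x.ped").read_text()
        assert (d / "y.map").read_text() == (d / "x.map").read_text()
        final = read_ped_map(d / "y.ped", d / "y.map")
        assert final.codes.tolist() == again.codes.tolist()


def hwe_enumeration_oracle(n11, n12, n22):
    """Direct enumeration over all heterozygote counts with the observed
    allele counts, via log-factorial probabilities."""
    n = n11 + n12 + n22
    rare = 2 * min(n11, n22) + n12
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def lf(x):
        return lgamma(x + 1)

    hets = np.arange(rare % 2, rare + 1, 2)
    lp = np.array(
        [
            lf(n) - lf((rare - h) // 2) - lf(h) - lf(n - h - (rare - h) // 2) + h * log(2)
            for h in hets.tolist()
        ]
    )
    p = np.exp(lp - lp.max())
    p /= p.sum()
    p_obs = p[hets == n12][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


class TestHwe:
    def test_perfect_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_total_het_deficit_fails_filter(self):
        assert hwe_test(50, 0, 50) < 1e-4

    def test_monomorphic_returns_one(self):
        assert hwe_test(40, 0, 0) == 1.0
        assert hwe_test(0, 0, 40) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            n11, n12, n22 = rng.multinomial(n, [1 / 3, 1 / 3, 1 / 3])
            assert hwe_test(n11, n12, n22) == pytest.approx(
                hwe_enumeration_oracle(n11, n12, n22), rel=1e-9, abs=1e-12
            )

    def test_chisq_agrees_at_large_n(self):
        # large balanced sample: both tests should be far from significance
        assert hwe_chisq(250, 500, 250) > 0.9
        assert hwe_chisq(500, 0, 500) < 1e-4


class TestFilters:
    def build_panel(self):
        """5 SNPs: #0 clean, #1 high missingness, #2 low MAF, #3 HWE
        failure, #4 clean. 4 cases + 100 controls."""
        rng = np.random.default_rng(0)
        n_ctrl = 100
        codes = np.zeros((5, 4 + n_ctrl), dtype=np.int8)
        # clean common SNPs near HWE for #0 and #4
        for i in (0, 4):
            codes[i, :] = rng.choice([0, 1, 2], size=4 + n_ctrl, p=[0.25, 0.5, 0.25])
        # SNP 1: 6 of 100 controls missing (6% > 5%)
        codes[1, :] = 1
        codes[1, 4 : 4 + 6] = MISSING
        # SNP 2: control MAF 0.9% (allele-2 count 2 kept low): one het, rest hom-1
        codes[2, :] = 0
        codes[2, 10] = 1  # MAF = 1/200 = 0.005 < 1%
        # SNP 3: no hets at all among controls (extreme HWE violation)
        codes[3, 4:54] = 0
        codes[3, 54:] = 2
        case_ids = [f"x{j}" for j in range(4)]
        ctrl_ids = [f"x{j}" for j in range(4, 4 + n_ctrl)]
        return make_matrix(codes), case_ids, ctrl_ids

    def test_each_filter_fires_once(self):
        genos, case_ids, ctrl_ids = self.build_panel()
        kept, report = filter_snps(genos, case_ids, ctrl_ids)
        assert report.n_input == 5
        assert report.n_retained == 2
        reasons = dict(zip(report.per_snp["snp_id"], report.per_snp["fail_reasons"]))
        assert "missing_rate" in reasons["s1"]
        assert "maf" in reasons["s2"]
        assert "hwe" in reasons["s3"]
        assert reasons["s0"] == "" and reasons["s4"] == ""
        assert list(kept.snps["snp_id"]) == ["s0", "s4"]

    def test_maf_boundary(self):
        """Control MAF 0.9% removed, 1.1% retained."""
        n_ctrl = 1000
        codes = np.zeros((2, n_ctrl + 2), dtype=np.int8)
        codes[0, 2 : 2 + 18] = 1  # 18/2000 = 0.9%
        codes[1, 2 : 2 + 22] = 1  # 22/2000 = 1.1%
        # keep HWE happy: rare hets only, no rare homs
        genos = make_matrix(codes)
        case_ids = ["x0", "x1"]
        ctrl_ids = [f"x{j}" for j in range(2, n_ctrl + 2)]
        th = QcThresholds(hwe_p=0.0)  # isolate the MAF filter
        kept, report = filter_snps(genos, case_ids, ctrl_ids, th)
        assert list(kept.snps["snp_id"]) == ["s1"]
        maf = report.per_snp["maf"].to_numpy()
        assert maf[0] == pytest.approx(0.009) and maf[1] == pytest.approx(0.011)

    def test_differential_missingness(self):
        n = 60
        codes = np.full((1, 2 * n), HET, dtype=np.int8)
        codes[0, :25] = MISSING  # 25/60 cases missing, 0/60 controls
        genos = make_matrix(codes)
        case_ids = [f"x{j}" for j in range(n)]
        ctrl_ids = [f"x{j}" for j in range(n, 2 * n)]
        th = QcThresholds(max_missing_rate=1.0, min_maf=0.0, hwe_p=0.0)
        kept, report = filter_snps(genos, case_ids, ctrl_ids, th)
        assert report.n_retained == 0
        assert report.per_snp["diff_missing_p"][0] < 1e-5

    def test_retained_plus_removed_equals_input(self):
        genos, case_ids, ctrl_ids = self.build_panel()
        _, report = filter_snps(genos, case_ids, ctrl_ids)
        n_failed = int((~report.per_snp["pass"]).sum())
        assert report.n_retained + n_failed == report.n_input

    def test_empty_controls_rejected(self):
        genos, case_ids, _ = self.build_panel()
        with pytest.raises(ValueError, match="control"):
            filter_snps(genos, case_ids, [])
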