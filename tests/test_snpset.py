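"""Cross-dataset matching, allele harmonisation and effect orientation."""

import numpy as np
import pandas as pd
import pytest

import gwasviz as gv
from gwasviz.errors import MissingColumnError, ValidationError
from gwasviz.snpset import SNPSET_COLUMNS, match_by_alleles, match_by_pos

from conftest import make_dataset


def allele_dataset(rows, label="d"):
    """rows: (chrom, pos, p, ref, alt, beta)"""
    df = pd.DataFrame(rows, columns=["CHROM", "POS", "P", "REF", "ALT", "BETA"])
    return make_dataset(
        {"CHROM": df["CHROM"], "POS": df["POS"], "P": df["P"]},
        label=label,
        REF=list(df["REF"]),
        ALT=list(df["ALT"]),
        BETA=list(df["BETA"]),
    )


@pytest.fixture
def ten_leads():
    """Ten strongly associated, well-separated variants with positive effects."""
    rows = [
        ("1", 1_000_000 + 2_000_000 * i, 1e-12, "A", "G", 0.1 + 0.01 * i)
        for i in range(5)
    ] + [
        ("2", 1_500_000 + 2_000_000 * i, 1e-11, "C", "T", 0.2 + 0.01 * i)
        for i in range(5)
    ]
    return allele_dataset(rows, label="d1")


class TestOrToBeta:
    @pytest.mark.parametrize(
        "odds, beta",
        [(1.0, 0.0), (np.e, 1.0), (0.5, -np.log(2))],
    )
    def test_log_identities(self, odds, beta):
        assert gv.or_to_beta(odds) == pytest.approx(beta)

    def test_inverse_of_exp(self):
        betas = np.linspace(-2, 2, 9)
        assert gv.or_to_beta(np.exp(betas)) == pytest.approx(betas)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            gv.or_to_beta(0.0)
        with pytest.raises(ValidationError):
            gv.or_to_beta(-1.2)


class TestMatchByPos:
    def test_empty_d2_puts_all_in_not_found(self, ten_leads):
        leads = gv.get_lead_snps(ten_leads)
        pairs, not_found = match_by_pos(leads, ten_leads.df.iloc[0:0])
        assert len(pairs) == 0 and len(not_found) == len(leads)

    def test_full_overlap_has_no_not_found(self, ten_leads):
        leads = gv.get_lead_snps(ten_leads)
        pairs, not_found = match_by_pos(leads, ten_leads.df)
        assert len(not_found) == 0 and len(pairs) == len(leads)

    def test_partition_matches_nested_loop_join(self):
        rng = np.random.default_rng(9)
        d1 = allele_dataset(
            [
                ("1", int(p), 1e-9, "A", "G", 0.1)
                for p in rng.choice(np.arange(1, 60) * 100_000, 25, replace=False)
            ]
        )
        d2 = allele_dataset(
            [
                ("1", int(p), 0.5, "A", "G", 0.1)
                for p in rng.choice(np.arange(1, 60) * 100_000, 25, replace=False)
            ]
        )
        leads = gv.get_lead_snps(d1, region_size=1)
        pairs, not_found = match_by_pos(leads, d2.df)
        d2_keys = set(zip(d2.df["CHROM"], d2.df["POS"]))
        expected_found = [
            (c, p) for c, p in zip(leads["CHROM"], leads["POS"]) if (c, p) in d2_keys
        ]
        assert sorted(zip(pairs["CHROM"], pairs["POS"])) == sorted(expected_found)
        assert len(pairs) + len(not_found) == len(leads)


class TestMatchByAlleles:
    def _pairs(self, ref2, alt2, e2=0.5):
        return pd.DataFrame(
            {
                "CHROM": ["1"], "POS": [100], "REF1": ["A"], "ALT1": ["G"],
                "P1": [1e-9], "E1": [0.3], "REF2": [ref2], "ALT2": [alt2],
                "P2": [1e-4], "E2": [e2],
            }
        )

    def test_exact_match_kept_unchanged(self):
        harm, lost = match_by_alleles(self._pairs("A", "G", 0.3))
        assert len(harm) == 1 and len(lost) == 0
        assert harm["E2"].iloc[0] == 0.3

    def test_swapped_match_flips_effect_and_alleles(self):
        harm, lost = match_by_alleles(self._pairs("G", "A", 0.5))
        assert len(harm) == 1
        assert harm["E2"].iloc[0] == -0.5
        assert (harm["REF2"].iloc[0], harm["ALT2"].iloc[0]) == ("A", "G")

    def test_irreconcilable_alleles_routed_out(self):
        harm, lost = match_by_alleles(self._pairs("A", "C"))
        assert len(harm) == 0 and len(lost) == 1

    def test_swap_is_involution(self):
        once, _ = match_by_alleles(self._pairs("G", "A", 0.5))
        again = once.rename(columns={})  # feed the harmonised row back in
        harm, _ = match_by_alleles(again)
        assert harm["E2"].iloc[0] == -0.5  # exact match now: unchanged

    def test_missing_allele_columns_rejected(self):
        with pytest.raises(MissingColumnError):
            match_by_alleles(pd.DataFrame({"REF1": ["A"]}))


class TestFlip:
    def test_positive_rows_untouched_and_zero_is_nonnegative(self):
        df = pd.DataFrame(
            {"E1": [0.4, 0.0], "E2": [0.2, -0.1], "REF1": ["A", "C"],
             "ALT1": ["G", "T"], "REF2": ["A", "C"], "ALT2": ["G", "T"]}
        )
        out = gv.flip_to_positive_allele_for_dat1(df)
        pd.testing.assert_frame_equal(out, df)

    def test_negative_row_fully_flipped(self):
        df = pd.DataFrame(
            {"E1": [-0.4], "E2": [0.2], "REF1": ["A"], "ALT1": ["G"],
             "REF2": ["A"], "ALT2": ["G"]}
        )
        out = gv.flip_to_positive_allele_for_dat1(df)
        assert out.loc[0, "E1"] == 0.4 and out.loc[0, "E2"] == -0.2
        assert (out.loc[0, "REF1"], out.loc[0, "ALT1"]) == ("G", "A")
        assert (out.loc[0, "REF2"], out.loc[0, "ALT2"]) == ("G", "A")

    def test_double_application_is_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "E1": rng.normal(size=20), "E2": rng.normal(size=20),
                "REF1": ["A"] * 20, "ALT1": ["G"] * 20,
                "REF2": ["A"] * 20, "ALT2": ["G"] * 20,
            }
        )
        once = gv.flip_to_positive_allele_for_dat1(df)
        twice = gv.flip_to_positive_allele_for_dat1(once)
        pd.testing.assert_frame_equal(once, twice)


class TestGetSnpset:
    def test_self_comparison_identity(self, ten_leads):
        rep = gv.get_snpset(ten_leads, ten_leads, verbose=True)
        assert len(rep.not_found) == 0 and len(rep.no_allele_match) == 0
        assert (rep.snpset["E1"] == rep.snpset["E2"]).all()
        assert (rep.snpset["P1"] == rep.snpset["P2"]).all()

    def test_fully_swapped_d2_equals_self_comparison(self, ten_leads):
        base = gv.get_snpset(ten_leads, ten_leads)
        swapped = ten_leads.df.copy()
        swapped[["REF", "ALT"]] = swapped[["ALT", "REF"]].to_numpy()
        swapped["BETA"] = -swapped["BETA"]
        d2 = gv.GwasDataset(df=swapped, label="d2")
        got = gv.get_snpset(ten_leads, d2)
        pd.testing.assert_frame_equal(got, base)

    def test_constructed_partition_counts(self, ten_leads):
        """d2 drops 2 lead positions and corrupts alleles on 1 -> 7/2/1."""
        leads = gv.get_lead_snps(ten_leads)
        d2f = ten_leads.df.copy()
        drop_pos = set(leads["POS"].iloc[:2])
        d2f = d2f[~d2f["POS"].isin(drop_pos)].reset_index(drop=True)
        corrupt_pos = leads["POS"].iloc[2]
        d2f.loc[d2f["POS"] == corrupt_pos, "ALT"] = "N"
        rep = gv.get_snpset(ten_leads, gv.GwasDataset(df=d2f, label="d2"), verbose=True)
        assert (len(rep.snpset), len(rep.not_found), len(rep.no_allele_match)) == (7, 2, 1)

    def test_snpset_has_paper_schema(self, ten_leads):
        snp = gv.get_snpset(ten_leads, ten_leads)
        assert set(SNPSET_COLUMNS) <= set(snp.columns)
        assert (snp["E1"] >= 0).all()
        assert (snp["REF1"] == snp["REF2"]).all()
        assert (snp["ALT1"] == snp["ALT2"]).all()

    def test_or_input_converted_to_beta(self):
        rows = [("1", 1_000_000, 1e-12, "A", "G")]
        df = pd.DataFrame(rows, columns=["CHROM", "POS", "P", "REF", "ALT"])
        df["OR"] = [2.0]
        d = gv.GwasDataset(df=df, label="or_d")
        snp = gv.get_snpset(d, d)
        assert snp["E1"].iloc[0] == pytest.approx(np.log(2.0))

    def test_missing_alleles_rejected(self):
        d = make_dataset([("1", 1_000_000, 1e-12)])
        with pytest.raises(MissingColumnError):
            gv.get_snpset(d, d)

    def test_multiallelic_position_resolved_by_alleles(self, ten_leads):
        d2f = ten_leads.df.copy()
        extra = d2f.iloc[[0]].copy()
        extra["ALT"] = "T" if extra["REF"].iloc[0] != "T" else "C"
        d2 = gv.GwasDataset(df=pd.concat([d2f, extra], ignore_index=True), label="d2")
        rep = gv.get_snpset(ten_leads, d2, verbose=True)
        assert len(rep.snpset) == len(gv.get_lead_snps(ten_leads))
        assert len(rep.no_allele_match) == 0


class TestEffectTable:
    def test_significance_flag(self, ten_leads):
        snp = gv.get_snpset(ten_leads, ten_leads)
        table = gv.effect_table(snpset=snp)
        assert table["significant2"].all()  # P2 = 1e-12 / 1e-11 < 5e-8
        snp2 = snp.copy()
        snp2["P2"] = 0.01
        assert not gv.effect_table(snpset=snp2)["significant2"].any()

    def test_empty_snpset_gives_empty_table(self, ten_leads):
        snp = gv.get_snpset(ten_leads, ten_leads).iloc[0:0]
        assert len(gv.effect_table(snpset=snp)) == 0

    def test_gene_labels_from_track(self, ten_leads, sim_track):
        table = gv.effect_table(d1=ten_leads, d2=ten_leads, track=sim_track)
        assert "gene" in table.columns and table["gene"].notna().all()
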