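"""Reading, selection, clumping, proxy search and harmonisation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrcausal import summary_data as sd


def _assoc(snp, chrom, pos, ea, oa, eaf, beta, se, pval):
    return {
        "snp": snp, "chrom": chrom, "pos": pos, "ea": ea, "oa": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval, "n": 10000,
    }


@pytest.fixture
def small_file(tmp_path):
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
        "rs1\t1\t1000\ta\tg\t0.2\t0.1\t0.01\t1e-9\t5000\n"
        "rs2\t2\t2000\tC\tT\t0.4\t-0.05\t0.02\t1e-6\t5000\n"
        "rs3\t3\t3000\tG\tA\t0.1\t0.02\t0.03\t0.2\t5000\n"
    )
    return path


class TestReadWrite:
    def test_well_formed_file_parses_with_uppercased_alleles(self, small_file):
        df = sd.read_summary_stats(small_file)
        assert len(df) == 3
        assert list(df["ea"]) == ["A", "C", "G"]
        assert df.loc[0, "pval"] == 1e-9

    def test_zero_se_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\n"
            "rs1\t1\t1000\tA\tG\t0.2\t0.1\t0.01\t1e-9\n"
            "rs2\t2\t2000\tC\tT\t0.4\t-0.05\t0.0\t1e-6\n"
        )
        with pytest.raises(sd.SummaryDataError, match="line 3"):
            sd.read_summary_stats(path)

    def test_invalid_allele_and_pval_collected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\n"
            "rs1\t1\t1000\tZ\tG\t0.2\t0.1\t0.01\t1e-9\n"
            "rs2\t2\t2000\tC\tT\t0.4\t-0.05\t0.02\t0.0\n"
        )
        with pytest.raises(sd.SummaryDataError) as err:
            sd.read_summary_stats(path)
        assert "line 2" in str(err.value) and "line 3" in str(err.value)

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tP\nrs1\t1\t1\tA\tG\t0.2\t0.1\t0.5\n")
        with pytest.raises(sd.SummaryDataError, match="se"):
            sd.read_summary_stats(path)

    def test_column_map_roundtrip_matches_canonical(self, small_file, tmp_path):
        canonical = sd.read_summary_stats(small_file)
        renamed = tmp_path / "renamed.tsv"
        raw = pd.read_csv(small_file, sep="\t").rename(
            columns={"SNP": "rsid", "BETA": "effect", "SE": "stderr", "P": "pvalue"}
        )
        raw.to_csv(renamed, sep="\t", index=False)
        mapped = sd.read_summary_stats(
            renamed,
            column_map={"rsid": "SNP", "effect": "BETA", "stderr": "SE", "pvalue": "P"},
        )
        pd.testing.assert_frame_equal(canonical, mapped)

    def test_write_then_read_is_identity(self, small_file, tmp_path):
        df = sd.read_summary_stats(small_file)
        out = tmp_path / "rt.tsv"
        sd.write_summary_stats(df, out)
        again = sd.read_summary_stats(out)
        pd.testing.assert_frame_equal(df, again)


class TestSelectInstruments:
    @pytest.mark.parametrize(
        "pvals, threshold, expected",
        [
            ([1e-9, 1e-6, 0.2], 5e-8, 1),  # genome-wide threshold
            ([1e-6, 2e-5], 5e-5, 2),  # liberal threshold
            ([1e-9, 1e-6, 0.2], 1.0, 3),  # vacuous filter
        ],
    )
    def test_threshold_filtering(self, pvals, threshold, expected):
        df = pd.DataFrame(
            [_assoc(f"rs{i}", 1, 1000 * i, "A", "G", 0.2, 0.1, 0.01, p)
             for i, p in enumerate(pvals)]
        )
        kept = sd.select_instruments(df, threshold)
        assert len(kept) == expected
        assert list(kept["pval"]) == sorted(kept["pval"], key=list(df["pval"]).index)

    def test_empty_result_warns_not_raises(self):
        df = pd.DataFrame([_assoc("rs1", 1, 1, "A", "G", 0.2, 0.1, 0.01, 0.5)])
        with pytest.warns(UserWarning, match="empty"):
            out = sd.select_instruments(df, 1e-10)
        assert out.empty


def _brute_force_clump(assocs: pd.DataFrame, ld, r2_max, window_kb):
    """Independent re-derivation: pure-python greedy on (pval, snp) tuples."""
    rows = sorted(assocs.to_dict("records"), key=lambda r: r["pval"])
    kept = []
    for row in rows:
        conflict = False
        for k in kept:
            if str(k["chrom"]) != str(row["chrom"]):
                continue
            if abs(k["pos"] - row["pos"]) > window_kb * 1000:
                continue
            r2 = ld.get(k["snp"], row["snp"]) or 0.0
            if r2 > r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(row)
    return {r["snp"] for r in kept}


class TestClump:
    def test_dominant_low_p_snp_survives(self):
        df = pd.DataFrame(
            [
                _assoc("rs1", 1, 100_000, "A", "G", 0.2, 0.1, 0.01, 1e-10),
                _assoc("rs2", 1, 105_000, "C", "T", 0.3, 0.1, 0.01, 1e-9),
            ]
        )
        ld = sd.LDTable({("rs1", "rs2"): 0.9})
        out = sd.clump(df, ld)
        assert list(out["snp"]) == ["rs1"]

    def test_different_chromosomes_all_retained(self):
        df = pd.DataFrame(
            [
                _assoc("rs1", 1, 100_000, "A", "G", 0.2, 0.1, 0.01, 1e-10),
                _assoc("rs2", 2, 100_000, "C", "T", 0.3, 0.1, 0.01, 1e-9),
            ]
        )
        ld = sd.LDTable({("rs1", "rs2"): 0.99})
        assert len(sd.clump(df, ld)) == 2

    def test_six_snp_instance_matches_brute_force_and_is_valid(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            [
                _assoc(f"rs{i}", 1, 100_000 + i * 3000, "A", "G", 0.2, 0.1, 0.01,
                       float(rng.uniform(1e-12, 1e-4)))
                for i in range(6)
            ]
        )
        pairs = {}
        for a, b in itertools.combinations(range(6), 2):
            pairs[(f"rs{a}", f"rs{b}")] = float(rng.uniform(0, 1))
        ld = sd.LDTable(pairs)
        out = sd.clump(df, ld, r2_max=0.3, window_kb=10)
        kept = set(out["snp"])
        assert kept == _brute_force_clump(df, ld, 0.3, 10)
        # no retained pair violates the rule
        for a, b in itertools.combinations(sorted(kept), 2):
            ra = df.loc[df["snp"] == a].iloc[0]
            rb = df.loc[df["snp"] == b].iloc[0]
            if abs(ra["pos"] - rb["pos"]) <= 10_000:
                assert (ld.get(a, b) or 0.0) <= 0.3
        # every dropped SNP conflicts with a better-p retained SNP
        for _, row in df.iterrows():
            if row["snp"] in kept:
                continue
            conflicts = [
                k for k in kept
                if abs(df.loc[df["snp"] == k, "pos"].iloc[0] - row["pos"]) <= 10_000
                and (ld.get(k, row["snp"]) or 0.0) > 0.3
                and df.loc[df["snp"] == k, "pval"].iloc[0] < row["pval"]
            ]
            assert conflicts

    def test_missing_ld_policy(self):
        df = pd.DataFrame(
            [
                _assoc("rs1", 1, 100_000, "A", "G", 0.2, 0.1, 0.01, 1e-10),
                _assoc("rs2", 1, 105_000, "C", "T", 0.3, 0.1, 0.01, 1e-9),
            ]
        )
        ld = sd.LDTable({("rs1", "rs9"): 0.5})
        with pytest.raises(sd.SummaryDataError):
            sd.clump(df, ld, missing_ld="strict")
        with pytest.warns(UserWarning, match="assumed r2=0"):
            out = sd.clump(df, ld, missing_ld="permissive")
        assert len(out) == 2


class TestFindProxy:
    def _outcome(self):
        return pd.DataFrame(
            [
                _assoc("rsA", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-4),
                _assoc("rsB", 1, 2000, "C", "T", 0.3, 0.1, 0.01, 1e-6),
                _assoc("rsC", 1, 3000, "A", "C", 0.1, 0.1, 0.01, 1e-2),
            ]
        )

    def test_highest_r2_wins(self):
        ld = sd.LDTable({("rsX", "rsA"): 0.95, ("rsX", "rsB"): 0.85, ("rsX", "rsC"): 0.5})
        assert sd.find_proxy("rsX", self._outcome(), ld)["snp"] == "rsA"

    def test_none_when_below_threshold(self):
        ld = sd.LDTable({("rsX", "rsA"): 0.75, ("rsX", "rsB"): 0.5})
        assert sd.find_proxy("rsX", self._outcome(), ld) is None

    def test_tie_breaks_on_pval(self):
        ld = sd.LDTable({("rsX", "rsA"): 0.9, ("rsX", "rsB"): 0.9})
        assert sd.find_proxy("rsX", self._outcome(), ld)["snp"] == "rsB"

    def test_unknown_target_warns_and_returns_none(self):
        ld = sd.LDTable({("rsA", "rsB"): 0.9})
        with pytest.warns(UserWarning, match="absent"):
            assert sd.find_proxy("rsX", self._outcome(), ld) is None


class TestHarmonise:
    def test_allele_swap_flips_outcome_sign(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "G", "A", 0.8, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome)
        row = h.iloc[0]
        assert row["action"] == "sign_flipped"
        assert row["Gamma_hat"] == pytest.approx(-0.05)
        assert row["eaf_outcome"] == pytest.approx(0.2)

    def test_strand_complement_resolved_before_dropping(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "T", "C", 0.2, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome)
        assert h.iloc[0]["action"] == "kept"
        assert h.iloc[0]["Gamma_hat"] == pytest.approx(0.05)

    def test_palindromic_low_maf_aligned(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "T", 0.10, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "T", 0.12, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome, maf_limit=0.3)
        assert h.iloc[0]["action"] == "palindromic_aligned"
        assert h.iloc[0]["Gamma_hat"] == pytest.approx(0.05)

    def test_palindromic_high_maf_dropped(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "C", "G", 0.45, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "C", "G", 0.48, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome, maf_limit=0.3)
        assert h.iloc[0]["action"] == "palindromic_dropped"

    def test_palindromic_minor_allele_disagreement_dropped(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "T", 0.10, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "T", 0.90, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome, maf_limit=0.3)
        assert h.iloc[0]["action"] == "palindromic_dropped"

    def test_missing_snp_dropped_or_proxied(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs9", 1, 1500, "A", "G", 0.2, 0.07, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome)
        assert h.iloc[0]["action"] == "missing_dropped"
        ld = sd.LDTable({("rs1", "rs9"): 0.9})
        h2 = sd.harmonise(exposure, outcome, use_proxies=True, ld=ld)
        assert h2.iloc[0]["action"] == "proxy_substituted"
        assert h2.iloc[0]["proxy_snp"] == "rs9"
        assert h2.iloc[0]["Gamma_hat"] == pytest.approx(0.07)

    def test_duplicate_snp_ids_error(self):
        exposure = pd.DataFrame(
            [
                _assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9),
                _assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9),
            ]
        )
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.05, 0.02, 1e-3)])
        with pytest.raises(sd.SummaryDataError, match="rs1"):
            sd.harmonise(exposure, outcome)

    def test_incompatible_alleles_excluded_with_warning(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "C", 0.2, 0.05, 0.02, 1e-3)])
        with pytest.warns(UserWarning, match="incompatible"):
            h = sd.harmonise(exposure, outcome)
        assert h.empty

    def test_exposure_negative_beta_is_reoriented(self):
        exposure = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, -0.1, 0.01, 1e-9)])
        outcome = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.05, 0.02, 1e-3)])
        h = sd.harmonise(exposure, outcome)
        row = h.iloc[0]
        assert row["gamma_hat"] == pytest.approx(0.1)
        assert row["Gamma_hat"] == pytest.approx(-0.05)
        assert (row["ea"], row["oa"]) == ("G", "A")
        assert row["eaf_exposure"] == pytest.approx(0.8)


@st.composite
def _harmonisable_pair(draw):
    """Random exposure/outcome records over the same SNPs."""
    n = draw(st.integers(2, 6))
    pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G"), ("G", "T")]
    exp_rows, out_rows = [], []
    for i in range(n):
        ea, oa = pairs[draw(st.integers(0, len(pairs) - 1))]
        eaf = draw(st.floats(0.05, 0.28))
        beta = draw(st.floats(-0.5, 0.5).filter(lambda b: abs(b) > 1e-3))
        exp_rows.append(_assoc(f"rs{i}", 1, 1000 * i, ea, oa, eaf, beta, 0.01, 1e-9))
        swap = draw(st.booleans())
        if swap and (ea, oa) not in (("A", "T"), ("C", "G")):
            out_rows.append(
                _assoc(f"rs{i}", 1, 1000 * i, oa, ea, 1 - eaf, -draw(st.floats(-0.3, 0.3)),
                       0.02, 1e-3)
            )
        else:
            out_rows.append(
                _assoc(f"rs{i}", 1, 1000 * i, ea, oa, eaf, draw(st.floats(-0.3, 0.3)),
                       0.02, 1e-3)
            )
    return pd.DataFrame(exp_rows), pd.DataFrame(out_rows)


class TestHarmoniseProperties:
    @given(_harmonisable_pair())
    def test_idempotent_on_retained_output(self, pair):
        exposure, outcome = pair
        h1 = sd.retained(sd.harmonise(exposure, outcome))
        if h1.empty:
            return
        # rebuild summary frames from the aligned output and re-harmonise
        exp2 = pd.DataFrame(
            {
                "snp": h1["snp"], "chrom": h1["chrom"], "pos": h1["pos"],
                "ea": h1["ea"], "oa": h1["oa"], "eaf": h1["eaf_exposure"],
                "beta": h1["gamma_hat"], "se": h1["sigma_x"],
                "pval": h1["pval_exposure"], "n": np.nan,
            }
        )
        out2 = exp2.assign(beta=h1["Gamma_hat"], se=h1["sigma_y"], eaf=h1["eaf_outcome"])
        h2 = sd.retained(sd.harmonise(exp2, out2))
        np.testing.assert_allclose(h2["gamma_hat"], h1["gamma_hat"])
        np.testing.assert_allclose(h2["Gamma_hat"], h1["Gamma_hat"])

    @given(_harmonisable_pair())
    def test_sign_flip_of_exposure_coding_is_invisible(self, pair):
        exposure, outcome = pair
        h1 = sd.retained(sd.harmonise(exposure, outcome))
        flipped = exposure.assign(
            beta=-exposure["beta"],
            ea=exposure["oa"],
            oa=exposure["ea"],
            eaf=1 - exposure["eaf"],
        )
        h2 = sd.retained(sd.harmonise(flipped, outcome))
        np.testing.assert_allclose(h2["gamma_hat"], h1["gamma_hat"], atol=1e-12)
        np.testing.assert_allclose(h2["Gamma_hat"], h1["Gamma_hat"], atol=1e-12)

    @given(_harmonisable_pair())
    def test_retained_records_are_exposure_positive(self, pair):
        exposure, outcome = pair
        h = sd.retained(sd.harmonise(exposure, outcome))
        assert (h["gamma_hat"] >= 0).all()


class TestCrossTraitOverlap:
    def test_flagging_by_threshold(self):
        instrument = pd.DataFrame(
            [
                _assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9),
                _assoc("rs2", 1, 2000, "C", "T", 0.3, 0.1, 0.01, 1e-9),
                _assoc("rs3", 1, 3000, "A", "C", 0.1, 0.1, 0.01, 1e-9),
            ]
        )
        other = pd.DataFrame(
            [
                _assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-3),
                _assoc("rs2", 1, 2000, "C", "T", 0.3, 0.1, 0.01, 1e-9),
            ]
        )
        rep = sd.cross_trait_overlap(instrument, other)
        assert rep.n_flagged == 1
        table = rep.table.set_index("snp")
        assert not table.loc["rs1", "flagged"]
        assert table.loc["rs2", "flagged"]
        assert not table.loc["rs3", "found"]

    def test_empty_intersection(self):
        instrument = pd.DataFrame([_assoc("rs1", 1, 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        other = pd.DataFrame([_assoc("rs9", 1, 9000, "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        rep = sd.cross_trait_overlap(instrument, other)
        assert rep.n_flagged == 0
        assert not rep.table["found"].any()
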