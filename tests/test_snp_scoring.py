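import math

import numpy as np
import pytest

from pipetarget.snp_scoring import (
    GWAS_THRESHOLD,
    PleioSNP,
    expand_ld,
    load_lead_snps,
    score_snp,
)


def snp_score_formula(p, r2):
    """Independent literal evaluation of the SNP score formula."""
    return r2 * (math.log10((1 - p) / p) - math.log10((1 - 5e-8) / 5e-8))


class TestScoreSnp:
    def test_zero_at_genome_wide_threshold_for_any_r2(self):
        for r2 in (0.0, 0.25, 0.8, 1.0):
            assert score_snp(5e-8, r2) == pytest.approx(0.0, abs=1e-12)

    def test_two_log_units_below_threshold(self):
        # p = 5e-10 is two orders of magnitude below 5e-8, and at these
        # magnitudes log10((1-p)/p) is within 1e-7 of -log10(p)
        assert score_snp(5e-10, 1.0) == pytest.approx(2.0, abs=1e-6)

    def test_linear_in_r2(self):
        assert score_snp(5e-10, 0.8) == pytest.approx(0.8 * score_snp(5e-10, 1.0))

    def test_matches_literal_formula_on_grid(self):
        rng = np.random.default_rng(7)
        for p in 10.0 ** (-rng.uniform(1, 30, 25)):
            for r2 in rng.uniform(0, 1, 4):
                assert score_snp(p, r2) == pytest.approx(snp_score_formula(p, r2), rel=1e-12)

    def test_strictly_monotone(self):
        rng = np.random.default_rng(11)
        ps = np.sort(10.0 ** (-rng.uniform(8, 30, 50)))[::-1]
        scores = [score_snp(p, 0.9) for p in ps]
        assert all(a < b for a, b in zip(scores, scores[1:]))
        r2s = np.sort(rng.uniform(0.01, 1.0, 50))
        scores = [score_snp(1e-10, r) for r in r2s]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.5, 1.5])
    def test_domain_error(self, bad_p):
        with pytest.raises(ValueError):
            score_snp(bad_p, 1.0)


from hypothesis import given, settings, strategies as st  # noqa: E402


class TestScoreSnpProperties:
    @settings(max_examples=100, derandomize=True)
    @given(exp=st.floats(min_value=7.4, max_value=29.9),
           r2=st.floats(min_value=1e-6, max_value=1.0),
           shrink=st.floats(min_value=0.1, max_value=0.99))
    def test_sharper_p_scores_strictly_higher(self, exp, r2, shrink):
        p = 10.0 ** (-exp)
        assert score_snp(p * shrink, r2) > score_snp(p, r2)

    @settings(max_examples=100, derandomize=True)
    @given(exp=st.floats(min_value=8.0, max_value=29.9),
           r2=st.floats(min_value=0.0, max_value=1.0))
    def test_retained_snp_scores_nonnegative_and_linear_in_r2(self, exp, r2):
        p = 10.0 ** (-exp)
        s = score_snp(p, r2)
        assert s >= 0.0
        assert s == pytest.approx(r2 * score_snp(p, 1.0), rel=1e-9, abs=1e-12)


def _write_leads(path, rows):
    lines = ["rsid\tchrom\tpos\tpvalue"] + [
        f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}" for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestLoadLeadSnps:
    def test_threshold_is_strict(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "1", 100, "5e-8"), ("rs2", "1", 200, "4.9e-8")])
        snps = load_lead_snps(f)
        assert [s.rsid for s in snps] == ["rs2"]

    def test_duplicates_keep_smallest_p(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "1", 100, "1e-9"), ("rs1", "1", 100, "1e-12")])
        snps = load_lead_snps(f)
        assert len(snps) == 1
        assert snps[0].p_pleio == 1e-12

    def test_filter_count_on_mixed_file(self, tmp_path):
        # 10 rows, 3 at/above the threshold -> 7 retained
        rows = [(f"rs{i}", "2", 1000 + i, f"1e-{9 + i}") for i in range(7)]
        rows += [("rsA", "2", 50, "5e-8"), ("rsB", "2", 60, "1e-6"), ("rsC", "2", 70, "0.5")]
        f = tmp_path / "leads.tsv"
        _write_leads(f, rows)
        assert len(load_lead_snps(f)) == 7

    def test_lead_fields(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "chr3", 500, "1e-10")])
        (s,) = load_lead_snps(f)
        assert s.r2 == 1.0 and s.lead_rsid == "rs1" and s.chrom == "3"
        assert s.s_snp == pytest.approx(snp_score_formula(1e-10, 1.0))

    def test_malformed_p_reports_line(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "1", 100, "not-a-p")])
        with pytest.raises(ValueError, match=":2"):
            load_lead_snps(f)

    def test_nonpositive_position(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "1", 0, "1e-9")])
        with pytest.raises(ValueError, match="position"):
            load_lead_snps(f)

    def test_empty_result_is_hard_error(self, tmp_path):
        f = tmp_path / "leads.tsv"
        _write_leads(f, [("rs1", "1", 100, "1e-4")])
        with pytest.raises(ValueError, match="no SNP"):
            load_lead_snps(f)


def _write_ld(path, rows):
    lines = ["lead_rsid\tproxy_rsid\tr2"] + [f"{a}\t{b}\t{c}" for a, b, c in rows]
    path.write_text("\n".join(lines) + "\n")


def _lead(rsid, p):
    return PleioSNP(rsid=rsid, chrom="1", pos=1000, p_pleio=p, r2=1.0,
                    lead_rsid=rsid, s_snp=snp_score_formula(p, 1.0))


class TestExpandLd:
    def test_r2_below_threshold_excluded(self, tmp_path):
        f = tmp_path / "ld.tsv"
        _write_ld(f, [("rs1", "rsP", 0.79)])
        out = expand_ld([_lead("rs1", 1e-10)], f, r2_min=0.8)
        assert {s.rsid for s in out} == {"rs1"}

    def test_lead_without_proxies_passes_through(self, tmp_path):
        f = tmp_path / "ld.tsv"
        _write_ld(f, [("rsX", "rsP", 0.9)])  # unknown lead, warned + skipped
        out = expand_ld([_lead("rs1", 1e-10)], f)
        assert {s.rsid for s in out} == {"rs1"}

    def test_proxy_inherits_lead_p_and_is_attenuated(self, tmp_path):
        f = tmp_path / "ld.tsv"
        _write_ld(f, [("rs1", "rsP", 0.85)])
        out = {s.rsid: s for s in expand_ld([_lead("rs1", 1e-10)], f)}
        assert out["rsP"].p_pleio == 1e-10
        assert out["rsP"].s_snp == pytest.approx(snp_score_formula(1e-10, 0.85))

    def test_multi_lead_proxy_takes_higher_scoring_assignment(self, tmp_path):
        # lead A: p=1e-10, R2=0.9 -> 0.9*(10 - 7.301) ~ 2.43
        # lead B: p=1e-20, R2=0.8 -> 0.8*(20 - 7.301) ~ 10.16  (wins)
        f = tmp_path / "ld.tsv"
        _write_ld(f, [("rsA", "rsP", 0.9), ("rsB", "rsP", 0.8)])
        out = {s.rsid: s for s in expand_ld([_lead("rsA", 1e-10), _lead("rsB", 1e-20)], f)}
        assert out["rsP"].lead_rsid == "rsB"
        assert out["rsP"].s_snp == pytest.approx(snp_score_formula(1e-20, 0.8))

    def test_all_retained_scores_nonnegative(self, bundle):
        from pipetarget.snp_scoring import frame_to_snps
        import pandas as pd

        leads = load_lead_snps(bundle["files"]["lead_snps"])
        snps = expand_ld(leads, bundle["files"]["ld"])
        assert all(s.s_snp >= 0 for s in snps)
        assert all(s.r2 >= 0.8 for s in snps)
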