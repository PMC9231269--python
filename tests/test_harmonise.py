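"""Harmonisation sign rules, palindrome handling and LD clumping."""

from __future__ import annotations

import numpy as np
import pytest

from metabomr.gwas_io import SnpAssociation
from metabomr.harmonise import (
    HarmonisationError,
    LdMatrix,
    clump,
    harmonise_pair,
    select_instruments,
)

from conftest import make_record, make_table


def pair_tables(x_alleles, y_alleles, eaf_x=0.3, eaf_y=0.3, beta_y=0.2):
    exp = make_table("X", [make_record("rs1", *x_alleles, eaf=eaf_x, beta=0.1)])
    out = make_table("Y", [make_record("rs1", *y_alleles, eaf=eaf_y, beta=beta_y)])
    return exp, out


class TestAlleleAlignment:
    @pytest.mark.parametrize(
        "y_alleles, expected_beta, flipped",
        [
            (("A", "G"), 0.2, False),  # direct match
            (("G", "A"), -0.2, True),  # swapped alleles
            (("T", "C"), 0.2, False),  # strand complement
            (("C", "T"), -0.2, True),  # complement + swap
        ],
    )
    def test_sign_rules(self, y_alleles, expected_beta, flipped):
        exp, out = pair_tables(("A", "G"), y_alleles)
        hset = harmonise_pair(exp, out)
        assert len(hset.records) == 1
        rec = hset.records[0]
        assert rec.beta_y == pytest.approx(expected_beta)
        assert rec.flipped is flipped
        assert rec.beta_x == pytest.approx(0.1)  # exposure side never touched

    def test_irreconcilable_alleles_removed(self):
        exp, out = pair_tables(("A", "G"), ("A", "C"))
        hset = harmonise_pair(exp, out)
        assert hset.records == []
        assert hset.removed == [("rs1", "incompatible_alleles")]

    def test_empty_intersection_is_error(self):
        exp = make_table("X", [make_record("rs1")])
        out = make_table("Y", [make_record("rs2")])
        with pytest.raises(HarmonisationError):
            harmonise_pair(exp, out)


class TestPalindromes:
    def test_high_maf_palindrome_removed(self):
        # MAF 45% on either side exceeds the 42% ambiguity limit
        exp, out = pair_tables(("A", "T"), ("A", "T"), eaf_x=0.45, eaf_y=0.45)
        hset = harmonise_pair(exp, out)
        assert hset.removed == [("rs1", "ambiguous_palindrome")]

    def test_limit_is_strict_and_two_sided(self):
        exp, out = pair_tables(("A", "T"), ("A", "T"), eaf_x=0.42, eaf_y=0.42)
        assert len(harmonise_pair(exp, out).records) == 1  # exactly 42% kept
        exp, out = pair_tables(("A", "T"), ("A", "T"), eaf_x=0.30, eaf_y=0.43)
        assert harmonise_pair(exp, out).removed == [("rs1", "ambiguous_palindrome")]

    def test_frequency_inference_flips_discordant_strand(self):
        exp, out = pair_tables(("C", "G"), ("C", "G"), eaf_x=0.3, eaf_y=0.7)
        rec = harmonise_pair(exp, out).records[0]
        assert rec.beta_y == pytest.approx(-0.2)
        assert rec.flipped and rec.palindromic

    def test_concordant_frequency_kept_unflipped(self):
        exp, out = pair_tables(("C", "G"), ("C", "G"), eaf_x=0.3, eaf_y=0.25)
        rec = harmonise_pair(exp, out).records[0]
        assert rec.beta_y == pytest.approx(0.2)
        assert not rec.flipped

    def test_missing_eaf_palindrome_removed(self):
        exp, out = pair_tables(("A", "T"), ("A", "T"), eaf_x=None)
        assert harmonise_pair(exp, out).removed == [("rs1", "missing_eaf")]


class TestInvariants:
    def test_idempotence(self, rng):
        """Harmonising identical tables keeps everything unflipped, and
        re-harmonising the aligned output changes nothing."""
        records = [
            make_record(f"rs{i}", "A", "G", eaf=float(rng.uniform(0.05, 0.95)),
                        beta=float(rng.normal(0, 0.05)))
            for i in range(20)
        ]
        table = make_table("X", records)
        hset = harmonise_pair(table, make_table("Y", records))
        assert len(hset.records) == 20
        assert not any(r.flipped for r in hset.records)
        aligned = make_table(
            "Y2",
            [
                SnpAssociation(r.snp_id, "A", "G", r.eaf, r.beta_y, r.se_y, 0.5, None)
                for r in hset.records
            ],
        )
        again = harmonise_pair(table, aligned)
        assert [r.beta_y for r in again.records] == [r.beta_y for r in hset.records]
        assert not any(r.flipped for r in again.records)

    def test_sign_coherence(self, rng):
        """Negating every outcome beta negates every harmonised beta_y."""
        recs_x, recs_y, recs_y_neg = [], [], []
        alleles = [("A", "G"), ("G", "A"), ("T", "C"), ("C", "G"), ("A", "T")]
        for i in range(30):
            ea, oa = alleles[i % len(alleles)]
            eaf = float(rng.uniform(0.05, 0.40))
            beta_y = float(rng.normal(0, 0.05))
            recs_x.append(make_record(f"rs{i}", ea, oa, eaf=eaf, beta=0.1))
            recs_y.append(make_record(f"rs{i}", ea, oa, eaf=eaf, beta=beta_y))
            recs_y_neg.append(make_record(f"rs{i}", ea, oa, eaf=eaf, beta=-beta_y))
        exp = make_table("X", recs_x)
        h1 = harmonise_pair(exp, make_table("Y", recs_y))
        h2 = harmonise_pair(exp, make_table("Y", recs_y_neg))
        assert [r.snp_id for r in h1.records] == [r.snp_id for r in h2.records]
        for a, b in zip(h1.records, h2.records):
            assert b.beta_y == pytest.approx(-a.beta_y)


def brute_force_clump_check(table, ld, accepted_ids, p_threshold, r2_threshold):
    """Independent verification of the greedy clumping contract."""
    sig = {r.snp_id: r.pvalue for r in table.records if r.pvalue < p_threshold and r.snp_id in ld}
    accepted = set(accepted_ids)
    # every accepted pair independent
    for a in accepted:
        for b in accepted:
            if a != b:
                assert ld.r2(a, b) < r2_threshold
    # every rejected significant SNP conflicts with an accepted SNP of
    # smaller-or-equal p (equal broken by id)
    for s, p in sig.items():
        if s in accepted:
            continue
        assert any(
            ld.r2(s, a) >= r2_threshold and (sig[a], a) < (p, s) for a in accepted
        ), f"{s} rejected without a dominating accepted conflict"


class TestClump:
    def test_dominant_snp_wins(self):
        table = make_table(
            "X",
            [make_record("rs1", pvalue=1e-10), make_record("rs2", ea="T", oa="C", pvalue=1e-9)],
        )
        ld = LdMatrix(["rs1", "rs2"], np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]))
        kept = clump(table, ld)
        assert kept.snp_ids == ["rs1"]

    def test_independent_snps_all_kept(self, ld_identity):
        records = [make_record(f"rs{i}", pvalue=1e-9) for i in range(5)]
        records.append(make_record("rs_weak", pvalue=1e-3))
        table = make_table("X", records)
        kept = clump(table, ld_identity([r.snp_id for r in records]))
        assert len(kept) == 5 and "rs_weak" not in kept

    def test_block_ld_fixture_matches_oracle(self, rng):
        """20 SNPs in 4 LD blocks: greedy output satisfies the brute-force
        p-minimality and independence contract."""
        n = 20
        r = np.eye(n)
        for b in range(4):
            idx = slice(5 * b, 5 * b + 5)
            block = np.full((5, 5), 0.6 + 0.1 * b)
            np.fill_diagonal(block, 1.0)
            r[idx, idx] = block
        snps = [f"rs{i:02d}" for i in range(n)]
        ld = LdMatrix(snps, r)
        pvals = rng.uniform(0, 2e-8, n)  # some above, some below threshold
        table = make_table("X", [
            make_record(s, pvalue=float(p)) for s, p in zip(snps, pvals)
        ])
        kept = clump(table, ld)
        brute_force_clump_check(table, ld, kept.snp_ids, 5e-8, 0.01)
        # within each fully-linked block at most one survivor
        for b in range(4):
            assert sum(1 for s in kept.snp_ids if 5 * b <= int(s[2:]) < 5 * b + 5) <= 1

    def test_missing_from_ld_dropped_with_warning(self, ld_identity, caplog):
        table = make_table("X", [make_record("rs1", pvalue=1e-9), make_record("rs9", pvalue=1e-9)])
        with caplog.at_level("WARNING"):
            kept = clump(table, ld_identity(["rs1"]))
        assert kept.snp_ids == ["rs1"]
        assert "rs9" in caplog.text


class TestSelectInstruments:
    def test_composition_counts_instruments(self, ld_identity):
        recs = [make_record(f"rs{i}", pvalue=1e-9 if i < 3 else 0.5) for i in range(6)]
        exp = make_table("X", recs)
        out = make_table("Y", [make_record(r.snp_id, beta=0.01) for r in recs])
        hset = select_instruments(exp, out, ld_identity([r.snp_id for r in recs]))
        assert hset.n_snps == 3

    def test_only_instrument_ambiguous_palindrome_gives_k0(self, ld_identity):
        exp = make_table("X", [make_record("rs1", "A", "T", eaf=0.45, pvalue=1e-9)])
        out = make_table("Y", [make_record("rs1", "A", "T", eaf=0.45, beta=0.01)])
        hset = select_instruments(exp, out, ld_identity(["rs1"]))
        assert hset.n_snps == 0
        assert len(hset.removed) == 1
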