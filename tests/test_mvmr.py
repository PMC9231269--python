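"""Multivariable MR: GLS oracle, reductions, conditional F and Q."""

from __future__ import annotations

import numpy as np
import pytest
import statsmodels.api as sm

from metabomr.gwas_io import GwasSummaryTable, SnpAssociation
from metabomr.harmonise import LdMatrix
from metabomr.mvmr import (
    CollinearityError,
    MvmrDataset,
    MvmrError,
    assemble_mvmr,
    conditional_f,
    mvmr_ivw,
    mvmr_q,
)
from metabomr.synthgwas import SimulationScenario, simulate_summary_stats
from metabomr.uvmr import ivw, mean_f


def make_dataset(rng, L=30, K=3, theta=(0.3, 0.1, -0.2), noise=True, rho=None):
    Bx = rng.normal(0, 0.05, (L, K))
    Sx = rng.uniform(0.002, 0.006, (L, K))
    sy = rng.uniform(0.002, 0.006, L)
    by = Bx @ np.asarray(theta[:K]) + (rng.normal(0, sy) if noise else 0.0)
    return MvmrDataset(
        exposure_ids=[f"X{k + 1}" for k in range(K)],
        snp_ids=[f"rs{j}" for j in range(L)],
        Bx=Bx, Sx=Sx, by=by, sy=sy, rho=np.eye(K) if rho is None else rho,
    )


class TestDatasetValidation:
    def test_underidentified_is_error(self, rng):
        with pytest.raises(MvmrError, match="underidentified"):
            make_dataset(rng, L=3, K=3)

    def test_bad_rho_is_error(self, rng):
        bad = np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]])
        with pytest.raises(MvmrError):
            make_dataset(rng, rho=bad)

    def test_missing_rho_warns_and_defaults_to_identity(self, rng):
        Bx = rng.normal(0, 0.05, (10, 2))
        with pytest.warns(UserWarning, match="identity"):
            ds = MvmrDataset(
                exposure_ids=["a", "b"], snp_ids=[f"rs{j}" for j in range(10)],
                Bx=Bx, Sx=np.full((10, 2), 0.01), by=Bx[:, 0] * 0.3,
                sy=np.full(10, 0.01), rho=None,
            )
        assert np.array_equal(ds.rho, np.eye(2))


class TestMvmrIvw:
    def test_k1_reduces_to_univariable_ivw(self, rng):
        ds = make_dataset(rng, L=15, K=1, theta=(0.3,))
        from conftest import make_hset

        hset = make_hset(ds.Bx[:, 0], ds.by, ds.Sx[:, 0], ds.sy)
        uni = ivw(hset)
        multi = mvmr_ivw(ds)
        assert multi.estimates[0] == pytest.approx(uni.estimate, rel=1e-12)
        assert multi.se[0] == pytest.approx(uni.se, rel=1e-12)

    def test_noiseless_recovery_to_machine_precision(self, rng):
        ds = make_dataset(rng, L=20, K=2, theta=(0.3, 0.1), noise=False)
        res = mvmr_ivw(ds)
        assert res.estimates == pytest.approx([0.3, 0.1], abs=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-16)
        assert res.q_p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gls_oracle(self, seed):
        """Estimates and covariance equal statsmodels WLS (no intercept)."""
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng, L=60, K=3)
        res = mvmr_ivw(ds)
        fit = sm.WLS(ds.by, ds.Bx, weights=ds.sy**-2).fit()
        np.testing.assert_allclose(res.estimates, fit.params, rtol=1e-10)
        scale = max(1.0, float(fit.scale))
        np.testing.assert_allclose(
            res.se, np.sqrt(np.diag(fit.normalized_cov_params) * scale), rtol=1e-10
        )

    def test_collinear_exposures_rejected(self, rng):
        Bx1 = rng.normal(0, 0.05, 20)
        Bx = np.column_stack([Bx1, Bx1 * 1.0000001])
        with pytest.raises(CollinearityError, match="prune"):
            mvmr_ivw(
                MvmrDataset(
                    exposure_ids=["a", "b"], snp_ids=[f"rs{j}" for j in range(20)],
                    Bx=Bx, Sx=np.full((20, 2), 0.005), by=Bx1 * 0.3,
                    sy=np.full(20, 0.005), rho=np.eye(2),
                )
            )

    def test_exposure_permutation_equivariance(self, rng):
        ds = make_dataset(rng, L=40, K=3)
        res = mvmr_ivw(ds)
        perm = [2, 0, 1]
        ds_p = MvmrDataset(
            exposure_ids=[ds.exposure_ids[i] for i in perm],
            snp_ids=ds.snp_ids, Bx=ds.Bx[:, perm], Sx=ds.Sx[:, perm],
            by=ds.by, sy=ds.sy, rho=ds.rho[np.ix_(perm, perm)],
        )
        res_p = mvmr_ivw(ds_p)
        np.testing.assert_allclose(res_p.estimates, res.estimates[perm], rtol=1e-10)
        np.testing.assert_allclose(res_p.conditional_f, res.conditional_f[perm], rtol=1e-8)


def grid_conditional_f_oracle(ds, k, span=2.0, n=401):
    """Brute-force minimisation of Q_x,k over a dense delta grid (K = 2)."""
    other = 1 - k
    bk, sk = ds.Bx[:, k], ds.Sx[:, k]
    bo, so = ds.Bx[:, other], ds.Sx[:, other]
    rho_ko = ds.rho[k, other]
    best = np.inf
    for d in np.linspace(-span, span, n):
        v = sk**2 + d**2 * so**2 - 2 * d * rho_ko * sk * so
        q = np.sum((bk - d * bo) ** 2 / v)
        best = min(best, q)
    return best / (ds.L - ds.K + 1)


class TestConditionalF:
    def test_k1_reduces_to_mean_f(self, rng):
        ds = make_dataset(rng, L=15, K=1, theta=(0.3,))
        from conftest import make_hset

        hset = make_hset(ds.Bx[:, 0], ds.by, ds.Sx[:, 0], ds.sy)
        assert conditional_f(ds, 0) == pytest.approx(mean_f(hset), rel=1e-12)

    def test_duplicate_exposure_has_no_conditional_strength(self, rng):
        Bx1 = rng.normal(0, 0.05, 30)
        ds = MvmrDataset(
            exposure_ids=["a", "b"], snp_ids=[f"rs{j}" for j in range(30)],
            Bx=np.column_stack([Bx1, Bx1 * (1 + 1e-6)]),
            Sx=np.full((30, 2), 0.005), by=Bx1 * 0.3, sy=np.full(30, 0.005),
            rho=np.eye(2),
        )
        assert conditional_f(ds, 0) < 0.5
        assert conditional_f(ds, 1) < 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_minimiser(self, seed):
        """Weakly-overlapping exposures (exposure 1 = 0.4 x exposure 2 plus
        its own conditional signal): the iterated-WLS solution matches the
        dense-grid minimiser of Q_x,k within 1%."""
        rng = np.random.default_rng(seed)
        L = 40
        bo = rng.normal(0.05, 0.01, L) * rng.choice([-1, 1], L)
        sk = np.full(L, 0.004)
        bk = 0.4 * bo + rng.normal(0, 2 * sk)  # conditional signal ~ 2 SE
        ds = MvmrDataset(
            exposure_ids=["a", "b"], snp_ids=[f"rs{j}" for j in range(L)],
            Bx=np.column_stack([bk, bo]), Sx=np.column_stack([sk, sk]),
            by=bk * 0.3 + bo * 0.1, sy=np.full(L, 0.003),
            rho=np.array([[1.0, 0.3], [0.3, 1.0]]),
        )
        f = conditional_f(ds, 0)
        oracle = grid_conditional_f_oracle(ds, 0)
        assert abs(f - oracle) / oracle < 0.01

    def test_decreases_with_exposure_correlation(self, rng):
        """Conditional F falls monotonically as the two exposures' SNP-effect
        vectors become more correlated."""
        L = 60
        base = rng.normal(0, 0.05, L)
        indep = rng.normal(0, 0.05, L)
        fs = []
        for lam in [0.0, 0.5, 0.8, 0.95, 0.999]:
            Bx = np.column_stack([base, lam * base + (1 - lam) * indep])
            ds = MvmrDataset(
                exposure_ids=["a", "b"], snp_ids=[f"rs{j}" for j in range(L)],
                Bx=Bx, Sx=np.full((L, 2), 0.005), by=base * 0.3,
                sy=np.full(L, 0.005), rho=np.eye(2),
            )
            fs.append(conditional_f(ds, 0))
        assert all(a > b for a, b in zip(fs, fs[1:]))


class TestMvmrQ:
    def test_exact_fit_gives_zero(self, rng):
        ds = make_dataset(rng, L=20, K=2, theta=(0.3, 0.1), noise=False)
        q, df, p = mvmr_q(ds, np.array([0.3, 0.1]))
        assert q == pytest.approx(0.0, abs=1e-16)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("L, K, expected_df", [(84, 6, 77), (12, 6, 5)])
    def test_degrees_of_freedom_rule(self, rng, L, K, expected_df):
        ds = make_dataset(rng, L=L, K=K, theta=tuple([0.1] * K))
        _, df, _ = mvmr_q(ds, np.zeros(K))
        assert df == expected_df

    def test_nonpositive_df_is_error(self, rng):
        ds = make_dataset(rng, L=4, K=3)
        with pytest.raises(MvmrError):
            mvmr_q(ds, np.zeros(3))


def simple_table(trait_id, snp_betas, se=0.004, p=1e-12):
    return GwasSummaryTable(
        trait_id=trait_id,
        records=[
            SnpAssociation(s, "A", "G", 0.3, b, se, p, None)
            for s, b in snp_betas.items()
        ],
    )


class TestAssemble:
    def _sets(self, trait_snps, tables, outcome):
        from metabomr.harmonise import harmonise_pair

        return [harmonise_pair(tables[t].subset(snps), outcome) for t, snps in trait_snps.items()]

    def test_disjoint_instruments_concatenate(self):
        snps_a = {f"a{i}": 0.05 for i in range(4)}
        snps_b = {f"b{i}": 0.04 for i in range(3)}
        all_snps = {**snps_a, **snps_b}
        ta = simple_table("A", all_snps)
        tb = simple_table("B", all_snps)
        out = simple_table("Y", {s: 0.01 for s in all_snps}, p=0.5)
        ld = LdMatrix.identity(list(all_snps))
        sets = self._sets({"A": list(snps_a), "B": list(snps_b)}, {"A": ta, "B": tb}, out)
        ds = assemble_mvmr(sets, {"A": ta, "B": tb}, out, ld, rho=np.eye(2))
        assert ds.L == 7

    def test_shared_instruments_deduplicate(self):
        snps = {f"s{i}": 0.05 for i in range(5)}
        ta, tb = simple_table("A", snps), simple_table("B", snps)
        out = simple_table("Y", {s: 0.01 for s in snps}, p=0.5)
        ld = LdMatrix.identity(list(snps))
        sets = self._sets({"A": list(snps), "B": list(snps)}, {"A": ta, "B": tb}, out)
        ds = assemble_mvmr(sets, {"A": ta, "B": tb}, out, ld, rho=np.eye(2))
        assert ds.L == 5

    def test_cross_trait_clumping_matches_oracle(self, rng):
        """Block-LD panel: retained SNPs are pairwise independent and every
        rejected SNP conflicts with a retained SNP of smaller min-p."""
        n = 12
        snps = [f"rs{i:02d}" for i in range(n)]
        r = np.eye(n)
        for b in range(3):
            idx = slice(4 * b, 4 * b + 4)
            blk = np.full((4, 4), 0.7)
            np.fill_diagonal(blk, 1.0)
            r[idx, idx] = blk
        ld = LdMatrix(snps, r)
        pa = {s: float(p) for s, p in zip(snps, rng.uniform(1e-12, 1e-9, n))}
        betas = {s: float(b) for s, b in zip(snps, rng.normal(0.05, 0.01, n))}
        ta = GwasSummaryTable("A", [SnpAssociation(s, "A", "G", 0.3, betas[s], 0.004, pa[s], None) for s in snps])
        tb = GwasSummaryTable("B", [SnpAssociation(s, "A", "G", 0.3, betas[s] * 0.5 + 0.01, 0.004, pa[s] * 3, None) for s in snps])
        out = simple_table("Y", {s: 0.01 for s in snps}, p=0.5)
        sets = self._sets({"A": snps[:6], "B": snps[6:]}, {"A": ta, "B": tb}, out)
        ds = assemble_mvmr(sets, {"A": ta, "B": tb}, out, ld, rho=np.eye(2))
        retained = set(ds.snp_ids)
        minp = {s: min(pa[s], pa[s] * 3) for s in snps}
        for a in retained:
            for b in retained:
                if a != b:
                    assert ld.r2(a, b) < 0.01
        for s in snps:
            if s not in retained:
                assert any(ld.r2(s, a) >= 0.01 and minp[a] <= minp[s] for a in retained)

    def test_missing_snp_in_exposure_table_is_error(self):
        snps = {f"s{i}": 0.05 for i in range(5)}
        ta = simple_table("A", snps)
        tb = simple_table("B", {k: v for k, v in list(snps.items())[:3]})  # missing two
        out = simple_table("Y", {s: 0.01 for s in snps}, p=0.5)
        ld = LdMatrix.identity(list(snps))
        sets = self._sets({"A": list(snps), "B": list(snps)[:3]}, {"A": ta, "B": tb}, out)
        with pytest.raises(MvmrError, match="absent"):
            assemble_mvmr(sets, {"A": ta, "B": tb}, out, ld, rho=np.eye(2))


class TestRecovery:
    def test_direct_effects_recovered(self):
        """Three exposures with direct effects (0.29, 0.07, 0.08) and strong
        instruments: every mean estimate within 2 SE over 100 replicates."""
        theta = np.array([0.29, 0.07, 0.08])
        ests = []
        for i in range(100):
            scn = SimulationScenario(
                k_exposures=3, l_snps=60, theta=theta,
                instruments_per_exposure=20, mean_f_target=60.0,
                overlap_fraction=0.0, seed=3000 + i,
            )
            ds = simulate_summary_stats(scn, emit_tables=False).to_mvmr_dataset()
            ests.append(mvmr_ivw(ds).estimates)
        mean_est = np.mean(ests, axis=0)
        np.testing.assert_allclose(mean_est, theta, atol=0.02)
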