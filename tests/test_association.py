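"""CCA with Rao's F, BY-FDR, GWAS calibration, LD clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from facedna.association import (
    bh_fdr_threshold,
    by_fdr_threshold,
    cca_association,
    clump_loci,
    feature_scan,
    gwas_scan,
    ld_r_squared,
)


class TestCCA:
    def test_single_pc_reduces_to_regression_f(self):
        """With q = 1 the test is the classical simple-regression F with
        (1, N-2) degrees of freedom."""
        rng = np.random.default_rng(42)
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        res = cca_association(y, x[:, None])
        lin = stats.linregress(x, y)
        assert res.df1 == 1 and res.df2 == 8
        assert res.canonical_correlation == pytest.approx(abs(lin.rvalue), abs=1e-12)
        assert res.rao_f == pytest.approx(lin.rvalue**2 / (1 - lin.rvalue**2) * 8, rel=1e-10)
        assert res.p_value == pytest.approx(lin.pvalue, rel=1e-9)

    def test_matches_permutation_oracle(self):
        """Analytic Rao-F p-values match a 10,000-permutation null within
        3 Monte-Carlo standard errors over a 20-case grid."""
        B = 10_000
        cases = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            q = 2 if seed % 2 else 5
            N = 200
            S = rng.normal(size=(N, q))
            f = rng.normal(size=N) + (0.12 if seed % 3 == 0 else 0.0) * S[:, 0]
            res = cca_association(f, S)
            Q, _ = np.linalg.qr(S - S.mean(0))
            fc = f - f.mean()
            denom = fc @ fc
            perms = np.stack([rng.permutation(fc) for _ in range(B)], axis=1)
            r2p = np.sum((Q.T @ perms) ** 2, axis=0) / denom
            r2o = res.canonical_correlation**2
            p_perm = (1 + np.sum(r2p >= r2o)) / (B + 1)
            se = np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / B)
            assert abs(res.p_value - p_perm) < 3 * se + 2 / B
            cases += 1
        assert cases == 20

    def test_perfect_correlation_flagged(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(30, 3))
        res = cca_association(S[:, 0], S)
        assert res.saturated
        assert res.canonical_correlation == pytest.approx(1.0, abs=1e-6)
        assert res.p_value > 0

    def test_invariance_to_rescaling_and_rotation(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=80)
        S = rng.normal(size=(80, 4))
        base = cca_association(f, S)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        alt = cca_association(3.5 * f - 2.0, S @ Q)
        assert alt.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert alt.canonical_correlation == pytest.approx(
            base.canonical_correlation, abs=1e-10
        )

    def test_residualization_equivalence(self):
        """Partial CCA equals CCA on pre-residualized feature and scores."""
        rng = np.random.default_rng(3)
        C = rng.normal(size=(100, 2))
        f = rng.normal(size=100) + C @ [0.5, -0.2]
        S = rng.normal(size=(100, 3)) + np.outer(C[:, 0], [0.3, 0.1, 0.0])
        with_cov = cca_association(f, S, covariates=C)

        def resid(y):
            X = np.column_stack([np.ones(100), C])
            return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

        pre = cca_association(resid(f), resid(S))
        assert with_cov.canonical_correlation == pytest.approx(
            pre.canonical_correlation, abs=1e-10
        )

    def test_input_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="missing"):
            cca_association(np.array([1.0, np.nan, 2.0]), rng.normal(size=(3, 1)))
        with pytest.raises(ValueError, match="too small"):
            cca_association(rng.normal(size=5), rng.normal(size=(5, 3)))
        S = rng.normal(size=(30, 2))
        S = np.column_stack([S, S[:, 0]])  # rank deficient
        with pytest.raises(ValueError, match="rank"):
            cca_association(rng.normal(size=30), S)


class TestFDRThresholds:
    def test_single_test_reduces_to_alpha(self):
        assert by_fdr_threshold([0.04], alpha=0.05) == 0.04
        assert by_fdr_threshold([0.06], alpha=0.05) == 0.0

    def test_four_case_hand_enumeration(self):
        """m=4, alpha=0.05: c(4) = 25/12, crit_i = i*0.05/(4*25/12) = 0.006i;
        only p_(1)=0.001 <= 0.006 passes, so the threshold is 0.001."""
        p = [0.001, 0.02, 0.5, 0.9]
        assert by_fdr_threshold(p, alpha=0.05) == pytest.approx(0.001)
        # step-up: a late passing rank rescues everything below it
        p2 = [0.001, 0.005, 0.012, 0.9]
        # crit = 0.006, 0.012, 0.018, 0.024 -> p_(3)=0.012 <= 0.018 passes
        assert by_fdr_threshold(p2, alpha=0.05) == pytest.approx(0.012)

    def test_no_discoveries_when_all_p_one(self):
        assert by_fdr_threshold([1.0] * 10, alpha=0.05) == 0.0
        with pytest.raises(ValueError):
            by_fdr_threshold([], alpha=0.05)
        with pytest.raises(ValueError):
            by_fdr_threshold([0.0, 0.5], alpha=0.05)

    def test_matches_statsmodels_rejections(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(5):
            p = np.concatenate([rng.uniform(0, 1e-3, 5), rng.uniform(0, 1, 50)])
            thr = by_fdr_threshold(p, alpha=0.05)
            reject_sm = multipletests(p, alpha=0.05, method="fdr_by")[0]
            assert np.array_equal(p <= thr if thr > 0 else np.zeros_like(p, bool),
                                  reject_sm)

    def test_by_below_bh_below_alpha(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.2, 100)
        by = by_fdr_threshold(p, alpha=0.05)
        bh = bh_fdr_threshold(p, alpha=0.05)
        assert by <= bh <= 0.05


class TestGWAS:
    @pytest.fixture(scope="class")
    def null_inputs(self):
        rng = np.random.default_rng(99)
        N, S = 300, 1500
        G = rng.binomial(2, rng.uniform(0.1, 0.5, S), size=(N, S)).astype(float)
        scores = {1: rng.normal(size=(N, 5))}
        return G, scores

    def test_null_p_values_are_uniform(self, null_inputs):
        G, scores = null_inputs
        table, _ = gwas_scan(G, [f"s{i}" for i in range(G.shape[1])], scores,
                             maf_min=0.05)
        p = table["p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        rate = np.mean(p <= 0.05)
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < 4 * se

    def test_permuted_genotypes_control_fdr(self, null_inputs):
        G, scores = null_inputs
        rng = np.random.default_rng(1)
        Gp = G[rng.permutation(G.shape[0])]
        table, fdrd = gwas_scan(Gp, [f"s{i}" for i in range(G.shape[1])], scores)
        n_disc = int(np.sum(table["p"] <= fdrd)) if fdrd > 0 else 0
        assert n_disc <= 3  # FDR 0.05 on a global null: discoveries are rare

    def test_missing_dosages_match_complete_case_oracle(self):
        rng = np.random.default_rng(4)
        N = 120
        g = rng.binomial(2, 0.3, N).astype(float)
        g[rng.choice(N, 10, replace=False)] = np.nan
        scores = {1: rng.normal(size=(N, 3))}
        table, _ = gwas_scan(g[:, None], ["snp"], scores, maf_min=0.0)
        m = np.isfinite(g)
        direct = cca_association(g[m], scores[1][m])
        assert table["p"].iloc[0] == pytest.approx(direct.p_value, rel=1e-9)

    def test_constant_column_skipped(self):
        rng = np.random.default_rng(2)
        N = 60
        G = np.column_stack([np.full(N, 2.0), rng.binomial(2, 0.4, N)]).astype(float)
        scores = {1: rng.normal(size=(N, 2))}
        table, _ = gwas_scan(G, ["const", "ok"], scores, maf_min=0.0)
        assert set(table["snp"]) == {"ok"}

    def test_feature_scan_matches_single_cca(self):
        rng = np.random.default_rng(8)
        N = 90
        feats = {"a": rng.normal(size=N), "b": rng.binomial(1, 0.4, N).astype(float)}
        scores = {1: rng.normal(size=(N, 4)), 2: rng.normal(size=(N, 2))}
        C = rng.normal(size=(N, 2))
        table, _ = feature_scan(feats, scores, covariates=C)
        for _, row in table.iterrows():
            direct = cca_association(feats[row["feature"]], scores[row["segment"]], C)
            assert row["p"] == pytest.approx(direct.p_value, rel=1e-9)


def brute_force_clump(sig, G, ids, window, r2min):
    """Independent re-enactment of the greedy rule with explicit loops."""
    idx = {s: j for j, s in enumerate(ids)}
    rows = sorted(sig.to_dict("records"), key=lambda r: (r["p"], r["id"]))
    taken = set()
    loci = []
    for seed in rows:
        if seed["id"] in taken:
            continue
        members = [seed]
        taken.add(seed["id"])
        changed = True
        while changed:
            changed = False
            for cand in rows:
                if cand["id"] in taken or cand["chrom"] != seed["chrom"]:
                    continue
                if not any(abs(cand["pos"] - m["pos"]) <= window for m in members):
                    continue
                a, b = G[:, idx[seed["id"]]], G[:, idx[cand["id"]]]
                r = np.corrcoef(a, b)[0, 1] ** 2
                if r > r2min:
                    members.append(cand)
                    taken.add(cand["id"])
                    changed = True
        loci.append((seed["id"], sorted(m["id"] for m in members)))
    return loci


class TestClumping:
    def test_distant_snps_form_two_loci(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        sig = pd.DataFrame(
            {"id": ["a", "b"], "chrom": [1, 1], "pos": [1_000_000, 11_000_000],
             "p": [1e-10, 1e-8]}
        )
        loci = clump_loci(sig, G, ["a", "b"])
        assert len(loci) == 2

    def test_perfect_copy_joins_the_seed(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 100).astype(float)
        G = np.column_stack([g, g])
        sig = pd.DataFrame(
            {"id": ["a", "b"], "chrom": [2, 2], "pos": [500_000, 600_000],
             "p": [1e-12, 1e-9]}
        )
        loci = clump_loci(sig, G, ["a", "b"])
        assert len(loci) == 1
        assert loci.iloc[0]["peak_snp"] == "a"
        assert loci.iloc[0]["n_snps"] == 2

    def test_randomized_toy_matches_brute_force(self):
        rng = np.random.default_rng(31)
        n_snp = 20
        base = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        cols, chroms, pos = [], [], []
        for j in range(n_snp):
            src = base[:, j % 5]
            noisy = np.where(rng.random(200) < 0.25, rng.binomial(2, 0.4, 200), src)
            cols.append(noisy.astype(float))
            chroms.append(1 + j // 10)
            pos.append(100_000 * (j % 10) + 50_000)
        G = np.column_stack(cols)
        ids = [f"t{j}" for j in range(n_snp)]
        sig = pd.DataFrame(
            {"id": ids, "chrom": chroms, "pos": pos,
             "p": rng.uniform(1e-12, 1e-6, n_snp)}
        )
        got = clump_loci(sig, G, ids, window_bp=250_000, ld_r2_min=0.5)
        want = brute_force_clump(sig, G, ids, 250_000, 0.5)
        got_sets = [(r["peak_snp"], sorted(r["member_snps"])) for _, r in got.iterrows()]
        assert sorted(got_sets) == sorted(want)

    def test_ld_r_squared_handles_missing(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.5, 100).astype(float)
        b = a.copy()
        b[:5] = np.nan
        assert ld_r_squared(a, b) == pytest.approx(1.0)
        assert ld_r_squared(a, np.full(100, 1.0)) == 0.0
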