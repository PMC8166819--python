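"""TMM normalization, differential expression/methylation, aggregation, ORA."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from tmedissect import (
    de_by_tumor_type,
    de_test,
    dmp_test,
    ora_test,
    pan_cancer_aggregate,
    tmm_factors,
)


def oracle_tmm(counts: np.ndarray, ref_i: int | None = None) -> np.ndarray:
    """Independent literal implementation of the trim-and-average steps."""
    lib = counts.sum(axis=1)
    if ref_i is None:
        f75 = np.array([np.quantile(c[c > 0] / l, 0.75) for c, l in zip(counts, lib)])
        ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for i in range(counts.shape[0]):
        o, r, No, Nr = counts[i], counts[ref_i], lib[i], lib[ref_i]
        keep = (o > 0) & (r > 0)
        o, r = o[keep].astype(float), r[keep].astype(float)
        m = np.log2((o / No) / (r / Nr))
        a = 0.5 * np.log2((o / No) * (r / Nr))
        v = (No - o) / (No * o) + (Nr - r) / (Nr * r)
        n = len(m)
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rm, ra = rankdata(m), rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2 ** (np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_all_one(self):
        counts = pd.DataFrame(np.tile(np.arange(1, 21), (4, 1)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_library_doubling_absorbed(self):
        base = np.arange(1, 31)
        counts = pd.DataFrame([base, 2 * base])
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_geometric_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(6, 200)) + 1)
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_handtrace_oracle_inflated_genes(self):
        """50-gene toy with 10 inflated genes in one sample: factors equal an
        independent trace of the stated trim-and-average steps."""
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=(3, 50)) + 1
        counts[2, :10] *= 8  # composition bias in sample 2
        got = tmm_factors(pd.DataFrame(counts))
        np.testing.assert_allclose(got.to_numpy(), oracle_tmm(counts), rtol=1e-10)

    def test_disjoint_support_error(self):
        counts = pd.DataFrame([[5, 5, 0, 0], [4, 6, 0, 0], [0, 0, 3, 7]])
        with pytest.raises(ValueError):
            tmm_factors(counts)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Cross-check against edgeR::calcNormFactors (TMM) via Rscript."""
        rng = np.random.default_rng(11)
        counts = rng.poisson(80, size=(5, 120)) + 1
        counts[1, :15] *= 5
        mat = pd.DataFrame(counts)
        csv = tmp_path / "counts.csv"
        mat.T.to_csv(csv, index=False)  # genes x samples for edgeR
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv(commandArgs(TRUE)[1]))
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.12f", f), sep="\\n")
        """))
        res = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        expected = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(tmm_factors(mat).to_numpy(), expected, rtol=1e-6)


class TestDETest:
    def _toy(self, n_per=20, n_genes=300, fold=None, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.gamma(3, 30, size=n_genes)
        counts = rng.poisson(np.tile(mu, (2 * n_per, 1)))
        labels = pd.Series(
            ["inflamed"] * n_per + ["noninflamed"] * n_per,
            index=[f"s{i}" for i in range(2 * n_per)],
        )
        return pd.DataFrame(counts, index=labels.index), labels

    def test_null_uniform_p(self):
        counts, labels = self._toy(n_per=30, n_genes=500, seed=1)
        res = de_test(counts, labels)
        assert res["logFC"].abs().mean() < 0.2
        assert stats.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_label_negation_negates_logfc(self):
        counts, labels = self._toy(seed=2)
        res1 = de_test(counts, labels)
        flipped = labels.map({"inflamed": "noninflamed", "noninflamed": "inflamed"})
        res2 = de_test(counts, flipped)
        np.testing.assert_allclose(res1["logFC"], -res2["logFC"], atol=1e-10)

    def test_small_group_error_and_skip(self):
        counts, labels = self._toy(n_per=2)
        with pytest.raises(ValueError, match=">= 3 samples"):
            de_test(counts, labels)
        tt = pd.Series("only", index=counts.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = de_by_tumor_type(counts, labels, tt)
        assert out.empty

    def test_fdr_bounds(self):
        counts, labels = self._toy(seed=3)
        res = de_test(counts, labels)
        assert ((res["fdr"] >= res["p_value"] - 1e-12) & (res["fdr"] <= 1.0)).all()


class TestBH:
    def test_worked_stepup_case(self):
        """p = (.01, .02, .03, .04), m = 4 -> all adjusted to 0.04."""
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_under_permutation(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = multipletests(p, method="fdr_bh")[1]
        perm = rng.permutation(50)
        adj_perm = multipletests(p[perm], method="fdr_bh")[1]
        np.testing.assert_allclose(adj[perm], adj_perm)


class TestPanCancer:
    def _table(self, patterns):
        rows = []
        for mol, tts in patterns.items():
            for tt, (lfc, fdr) in tts.items():
                rows.append((mol, lfc, 1e-4, fdr, tt, "mRNA"))
        return pd.DataFrame(
            rows, columns=["molecule", "logFC", "p_value", "fdr", "tumor_type", "molecule_class"]
        )

    def test_four_of_ten_included_three_excluded(self):
        patterns = {
            "gA": {f"T{i}": (2.0, 0.01) for i in range(4)},
            "gB": {f"T{i}": (2.0, 0.01) for i in range(3)},
        }
        patterns["gB"]["T9"] = (0.5, 0.01)  # fails |logFC|
        sig = pan_cancer_aggregate(self._table(patterns))
        assert sig.members == ["gA"]
        assert set(sig.membership["gA"].values()) == {"up_in_noninflamed"}

    def test_empty_input(self):
        assert pan_cancer_aggregate(pd.DataFrame(
            columns=["molecule", "logFC", "fdr", "tumor_type"])).members == []

    def test_membership_matches_bruteforce_recount(self):
        rng = np.random.default_rng(5)
        rows = []
        for mol in [f"m{i}" for i in range(100)]:
            for tt in [f"T{j}" for j in range(6)]:
                rows.append((mol, rng.normal(0, 2), 0.0, rng.random(), tt, "mRNA"))
        tab = pd.DataFrame(
            rows, columns=["molecule", "logFC", "p_value", "fdr", "tumor_type", "molecule_class"]
        )
        sig = pan_cancer_aggregate(tab, lfc=1.5, fdr=0.05, min_types=2)
        expected = set()
        for mol in tab["molecule"].unique():
            sub = tab[tab["molecule"] == mol]
            n = sum((abs(r.logFC) > 1.5) and (r.fdr < 0.05) for r in sub.itertuples())
            if n >= 2:
                expected.add(mol)
        assert set(sig.members) == expected


class TestDMP:
    def _fixture(self, seed=0, n_per=15):
        rng = np.random.default_rng(seed)
        probes = [f"cg{i}" for i in range(10)]
        samples = [f"s{i}" for i in range(2 * n_per)]
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(10, 2 * n_per)),
                            index=probes, columns=samples)
        annot = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(10)],
             "region": ["TSS200"] * 4 + ["Body"] * 3 + ["TSS1500", "5'UTR", "1stExon"]},
            index=pd.Index(probes, name="probe"),
        )
        labels = pd.Series(["inflamed"] * n_per + ["noninflamed"] * n_per, index=samples)
        return beta, annot, labels

    def test_body_probes_excluded(self):
        beta, annot, labels = self._fixture()
        res = dmp_test(beta, labels, annot)
        assert not (res["region"] == "Body").any()
        assert len(res) == 7  # the promoter probes only

    def test_identical_groups_zero_delta(self):
        beta, annot, labels = self._fixture()
        sym = pd.concat([beta.iloc[:, :15], beta.iloc[:, :15].set_axis(
            beta.columns[15:], axis=1)], axis=1)
        res = dmp_test(sym, labels, annot)
        assert np.allclose(res["delta_beta"], 0.0)
        assert not res["significant"].any()

    def test_unannotated_probes_dropped(self):
        beta, annot, labels = self._fixture()
        res = dmp_test(beta, labels, annot.iloc[:5])
        assert set(res.index) <= set(annot.index[:5])

    def test_all_promoter_annotation_conserves_probes(self):
        beta, annot, labels = self._fixture()
        annot["region"] = "TSS200"
        res = dmp_test(beta, labels, annot)
        assert len(res) == len(beta)


class TestORA:
    def test_zero_overlap_p_one(self):
        res = ora_test({"a", "b"}, {"c", "d"}, {"a", "b", "c", "d", "e"})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_annotation_equals_universe(self):
        uni = {f"g{i}" for i in range(10)}
        res = ora_test(set(list(uni)[:4]), uni, uni)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["fold_enrichment"].iloc[0] == pytest.approx(1.0)

    def test_matches_explicit_tail_sum(self):
        """Universe 20, set 5, query 10, overlap 4: p equals the explicit
        hypergeometric tail sum."""
        uni = [f"g{i}" for i in range(20)]
        ann = set(uni[:5])
        query = set(uni[1:5]) | set(uni[10:16])  # overlap 4
        res = ora_test(query, ann, set(uni))
        expected = sum(
            math.comb(5, k) * math.comb(15, 10 - k) / math.comb(20, 10) for k in range(4, 6)
        )
        assert res["p_value"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert res["overlap"].iloc[0] == 4

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            ora_test({"a"}, {"a"}, set())
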