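import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from microgeostat import (
    OtuTable,
    bioenv,
    collinearity_filter,
    relative_abundance,
    spearman_matrix,
)


def rank_difference_spearman(x, y):
    """Independent oracle: r = 1 - 6 sum d^2 / (n(n^2-1)), tie-free data."""
    rx, ry = rankdata(x), rankdata(y)
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1 - 6 * d2 / (n * (n ** 2 - 1))


def _table(abund_rows, samples):
    frame = pd.DataFrame(abund_rows,
                         index=[f"t{i}" for i in range(len(abund_rows))],
                         columns=samples)
    return frame


class TestSpearmanMatrix:
    @pytest.fixture
    def env(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(8)]
        return pd.DataFrame({
            "EC": np.linspace(10, 150, 8),
            "WC": rng.uniform(15, 55, 8),
            "pH": np.full(8, 10.4),
        }, index=samples)

    def test_monotone_pair_gives_unit_correlation(self, env):
        ab = _table([env["EC"].to_numpy() ** 2], env.index)  # monotone in EC
        out = spearman_matrix(ab, env)
        row = out[(out.taxon == "t0") & (out.variable == "EC")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["tier"] == "highly significant"

    def test_antitone_pair_gives_minus_one(self, env):
        ab = _table([-env["EC"].to_numpy()], env.index)
        out = spearman_matrix(ab, env)
        row = out[(out.taxon == "t0") & (out.variable == "EC")].iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        assert row["sign"] == "-"

    def test_matches_rank_difference_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        env = pd.DataFrame({"v": y}, index=list("abcde"))
        ab = _table([x], list("abcde"))
        out = spearman_matrix(ab, env)
        expect = rank_difference_spearman(x, y)  # = 0.8
        assert expect == pytest.approx(0.8)
        assert out["r"].iloc[0] == pytest.approx(expect)

    def test_constant_vector_yields_nan_and_ns(self, env):
        ab = _table([np.ones(8)], env.index)
        out = spearman_matrix(ab, env)
        row = out[(out.taxon == "t0") & (out.variable == "EC")].iloc[0]
        assert np.isnan(row["r"]) and row["tier"] == "ns"

    def test_invariant_under_monotone_transforms(self, env):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 8)
        a = spearman_matrix(_table([x], env.index), env)
        b = spearman_matrix(_table([np.exp(3 * x)], env.index), env)
        assert np.allclose(a["r"], b["r"], equal_nan=True)

    def test_tier_consistent_with_p(self, env):
        rng = np.random.default_rng(2)
        ab = _table(rng.uniform(size=(6, 8)), env.index)
        out = spearman_matrix(ab, env)
        finite = out.dropna(subset=["p"])
        assert ((finite["p"] < 0.01) == (finite["tier"] == "highly significant")).all()
        mid = (finite["p"] >= 0.01) & (finite["p"] < 0.05)
        assert (mid == (finite["tier"] == "significant")).all()

    def test_too_few_shared_samples(self, env):
        ab = _table([np.arange(3)], ["S0", "S1", "S2"])
        with pytest.raises(ValueError, match="4 shared"):
            spearman_matrix(ab, env.iloc[:3])


class TestCollinearityFilter:
    def test_identical_variables_keep_exactly_one(self):
        x = np.arange(10.0)
        env = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(3).normal(size=10)})
        kept = collinearity_filter(env)
        assert sorted(kept) in (["a", "c"], ["b", "c"])
        assert len(kept) == 2

    def test_near_orthogonal_variables_all_kept(self):
        rng = np.random.default_rng(4)
        env = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        assert collinearity_filter(env) == list("abcd")

    def test_matches_exhaustive_search_on_small_case(self):
        """One redundant pair among 5 variables: greedy result equals the
        largest subset with all |r| below threshold."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=(40, 4))
        env = pd.DataFrame(base, columns=list("abcd"))
        env["e"] = env["a"] + rng.normal(0, 0.05, 40)  # redundant with a
        kept = set(collinearity_filter(env, 0.8))
        corr = env.corr().abs()
        best = set()
        for k in range(5, 0, -1):
            for combo in itertools.combinations(env.columns, k):
                sub = corr.loc[list(combo), list(combo)].to_numpy()
                np.fill_diagonal(sub, 0)
                if sub.max() <= 0.8:
                    best = set(combo)
                    break
            if best:
                break
        assert len(kept) == len(best)
        assert kept == best or "a" in kept or "e" in kept

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        env = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("vwxyz"))
        env["w"] = env["v"] * 0.99 + rng.normal(0, 0.01, 30)
        assert collinearity_filter(env) == collinearity_filter(env)


def naive_bioenv(dvec, env, max_size):
    """Independent double-loop reimplementation used as the oracle."""
    scaled = (env - env.mean()) / env.std(ddof=1)
    best = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(env.columns, size):
            evec = pdist(scaled[list(combo)].to_numpy())
            r = np.corrcoef(rankdata(dvec), rankdata(evec))[0, 1]
            key = tuple(combo)
            best[key] = r
    return best


class TestBioenv:
    @pytest.fixture
    def planted(self):
        """Community driven by a 1-D gradient; EC is a monotone transform
        of that gradient, other variables are noise."""
        rng = np.random.default_rng(7)
        n = 10
        grad = np.linspace(0, 1, n)
        env = pd.DataFrame({
            "EC": np.exp(2 * grad),
            "WC": rng.uniform(size=n),
            "pH": rng.uniform(size=n),
        }, index=[f"S{i}" for i in range(n)])
        intensity = np.exp(np.outer(grad, rng.normal(0, 2, 25)))
        prop = intensity / intensity.sum(axis=1, keepdims=True)
        counts = np.array([rng.multinomial(2000, p) for p in prop]).T
        table = OtuTable(counts, taxon_ids=[f"t{i}" for i in range(25)],
                         sample_ids=list(env.index))
        return table, env

    def test_planted_gradient_variable_is_best_singleton(self, planted):
        table, env = planted
        res = bioenv(table, env)
        singles = res.best_per_size[res.best_per_size["size"] == 1]
        assert singles["subset"].iloc[0] == ("EC",)

    def test_exhaustive_equals_naive_double_loop(self, planted):
        table, env = planted
        res = bioenv(table, env)
        prof = relative_abundance(table)
        dvec = pdist(prof.T.to_numpy(), metric="braycurtis")
        oracle = naive_bioenv(dvec, env, 3)
        assert len(res.results) == 7  # all non-empty subsets of 3 variables
        for _, row in res.results.iterrows():
            assert row["r"] == pytest.approx(oracle[row["subset"]], abs=1e-12)
        assert res.best_r == pytest.approx(max(oracle.values()), abs=1e-12)
        assert res.best_subset == max(oracle, key=oracle.get)

    def test_reported_best_dominates_every_subset(self, planted):
        table, env = planted
        res = bioenv(table, env)
        assert (res.results["r"] <= res.best_r + 1e-12).all()

    def test_adding_pure_noise_variable_keeps_best_correlation(self, planted):
        table, env = planted
        base = bioenv(table, env)
        env2 = env.copy()
        env2["noise"] = np.random.default_rng(99).normal(size=len(env))
        augmented = bioenv(table, env2)
        key = tuple(base.best_subset)
        r_aug = augmented.results.set_index("subset")["r"][key]
        assert r_aug == pytest.approx(base.best_r, abs=1e-12)

    def test_matches_skbio_reference(self, planted):
        from skbio import DistanceMatrix
        from skbio.stats.distance import bioenv as skbio_bioenv
        from scipy.spatial.distance import squareform
        table, env = planted
        prof = relative_abundance(table)
        dvec = pdist(prof.T.to_numpy(), metric="braycurtis")
        dm = DistanceMatrix(squareform(dvec), ids=list(env.index))
        theirs = skbio_bioenv(dm, env)
        ours = bioenv(table, env)
        best_theirs = theirs["correlation"].max()
        assert ours.best_r == pytest.approx(best_theirs, abs=1e-10)

    def test_subset_size_clamped_with_warning(self, planted):
        table, env = planted
        with pytest.warns(UserWarning, match="clamped"):
            res = bioenv(table, env, max_subset_size=10)
        assert res.results["size"].max() == 3

    def test_bray_curtis_bounded(self, planted):
        table, _ = planted
        prof = relative_abundance(table)
        dvec = pdist(prof.T.to_numpy(), metric="braycurtis")
        assert ((dvec >= 0) & (dvec <= 1)).all()
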