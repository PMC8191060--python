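"""Distances, Gower centering, signed decomposition and the pseudo-F test."""

import numpy as np
import pytest

from matchset import (
    CountTable,
    MatchedDesign,
    PermutationPlan,
    Submodel,
    bray_curtis,
    build_design,
    decompose,
    gower_center,
    hellinger,
    permanova_test,
    pseudo_F,
)
from matchset.permanova import DistanceMatrix

from conftest import random_table


def table_from_freqs(freqs):
    counts = (np.asarray(freqs) * 1000).astype(int)
    return CountTable(
        counts, [f"s{i}" for i in range(counts.shape[0])],
        [f"o{j}" for j in range(counts.shape[1])],
    )


class TestDistances:
    def test_identical_samples_zero(self):
        t = table_from_freqs([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)
        assert hellinger(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_bray_one(self):
        t = table_from_freqs([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)
        assert hellinger(t).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_bray_hand_example(self):
        t = table_from_freqs([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]])
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_hellinger_closed_form(self):
        t = table_from_freqs([[0.5, 0.5], [1.0, 0.0]])
        expected = np.sqrt((np.sqrt(0.5) - 1) ** 2 + 0.5)
        assert hellinger(t).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_sample_errors(self):
        t = CountTable(np.array([[1, 1], [0, 0]]), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            bray_curtis(t)


class TestGowerCenter:
    def test_zero_matrix(self):
        assert np.all(gower_center(np.zeros((3, 3))) == 0)

    def test_two_samples_closed_form(self):
        d = 0.6
        D = np.array([[0, d], [d, 0]])
        expected = (d**2 / 4) * np.array([[1, -1], [-1, 1]])
        np.testing.assert_allclose(gower_center(D), expected, atol=1e-14)

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(0)
        delta = gower_center(bray_curtis(random_table(rng, n=6)))
        np.testing.assert_allclose(delta.sum(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(delta.sum(axis=1), 0, atol=1e-10)


class TestDecompose:
    def test_reconstruction_bray(self):
        rng = np.random.default_rng(1)
        delta = gower_center(bray_curtis(random_table(rng, n=6)))
        dec = decompose(delta)
        recon = dec.embedding @ np.diag(dec.signs) @ dec.embedding.T
        assert np.abs(recon - delta).max() <= 1e-8 * np.abs(delta).max()

    def test_bray_has_negative_eigenvalues_retained(self):
        rng = np.random.default_rng(8)
        dec = decompose(gower_center(bray_curtis(random_table(rng, n=10))))
        assert set(np.unique(dec.signs)) <= {-1.0, 1.0}

    def test_euclidean_embeddable_all_positive(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dec = decompose(gower_center(DistanceMatrix(D, "euclidean")))
        assert np.all(dec.signs == 1)

    def test_two_sample_single_axis(self):
        d = 0.8
        dec = decompose(gower_center(DistanceMatrix(np.array([[0, d], [d, 0]]), "m")))
        assert dec.embedding.shape[1] == 1
        assert dec.signs[0] == 1
        assert np.sum(dec.embedding**2) == pytest.approx(d**2 / 2, abs=1e-12)


class TestPseudoF:
    def _model(self, n, trait, set_ids=None, seed=0):
        return build_design(
            MatchedDesign(
                sample_ids=[f"s{i}" for i in range(n)],
                set_ids=np.arange(n) if set_ids is None else set_ids,
                submodels=[Submodel("trait", trait)],
                adjust_set_id=set_ids is not None,
            )
        )

    def test_orthogonal_embedding_gives_zero(self):
        trait = np.array([1.0, -1, 1, -1])
        model = self._model(4, trait)
        # embedding orthogonal to the trait contrast
        y = np.array([1.0, 1, -1, -1])[:, None]
        from matchset.permanova import DistanceDecomposition

        dec = DistanceDecomposition(y, np.array([1.0]), np.array([1.0]))
        assert pseudo_F(model, dec, "trait") == pytest.approx(0.0, abs=1e-15)

    def test_matches_ols_on_one_axis(self):
        # single embedding coordinate: pseudo-F equals SSR/SSE of OLS
        rng = np.random.default_rng(3)
        trait = rng.normal(size=4)
        y = rng.normal(size=4)
        model = self._model(4, trait)
        x = model.blocks[0][:, 0]
        yc = y - y.mean()
        ssr = float((x @ yc) ** 2)
        sse = float(yc @ yc - ssr)
        from matchset.permanova import DistanceDecomposition

        dec = DistanceDecomposition(yc[:, None], np.array([1.0]), np.array([1.0]))
        assert pseudo_F(model, dec, "trait") == pytest.approx(ssr / sse, abs=1e-10)

    def test_invariant_to_set_level_shift(self):
        """Adding a per-set constant to the embedding rows leaves F unchanged
        when set indicators are in block 1 (the statistic sees only the
        within-set deviations)."""
        rng = np.random.default_rng(4)
        set_ids = np.repeat([0, 1, 2], 2)
        trait = rng.normal(size=6)
        model = self._model(6, trait, set_ids=set_ids)
        from matchset.design import center_columns
        from matchset.permanova import DistanceDecomposition

        Y = center_columns(rng.normal(size=(6, 3)))
        signs = np.ones(3)
        f1 = pseudo_F(model, DistanceDecomposition(Y, signs, signs), "trait")
        shift = np.repeat(rng.normal(size=(3, 3)), 2, axis=0)
        f2 = pseudo_F(
            model, DistanceDecomposition(center_columns(Y + shift), signs, signs), "trait"
        )
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_variance_decomposition_identity(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=8)
        set_ids = np.repeat(np.arange(4), 2)
        model = self._model(8, rng.normal(size=8), set_ids=set_ids)
        dec = decompose(gower_center(bray_curtis(table)))
        Z, S = dec.embedding, dec.signs
        total = ((Z * Z) @ S).sum()
        explained = sum((((B.T @ Z) ** 2) @ S).sum() for B in model.blocks)
        resid = total - explained
        idx = model.tested_index("trait")
        num = (((model.blocks[idx].T @ Z) ** 2) @ S).sum()
        other = explained - num
        assert num + other + resid == pytest.approx(total, abs=1e-8 * abs(total))

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=8)
        model = self._model(8, rng.normal(size=8))
        d1 = decompose(gower_center(bray_curtis(table)))
        scaled = gower_center(bray_curtis(table)) * 7.3
        d2 = decompose(scaled)
        f1 = pseudo_F(model, d1, "trait")
        f2 = pseudo_F(model, d2, "trait")
        assert f1 == pytest.approx(f2, rel=1e-9)


def test_euclidean_permanova_equals_ldm_frequency_stat():
    """With Euclidean distance on the centered frequency table, the distance
    decomposition reproduces the Gram matrix of Y, so the pseudo-F equals the
    LDM frequency-scale global statistic exactly (cross-module consistency)."""
    from scipy.spatial.distance import pdist, squareform

    from matchset import ldm_statistics, to_frequency

    rng = np.random.default_rng(21)
    table = random_table(rng, n=10, J=12, depth=400)
    resp = to_frequency(table)
    D = DistanceMatrix(squareform(pdist(resp.values, "euclidean")), "euclidean")
    dec = decompose(gower_center(D))
    model = build_design(
        MatchedDesign(
            table.sample_ids,
            np.repeat(np.arange(5), 2),
            [Submodel("trait", rng.normal(size=10))],
        )
    )
    f_perm = pseudo_F(model, dec, "trait")
    f_ldm, _ = ldm_statistics(model, resp, "trait")
    assert f_perm == pytest.approx(f_ldm, abs=1e-10)


def test_pseudo_f_matches_adonis2_oracle(tmp_path):
    """The pseudo-F equals vegan::adonis2's F up to its degrees-of-freedom
    constants on a small matched design (independent reference implementation
    run through Rscript)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(5)
    n, J = 10, 8
    counts = rng.multinomial(500, rng.dirichlet(np.ones(J)), size=n)
    table = CountTable(counts, [f"s{i}" for i in range(n)], [f"o{j}" for j in range(J)])
    set_ids = np.repeat(np.arange(5), 2)
    trait = rng.normal(size=n)
    model = build_design(
        MatchedDesign(table.sample_ids, set_ids, [Submodel("trait", trait)])
    )
    dec = decompose(gower_center(bray_curtis(table)))
    f_ours = pseudo_F(model, dec, "trait")

    np.savetxt(tmp_path / "counts.txt", counts)
    np.savetxt(tmp_path / "trait.txt", trait)
    rscript = f"""
suppressMessages(library(vegan))
Y <- as.matrix(read.table("{tmp_path}/counts.txt"))
x <- scan("{tmp_path}/trait.txt", quiet=TRUE)
setid <- factor(rep(1:5, each=2))
D <- vegdist(Y/rowSums(Y), method="bray")
fit <- adonis2(D ~ setid + x, permutations=2, by="terms")
cat(sprintf("%.12g %d %d", fit$F[2], fit$Df[2], fit$Df[3]))
"""
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=120
    )
    if out.returncode != 0:
        pytest.skip(f"vegan unavailable: {out.stderr[-200:]}")
    f_adonis, df1, df2 = out.stdout.split()
    rescaled = float(f_adonis) * float(df1) / float(df2)
    assert f_ours == pytest.approx(rescaled, rel=1e-9)


class TestPermanovaTest:
    def test_strong_effect_minimal_pvalue(self):
        # within-pair separation so large the observed F beats all permutations
        rng = np.random.default_rng(9)
        n_pairs, J = 6, 10
        counts = np.zeros((2 * n_pairs, J), dtype=int)
        counts[::2, :5] = rng.integers(90, 110, size=(n_pairs, 5))
        counts[1::2, 5:] = rng.integers(90, 110, size=(n_pairs, 5))
        table = CountTable(counts, [f"s{i}" for i in range(2 * n_pairs)],
                           [f"o{j}" for j in range(J)])
        design = MatchedDesign(
            sample_ids=table.sample_ids,
            set_ids=np.repeat(np.arange(n_pairs), 2),
            submodels=[Submodel("trait", np.tile([1.0, 0.0], n_pairs))],
        )
        plan = PermutationPlan(set_ids=design.set_ids, exhaustive=True)
        res = permanova_test(table, design, plan)
        # identity and the all-pairs flip (x -> -x) tie at the maximum among
        # the 2^6 = 64 within-pair sign patterns
        assert res["trait"]["p"] == pytest.approx(2 / 64)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            table = random_table(rng, n=12, J=15, depth=500)
            design = MatchedDesign(
                sample_ids=table.sample_ids,
                set_ids=np.repeat(np.arange(6), 2),
                submodels=[Submodel("trait", rng.normal(size=12))],
            )
            plan = PermutationPlan(set_ids=design.set_ids, n_perm=99, seed=rep)
            res = permanova_test(table, design, plan)
            if res["trait"]["p"] <= 0.05:
                rejections += 1
        assert rejections <= 5 + 4 * np.sqrt(100 * 0.05 * 0.95)
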