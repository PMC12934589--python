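import numpy as np
import pandas as pd
import pytest

import oralpair as op
from oralpair.lda import (
    KSelectionCurve,
    ScaledCorpus,
    arun2010,
    build_scaled_corpus,
    caojuan2009,
    deveaud2014,
    embed_gamma,
    fit_lda_gibbs,
    griffiths2004,
    k_selection,
    select_scaling_factor,
    topic_drivers,
    topic_type_association,
)


def _table(counts):
    counts = np.asarray(counts)
    return op.CountTable(
        [f"t{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


def test_build_scaled_corpus_examples():
    ct = _table([[5], [3], [2]])
    corpus = build_scaled_corpus(ct, 1000)
    np.testing.assert_array_equal(corpus.matrix[0], [500, 300, 200])
    # tiny relative abundance rounds to zero
    ct2 = _table([[4], [9996]])
    corpus2 = build_scaled_corpus(ct2, 1000)
    assert corpus2.matrix[0, 0] == 0
    with pytest.raises(ValueError, match=">= 10"):
        build_scaled_corpus(ct, 5)


def test_scaled_corpus_token_total_bound():
    rng = np.random.default_rng(0)
    ct = _table(rng.integers(0, 200, size=(40, 10)) + 1)
    for S in (100, 1000):
        corpus = build_scaled_corpus(ct, S)
        totals = corpus.matrix.sum(axis=1)
        assert np.all(np.abs(totals - S) <= 40 / 2)


def _separable_corpus(tokens_per_doc=500):
    """Two documents on disjoint 10-word vocabularies."""
    m = np.zeros((2, 20), dtype=int)
    m[0, :10] = tokens_per_doc // 10
    m[1, 10:] = tokens_per_doc // 10
    return ScaledCorpus(m, ["d0", "d1"], [f"w{i:02d}" for i in range(20)], 1000)


def test_k1_degenerate_model():
    corpus = _separable_corpus()
    model = fit_lda_gibbs(corpus, K=1, iterations=20, burn_in=10, thin=5, seed=0)
    np.testing.assert_allclose(model.gamma, 1.0)
    freqs = corpus.matrix.sum(axis=0)
    expected = (freqs + model.eta) / (freqs.sum() + 20 * model.eta)
    np.testing.assert_allclose(model.beta[0], expected, atol=1e-12)


def test_separable_corpus_recovery():
    corpus = _separable_corpus()
    model = fit_lda_gibbs(corpus, K=2, iterations=300, burn_in=150, thin=25, seed=3)
    assert model.gamma.max(axis=1).min() >= 0.95
    top = np.argmax(model.gamma, axis=1)
    assert top[0] != top[1]
    assert model.beta[top[0], :10].sum() >= 0.95
    assert model.beta[top[1], 10:].sum() >= 0.95


def test_model_invariants_and_determinism():
    corpus = _separable_corpus()
    a = fit_lda_gibbs(corpus, K=3, iterations=100, burn_in=50, thin=10, seed=11)
    b = fit_lda_gibbs(corpus, K=3, iterations=100, burn_in=50, thin=10, seed=11)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_array_equal(a.gamma, b.gamma)
    np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
    np.testing.assert_allclose(a.beta.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(a.gamma.sum(axis=1), 1.0, atol=1e-9)
    assert len(a.loglik_trace) == 5
    c = fit_lda_gibbs(corpus, K=3, iterations=100, burn_in=50, thin=10, seed=12)
    assert not np.array_equal(a.gamma, c.gamma)


def test_fit_errors():
    corpus = _separable_corpus()
    with pytest.raises(ValueError, match="exceed"):
        fit_lda_gibbs(corpus, K=2, iterations=10, burn_in=10)
    with pytest.raises(ValueError, match="tokens"):
        fit_lda_gibbs(ScaledCorpus(np.eye(2, dtype=int), ["a", "b"], ["x", "y"], 1000), K=5)


def test_loglik_increases_on_separable_corpus():
    corpus = _separable_corpus()
    model = fit_lda_gibbs(corpus, K=2, iterations=400, burn_in=20, thin=20, seed=1)
    trace = model.loglik_trace
    # running median over the trace should not decrease appreciably
    first = np.median(trace[: len(trace) // 3])
    last = np.median(trace[-len(trace) // 3 :])
    assert last >= first


def test_metric_building_blocks():
    beta = np.array([[0.5, 0.3, 0.2], [0.5, 0.3, 0.2]])
    assert caojuan2009(beta) == pytest.approx(1.0)
    assert deveaud2014(beta) == pytest.approx(0.0, abs=1e-12)
    distinct = np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01]])
    assert caojuan2009(distinct) < 0.1
    assert deveaud2014(distinct) > 1.0
    # griffiths harmonic mean lies at or below the max of the trace
    trace = np.array([-1000.0, -995.0, -990.0])
    g = griffiths2004(trace)
    assert -1000.0 <= g <= -990.0
    # arun is zero when the two spectra coincide
    b = np.array([[0.6, 0.4], [0.6, 0.4]])
    sv = np.linalg.svd(b, compute_uv=False)
    c1 = sv / sv.sum()
    gamma = np.tile(c1, (3, 1))
    lengths = np.ones(3)
    assert arun2010(b, gamma, lengths) == pytest.approx(0.0, abs=1e-9)


def test_k_selection_grid_rules():
    corpus = _separable_corpus()
    with pytest.raises(ValueError, match="K >= 2"):
        k_selection(corpus, [1, 2])
    curve = k_selection(corpus, [2], iterations=60, burn_in=30, thin=10, seed=0)
    assert isinstance(curve, KSelectionCurve)
    assert curve.chosen_k == 2 and curve.degenerate
    curve2 = k_selection(corpus, [2, 3, 4], iterations=60, burn_in=30, thin=10, seed=0)
    assert curve2.chosen_k in (2, 3, 4)
    assert np.isfinite(curve2.metrics.to_numpy()).all()


def test_select_scaling_factor_prefers_informative_scale(standard_cohort):
    ct, md, tax, truth = standard_cohort
    # S=10 collapses most taxa to zero tokens; S=1000 must score higher
    S, diag = select_scaling_factor(
        ct, md, K=6, s_grid=(10, 1000), seed=4, iterations=200, burn_in=100, thin=20
    )
    diag = diag.set_index("S")
    assert S == 1000
    assert diag.loc[10, "score"] < diag.loc[1000, "score"]
    one, diag1 = select_scaling_factor(
        ct, md, K=6, s_grid=(500,), seed=4, iterations=100, burn_in=50, thin=10
    )
    assert one == 500


def test_topic_type_association_trivia(standard_cohort):
    ct, md, tax, truth = standard_cohort
    n_pairs = len(md.pairs())
    docs = [s for s in ct.samples]
    K = 2
    gamma = np.full((len(docs), K), 0.5)
    model = op.LdaModel(
        K=K, alpha=1.0, eta=0.1, beta=np.full((K, 3), 1 / 3), gamma=gamma,
        loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0, thin=1,
        docs=docs, vocab=["a", "b", "c"],
    )
    assoc = topic_type_association(model, md)
    assert (assoc["class"] == "shared").all()
    assert (assoc["p"] == 1.0).all()
    # topic higher in plaque for every pair -> exact p = 2/2^n, class plaque
    gamma2 = gamma.copy()
    pairs = md.pairs()
    doc_idx = {s: i for i, s in enumerate(docs)}
    for i, pid in enumerate(pairs.index):
        hi, lo = 0.9 - 1e-3 * i, 0.1 + 5e-4 * i  # distinct |diffs|: exact branch
        gamma2[doc_idx[pairs.loc[pid, "plaque"]], 0] = hi
        gamma2[doc_idx[pairs.loc[pid, "plaque"]], 1] = 1 - hi
        gamma2[doc_idx[pairs.loc[pid, "abscess"]], 0] = lo
        gamma2[doc_idx[pairs.loc[pid, "abscess"]], 1] = 1 - lo
    model2 = op.LdaModel(
        K=K, alpha=1.0, eta=0.1, beta=np.full((K, 3), 1 / 3), gamma=gamma2,
        loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0, thin=1,
        docs=docs, vocab=["a", "b", "c"],
    )
    assoc2 = topic_type_association(model2, md)
    assert assoc2.loc["topic_1", "class"] == "plaque"
    assert assoc2.loc["topic_2", "class"] == "abscess"
    assert assoc2.loc["topic_1", "p"] == pytest.approx(2 / 2**n_pairs)


def test_topic_association_invariant_under_label_permutation(standard_cohort):
    ct, md, tax, truth = standard_cohort
    corpus = build_scaled_corpus(ct, 1000)
    model = fit_lda_gibbs(corpus, 4, iterations=200, burn_in=100, thin=20, seed=2)
    assoc = topic_type_association(model, md)
    perm = np.array([2, 0, 3, 1])
    permuted = op.LdaModel(
        K=4, alpha=model.alpha, eta=model.eta, beta=model.beta[perm],
        gamma=model.gamma[:, perm], loglik_trace=model.loglik_trace, seed=model.seed,
        iterations=model.iterations, burn_in=model.burn_in, thin=model.thin,
        docs=model.docs, vocab=model.vocab,
    )
    assoc_p = topic_type_association(permuted, md)
    # classes follow the beta rows through the permutation
    assert list(assoc_p["class"]) == [assoc["class"].iloc[j] for j in perm]


def test_topic_drivers_sorting():
    beta = np.array([[0.7, 0.2, 0.1], [1 / 3, 1 / 3, 1 / 3]])
    model = op.LdaModel(
        K=2, alpha=1.0, eta=0.1, beta=beta, gamma=np.full((2, 2), 0.5),
        loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0, thin=1,
        docs=["d0", "d1"], vocab=["b", "a", "c"],
    )
    drv = topic_drivers(model, top_n=3)
    assert list(drv["topic_1"].index) == ["b", "a", "c"]  # by beta descending
    assert list(drv["topic_2"].index) == ["a", "b", "c"]  # ties -> name order
    # oracle sort on a random model
    rng = np.random.default_rng(1)
    beta2 = rng.dirichlet(np.ones(8), size=3)
    model2 = op.LdaModel(
        K=3, alpha=1.0, eta=0.1, beta=beta2, gamma=np.full((2, 3), 1 / 3),
        loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0, thin=1,
        docs=["d0", "d1"], vocab=[f"w{i}" for i in range(8)],
    )
    drv2 = topic_drivers(model2, top_n=5)
    for k in range(3):
        expected = sorted(
            zip(-beta2[k], [f"w{i}" for i in range(8)])
        )[:5]
        assert list(drv2[f"topic_{k+1}"].index) == [w for _, w in expected]


def test_embed_gamma_determinism_and_separation(standard_cohort):
    ct, md, tax, truth = standard_cohort
    # two coincident-point groups in gamma space embed to high silhouettes
    docs = list(ct.samples)
    gamma = np.zeros((len(docs), 2))
    types = md.frame.loc[docs, "specimen_type"]
    gamma[(types == "plaque").to_numpy(), 0] = 1.0
    gamma[(types == "abscess").to_numpy(), 1] = 1.0
    model = op.LdaModel(
        K=2, alpha=1.0, eta=0.1, beta=np.full((2, 3), 1 / 3), gamma=gamma,
        loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0, thin=1,
        docs=docs, vocab=["a", "b", "c"],
    )
    emb1, sil1 = embed_gamma(model, md, seed=5)
    assert sil1["plaque"] >= 0.9 and sil1["abscess"] >= 0.9
    emb2, sil2 = embed_gamma(model, md, seed=5)
    pd.testing.assert_frame_equal(emb1, emb2)
    with pytest.raises(ValueError, match="4 samples"):
        embed_gamma(
            op.LdaModel(
                K=2, alpha=1.0, eta=0.1, beta=model.beta, gamma=gamma[:3],
                loglik_trace=np.array([0.0]), seed=0, iterations=1, burn_in=0,
                thin=1, docs=docs[:3], vocab=["a", "b", "c"],
            ),
            md,
        )
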