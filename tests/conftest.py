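import pytest

import litmine as lm
from litmine.synthgen import GeneratorSpec, gen_corpus


@pytest.fixture(scope="session")
def separable_fit():
    """A small disjoint-topic synthetic corpus with a fitted model.

    Session-scoped: several tests only need *some* well-separated fitted
    model, and Gibbs runs are the slow part of the suite.
    """
    spec = GeneratorSpec(
        K_true=3, vocab_size=60, n_docs=50, doc_length_mean=40,
        disjoint_topics=True, seed=1,
    )
    articles, truth = gen_corpus(spec)
    dictionary = lm.build_dictionary(articles)
    bow = lm.to_bow(articles, dictionary)
    results = lm.LDA(bow, K=3, alpha=0.1, vocabulary=dictionary.words()).fit(
        n_iter=300, seed=2
    )
    return {
        "spec": spec,
        "articles": articles,
        "truth": truth,
        "dictionary": dictionary,
        "bow": bow,
        "results": results,
    }
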