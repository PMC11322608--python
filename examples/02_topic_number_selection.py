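"""Automatic topic-number selection on a planted two-community corpus.

400 documents: half contain words {A..E}, half {F..J}. The specificity score
(topics occur with very different probability across documents) and purity
score (few topics per document) combine into a single selection criterion;
the correct answer here is two topics.
"""

import numpy as np

from condsig import Corpus, fit_btm, select_topic_number, topic_coherence

docs = [np.arange(5) if i < 200 else np.arange(5, 10) for i in range(400)]
corpus = Corpus.from_documents(docs, list("ABCDEFGHIJ"))

model, report = select_topic_number(corpus, seed=0)
print(report.table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
print(f"\nselected k = {report.chosen_k}")

for t in range(model.k):
    words = [corpus.vocab[w] for w in model.top_words(t, 5)]
    print(f"topic {t}: top words {words}")
print("coherence per topic:", np.round(topic_coherence(model, corpus), 3))
# CS is maximal at k=2 and each topic's top-5 words reproduce one planted
# community; coherence near 0 means the top words almost always co-occur.
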