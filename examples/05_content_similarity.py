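"""Content overview of predicted at-risk posts via a phrase embedding.

After a transfer run, the posts a model scored as at-risk can be summarized
by training a bigram-phrase skip-gram embedding on them and querying the
nearest neighbours of a seed word. Strong collocations ("want to die"-style
phrases merge to single tokens) and topical neighbours of "suicidal" give a
quick qualitative read on what the predictions captured.
"""

from opirisk.content import detect_phrases, phrase_embedding, top_similar
from opirisk.preprocessing import tokenize_post
from opirisk.synthetic import GeneratorConfig, generate_corpus

posts, truth = generate_corpus(GeneratorConfig(
    seed=13, separability=0.95, keyword_inclusion_rate=0.8,
    n_posts_per_group={"suicidewatch": 600, "depression": 0,
                       "control": 0, "opiates": 0}))

# stand-in for "posts predicted positive": the latently suicidal posts
docs = [tokenize_post(p) for p, t in zip(posts, truth) if t.is_suicidal]

phrases = detect_phrases(docs, min_count=5, threshold=5.0)
print(f"detected {len(phrases.phrases)} collocations, e.g.:")
for pair, score in sorted(phrases.phrases.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {'_'.join(pair):<20} score {score:.1f}")

table = phrase_embedding(docs, phrases, dim=48, window=4, epochs=4, seed=2)
print('\ntop 15 words most similar to "suicidal":')
for rank, (token, sim) in enumerate(top_similar(table, "suicidal", k=15), 1):
    print(f"  {rank:>2}. {token:<20} cosine {sim:.3f}")

# Neighbours drawn from the risk lexicon (hopeless, burden, ...) indicate
# the embedding recovered the topical structure of the predicted posts.
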