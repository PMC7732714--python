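"""Generate a synthetic four-group corpus and summarize it.

The generator emulates four communities — a suicidal-language group, a
depression group, a diverse control group, and an opioid cluster with mixed
emotional registers — and records latent ground truth (is the post's
language suicidal? does it signal opioid misuse?) for every post. A slice of
opioid-group posts also carries suicidal content and vice versa, which is
exactly the intersection the transfer experiments try to recover.
"""

import json

from opirisk.synthetic import GeneratorConfig, corpus_report, generate_corpus
from opirisk.transfer import C1_KEYWORDS

config = GeneratorConfig(
    seed=7,
    n_posts_per_group={"suicidewatch": 400, "depression": 400,
                       "control": 400, "opiates": 400},
    intersection_rate_opiates=0.15,   # opioid posts that are also suicidal
    intersection_rate_sw=0.2,         # suicidal posts that also mention opioids
    separability=0.8,
)
posts, truth = generate_corpus(config)

report = corpus_report(posts, truth, keywords=C1_KEYWORDS)
print(json.dumps(report, indent=2))

example = next(p for p, t in zip(posts, truth) if t.is_suicidal and t.is_opioid)
print("\nan intersection post (suicidal AND opioid):")
print(" ", example.title)
print(" ", example.body[:160], "...")

# The group counts confirm the four communities; the word-count quantiles
# span short notes to long essays; suicidal_rate/opioid_rate are the latent
# prevalences the intersection rates induce; keyword_prevalence is the share
# of posts containing an explicit risk keyword or phrase.
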