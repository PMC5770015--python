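"""Jaccard distance between signal grounds and the by-item JD_mu.

Two independent drawings of 'Harrison Ford', tagged {MAN, HAT, CLIFF, GUN,
WHIP} and {MAN, HAT, WHIP, CAR}, share 3 of 6 distinct tags: JD = 1 - 3/6
= 0.5.  Averaging JD over all first-exposure signal pairs of an item gives
JD_mu, the item's ground unpredictability (0 = code-like, 1 = no overlap).
"""

from symsig import TagSet, item_jd_mean, jaccard_distance, tagger_agreement

a = {"MAN", "HAT", "CLIFF", "GUN", "WHIP"}
b = {"MAN", "HAT", "WHIP", "CAR"}
print("JD(worked example) =", jaccard_distance(a, b))

signals = [
    TagSet.make("s1", "harrison ford", "tagger1", a),
    TagSet.make("s2", "harrison ford", "tagger1", b),
    TagSet.make("s3", "harrison ford", "tagger1", {"MAN", "WHIP", "SNAKE"}),
]
jd = item_jd_mean(signals)
print(f"JD_mu over {jd.n_pairs} pairs of {jd.n_signals} signals = {jd.jd_mu:.3f}")

# Tagger agreement: rank correlation of two coders' by-item JD_mu vectors
t1 = [0.2, 0.5, 0.9, 0.4, 0.7, 0.1, 0.65, 0.3, 0.8, 0.55]
t2 = [0.25, 0.45, 0.85, 0.5, 0.6, 0.15, 0.7, 0.2, 0.9, 0.5]
rho, p = tagger_agreement(t1, t2)
print(f"tagger agreement: Spearman rho = {rho:.3f}, p = {p:.4f}")
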