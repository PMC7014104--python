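"""Docking-score enrichment of an active series against library and decoys.

Generates a Gaussian score table planting a 1.0 kcal/mol mean improvement of
the actives over library/decoys, then measures the ROC AUC (probability that
a random active outranks a random decoy), the mean score shift, and the
distribution overlap.
"""

from allosite.enrichment import (
    distribution_summary, overlap_coefficient, roc_auc, score_shift,
)
from allosite.synthetic import ScoreClassSpec, ScoreTableConfig, gen_score_table

cfg = ScoreTableConfig(seed=1, receptor="AR", site="BF3", classes={
    "active": ScoreClassSpec(mean=-6.0, sd=1.0, n=50),
    "library": ScoreClassSpec(mean=-5.0, sd=1.0, n=500),
    "decoy": ScoreClassSpec(mean=-5.0, sd=1.0, n=500),
})
df, truth = gen_score_table(cfg)

act = df.loc[df["class"] == "active", "score"]
lib = df.loc[df["class"] == "library", "score"]
dec = df.loc[df["class"] == "decoy", "score"]

print(distribution_summary(df).round(2))
print(f"\nscore shift vs library : {score_shift(act, lib):+.2f} kcal/mol "
      f"(planted {truth['shift_vs_library']:+.2f})")
print(f"ROC AUC vs decoys      : {roc_auc(act, dec):.3f} "
      f"(analytic {truth['auc_vs_decoy']:.3f})")
print(f"active/library overlap : {overlap_coefficient(act, lib):.2f}")
# A ~1 kcal/mol shift with sd 1.0 separates the distributions only partially
# (AUC ≈ 0.76, overlap ≈ 0.6): enrichment is real but the histograms overlap,
# the typical picture for a confirmed-active series against a screening library.
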