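"""Synthetic two-reader Likert ratings: summaries, tests and agreement.

Generates 5-point ratings for 30 subjects x 12 reconstructions x 2 readers
from a latent-quality ordinal model, then reproduces the subjective
image-quality analysis: median (IQR) per kernel family and level,
Kruskal-Wallis tests, and the inter-reader ICC(2,1) with its agreement
label.
"""

from vesseliq import (
    default_kernel_grid,
    default_rating_model,
    generate_ratings,
    icc_absolute_agreement,
    kruskal_wallis,
    likert_summary,
)

ratings = generate_ratings(default_rating_model(30, seed=5),
                           default_kernel_grid())

overall = ratings[ratings["criterion"] == "overall"]
print("overall image quality, median (IQR):")
for _, r in likert_summary(overall, by=("family",)).iterrows():
    print(f"  {r['family']}: {r['formatted']}")
for _, r in likert_summary(overall, by=("level",)).iterrows():
    print(f"  level {r['level']}: {r['formatted']}")

kw = kruskal_wallis({f: g["score"].to_numpy()
                     for f, g in overall.groupby("family")})
print(f"Kruskal-Wallis across families: H = {kw.statistic:.1f}, "
      f"p = {kw.p_value:.2g}")

wide = overall.pivot_table(index=["subject", "family", "level"],
                           columns="rater", values="score")
icc = icc_absolute_agreement(wide)
print(f"inter-reader ICC(2,1) = {icc.icc:.2f} ({icc.interpretation})")
print("The vascular kernel at low/moderate sharpness rates best, and the")
print("two simulated readers agree closely on the ordinal scores.")
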