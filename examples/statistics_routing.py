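"""Normality-gated group statistics on survival percentages.

Each group is screened with Shapiro-Wilk; if any group fails, medians with
Kruskal-Wallis + Bonferroni-corrected Mann-Whitney pairs are used,
otherwise means with Welch ANOVA + Games-Howell pairs. A rank-based
two-factor analysis (Scheirer-Ray-Hare) handles crossed age x time designs.
"""

import numpy as np
import pandas as pd

from rgcquant.stats import (
    normality_gate, omnibus_test, pairwise_posthoc, two_factor_rank_anova,
)

rng = np.random.default_rng(0)
groups = {
    "0dpi": rng.normal(100, 4, 8),
    "7dpi": rng.normal(41, 5, 8),
    "14dpi": rng.normal(19, 3, 8),
}

route = normality_gate(list(groups.values()))
print(f"route: {route.route} (per-group Shapiro-Wilk p: "
      + ", ".join(f"{p:.2f}" for p in route.per_group_normality_p) + ")")

omni = omnibus_test(list(groups.values()), route)
print(f"omnibus {omni.test_name}: statistic {omni.statistic:.2f}, p {omni.p_value:.2e}")
for res in pairwise_posthoc(list(groups.values()), route, list(groups)):
    print(f"  {res.group_pair[0]} vs {res.group_pair[1]}: {res.test_name} "
          f"p = {res.p_value:.4f} ({res.adjustment})")

# Two-factor rank analysis: an age shift with no age x time interaction.
rows = []
for age in ("6w", "18w"):
    for dpi in (4, 14):
        base = 79 if dpi == 4 else 67
        shift = 0 if age == "6w" else -8
        for v in rng.normal(base + shift, 4, 8):
            rows.append({"age_label": age, "dpi": dpi, "survival_pct": v})
print()
for res in two_factor_rank_anova(pd.DataFrame(rows)):
    print(f"{res.test_name}: H = {res.statistic:.2f}, p = {res.p_value:.4f}")
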