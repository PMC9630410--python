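#!/usr/bin/env python
"""Association of morphologic heterogeneity with clinical benefit, and the
rank/correlation statistics used across the study.

The 29-patient checkpoint-blockade cohort enters as its printed 2x2 table:
9 patients with durable clinical benefit (7 morphologically monotonous, 2
mixed) versus 20 without benefit (4 monotonous, 16 mixed). Also demonstrates
the paired Wilcoxon, Spearman and Bonferroni/BH routes on synthetic paired
scores. Writes results/morphology_response.tsv.
"""
from pathlib import Path

import numpy as np

from mixhet import io_formats, stats_util as su

SEED = 15
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = [[7, 2], [4, 16]]
    p = su.fisher_exact_2x2(table)
    io_formats.write_table(
        [{"benefit": "durable", "monotonous": 7, "mixed": 2},
         {"benefit": "none", "monotonous": 4, "mixed": 16},
         {"benefit": "fisher_two_sided_p", "monotonous": round(p, 4),
          "mixed": ""}],
        OUT / "morphology_response.tsv",
    )
    print(f"morphologic heterogeneity vs clinical benefit: "
          f"Fisher exact p = {p:.4f} (prints as {p:.2f})")

    rng = np.random.default_rng(SEED)
    uc = rng.normal(0.0, 1.0, size=12)
    sqd = uc + rng.normal(0.8, 1.0, size=12)  # paired shift, as in 12 pairs
    w, p_w = su.wilcoxon_signed_rank(sqd, uc)
    print(f"paired Wilcoxon on 12 synthetic UC/SqD score pairs: "
          f"W+={w:.0f}, p = {p_w:.4f}")

    x = rng.normal(size=100)
    y = -0.5 * x + rng.normal(0, 1, size=100)  # negative association
    rho, p_s = su.spearman(x, y)
    print(f"Spearman on synthetic anti-correlated expression: "
          f"rho = {rho:.2f}, p = {p_s:.2e}, "
          f"Bonferroni x24 = {su.bonferroni([p_s] * 24)[0]:.2e}")

    q = su.bh_fdr([p, p_w, p_s])
    print(f"BH q-values across the three tests: "
          f"{', '.join(f'{v:.4f}' for v in q)}")


if __name__ == "__main__":
    main()
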