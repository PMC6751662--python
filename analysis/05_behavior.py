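#!/usr/bin/env python
"""Behavioral read-outs: chemical avoidance and lawn bordering.

Simulates quadrant-assay worm counts for a wild type, an avoidance-defective
receptor mutant, and a transgenic rescue, plus lawn-bordering counts for the
social-feeding phenotype, then compares genotypes plate-wise (ANOVA with
Bonferroni-adjusted pairwise tests against the mutant reference) and writes
the count tables and comparison summaries.
"""

import argparse
from pathlib import Path

import numpy as np

from flpnpr.behavior import compare_groups, plate_bordering, plate_indices
from flpnpr.io import comparison_to_dict, write_json, write_lawn_tsv, write_quadrant_tsv
from flpnpr.synth import (
    AvoidanceTruth,
    BorderingTruth,
    simulate_avoidance_plates,
    simulate_bordering_plates,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # avoidance: wild type avoids the repellent quadrants (index near -0.6),
    # the receptor mutant is defective (near -0.1), the rescue restores it
    quad = simulate_avoidance_plates(
        [
            AvoidanceTruth("wt", p_mesa=0.18, p_eoh=0.80, n_worms=100, n_plates=6),
            AvoidanceTruth("mutant", p_mesa=0.44, p_eoh=0.54, n_worms=100, n_plates=6),
            AvoidanceTruth("rescue", p_mesa=0.21, p_eoh=0.77, n_worms=100, n_plates=6),
        ],
        seed=args.seed,
    )
    write_quadrant_tsv(quad, args.outdir / "quadrant_counts.tsv")
    ai = plate_indices(quad)
    cmp_ai = compare_groups(ai, reference="mutant")
    write_json(comparison_to_dict(cmp_ai), args.outdir / "avoidance_comparison.json")

    print("avoidance index (mean over plates, vs mutant):")
    for g in cmp_ai.genotypes:
        star = cmp_ai.stars.get(g, "")
        print(f"  {g:<8} {np.mean(ai[g]):+.3f}  {star}")

    # bordering: loss of the receptor produces the social phenotype
    lawn = simulate_bordering_plates(
        [
            BorderingTruth("wt", p_border=0.15, n_plates=6),
            BorderingTruth("mutant", p_border=0.82, n_plates=6),
            BorderingTruth("rescue", p_border=0.22, n_plates=6),
        ],
        seed=args.seed + 1,
    )
    write_lawn_tsv(lawn, args.outdir / "lawn_counts.tsv")
    borders = plate_bordering(lawn)
    cmp_b = compare_groups(borders, reference="mutant")
    write_json(comparison_to_dict(cmp_b), args.outdir / "bordering_comparison.json")

    print("bordering fraction (mean over plates, vs mutant):")
    for g in cmp_b.genotypes:
        star = cmp_b.stars.get(g, "")
        print(f"  {g:<8} {np.mean(borders[g]):.3f}  {star}")


if __name__ == "__main__":
    main()
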