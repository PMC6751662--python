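#!/usr/bin/env python
"""Infer candidate in vivo ligands from the interaction matrix.

Reads the called matrix, intersects the peptides active at the native target
receptor with those active at every heterologous receptor that substitutes it
in vivo, and writes the ranked candidate list. The non-substituting receptors
serve as specificity controls.
"""

import argparse
from pathlib import Path

from flpnpr.candidates import infer_candidates
from flpnpr.io import read_matrix_json, write_json
from flpnpr.studies import DEMO_RESCUE_PANEL


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--min-grade", default="i", choices=["i", "ii", "iii", "iv", "v"])
    args = parser.parse_args()

    matrix = read_matrix_json(args.outdir / "matrix.json")
    panel = DEMO_RESCUE_PANEL
    candidates = infer_candidates(matrix, panel, min_grade=args.min_grade)
    strict = infer_candidates(matrix, panel, min_grade=args.min_grade,
                              exclude_non_rescuers=True)

    out = {
        "target_receptor": panel.target_receptor_id,
        "rescuing_receptors": list(panel.rescuing_receptor_ids),
        "non_rescuing_receptors": list(panel.non_rescuing_receptor_ids),
        "min_grade": args.min_grade,
        "candidates": candidates,
        "candidates_strict": strict,
        "grades_at_target": {p: matrix.grade(p, panel.target_receptor_id)
                             for p in candidates},
    }
    write_json(out, args.outdir / "candidates.json")

    print(f"target {panel.target_receptor_id}; "
          f"rescuers {', '.join(panel.rescuing_receptor_ids)}")
    print(f"candidate ligands (strongest minimum grade first): {candidates}")
    print(f"after excluding peptides active at all specificity controls: {strict}")


if __name__ == "__main__":
    main()
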