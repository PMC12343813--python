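"""Score polygenic scores for mothers, partners and children and check the
familial correlation structure.

Reads the cohort written by 01_simulate_cohort.py, computes standardized
weighted PGS per role, writes score CSVs, and prints the mother-child,
father-child and mother-father PGS correlations (expected ~0.5, ~0.5 and
~the configured spousal correlation).
"""

import argparse
from pathlib import Path

import numpy as np

from dyadsim import panel_io, pgs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel_io.read_weights(cohort / "panel.tsv")
    z = {}
    for role in ("mothers", "fathers", "children"):
        gm = panel_io.read_genotypes(cohort / f"genotypes_{role}.tsv", panel)
        sv = pgs.standardize(pgs.compute_pgs(gm, panel))
        pgs.write_scores(sv, out / f"scores_{role}.csv")
        z[role] = sv.z

    print(f"scored {len(z['mothers'])} individuals per role on {len(panel)} SNPs")
    print(f"mother-child  PGS r = {np.corrcoef(z['mothers'], z['children'])[0, 1]:.3f}")
    print(f"father-child  PGS r = {np.corrcoef(z['fathers'], z['children'])[0, 1]:.3f}")
    print(f"mother-father PGS r = {np.corrcoef(z['mothers'], z['fathers'])[0, 1]:.3f}")


if __name__ == "__main__":
    main()
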