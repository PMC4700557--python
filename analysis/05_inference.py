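"""Second-stage inference on participant-level posterior means: 2x2
within-subject ANOVAs (language x stimulus type) for each diffusion
parameter, t-tests of the length slopes against 0 per condition, and a
paired t-test on the decision boundary between language blocks.

Usage: python analysis/05_inference.py [--posterior results] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from lexhdm import inference


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--posterior", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    pm = pd.read_csv(args.posterior / "posterior_participants.tsv", sep="\t")
    effects = inference.posterior_inference(pm)
    effects.to_csv(args.out / "effects.tsv", sep="\t", index=False, float_format="%.6g")
    print(effects.to_string(index=False))

    slopes = effects[(effects["parameter"].isin(["t1", "v1"])) & (effects["statistic"] == "t")]
    sig = slopes[slopes["p"] < 0.05]
    print(f"\n{len(sig)}/{len(slopes)} length slopes differ from 0 at p < .05")


if __name__ == "__main__":
    main()
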