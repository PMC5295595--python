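#!/usr/bin/env python
"""Compare the models: Tukey HSD letters on per-environment mean abilities.

Two-way ANOVA (model + environment block) on the per-environment mean
correlations, followed by Tukey's HSD at alpha = 0.05. Models sharing a
letter are not significantly different.
"""

import json
from pathlib import Path

import pandas as pd

from gxepred import CVResult, tukey_compare

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = pd.read_csv(ROOT / "cv_long.csv")
    result = CVResult(rows=rows)
    out = {}
    for scheme in ("CV1", "CV2"):
        comp = tukey_compare(result, scheme)
        out[scheme] = comp
        print(f"{scheme}: HSD={comp['hsd']:.3f}")
        for model, mean in comp["model_means"].items():
            print(f"  {model}: {mean:+.3f}  {comp['letters'][model]}")
    (ROOT / "tukey.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {ROOT / 'tukey.json'}")


if __name__ == "__main__":
    main()
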