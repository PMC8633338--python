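#!/usr/bin/env python
"""Grade a suspected malignant-hyperthermia episode.

Scores a set of observed clinical indicators against the grading scale
(default: the five-indicator table) and maps the score to a qualitative
likelihood rank.  The index presentation — masseter spasm, CK elevation,
respiratory acidosis, inappropriate temperature increase and metabolic
acidosis — scores 70 points: an MH episode is almost certain.
"""

import argparse
import json
from pathlib import Path

from mhscreen.clinical_grading import (
    CaseIndicators,
    default_scale,
    grade_case,
    load_scale,
)

DEFAULT_INDICATORS = ("masseter_spasm,ck_elevation,respiratory_acidosis,"
                      "inappropriate_temperature_increase,metabolic_acidosis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indicators", default=DEFAULT_INDICATORS,
                        help="comma-separated observed indicator ids")
    parser.add_argument("--scale", type=Path, default=None,
                        help="optional YAML grading-scale config")
    parser.add_argument("--out", type=Path, default=Path("results/grading"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scale = load_scale(args.scale) if args.scale else default_scale()
    observed = {i.strip() for i in args.indicators.split(",") if i.strip()}
    score, rank = grade_case(CaseIndicators(observed), scale)

    print(f"observed indicators: {sorted(observed)}")
    print(f"score: {score} pts -> likelihood of an MH episode: {rank}")
    (args.out / "grade.json").write_text(json.dumps(
        {"observed": sorted(observed), "score": score, "rank": rank},
        indent=2) + "\n")


if __name__ == "__main__":
    main()
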