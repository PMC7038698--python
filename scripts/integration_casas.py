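#!/usr/bin/env python
"""Optional integration run against real household data (external downloads).

Not part of the test surface: it needs the annotated HH-series event logs
from the CASAS repository (http://casas.wsu.edu) and the pretrained 300-d
Google-News word2vec table converted to the text format, neither of which is
bundled.  Exact published numbers are additionally sensitive to unpublished
grid-searched hyperparameters, so this script demonstrates the pipeline on
the real inputs rather than asserting the printed tables.

Example:

    python scripts/integration_casas.py \
        --dataset data/hh101/ann.txt \
        --embedding data/GoogleNews-vectors.txt \
        --scenario 1 --seed 0 --out results/hh101_s1
"""

from __future__ import annotations

import argparse
import io
import sys
from pathlib import Path

import zeroshot_har as z
from zeroshot_har.evaluation import write_metrics_table

# published experimental designs: seen (training) vs unseen (zero-shot) labels
SCENARIOS = {
    1: {
        "seen": ("Bathe", "Cook", "Wash Dinner Dishes", "Watch TV", "Read"),
        "unseen": ("Sleep", "Toilet", "Relax"),
    },
    2: {
        "seen": ("Cook Breakfast", "Wash Dishes", "Phone", "Dress", "Eat Dinner"),
        "unseen": ("Cook Lunch", "Personal Hygiene", "Eat Lunch"),
    },
}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, required=True,
                        help="annotated CASAS event log (e.g. HH101)")
    parser.add_argument("--embedding", type=Path, required=True,
                        help="word2vec TEXT-format table (300-d)")
    parser.add_argument("--scenario", type=int, choices=(1, 2), default=1)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    design = SCENARIOS[args.scenario]
    config = z.ScenarioConfig(
        seen_labels=design["seen"],
        unseen_labels=design["unseen"],
        dataset_path=str(args.dataset),
        embedding_path=str(args.embedding),
        seed=args.seed,
        output_dir=str(args.out) if args.out else None,
    )
    result = z.run_pipeline(config)

    print(f"zero-shot accuracy: {result.zero_shot_accuracy:.4f} "
          f"over {result.confusion.total} instances")
    buf = io.StringIO()
    write_metrics_table(result.confusion, buf)
    print(buf.getvalue(), end="")
    return 0


if __name__ == "__main__":
    sys.exit(main())
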