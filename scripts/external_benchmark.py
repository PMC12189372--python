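"""Run the full pipeline on the real RBPLight benchmark (external data).

The benchmark (2496 + 2496 training pairs and 543 + 543 independent pairs
of plant RBP / non-RBP sequences) is distributed with the RBPLight GitHub
release and is NOT bundled here; download it and point this script at the
four FASTA files.  The script trains the default pipeline, runs 5-fold
cross-validation on the training pairs, evaluates the fitted bundle on
the independent pairs, and prints each metric next to the published
reference value for this method on that benchmark so the gap is explicit.
Retraining is stochastic and the exact published numbers are not expected
to reproduce to the decimal.

Usage:
    python scripts/external_benchmark.py \
        --train-pos train_rbp.fasta --train-neg train_nonrbp.fasta \
        --test-pos test_rbp.fasta --test-neg test_nonrbp.fasta \
        [--cv-folds 5] [--seed 0] [--out-dir runs/rbplight]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

#: Published reference values (percent) for this method on the RBPLight
#: benchmark: 5-fold CV on the training pairs, and the independent set.
REFERENCE_CV = {"ACC": 97.20, "AUC": 99.29, "MCC": 94.43, "F1": 97.19,
                "SN": 95.73, "SP": 98.67}
REFERENCE_INDEPENDENT = {"ACC": 99.72, "F1": 99.72, "MCC": 99.45,
                         "SN": 99.63, "SP": 99.82, "Precision": 99.72}


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--train-pos", required=True, type=Path)
    parser.add_argument("--train-neg", required=True, type=Path)
    parser.add_argument("--test-pos", required=True, type=Path)
    parser.add_argument("--test-neg", required=True, type=Path)
    parser.add_argument("--cv-folds", type=int, default=5)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("runs/rbplight"))
    args = parser.parse_args(argv)

    for path in (args.train_pos, args.train_neg, args.test_pos, args.test_neg):
        if not path.exists():
            parser.error(f"input not found: {path} (download the RBPLight "
                         "release and pass its FASTA files)")

    from plantrbp.model import RBPEnsembleModel, RunConfig
    from plantrbp.seqio import load_dataset

    config = RunConfig(seed=args.seed)
    model = RBPEnsembleModel.from_fasta(args.train_pos, args.train_neg, config)
    print(f"training sequences: {len(model.sequences)}")
    summary = model.cross_validate(n_folds=args.cv_folds)
    print(f"\n{args.cv_folds}-fold cross-validation (this run vs. reference):")
    for name, ref in REFERENCE_CV.items():
        mean = summary.mean(name)
        print(f"  {name:>9s}: {mean:6.2f} ± {summary.std(name):.2f}   "
              f"reference {ref:6.2f}   gap {mean - ref:+.2f}")

    results = model.fit()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    results.save(args.out_dir)
    independent = load_dataset(args.test_pos, args.test_neg)
    mset = results.evaluate(independent, averaging="weighted")
    print(f"\nindependent set ({len(independent)} sequences, "
          "this run vs. reference):")
    for name, ref in REFERENCE_INDEPENDENT.items():
        value = getattr(mset, name)
        shown = f"{value:6.2f}" if value is not None else "  n/a "
        gap = f"{value - ref:+.2f}" if value is not None else "  n/a"
        print(f"  {name:>9s}: {shown}   reference {ref:6.2f}   gap {gap}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
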