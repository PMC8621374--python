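"""Score the pipeline run against the planted ground truth.

Compares results/run/ with results/data/reference/ground_truth.json:
fraction of planted miRNAs recovered as called miRNAs, and agreement of the
called differential-expression classes with the intended ones; writes
results/recovery_detail.tsv.
"""

from pathlib import Path

import pandas as pd

from mirpipe import scoring
from mirpipe.simulate import GENOTYPES, GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    mirnas = pd.read_csv(ROOT / "run" / "mirnas.tsv", sep="\t")
    de = {g: pd.read_csv(ROOT / "run" / f"de_{g}.tsv", sep="\t", index_col=0) for g in GENOTYPES}
    truth = GroundTruth.from_json(ROOT / "data" / "reference" / "ground_truth.json")
    rec, hits = scoring.recovery_rate(mirnas, truth)
    acc_all, detail = scoring.de_class_accuracy(mirnas, de, truth)
    acc_strong, _ = scoring.de_class_accuracy(
        mirnas, de, truth, lfc_filter=lambda a: a == 0 or a >= 1.5
    )
    detail.to_csv(ROOT / "recovery_detail.tsv", sep="\t", index=False)
    missed = sorted(k for k, v in hits.items() if not v)
    print(f"planted-miRNA recovery: {rec:.1%} ({sum(hits.values())}/{len(hits)})"
          + (f"; missed: {', '.join(missed)}" if missed else ""))
    print(f"DE-class agreement, all intended effects: {acc_all:.1%}")
    print(f"DE-class agreement, |log2fc| in {{0, >=1.5}}: {acc_strong:.1%}")
    print(f"detail in {ROOT / 'recovery_detail.tsv'}")


if __name__ == "__main__":
    main()
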