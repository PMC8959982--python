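"""Compare all feature conditions and classifiers at threshold 0.71.

Builds the eight feature conditions — power spectrum (PS), five
single-layer band networks, the multilayer network (MN) and the
spectrally weighted improved multilayer network (IMN) — then runs every
classifier through 10-fold cross-validation with per-fold Filter
feature selection.

Output: results/04_classification.csv
"""

from pathlib import Path

from plvnet import CohortSpec, generate_cohort
from plvnet.features import CLASSIFIER_KINDS, run_comparison
from plvnet.pipeline import compute_sample_bank, feature_tables_from_bank

SEED = 1
THRESHOLD = 0.71
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = generate_cohort(CohortSpec(seed=SEED))
    bank = compute_sample_bank(cohort)
    tables = feature_tables_from_bank(bank, threshold=THRESHOLD)
    df = run_comparison(tables, kinds=CLASSIFIER_KINDS, seeds=(SEED,))
    OUT.mkdir(exist_ok=True)
    df.round(4).to_csv(OUT / "04_classification.csv", index=False)
    pivot = df.pivot_table(index="condition", columns="classifier",
                           values="mean_accuracy")
    print((100 * pivot).round(1).to_string())


if __name__ == "__main__":
    main()
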