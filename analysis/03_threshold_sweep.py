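"""Sweep the binarization threshold and report classification accuracy.

Runs the alpha-band condition through the Filter + soft-voting ensemble
classifier at thresholds 0.11-0.91 (step 0.1) to show how the choice of
binarization level affects discriminability.

Output: results/03_threshold_sweep.csv
"""

from pathlib import Path

from plvnet import CohortSpec, generate_cohort
from plvnet.pipeline import compute_sample_bank, threshold_sweep

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = generate_cohort(CohortSpec(seed=SEED))
    bank = compute_sample_bank(cohort)
    df = threshold_sweep(bank, condition="alpha", classifier="elts",
                         seed=SEED)
    OUT.mkdir(exist_ok=True)
    df.round(4).to_csv(OUT / "03_threshold_sweep.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(f"best threshold: {df.attrs['best_threshold']}")


if __name__ == "__main__":
    main()
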