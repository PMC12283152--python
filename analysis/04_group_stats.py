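"""Paired Wilcoxon signed-rank tests with BH-FDR on the similarity scores
of the intermediate (cibi) group: motor-ref vs bvftd-ref per timepoint
(cross-sectional family) and baseline vs follow-up per reference
(longitudinal family)."""

from pathlib import Path

import pandas as pd

from spectrumst.stats import run_comparisons

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    scores_path = OUT / "similarity_scores.csv"
    if not scores_path.exists():
        raise SystemExit("run 03_similarity_spectrum.py first")
    scores = pd.read_csv(scores_path)
    tables = run_comparisons(scores, q=0.05)
    tables.table.to_csv(OUT / "stat_tests.csv", index=False,
                        float_format="%.17g")
    cols = ["family", "band", "timepoint", "reference", "n_pairs", "z",
            "p_raw", "p_adj", "rejected"]
    print(tables.table[cols].round(4).to_string(index=False))
    n_rej = int(tables.table.rejected.sum())
    print(f"\n{n_rej}/{len(tables.table)} comparisons rejected at q=0.05")
    print(f"wrote {OUT / 'stat_tests.csv'}")


if __name__ == "__main__":
    main()
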