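"""TMM-normalize, convert to log2CPM, and filter each cohort x tissue slice.

Keeps genes with average log2CPM >= 4 per slice and intersects the
candidates across both cohorts and both tissues, mirroring the
"expressed in both tissues in both datasets" candidate rule.  Writes the
four expression matrices and the candidate list under results/expression/.
"""

from pathlib import Path

import pandas as pd

from xtissue import io
from xtissue.preprocess import filter_genes, intersect_candidates, log2cpm, tmm_factors

DATA = Path("results/data")
OUT = Path("results/expression")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = {}
    for cohort in ("reference", "intervention"):
        counts = io.read_counts(DATA / f"{cohort}_counts.tsv.gz")
        samples = io.read_sample_sheet(DATA / f"{cohort}_samples.csv")
        for tissue in ("SM", "SAT"):
            cols = samples.loc[samples["tissue"] == tissue, "sample_id"]
            sub = counts[list(cols)]
            expr = filter_genes(log2cpm(sub, tmm_factors(sub)), min_avg_log2cpm=4.0)
            matrices[(cohort, tissue)] = expr
            expr.to_csv(OUT / f"{cohort}_{tissue}_log2cpm.tsv.gz", sep="\t")
            print(f"{cohort}/{tissue}: {expr.shape[0]} genes pass filtering")
    candidates = intersect_candidates(list(matrices.values()))
    pd.Series(candidates).to_csv(OUT / "candidates.txt", index=False, header=False)
    print(f"candidate genes expressed everywhere: {len(candidates)}")


if __name__ == "__main__":
    main()
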