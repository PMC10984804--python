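"""Generate the two synthetic study cohorts.

Produces (a) a large cross-sectional two-tissue reference cohort with eight
planted co-expression communities and trait links, and (b) a small paired
pre/post intervention cohort (16 subjects, SM + SAT biopsies before and
after training) with a planted tissue-discordant time effect on community 2.
Writes counts, sample sheets, traits and the ground truth under
results/data/.
"""

import sys
from pathlib import Path

from xtissue import io
from xtissue.simulate import (
    SimulationConfig,
    generate_intervention_cohort,
    generate_reference_cohort,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    cohorts = {
        "reference": generate_reference_cohort(config, seed=SEED),
        "intervention": generate_intervention_cohort(config, seed=SEED + 1),
    }
    for name, cohort in cohorts.items():
        io.write_counts(cohort.counts, OUT / f"{name}_counts.tsv.gz")
        cohort.annotations.to_csv(OUT / f"{name}_samples.csv", index=False)
        cohort.traits.to_csv(OUT / f"{name}_traits.csv", index=False)
        io.write_json(
            {k: v for k, v in cohort.truth.items() if k != "latent_log2cpm"},
            OUT / f"{name}_truth.json",
        )
        n_comm = len(config.community_sizes)
        print(
            f"{name}: {cohort.counts.shape[0]} genes x {cohort.counts.shape[1]} "
            f"samples, {n_comm} planted communities"
        )
    print(f"planted discordant community: 2 (time effect {config.time_effect[2]})")


if __name__ == "__main__":
    main()
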