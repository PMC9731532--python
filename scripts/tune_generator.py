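"""Diary-model tuning harness for the synthetic generator.

Runs generator -> intake -> exposure at the default configuration and prints
the All-group and subgroup EDI summaries next to the published calibration
targets (All 7.10/5.20, core 7.75/5.62 ng/kg/day). Used to choose the frozen
defaults in baprisk.synthetic; re-run it after any change to the consumption
model to see where the generated exposure distribution lands.

Usage: python scripts/tune_generator.py [seed ...]
"""

import sys

from baprisk.cohort_survey import diary_to_intake, subgroup_partition
from baprisk.concentration_db import summarize_concentrations
from baprisk.exposure import compute_exposure_results, subgroup_table
from baprisk.synthetic import SyntheticConfig, generate_cohort, generate_concentration_db


def edi_table(seed: int) -> None:
    config = SyntheticConfig(seed=seed)
    records = generate_concentration_db(config)
    participants, diary = generate_cohort(config)
    conc = {s.food_category: s.mean for s in summarize_concentrations(records)}
    profiles = diary_to_intake(diary, config.n_days, participant_ids=[p.id for p in participants])
    results = compute_exposure_results(participants, profiles, conc)
    partitions = subgroup_partition(participants, ["region", "sex", "education"])
    print(f"--- seed {seed} ---")
    print(f"{'group':<18}{'n':>5}{'mean':>8}{'median':>8}{'p95':>8}")
    for row in subgroup_table(results, partitions):
        print(
            f"{row.group_label:<18}{row.n:>5}"
            f"{row.edi.mean:>8.2f}{row.edi.median:>8.2f}{row.edi.p95:>8.2f}"
        )
    print("targets: All 7.10/5.20/20.63  core 7.75/5.62  peripheral 6.75/4.75")


if __name__ == "__main__":
    seeds = [int(s) for s in sys.argv[1:]] or [0]
    for s in seeds:
        edi_table(s)
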