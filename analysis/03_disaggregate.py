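#!/usr/bin/env python
"""Monte Carlo disaggregation of cases from zones to blocks.

Reads the fixtures from step 01, filters to staged female cases, and
imputes each case to a block of its zone in proportion to its age-race
subgroup population, without replacement, over R replicates.  Writes the
long-form assignment table and run metadata per scenario.
"""

import sys

from geoimpute import disaggregate, filter_cases
from geoimpute.io import read_tables, write_assignments

R = int(sys.argv[1]) if len(sys.argv) > 1 else 100
SEED = 0


def main():
    for name in ("kane_like", "peoria_like"):
        base = f"results/fixtures/{name}"
        area, cases = read_tables({
            "blocks": f"{base}/blocks.csv", "cases": f"{base}/cases.csv",
            "facilities": f"{base}/facilities.csv",
        })
        staged, tally = filter_cases(cases)
        matrix = disaggregate(staged, area.blocks, R=R, master_seed=SEED)
        write_assignments(matrix, f"{base}/assignments.csv",
                          f"{base}/assignments_meta.json")
        print(f"{name}: assignment matrix {matrix.shape[0]} cases x "
              f"{matrix.shape[1]} replicates (seed {SEED}), "
              f"{len(matrix.metadata['fallback_events'])} empty-support fallbacks")


if __name__ == "__main__":
    main()
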