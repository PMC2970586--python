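#!/usr/bin/env python
"""Generate the two synthetic study areas and their case tables.

Writes blocks/cases/facilities/network/nodes/truth CSVs for the
``kane_like`` (uniform density, dispersed facilities) and ``peoria_like``
(monocentric, clustered facilities, highly segregated) scenarios under
results/fixtures/<scenario>/, and prints the case mix each produced.
"""

import sys

from geoimpute import filter_cases, scenario_presets, generate_study
from geoimpute.io import write_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    for name, config in scenario_presets(seed=SEED).items():
        study = generate_study(config)
        paths = write_study(study, f"results/fixtures/{name}")
        staged, tally = filter_cases(study.cases)
        print(f"{name}: {tally['input']} cases -> {tally['staged']} staged "
              f"({tally['unstaged']} unstaged), late share "
              f"{staged['late'].mean():.3f}, "
              f"{len(study.study_area.blocks)} blocks / "
              f"{len(study.study_area.zones)} zones, "
              f"{len(study.study_area.facilities)} facilities "
              f"({config.facility_mode})")
        print(f"  wrote {', '.join(sorted(paths))} under results/fixtures/{name}/")


if __name__ == "__main__":
    main()
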