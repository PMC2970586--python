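"""Published summary figures for the two Illinois county study areas.

The underlying registry records (Illinois State Cancer Registry, female
breast cancer 1998-2002, geocoded to zip code) are confidential and not
distributable, but the published county-level summaries are public and
serve as worked-example inputs: case counts by staging status and by
demographic subgroup, and the zone-level distance coefficient with the
reference-person baseline risk used for out-of-sample risk prediction.

:func:`county_case_table` reconstructs a case table consistent with these
counts so the filtering and tallying machinery can be exercised on data of
exactly the published shape.  Stage codes within the early/late classes
and ages within bands are representative placeholders; only the marginal
counts are meaningful.
"""

from __future__ import annotations

import pandas as pd

#: Case counts: total reported, unstaged, late-stage (among staged), and
#: staged cases per age-race subgroup (canonical subgroup order).
COUNTY_SUMMARY = {
    "kane": {
        "total_cases": 1102,
        "unstaged": 65,
        "late": 406,
        "subgroups": {
            ("nonblack", "lt50"): 243,
            ("nonblack", "50to69"): 420,
            ("nonblack", "ge70"): 334,
            ("black", "lt50"): 17,
            ("black", "50to69"): 14,
            ("black", "ge70"): 9,
        },
    },
    "peoria": {
        "total_cases": 804,
        "unstaged": 38,
        "late": 245,
        "subgroups": {
            ("nonblack", "lt50"): 131,
            ("nonblack", "50to69"): 294,
            ("nonblack", "ge70"): 276,
            ("black", "lt50"): 24,
            ("black", "50to69"): 30,
            ("black", "ge70"): 11,
        },
    },
}

#: Peoria zone-level model: shortest-travel-distance coefficient (per meter)
#: and the predicted late-stage risk for the reference person (non-black,
#: age >= 70) at distance 0 — the published inputs to the 20 km risk
#: extrapolation.
PEORIA_ZONE_DISTANCE_COEF_PER_M = -3.51e-4
PEORIA_REFERENCE_RISK_AT_0 = 0.250

_AGE_REP = {"lt50": 45, "50to69": 60, "ge70": 80}


def county_case_table(county: str) -> pd.DataFrame:
    """Case table (case_id, zone_id, age, race, sex, stage, year) matching
    the published county counts.

    Staged cases get stage 2 (late) or 0 (early) so that the late and
    staged totals reproduce the published figures exactly; unstaged cases
    carry the "U" sentinel.  All cases sit in a single placeholder zone.
    """
    summary = COUNTY_SUMMARY[county.lower()]
    rows = []
    late_left = summary["late"]
    years = list(range(1998, 2003))
    k = 0
    for (race, band), count in summary["subgroups"].items():
        for _ in range(count):
            late = late_left > 0
            if late:
                late_left -= 1
            rows.append({
                "case_id": f"{county[:1].upper()}{k:05d}",
                "zone_id": "Z0",
                "age": _AGE_REP[band],
                "race": race,
                "sex": "F",
                "stage": 2 if late else 0,
                "year": years[k % 5],
            })
            k += 1
    for _ in range(summary["unstaged"]):
        rows.append({
            "case_id": f"{county[:1].upper()}{k:05d}",
            "zone_id": "Z0",
            "age": 60,
            "race": "nonblack",
            "sex": "F",
            "stage": "U",
            "year": years[k % 5],
        })
        k += 1
    return pd.DataFrame(rows)
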