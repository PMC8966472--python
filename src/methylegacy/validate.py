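"""Worked-example validation against the bundled published counts.

``run_validate`` recomputes, from the stored integer tallies only, the
heavy-site percentages and odds ratios and all bracketed expected DM
counts, and reports pass/fail per check as a JSON-serializable dict.
"""

from __future__ import annotations

import copy

from .enrichment import expected_count
from .profile import heavy_site_table_from_counts
from . import reference_counts as ref


def run_validate(
    heavy_counts=None, heavy_printed=None, dm_counts=None
) -> dict:
    """Recompute the worked examples and compare with the printed values.

    Arguments default to the bundled counts; passing tampered copies is
    how the negative-control tests exercise failure detection.
    """
    heavy_counts = ref.HEAVY_SITE_COUNTS if heavy_counts is None else heavy_counts
    heavy_printed = ref.HEAVY_SITE_PRINTED if heavy_printed is None else heavy_printed
    dm_counts = ref.DM_FEATURE_COUNTS if dm_counts is None else dm_counts

    checks = []
    table = heavy_site_table_from_counts(heavy_counts)
    for feature, printed in heavy_printed["pct"].items():
        got = round(float(table.loc[feature, "pct_heavy"]), 1)
        checks.append(
            {"check": f"heavy_pct_{feature}", "computed": got, "printed": printed,
             "pass": got == printed}
        )
    for feature in ("exon", "promoter"):  # intron OR not arithmetically consistent
        printed = heavy_printed["odds_ratio"][feature]
        got = round(float(table.loc[feature, "odds_ratio"]), 2)
        checks.append(
            {"check": f"heavy_odds_ratio_{feature}", "computed": got,
             "printed": printed, "pass": got == printed}
        )
    for pollutant, block in dm_counts.items():
        universe = block["universe"]
        for cls in ("direct", "persistent", "legacy"):
            n_dm = block[cls]["genome"]
            for feature in ("promoter", "exon", "intron"):
                observed, printed_expected = block[cls][feature]
                got = round(expected_count(n_dm, universe[feature], universe["genome"]))
                checks.append(
                    {
                        "check": f"expected_{pollutant}_{cls}_{feature}",
                        "computed": got,
                        "printed": printed_expected,
                        "pass": got == printed_expected,
                    }
                )
    return {
        "n_checks": len(checks),
        "n_pass": sum(c["pass"] for c in checks),
        "all_pass": all(c["pass"] for c in checks),
        "checks": checks,
    }
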