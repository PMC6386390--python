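"""Cell-line estradiol-withdrawal growth assay analysis.

Cell lines are grown with 1 nM estradiol (E2) for five days and then kept
either with or without E2 for another five days, mimicking the estrogen
deprivation an aromatase inhibitor produces. Per replicate the growth ratio
is day-5 count / day-0 count; the per-condition ratios are averaged and
contrasted in a growth measure. The default measure is the excess-growth
ratio

    measure = (GR_E2 - 1) / (GR_noE2 - 1),

which exceeds 1 exactly when estradiol confers more net growth than its
absence; lines with measure > 1 are called estrogen-responsive. The printed
form of this statistic in the source material is ambiguous, so the formula
is a named, swappable strategy (see ``GROWTH_MEASURE_FORMULAS``) and the
choice is documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GrowthExperiment
from .errors import ValidationError

RESPONSIVE_THRESHOLD = 1.0


def growth_ratio(day5: float, day0: float) -> float:
    """Growth ratio day5/day0 for one replicate; day0 must be positive."""
    if day0 <= 0:
        raise ValidationError(f"day-0 count must be positive, got {day0}")
    return float(day5) / float(day0)


def condition_growth_ratio(experiment: GrowthExperiment) -> float:
    """Mean of replicate-level growth ratios for one (cell line, condition)."""
    ratios = [growth_ratio(d5, d0) for d5, d0 in zip(experiment.day5_counts, experiment.day0_counts)]
    return float(np.mean(ratios))


def _excess_ratio(gr_e2: float, gr_noe2: float) -> float:
    if gr_noe2 == 1.0:
        raise ValidationError("growth measure undefined when GR without E2 equals 1")
    return (gr_e2 - 1.0) / (gr_noe2 - 1.0)


def _ratio_times_difference(gr_e2: float, gr_noe2: float) -> float:
    # alternative reading of the assay statistic: relative ratio scaled by
    # the raw growth-ratio difference
    if gr_noe2 == 0.0:
        raise ValidationError("growth measure undefined when GR without E2 equals 0")
    return (gr_e2 / gr_noe2) * (gr_e2 - gr_noe2)


GROWTH_MEASURE_FORMULAS = {
    "excess_ratio": _excess_ratio,
    "ratio_times_difference": _ratio_times_difference,
}


def growth_measure(gr_e2: float, gr_noe2: float, formula: str = "excess_ratio") -> float:
    """Contrast growth with vs without estradiol; the default excess-growth
    ratio equals 1.0 exactly when GR_E2 = GR_noE2 (the decision boundary)."""
    try:
        fn = GROWTH_MEASURE_FORMULAS[formula]
    except KeyError:
        raise ValidationError(
            f"unknown growth-measure formula {formula!r}; choose from {sorted(GROWTH_MEASURE_FORMULAS)}"
        ) from None
    return fn(float(gr_e2), float(gr_noe2))


def classify_cell_line(measure: float, threshold: float = RESPONSIVE_THRESHOLD) -> bool:
    """Responsive iff measure strictly exceeds the threshold; a measure
    exactly at the threshold is called non-responsive (tie rule)."""
    return measure > threshold


def read_growth_counts(path) -> list[GrowthExperiment]:
    """Read the growth CSV (cell_line, condition, day, replicate, count) and
    pair day-0/day-5 replicate counts per (cell line, condition)."""
    df = pd.read_csv(path)
    required = {"cell_line", "condition", "day", "replicate", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"growth file missing columns: {sorted(missing)}")
    er = {}
    if "er_status" in df.columns:
        er = df.groupby("cell_line")["er_status"].first().to_dict()
    experiments = []
    for (line, condition), group in df.groupby(["cell_line", "condition"], sort=True):
        pivot = group.pivot_table(index="replicate", columns="day", values="count")
        if not {0, 5} <= set(pivot.columns):
            raise ValidationError(f"{line}/{condition}: need counts at day 0 and day 5")
        pivot = pivot.dropna()
        experiments.append(
            GrowthExperiment(
                cell_line=str(line),
                condition=str(condition),
                day0_counts=pivot[0].to_numpy(),
                day5_counts=pivot[5].to_numpy(),
                er_status=str(er.get(line, "unknown")),
            )
        )
    return experiments


def write_growth_counts(experiments: list[GrowthExperiment], path) -> None:
    rows = []
    for exp in experiments:
        for rep, (d0, d5) in enumerate(zip(exp.day0_counts, exp.day5_counts), start=1):
            for day, count in ((0, d0), (5, d5)):
                rows.append(
                    {
                        "cell_line": exp.cell_line,
                        "condition": exp.condition,
                        "day": day,
                        "replicate": rep,
                        "count": count,
                        "er_status": exp.er_status,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def summarize_growth(
    experiments: list[GrowthExperiment],
    formula: str = "excess_ratio",
    threshold: float = RESPONSIVE_THRESHOLD,
) -> pd.DataFrame:
    """Per-cell-line table of condition growth ratios, the growth measure and
    the responsiveness call."""
    by_line: dict[str, dict[str, float]] = {}
    er_status: dict[str, str] = {}
    for exp in experiments:
        by_line.setdefault(exp.cell_line, {})[exp.condition] = condition_growth_ratio(exp)
        er_status[exp.cell_line] = exp.er_status
    rows = []
    for line, ratios in sorted(by_line.items()):
        if not {"E2", "noE2"} <= set(ratios):
            raise ValidationError(f"cell line {line!r} is missing one of the E2/noE2 conditions")
        measure = growth_measure(ratios["E2"], ratios["noE2"], formula=formula)
        rows.append(
            {
                "cell_line": line,
                "gr_e2": ratios["E2"],
                "gr_noe2": ratios["noE2"],
                "growth_measure": measure,
                "responsive": classify_cell_line(measure, threshold=threshold),
                "er_status": er_status[line],
            }
        )
    return pd.DataFrame(rows).set_index("cell_line")
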