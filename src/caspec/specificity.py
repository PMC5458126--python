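"""On/off-target specificity statistics.

For a condition measured at one on-target site and several off-target sites
(per-site editing percentages, e.g. percent reads with qualifying indels or
percent EGFP-negative cells), the on/off ratio of an off-target site is

    r = on_value / off_value

with any value equal to 0 replaced by a small floor (default 1e-05) before
dividing, so ratios stay finite; substitutions are counted and reported.  The
fold improvement of a test condition over a control at one site is the ratio
of their on/off ratios, and the experiment-level summary is the median and
quartiles (linear interpolation between order statistics) of the per-site fold
improvements.  A site counts as improved when its fold improvement is strictly
greater than 1.

No background subtraction is applied by default: untreated-sample background
editing is reported alongside, not subtracted (``subtract_background=True``
opts in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import read_tsv, write_tsv

DEFAULT_ZERO_FLOOR = 1e-05
QUARTILE_CONVENTION = "linear interpolation between order statistics"


@dataclass
class ConditionMeasurements:
    """Per-site editing percentages for one condition."""

    label: str
    values: Mapping[str, float]   # site name -> percentage in [0, 100]
    on_target: str

    def __post_init__(self) -> None:
        if self.on_target not in self.values:
            raise ValueError(
                f"condition {self.label!r}: on-target {self.on_target!r} "
                f"missing from values")
        for site, v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(
                    f"condition {self.label!r}, site {site!r}: percentage "
                    f"{v} outside [0, 100]")

    @property
    def off_targets(self) -> list[str]:
        return [s for s in self.values if s != self.on_target]


@dataclass
class SpecificityReport:
    test_label: str
    control_label: str
    per_site: list[dict] = field(default_factory=list)
    median: float = float("nan")
    q25: float = float("nan")
    q75: float = float("nan")
    n_improved: int = 0
    n_sites: int = 0
    zero_substitutions: int = 0
    zero_floor: float = DEFAULT_ZERO_FLOOR
    quartile_convention: str = QUARTILE_CONVENTION

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        write_tsv(
            self.per_site, path,
            ["site", "on_off_test", "on_off_control", "fold_improvement"],
            comments=[
                f"test={self.test_label} control={self.control_label}",
                f"median={self.median:.6g} q25={self.q25:.6g} "
                f"q75={self.q75:.6g} improved={self.n_improved}/{self.n_sites}",
                f"zero_floor={self.zero_floor} "
                f"zero_substitutions={self.zero_substitutions}",
                f"quartiles: {self.quartile_convention}",
            ])


class _SubstitutionCounter:
    def __init__(self) -> None:
        self.count = 0


def on_off_ratio(on_value: float, off_value: float,
                 zero_floor: float = DEFAULT_ZERO_FLOOR,
                 _counter: _SubstitutionCounter | None = None) -> float:
    """On-target over off-target signal; zeros floored before dividing."""
    if on_value < 0 or off_value < 0:
        raise ValueError("percentages must be non-negative")
    n_subs = (on_value == 0) + (off_value == 0)
    if _counter is not None:
        _counter.count += n_subs
    on = on_value if on_value != 0 else zero_floor
    off = off_value if off_value != 0 else zero_floor
    return on / off


def fold_improvement(ratio_test: float, ratio_control: float) -> float:
    """On/off ratio of the test condition over the control's."""
    if ratio_test <= 0 or ratio_control <= 0:
        raise ValueError("on/off ratios must be positive")
    return ratio_test / ratio_control


def summarize_folds(folds: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation) of fold improvements."""
    if len(folds) == 0:
        raise ValueError("no fold improvements to summarise")
    arr = np.asarray(folds, dtype=float)
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q25), float(q75)


def count_improved_sites(folds: Sequence[float], threshold: float = 1.0) -> int:
    """Number of sites with fold improvement strictly above ``threshold``."""
    if len(folds) == 0:
        raise ValueError("no fold improvements to count")
    return int(sum(f > threshold for f in folds))


def build_specificity_report(test: ConditionMeasurements,
                             control: ConditionMeasurements,
                             zero_floor: float = DEFAULT_ZERO_FLOOR,
                             ) -> SpecificityReport:
    """Per-site on/off ratios, fold improvements, and the median/IQR summary.

    The two conditions must share the same on-target and off-target sites.
    """
    if set(test.values) != set(control.values):
        raise ValueError("conditions measure different site sets")
    if test.on_target != control.on_target:
        raise ValueError("conditions disagree on the on-target site")
    counter = _SubstitutionCounter()
    rows = []
    folds = []
    for site in test.off_targets:
        rt = on_off_ratio(test.values[test.on_target], test.values[site],
                          zero_floor, counter)
        rc = on_off_ratio(control.values[control.on_target],
                          control.values[site], zero_floor, counter)
        fi = fold_improvement(rt, rc)
        folds.append(fi)
        rows.append({"site": site, "on_off_test": rt, "on_off_control": rc,
                     "fold_improvement": fi})
    med, q25, q75 = summarize_folds(folds)
    return SpecificityReport(
        test_label=test.label, control_label=control.label, per_site=rows,
        median=med, q25=q25, q75=q75,
        n_improved=count_improved_sites(folds), n_sites=len(folds),
        zero_substitutions=counter.count, zero_floor=zero_floor)


def read_condition_table(path: str | Path, on_target: str,
                         ) -> dict[str, ConditionMeasurements]:
    """Read a long-format TSV with columns site, condition, pct.

    The shape mirrors per-region editing summaries, so published per-site
    indel-percentage tables can be fed in directly.
    """
    by_cond: dict[str, dict[str, float]] = {}
    for row in read_tsv(path):
        by_cond.setdefault(row["condition"], {})[row["site"]] = float(row["pct"])
    return {label: ConditionMeasurements(label=label, values=vals,
                                         on_target=on_target)
            for label, vals in by_cond.items()}
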