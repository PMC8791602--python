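"""Input table loading, validation, and sample quality control.

Concentration units are fixed per nutrient (mg 100 g⁻¹ for calcium, iron
and zinc; µg 100 g⁻¹ for selenium; g 100 g⁻¹ for omega-3) and are never
rescaled internally — unit bookkeeping only happens when converting to
reef-level availability.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .config import NUTRIENTS

SCHEMAS = {
    "samples": [
        "fish_id", "species", "family", "site", "habitat", "year",
        "nutrient", "concentration", "below_loq",
    ],
    "traits": ["species", "family", "K", "TL", "AM", "PEL", "LMX"],
    "uvc": ["site", "year", "point_count", "species", "length_cm", "abundance"],
    "benthic": ["site", "year", "hard_coral", "macroalgae",
                "structural_complexity"],
}


@dataclass
class QCReport:
    """Per-nutrient accounting of the sample-exclusion process."""

    input_counts: dict = field(default_factory=dict)
    below_loq_removed: dict = field(default_factory=dict)
    outliers_removed: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)

    def removal_fraction(self, nutrient: str) -> float:
        n_in = self.input_counts[nutrient]
        removed = self.below_loq_removed[nutrient] + self.outliers_removed[nutrient]
        return removed / n_in if n_in else 0.0

    def validate(self) -> None:
        for nut, n_in in self.input_counts.items():
            assert self.retained[nut] == (
                n_in - self.below_loq_removed[nut] - self.outliers_removed[nut]
            )
            assert 0.0 <= self.removal_fraction(nut) <= 1.0

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["removal_fraction"] = {
            n: self.removal_fraction(n) for n in self.input_counts
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"table {name!r} is missing required column(s): {', '.join(missing)}"
        )


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")


def write_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    # shortest-repr float formatting round-trips binary64 exactly
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda v: repr(float(v)))


def load_tables(paths: dict, delimiter: str = ",", schemas: dict | None = None):
    """Load and validate the input tables.

    Parameters
    ----------
    paths : dict
        Mapping of table name (any of ``samples``, ``traits``, ``uvc``,
        ``benthic``) to a CSV path. Only the provided tables are loaded.

    Returns
    -------
    tables : dict of DataFrame
    report : dict
        Row counts plus a list of UVC species missing from the trait table
        (``unknown_uvc_species``), each of which also triggers a warning.
    """
    schemas = {**SCHEMAS, **(schemas or {})}
    tables: dict[str, pd.DataFrame] = {}
    report: dict = {"row_counts": {}, "unknown_uvc_species": []}
    for name, path in paths.items():
        df = read_table(path, delimiter)
        if name in schemas:
            _check_columns(df, schemas[name], name)
        tables[name] = df
        report["row_counts"][name] = len(df)

    if "samples" in tables:
        s = tables["samples"]
        bad = ~s["nutrient"].isin(NUTRIENTS)
        if bad.any():
            raise ValueError(
                f"unknown nutrient(s): {sorted(s.loc[bad, 'nutrient'].unique())}"
            )
        dup = s.duplicated(subset=["fish_id", "nutrient"])
        if dup.any():
            pairs = s.loc[dup, ["fish_id", "nutrient"]].to_records(index=False)
            raise ValueError(f"duplicate fish_id × nutrient rows: {list(pairs)[:5]}")
        if ((s["concentration"] <= 0) & ~s["below_loq"]).any():
            raise ValueError("non-positive concentration in non-LOQ sample")
        s["below_loq"] = s["below_loq"].astype(bool)

    if "uvc" in tables and "traits" in tables:
        known = set(tables["traits"]["species"])
        unknown = sorted(set(tables["uvc"]["species"]) - known)
        if unknown:
            warnings.warn(
                f"UVC species absent from trait table: {unknown}", stacklevel=2
            )
            report["unknown_uvc_species"] = unknown
    return tables, report


def apply_qc(
    samples: pd.DataFrame,
    multiplier: float = 2.0,
    spread: str = "sd",
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the sample-exclusion rules and return (filtered, QCReport).

    Below-LOQ samples are dropped first. Then, per nutrient, any value
    greater than ``mean + multiplier × spread`` is removed, where the mean
    and spread are computed once on the post-LOQ values (single pass, never
    iterated) and ``spread`` is the standard deviation by default, or the
    standard error of the mean with ``spread="sem"``. The filter is
    one-sided: only the upper tail is trimmed.
    """
    if spread not in ("sd", "sem"):
        raise ValueError("spread must be 'sd' or 'sem'")
    report = QCReport()
    kept = []
    for nut, grp in samples.groupby("nutrient", sort=False):
        report.input_counts[nut] = len(grp)
        loq = grp["below_loq"].astype(bool)
        report.below_loq_removed[nut] = int(loq.sum())
        vals = grp.loc[~loq]
        if len(vals) == 0:
            raise ValueError(f"all samples of {nut!r} are below LOQ")
        if len(vals) < 2:
            raise ValueError(f"need >= 2 retained samples for {nut!r}")
        x = vals["concentration"].to_numpy(float)
        s = x.std(ddof=1)
        if spread == "sem":
            s = s / len(x) ** 0.5
        threshold = x.mean() + multiplier * s
        keep = x <= threshold
        report.outliers_removed[nut] = int((~keep).sum())
        report.retained[nut] = int(keep.sum())
        kept.append(vals.loc[keep])
    filtered = pd.concat(kept).sort_index()
    report.validate()
    return filtered, report
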