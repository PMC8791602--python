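"""Interspecific vs intraspecific micronutrient variation.

Both scopes are quantified as pairwise absolute differences in predicted
concentrations, expressed as a percentage of the pair mean so magnitudes
are comparable across nutrients and invariant to units. Interspecific:
all unordered species pairs from the trait model's posterior medians.
Intraspecific: per dual-habitat species, the difference between its
predicted concentration in recovering-coral and macroalgal habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariationSummary",
    "pairwise_percent_difference",
    "interspecific_differences",
    "intraspecific_differences",
]


@dataclass
class VariationSummary:
    nutrient: str
    scope: str  # "interspecific" or "intraspecific"
    differences: pd.DataFrame  # long table of pairwise differences
    median_pct: float
    q25_pct: float
    q75_pct: float
    n_pairs: int


def pairwise_percent_difference(a: float, b: float) -> float:
    """|a − b| as a percentage of the pair mean (0 when both are 0)."""
    m = 0.5 * (a + b)
    if m == 0:
        return 0.0
    return 100.0 * abs(a - b) / m


def interspecific_differences(species_medians: pd.DataFrame,
                              nutrient: str) -> VariationSummary:
    """Among-species differences from posterior-median concentrations.

    ``species_medians`` needs columns ``species`` and ``median`` for one
    nutrient; all C(n, 2) unordered pairs are compared.
    """
    df = species_medians.dropna(subset=["median"])
    sp = df["species"].to_numpy()
    c = df["median"].to_numpy(float)
    n = len(sp)
    if n < 2:
        raise ValueError("need at least 2 species")
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({
                "species_a": sp[i],
                "species_b": sp[j],
                "abs_difference": abs(c[i] - c[j]),
                "pct_of_mean": pairwise_percent_difference(c[i], c[j]),
            })
    d = pd.DataFrame(rows)
    q25, med, q75 = np.percentile(d["pct_of_mean"], [25, 50, 75])
    return VariationSummary(nutrient, "interspecific", d,
                            float(med), float(q25), float(q75), len(d))


def intraspecific_differences(habitat_medians: pd.DataFrame,
                              nutrient: str) -> VariationSummary:
    """Within-species differences between habitat regimes.

    ``habitat_medians`` needs columns ``species``, ``habitat`` (coral /
    macroalgal) and ``median``. Species missing either habitat are
    excluded with a warning. The signed response-scale difference
    (macroalgal − coral) is retained for reporting absolute contrasts.
    """
    piv = habitat_medians.pivot_table(index="species", columns="habitat",
                                      values="median")
    need = {"coral", "macroalgal"}
    missing_cols = need - set(piv.columns)
    if missing_cols:
        raise ValueError(f"missing habitat predictions: {sorted(missing_cols)}")
    incomplete = piv.index[piv[list(need)].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"species missing one habitat excluded: {sorted(incomplete)}",
            stacklevel=2,
        )
        piv = piv.drop(index=incomplete)
    rows = []
    for sp, row in piv.iterrows():
        c_c, c_m = float(row["coral"]), float(row["macroalgal"])
        rows.append({
            "species": sp,
            "coral": c_c,
            "macroalgal": c_m,
            "signed_difference": c_m - c_c,
            "abs_difference": abs(c_m - c_c),
            "pct_of_mean": pairwise_percent_difference(c_c, c_m),
        })
    d = pd.DataFrame(rows)
    if d.empty:
        raise ValueError("no species with both habitats")
    q25, med, q75 = np.percentile(d["pct_of_mean"], [25, 50, 75])
    return VariationSummary(nutrient, "intraspecific", d,
                            float(med), float(q25), float(q75), len(d))
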