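"""RGC survival relative to uninjured age-matched controls (AMCs).

After optic nerve crush, per-retina RGC densities are expressed as
percentages of the median density of uninjured age-matched controls of the
same species/age stratum: survival_pct = 100 * density / median(control
densities). Densities (not raw counts) are normalized so that dissection
artifacts and, in growing fish, retinal expansion cancel out. Per-quadrant
survival normalizes each quadrant's density to the median of the same
quadrant in controls.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_amc",
    "build_survival_table",
    "summarize_survival",
    "MissingControlError",
]

GROUP_KEYS = ["species_id", "age_label", "dpi", "quadrant"]


class MissingControlError(ValueError):
    """An injured group has no uninjured (dpi 0) control group."""


def normalize_to_amc(
    injured_densities: Sequence[float], control_densities: Sequence[float]
) -> np.ndarray:
    """Survival percentages: 100 * density / median(control densities).

    The median uses the midpoint-of-two rule for even-sized control groups.
    Empty controls or a zero control median are errors.
    """
    controls = np.asarray(control_densities, dtype=float)
    injured = np.asarray(injured_densities, dtype=float)
    if controls.size == 0:
        raise ValueError("control group is empty")
    if np.any(controls < 0) or np.any(injured < 0):
        raise ValueError("densities must be >= 0")
    ref = float(np.median(controls))
    if ref == 0:
        raise ValueError("degenerate control group: median density is 0")
    return 100.0 * injured / ref


def build_survival_table(per_retina_results: pd.DataFrame) -> pd.DataFrame:
    """Assemble per-retina survival percentages from density measurements.

    ``per_retina_results`` needs columns ``retina_id, species_id, age_label,
    dpi, density`` and optionally ``quadrant`` (absent or NaN = whole
    retina). Every (species, age, quadrant) stratum containing injured rows
    (dpi > 0) must also contain dpi-0 control rows; otherwise
    :class:`MissingControlError` names the offending group. Within each
    stratum every density is normalized to the median control density, so
    the dpi-0 group's median survival is exactly 100%.
    """
    df = per_retina_results.copy()
    required = ["retina_id", "species_id", "age_label", "dpi", "density"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"per-retina results missing column(s) {missing}")
    if "quadrant" not in df.columns:
        df["quadrant"] = "whole"
    df["quadrant"] = df["quadrant"].fillna("whole")

    out = []
    for (species, age, quadrant), stratum in df.groupby(
        ["species_id", "age_label", "quadrant"], sort=False
    ):
        controls = stratum.loc[stratum["dpi"] == 0, "density"]
        if (stratum["dpi"] > 0).any() and controls.empty:
            raise MissingControlError(
                f"no dpi-0 controls for group (species={species}, age={age}, "
                f"quadrant={quadrant})"
            )
        if controls.empty:
            continue
        stratum = stratum.copy()
        stratum["survival_pct"] = normalize_to_amc(
            stratum["density"].to_numpy(), controls.to_numpy()
        )
        out.append(stratum)
    if not out:
        raise ValueError("no usable groups in per-retina results")
    table = pd.concat(out, ignore_index=True)
    return table[
        ["retina_id", "species_id", "age_label", "dpi", "quadrant", "density", "survival_pct"]
    ]


def summarize_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group median and 25th-75th percentile survival summary."""
    def q25(s):
        return float(np.percentile(s, 25))

    def q75(s):
        return float(np.percentile(s, 75))

    g = table.groupby(GROUP_KEYS, sort=True)["survival_pct"]
    summary = g.agg(median="median", q25=q25, q75=q75, n="count").reset_index()
    return summary
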