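"""Hakanson potential ecological risk index for soil heavy metals.

For each metal *i* the contamination factor ``C_r^i`` is the measured
concentration divided by a regulatory reference concentration, the
single-metal ecological risk is ``E_r^i = T_r^i * C_r^i`` with ``T_r^i``
the toxic-response factor, and the aggregate potential ecological risk
index is ``RI = sum_i E_r^i``.

``E_r`` grades follow the conventional breaks 40 / 80 / 160 / 320
(low, moderate, considerable, high, very high). The value 320 itself is
assigned to *very_high*. No grade scale is defined for RI: the literature
breaks for RI depend on how many metals enter the sum, so grading is left
to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, PanelError, SchemaError

#: Canonical metal order used throughout the package.
METALS: tuple[str, ...] = ("Cr", "Ni", "Zn", "Hg", "Cu", "As", "Cd", "Pb")

#: Conventional Hakanson toxic-response factors (dimensionless).
DEFAULT_TOXIC_RESPONSE: dict[str, float] = {
    "Hg": 40.0, "Cd": 30.0, "As": 10.0, "Cu": 5.0,
    "Pb": 5.0, "Ni": 5.0, "Cr": 2.0, "Zn": 1.0,
}

GRADE_LABELS = ("low", "moderate", "considerable", "high", "very_high")
GRADE_BOUNDS = (40.0, 80.0, 160.0, 320.0)


@dataclass(frozen=True)
class MetalPanel:
    """The eight metals with their toxic-response factors and reference concentrations.

    Parameters
    ----------
    toxic_response
        Dimensionless toxic-response factor per metal; defaults to the
        conventional Hakanson values.
    reference
        Reference concentration (mg/kg) per metal. There is no default:
        regulatory reference values are jurisdiction-specific and must be
        supplied (the synthetic scene generator supplies its own).
    """

    reference: Mapping[str, float]
    toxic_response: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOXIC_RESPONSE)
    )
    metals: tuple[str, ...] = METALS

    def __post_init__(self) -> None:
        for name, mapping in (("toxic_response", self.toxic_response),
                              ("reference", self.reference)):
            missing = [m for m in self.metals if m not in mapping]
            if missing:
                raise PanelError(f"{name} missing metals: {missing}")
            bad = [m for m in self.metals if not np.isfinite(mapping[m]) or mapping[m] <= 0]
            if bad:
                raise PanelError(f"{name} must be strictly positive and finite; bad: {bad}")
        if len(set(self.metals)) != len(self.metals):
            raise PanelError("duplicate metals in panel")

    def to_dict(self) -> dict:
        return {
            "metals": list(self.metals),
            "toxic_response": {m: float(self.toxic_response[m]) for m in self.metals},
            "reference": {m: float(self.reference[m]) for m in self.metals},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetalPanel":
        metals = tuple(d.get("metals", METALS))
        return cls(reference=dict(d["reference"]),
                   toxic_response=dict(d.get("toxic_response", DEFAULT_TOXIC_RESPONSE)),
                   metals=metals)


@dataclass(frozen=True)
class RiskResult:
    """Per-subject risk scores: contamination factors, per-metal risks, total RI, grades."""

    subject_id: str
    cf: Mapping[str, float]
    er: Mapping[str, float]
    ri: float
    grade: Mapping[str, str]


def contamination_factor(conc, ref):
    """Contamination factor ``C_r = conc / ref`` (both mg/kg).

    Accepts scalars or arrays; ``ref`` must be strictly positive and
    ``conc`` nonnegative.
    """
    conc = np.asarray(conc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if np.any(ref <= 0) or not np.all(np.isfinite(ref)):
        raise PanelError("reference concentration must be strictly positive and finite")
    if np.any(conc < 0):
        raise DataError("concentrations must be nonnegative")
    out = conc / ref
    return float(out) if out.ndim == 0 else out


def ecological_risk(panel: MetalPanel, metal: str, cf) -> float:
    """Single-metal ecological risk ``E_r = T_r * C_r``."""
    if metal not in panel.metals:
        raise KeyError(f"unknown metal {metal!r}; panel has {panel.metals}")
    cf = np.asarray(cf, dtype=float)
    out = panel.toxic_response[metal] * cf
    return float(out) if out.ndim == 0 else out


def grade_er(er) -> str | np.ndarray:
    """Risk grade for an ``E_r`` value: breaks at 40, 80, 160, 320.

    ``[0, 40)`` low, ``[40, 80)`` moderate, ``[80, 160)`` considerable,
    ``[160, 320)`` high, ``[320, inf)`` very_high.
    """
    arr = np.asarray(er, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DataError("E_r must be nonnegative and finite")
    idx = np.digitize(arr, GRADE_BOUNDS, right=False)
    labels = np.asarray(GRADE_LABELS, dtype=object)[idx]
    return str(labels) if arr.ndim == 0 else labels


def total_ri(er_by_metal: Mapping[str, float], metals: Iterable[str] = METALS) -> float:
    """Aggregate potential ecological risk index: the sum of ``E_r`` over all panel metals."""
    metals = tuple(metals)
    missing = [m for m in metals if m not in er_by_metal]
    if missing:
        raise SchemaError(f"incomplete panel: missing E_r for {missing}")
    return float(sum(float(er_by_metal[m]) for m in metals))


def score_samples(samples: pd.DataFrame, panel: MetalPanel) -> pd.DataFrame:
    """Score a sample table: one row of CF / E_r / RI / grades per input row.

    Parameters
    ----------
    samples
        DataFrame with a ``sample_id`` column and one concentration column
        (mg/kg) per panel metal. Extra columns (lon, lat, town_id...) pass
        through untouched in the index order.

    Returns
    -------
    DataFrame with columns ``subject_id``, ``cf_<metal>``, ``er_<metal>``,
    ``ri`` and ``grade_<metal>``, in input row order.
    """
    if len(samples) == 0:
        raise DataError("empty sample table")
    if "sample_id" not in samples.columns:
        raise SchemaError("sample table missing 'sample_id' column")
    for m in panel.metals:
        if m not in samples.columns:
            raise SchemaError(f"sample table missing concentration column for metal {m!r}")
        col = pd.to_numeric(samples[m], errors="coerce")
        if col.isna().any():
            bad = samples.loc[col.isna(), "sample_id"].iloc[0]
            raise SchemaError(f"non-numeric or missing {m} concentration for sample {bad!r}")
        if (col < 0).any():
            bad = samples.loc[col < 0, "sample_id"].iloc[0]
            raise DataError(f"negative {m} concentration for sample {bad!r}")

    out = pd.DataFrame({"subject_id": samples["sample_id"].to_numpy()})
    er_cols = {}
    for m in panel.metals:
        cf = contamination_factor(samples[m].to_numpy(dtype=float), panel.reference[m])
        er = panel.toxic_response[m] * cf
        out[f"cf_{m}"] = cf
        out[f"er_{m}"] = er
        er_cols[m] = er
    out["ri"] = np.sum([er_cols[m] for m in panel.metals], axis=0)
    for m in panel.metals:
        out[f"grade_{m}"] = grade_er(er_cols[m])
    return out


def risk_results(scored: pd.DataFrame, metals: Iterable[str] = METALS) -> list[RiskResult]:
    """View a scored table as a list of :class:`RiskResult` records."""
    metals = tuple(metals)
    return [
        RiskResult(
            subject_id=row["subject_id"],
            cf={m: row[f"cf_{m}"] for m in metals},
            er={m: row[f"er_{m}"] for m in metals},
            ri=row["ri"],
            grade={m: row[f"grade_{m}"] for m in metals},
        )
        for _, row in scored.iterrows()
    ]
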