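"""Unit selectivity typology.

A unit is "selective" for a digit in a modality when its
stimulus-specific information about that digit, measured on the
single-modality test subset, exceeds a threshold. Thresholds are set
once per modality as the 80th percentile of the pooled unit x digit
information values of a designated reference condition (the final
encoding layer of the consistent-trained network) and then applied
unchanged to every other condition.

Selective units fall into four types: visual (selective only to visual
input), auditory (only auditory), inconsistent (both modalities, but
disjoint digit sets), consistent (both modalities with at least one
shared digit — the shared representation). Units selective in neither
modality are labeled non_selective and sit outside the four-type
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .info_analysis import AnalysisError, InfoTable

TYPES = ("visual", "auditory", "inconsistent", "consistent", "non_selective")


@dataclass
class UnitTypology:
    """Per-unit type assignment with the selective-digit sets and the
    thresholds that produced it."""

    types: list[str]
    visual_digits: list[frozenset[int]]
    auditory_digits: list[frozenset[int]]
    theta_v: float
    theta_a: float

    @property
    def n_units(self) -> int:
        return len(self.types)

    @property
    def counts(self) -> dict[str, int]:
        return {t: self.types.count(t) for t in TYPES}

    def count(self, type_name: str) -> int:
        return self.types.count(type_name)

    def to_frame(self) -> pd.DataFrame:
        fmt = lambda s: ",".join(str(d) for d in sorted(s))
        return pd.DataFrame({
            "unit": np.arange(self.n_units),
            "type": self.types,
            "visual_digits": [fmt(s) for s in self.visual_digits],
            "auditory_digits": [fmt(s) for s in self.auditory_digits],
        })


def percentile_threshold(info: InfoTable, percentile: float = 80.0) -> float:
    """Selectivity threshold: the given percentile of the pooled
    (unit x digit) information values, linear-interpolation definition."""
    if not 0 < percentile < 100:
        raise AnalysisError("percentile must lie in (0, 100)")
    if info.info.size == 0:
        raise AnalysisError("empty info table")
    return float(np.percentile(info.info.ravel(), percentile, method="linear"))


def selective_digits(info_row: np.ndarray, theta: float) -> frozenset[int]:
    """Digits whose information strictly exceeds the threshold."""
    if theta < 0:
        raise AnalysisError("theta must be >= 0")
    return frozenset(int(d) for d in np.flatnonzero(np.asarray(info_row) > theta))


def classify_units(
    visual_info: InfoTable,
    audio_info: InfoTable,
    theta_v: float,
    theta_a: float,
) -> UnitTypology:
    """Assign every unit to its selectivity type (see module docstring)."""
    if visual_info.n_units != audio_info.n_units or \
            list(visual_info.unit_ids) != list(audio_info.unit_ids):
        raise AnalysisError("visual and auditory tables must cover identical units")
    types: list[str] = []
    v_sets: list[frozenset[int]] = []
    a_sets: list[frozenset[int]] = []
    for u in range(visual_info.n_units):
        v = selective_digits(visual_info.info[u], theta_v)
        a = selective_digits(audio_info.info[u], theta_a)
        if v and a:
            types.append("consistent" if v & a else "inconsistent")
        elif v:
            types.append("visual")
        elif a:
            types.append("auditory")
        else:
            types.append("non_selective")
        v_sets.append(v)
        a_sets.append(a)
    return UnitTypology(types=types, visual_digits=v_sets, auditory_digits=a_sets,
                        theta_v=float(theta_v), theta_a=float(theta_a))
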