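"""Categorical vocabularies for the ward data model.

The hospital schema carries five categorical patient attributes with fixed
category counts (admission type 5, referral source 49, patient class 21,
age band 8, wards-visited band 4).  Real extracts come with their own label
sets; the synthetic generator uses the neutral labels defined here.  The
feature builder only cares about the *sizes* and membership, so vocabularies
are injectable everywhere and these defaults are just the shipped ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel level that ingest assigns to missing categorical values.  It is
#: accepted everywhere but owns no count column: an UNKNOWN patient is in the
#: roster (and occupancy) yet contributes to none of that attribute's counts.
UNKNOWN = "UNKNOWN"

N_ADMISSION_TYPES = 5
N_REFERRALS = 49
N_PATIENT_CLASSES = 21
N_AGE_BANDS = 8
N_WARDS_VISITED_BANDS = 4


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}_{i:02d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class Vocabulary:
    """Category label sets plus the age-band edges used to discretize age."""

    admission_types: tuple[str, ...] = _labels("ADMTYPE", N_ADMISSION_TYPES)
    referrals: tuple[str, ...] = _labels("REF", N_REFERRALS)
    patient_classes: tuple[str, ...] = _labels("CLASS", N_PATIENT_CLASSES)
    #: 9 edges -> 8 half-open bands [e_i, e_{i+1});  the last edge is a cap.
    age_band_edges: tuple[float, ...] = (0, 18, 30, 40, 50, 60, 70, 80, 120)
    age_bands: tuple[str, ...] = _labels("AGE", N_AGE_BANDS)
    #: wards-visited counts 1, 2, 3 and "4 or more"
    wards_visited_bands: tuple[str, ...] = ("WV_1", "WV_2", "WV_3", "WV_4PLUS")
    genders: tuple[str, ...] = ("M", "F")

    def __post_init__(self) -> None:
        if len(self.age_band_edges) != len(self.age_bands) + 1:
            raise ValueError("age_band_edges must have len(age_bands) + 1 entries")

    def age_band(self, age: float) -> str:
        """Map an age in years to its band label (ages past the cap clamp)."""
        edges = np.asarray(self.age_band_edges)
        i = int(np.clip(np.searchsorted(edges, age, side="right") - 1,
                        0, len(self.age_bands) - 1))
        return self.age_bands[i]

    def wards_visited_band(self, n: int) -> str:
        """Map a wards-visited count (>= 1) to its band label."""
        i = int(np.clip(n, 1, len(self.wards_visited_bands))) - 1
        return self.wards_visited_bands[i]


DEFAULT_VOCAB = Vocabulary()
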