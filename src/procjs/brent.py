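"""Ingest of long-term goose colony encounter histories with three age codes.

Real colony datasets distinguish juveniles (ringed as goslings), second-year
birds (fledged the previous year) and adults.  Survival does not
discriminate second-year birds from adults, so for the survival process the
classes collapse to juvenile/adult; detection, however, keeps the
second-year class separate, because pre-breeding birds attend the colony at
lower and more variable rates — this is the age/time-varying detection
variant of the model (``detection="age_time"``).

The expected CSV dialect (converted once by the user from the archived
RDATA) is the package's encounter-history format with a three-level age
code: ``id, release_occasion, age_at_release`` in {``juv``, ``sy``, ``ad``},
then ``y1..yT``.  A bird released as a juvenile is in the second-year
detection class at the occasion immediately after release, which the m-array
likelihood handles structurally: only juvenile-release rows use the
second-year detection probability, and only at their first re-encounter
occasion.  Birds released as ``sy`` are adults from their next occasion on,
so they enter the adult m-array directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ADULT, JUVENILE, EncounterHistorySet

__all__ = ["BrentData", "brent_ingest"]

_CODE_MAP = {"juv": JUVENILE, "sy": ADULT, "ad": ADULT}


@dataclass
class BrentData:
    """Encounter histories plus the original three-level age codes."""

    histories: EncounterHistorySet
    age_codes: np.ndarray  # original labels per individual: 'juv'|'sy'|'ad'

    @property
    def n_by_code(self) -> dict:
        labels, counts = np.unique(self.age_codes, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def brent_ingest(path) -> BrentData:
    """Read a three-age-code encounter-history CSV.

    Age codes map to survival classes as juv -> juvenile and sy, ad ->
    adult; the original codes are retained for detection-class accounting.
    Unknown codes and empty files are rejected.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no encounter histories")
    ycols = sorted(
        [c for c in df.columns if c.startswith("y") and c[1:].isdigit()],
        key=lambda c: int(c[1:]),
    )
    if not ycols:
        raise ValueError(f"{path}: no detection columns y1..yT found")
    codes = df["age_at_release"].astype(str).to_numpy()
    unknown = sorted(set(codes) - set(_CODE_MAP))
    if unknown:
        raise ValueError(f"{path}: unknown age codes {unknown}; expected juv/sy/ad")
    survival_class = np.array([_CODE_MAP[c] for c in codes], dtype=np.int8)
    histories = EncounterHistorySet(
        y=df[ycols].to_numpy(dtype=np.int8),
        tau=df["release_occasion"].to_numpy(dtype=np.int64) - 1,
        age_at_release=survival_class,
    )
    return BrentData(histories=histories, age_codes=codes)
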