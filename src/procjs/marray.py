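"""Age-structured m-arrays and the multinomial CJS cell probabilities.

An m-array summarizes encounter histories by (release occasion, occasion of
first re-encounter) counts.  Conditioning on each release, the row of counts
is multinomial over "first re-encountered at occasion c" cells plus a
"never re-encountered" cell, which marginalizes the latent alive/dead states
out of the CJS likelihood and makes its cost independent of the number of
individuals.

Two arrays are kept: one for individuals released as juveniles (their first
interval uses juvenile survival) and one for adults.  Standard bookkeeping
applies: every re-encounter of a live individual before the final occasion
re-enters the *adult* array as a new release, since a juvenile that survived
its first interval has aged into an adult.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from numba import njit

from .simulate import ADULT, JUVENILE, EncounterHistorySet

__all__ = ["AgeMArraySet", "build_marrays", "cell_probabilities"]


@dataclass
class AgeMArraySet:
    """Juvenile and adult m-arrays for T occasions.

    Each array has shape (T-1, T): row r (0-based) collects individuals
    released at occasion r; column c for c < T-1 counts first re-encounters
    at occasion c+1; the final column counts those never re-encountered.
    Cells with c < r are structurally zero.
    """

    m_juv: np.ndarray
    m_ad: np.ndarray

    def __post_init__(self) -> None:
        self.m_juv = np.asarray(self.m_juv, dtype=np.int64)
        self.m_ad = np.asarray(self.m_ad, dtype=np.int64)
        if self.m_juv.shape != self.m_ad.shape:
            raise ValueError("juvenile and adult arrays must share a shape")
        rows, cols = self.m_juv.shape
        if cols != rows + 1:
            raise ValueError(
                f"expected shape (T-1, T), got ({rows}, {cols})"
            )
        if np.any(self.m_juv < 0) or np.any(self.m_ad < 0):
            raise ValueError("m-array counts must be non-negative")

    @property
    def n_occasions(self) -> int:
        return self.m_juv.shape[0] + 1

    @property
    def releases_juv(self) -> np.ndarray:
        """Row release totals for the juvenile array."""
        return self.m_juv.sum(axis=1)

    @property
    def releases_ad(self) -> np.ndarray:
        return self.m_ad.sum(axis=1)

    def to_frame(self, age_class: str) -> pd.DataFrame:
        m = {"juv": self.m_juv, "ad": self.m_ad}[age_class]
        T = self.n_occasions
        cols = [f"recap_{c}" for c in range(2, T + 1)] + ["never"]
        df = pd.DataFrame(m, columns=cols)
        df.insert(0, "release_occasion", np.arange(1, T))
        return df

    @classmethod
    def from_frames(cls, juv: pd.DataFrame, ad: pd.DataFrame) -> "AgeMArraySet":
        def grab(df):
            cols = [c for c in df.columns if c.startswith("recap_")] + ["never"]
            return df[cols].to_numpy(dtype=np.int64)

        return cls(m_juv=grab(juv), m_ad=grab(ad))


@njit(cache=True)
def _accumulate_marrays(y, tau, age, T):  # pragma: no cover - exercised via wrapper
    m_juv = np.zeros((T - 1, T), dtype=np.int64)
    m_ad = np.zeros((T - 1, T), dtype=np.int64)
    n = y.shape[0]
    for i in range(n):
        r = tau[i]
        juv_release = age[i] == 0
        while r < T - 1:
            nxt = -1
            for c in range(r + 1, T):
                if y[i, c] == 1:
                    nxt = c
                    break
            if juv_release:
                if nxt < 0:
                    m_juv[r, T - 1] += 1
                else:
                    m_juv[r, nxt - 1] += 1
            else:
                if nxt < 0:
                    m_ad[r, T - 1] += 1
                else:
                    m_ad[r, nxt - 1] += 1
            if nxt < 0:
                break
            r = nxt
            juv_release = False
    return m_juv, m_ad


def build_marrays(histories: EncounterHistorySet) -> AgeMArraySet:
    """Reduce encounter histories to age-structured m-arrays.

    Every (release, first re-encounter) pair in a history contributes one
    off-diagonal cell; re-encounters before the final occasion re-enter the
    adult array as fresh releases, so total re-encounter events are conserved
    between the histories and the arrays.  Individuals released at the final
    occasion carry no information and contribute nothing.
    """
    T = histories.n_occasions
    m_juv, m_ad = _accumulate_marrays(
        np.ascontiguousarray(histories.y),
        histories.tau,
        histories.age_at_release.astype(np.int64),
        T,
    )
    return AgeMArraySet(m_juv=m_juv, m_ad=m_ad)


def cell_probabilities(
    phi_ad: np.ndarray,
    phi_juv: np.ndarray,
    p: Union[float, np.ndarray],
    age_class: str,
    release_occasion: int,
    T: int,
    p_first: Optional[Union[float, np.ndarray]] = None,
) -> np.ndarray:
    """Multinomial cell probabilities for one m-array release row.

    P(first re-encounter at occasion c | released at r) =
    phi_first(r) * prod_{k=r+1}^{c-1} phi_ad[k] (1 - p_k) * p_c, where
    phi_first is the juvenile rate for a juvenile release row and the adult
    rate otherwise, and detection is indexed by the occasion of re-encounter.
    The "never re-encountered" cell is the complement, so the row sums to 1
    exactly.

    ``p`` may be scalar (constant detection) or a length-T vector indexed by
    occasion (entries 1..T-1 used).  ``p_first`` optionally overrides the
    detection probability at the occasion immediately after a *juvenile*
    release — the second-year detection class of the age/time-varying
    detection model; it defaults to ``p``.

    Occasions here are 0-based: ``release_occasion`` r in 0..T-2, and the
    returned row has T entries (columns c = 0..T-2 for re-encounter at
    occasion c+1, then "never").
    """
    phi_ad = np.asarray(phi_ad, dtype=float)
    phi_juv = np.asarray(phi_juv, dtype=float)
    p_vec = np.broadcast_to(np.asarray(p, dtype=float), (T,)).copy()
    pf_vec = (
        p_vec
        if p_first is None
        else np.broadcast_to(np.asarray(p_first, dtype=float), (T,)).copy()
    )
    for name, arr in (("phi_ad", phi_ad), ("phi_juv", phi_juv)):
        if np.any(arr <= 0) or np.any(arr > 1):
            raise ValueError(f"{name} entries must lie in (0, 1]")
    if np.any(p_vec < 0) or np.any(p_vec > 1) or np.any(pf_vec < 0) or np.any(pf_vec > 1):
        raise ValueError("detection probabilities must lie in [0, 1]")
    r = release_occasion
    if not 0 <= r <= T - 2:
        raise ValueError(f"release occasion must lie in [0, {T - 2}], got {r}")
    if age_class not in ("juv", "ad"):
        raise ValueError(f"age_class must be 'juv' or 'ad', got {age_class!r}")
    juv = age_class == "juv"
    row = np.zeros(T)
    alive = phi_juv[r] if juv else phi_ad[r]  # P(alive at r+1)
    for c in range(r + 1, T):
        pc = pf_vec[c] if (juv and c == r + 1) else p_vec[c]
        row[c - 1] = alive * pc
        if c < T - 1:
            miss = 1.0 - (pf_vec[c] if (juv and c == r + 1) else p_vec[c])
            alive *= miss * phi_ad[c]
    row[T - 1] = 1.0 - row[: T - 1].sum()
    return row
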