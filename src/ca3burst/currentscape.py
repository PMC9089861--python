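"""Decomposition of ionic currents into inward/outward totals and shares.

At every instant each species' current (positive = outward) is split into
its positive and negative part; the totals are the sums of those parts and
the percentage share of each species is its part divided by the total of the
same sign, ×100.  A species that changes sign mid-trace therefore moves
between the outward and inward pools instant by instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import CurrentTraces

__all__ = ["Currentscape", "compute_currentscape"]


@dataclass
class Currentscape:
    """Shares (%) and totals (mA/cm²) of inward and outward currents."""

    time: np.ndarray
    species: tuple[str, ...]
    total_outward: np.ndarray  # >= 0
    total_inward: np.ndarray  # >= 0 (magnitude of the inward sum)
    share_outward: np.ndarray  # (n_species, n_samples), %
    share_inward: np.ndarray  # (n_species, n_samples), %
    zero_outward: np.ndarray = None  # bool flags: total of that sign was 0
    zero_inward: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"total_outward": self.total_outward, "total_inward": self.total_inward}
        for k, s in enumerate(self.species):
            cols[f"out_pct_{s}"] = self.share_outward[k]
            cols[f"in_pct_{s}"] = self.share_inward[k]
        return pd.DataFrame(cols, index=pd.Index(self.time, name="time_ms"))


def compute_currentscape(currents: CurrentTraces) -> Currentscape:
    """Split per-species currents into signed pools and percentage shares.

    Instants where a pool's total is zero get all-zero shares and are
    flagged; otherwise shares of each sign sum to exactly 100%.
    """
    mat = currents.matrix()  # (n_species, n_samples)
    pos = np.clip(mat, 0.0, None)
    neg = np.clip(-mat, 0.0, None)
    total_out = pos.sum(axis=0)
    total_in = neg.sum(axis=0)
    zero_out = total_out == 0.0
    zero_in = total_in == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        share_out = np.where(zero_out[None, :], 0.0, pos / total_out[None, :] * 100.0)
        share_in = np.where(zero_in[None, :], 0.0, neg / total_in[None, :] * 100.0)
    return Currentscape(
        time=currents.time,
        species=currents.species,
        total_outward=total_out,
        total_inward=total_in,
        share_outward=share_out,
        share_inward=share_in,
        zero_outward=zero_out,
        zero_inward=zero_in,
    )
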