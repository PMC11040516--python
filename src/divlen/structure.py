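"""mRNA-accessibility z-score profiles around translation initiation sites.

Input: per-gene probabilities of each base being unpaired across the
thermodynamic ensemble of mRNA secondary structures, over a fixed window from
100 bp upstream to 200 bp downstream of the start codon (position 0 = first
base of the start codon).  The probabilities come from an external
partition-function folder; this module never invokes one.

Per-position probabilities are first averaged across genes, then converted to
z-scores against a baseline estimated from two flank windows (−90..−51 and
+151..+190) of the averaged profile.  Two summary statistics are extracted:

* ``S_ss`` — the maximum z-score over the window (strength of the
  accessibility bump after the start codon);
* ``L_ss`` — the first position at or beyond +5 at which the z-score drops to
  or below zero (extent of the bump); undefined if z stays positive
  through +200.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WINDOW_START = -100
WINDOW_END = 200  # inclusive
POSITIONS = np.arange(WINDOW_START, WINDOW_END + 1)
FLANKS = ((-90, -51), (151, 190))  # inclusive windows
MIN_EFFECT_POS = 5


@dataclass
class UnpairedProfile:
    """Per-base unpaired probabilities for one gene over −100..+200."""

    gene_id: str
    p_unpaired: np.ndarray  # aligned with POSITIONS

    def __post_init__(self) -> None:
        self.p_unpaired = np.asarray(self.p_unpaired, dtype=float)
        if self.p_unpaired.shape != POSITIONS.shape:
            raise ValueError(
                f"{self.gene_id}: expected {len(POSITIONS)} positions, "
                f"got {len(self.p_unpaired)}"
            )
        if np.any((self.p_unpaired < 0) | (self.p_unpaired > 1)):
            raise ValueError(f"{self.gene_id}: probabilities outside [0, 1]")


@dataclass
class ZProfile:
    """Species-level z-score profile with its baseline statistics."""

    positions: np.ndarray
    mean_p: np.ndarray
    z: np.ndarray
    flank_mean: float
    flank_sd: float
    L_ss: int | None
    S_ss: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "mean_p": self.mean_p, "z": self.z})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _flank_indices() -> np.ndarray:
    parts = [
        np.flatnonzero((POSITIONS >= lo) & (POSITIONS <= hi)) for lo, hi in FLANKS
    ]
    return np.concatenate(parts)


def zscore_profile(profiles: Sequence[UnpairedProfile]) -> ZProfile:
    """Average probabilities across genes, then z-score against the flank baseline.

    The two flank windows are pooled into a single 80-position sample; the
    baseline sd is the population sd of the averaged profile over that pool.
    """
    if not profiles:
        raise ValueError("no profiles given")
    mean_p = np.mean([p.p_unpaired for p in profiles], axis=0)
    idx = _flank_indices()
    flank_mean = float(mean_p[idx].mean())
    flank_sd = float(mean_p[idx].std(ddof=0))
    if flank_sd == 0:
        raise ValueError("degenerate baseline: flank sd is zero")
    z = (mean_p - flank_mean) / flank_sd
    L_ss, S_ss = structure_effects_from_z(z)
    return ZProfile(
        positions=POSITIONS.copy(),
        mean_p=mean_p,
        z=z,
        flank_mean=flank_mean,
        flank_sd=flank_sd,
        L_ss=L_ss,
        S_ss=S_ss,
    )


def structure_effects_from_z(z: np.ndarray) -> tuple[int | None, float]:
    """(L_ss, S_ss) from a z array aligned with POSITIONS.

    L_ss is the smallest position >= +5 with z <= 0 (None if z stays
    positive through +200); S_ss is the maximum z over the full window.
    """
    S_ss = float(np.max(z))
    tail = POSITIONS >= MIN_EFFECT_POS
    crossing = tail & (z <= 0)
    if not crossing.any():
        return None, S_ss
    return int(POSITIONS[crossing][0]), S_ss


def structure_effects(zprof: ZProfile) -> tuple[int | None, float]:
    """(L_ss, S_ss) of a computed z-profile."""
    return structure_effects_from_z(zprof.z)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_unpaired_tsv(path: str | Path) -> list[UnpairedProfile]:
    """Read a long TSV (gene_id, position, p_unpaired) into per-gene profiles."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        sub = sub.set_index("position").reindex(POSITIONS)
        if sub["p_unpaired"].isna().any():
            raise ValueError(f"{gene_id}: incomplete window (-100..+200)")
        out.append(UnpairedProfile(str(gene_id), sub["p_unpaired"].to_numpy()))
    return out


def write_unpaired_tsv(profiles: Iterable[UnpairedProfile], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"gene_id": p.gene_id, "position": POSITIONS, "p_unpaired": p.p_unpaired}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
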