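"""Dual-frequency echogram processing: MVBS, dB-difference classification
and NASC echo-integration into along-track distance bins.

Averaging of volume backscatter always happens in the linear domain
(``s_v = 10^(Sv/10)``); dB values are only a reporting scale.  The NASC
scaling constant ``4 * pi * 1852**2`` converts depth-integrated linear
backscatter (m^-1 integrated over m) to m^2 per square nautical mile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NASC_CONSTANT = 4.0 * np.pi * 1852.0**2

__all__ = [
    "EchogramGrid",
    "NASC_CONSTANT",
    "compute_mvbs",
    "db_difference_classify",
    "echo_integrate_nasc",
]


@dataclass
class EchogramGrid:
    """Sv matrix (dB re 1 m^-1), depth-sample rows by ping columns.

    ``depth_m`` gives the center depth of each row (strictly increasing)
    and ``along_track_nmi`` the cumulative distance of each ping
    (nondecreasing).  NaN marks missing samples.
    """

    sv_db: np.ndarray
    depth_m: np.ndarray
    along_track_nmi: np.ndarray
    frequency_khz: float

    def __post_init__(self) -> None:
        self.sv_db = np.asarray(self.sv_db, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.along_track_nmi = np.asarray(self.along_track_nmi, dtype=float)
        if self.sv_db.shape != (self.depth_m.size, self.along_track_nmi.size):
            raise ValueError("sv_db shape must be (n_depth, n_pings)")
        if self.depth_m.size > 1 and not np.all(np.diff(self.depth_m) > 0):
            raise ValueError("depths must be strictly increasing")
        if self.along_track_nmi.size > 1 and np.any(np.diff(self.along_track_nmi) < 0):
            raise ValueError("along-track distance must be nondecreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sv_db.shape


def _block_reduce_linear(sv_db: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Linear-domain block means; trailing partial blocks use what exists."""
    n_r, n_c = sv_db.shape
    out_r = -(-n_r // rows)
    out_c = -(-n_c // cols)
    lin = 10.0 ** (sv_db / 10.0)
    out = np.full((out_r, out_c), np.nan)
    for i in range(out_r):
        for j in range(out_c):
            block = lin[i * rows : (i + 1) * rows, j * cols : (j + 1) * cols]
            if np.isfinite(block).any():
                out[i, j] = np.nanmean(block)
    return 10.0 * np.log10(out)


def compute_mvbs(
    echogram: EchogramGrid, window_pings: int = 40, window_depth_m: float = 10.0
) -> EchogramGrid:
    """Mean volume backscattering strength over ping-by-depth windows.

    Each output cell is ``10*log10`` of the linear-domain mean of
    ``10^(Sv/10)`` over a window of ``window_pings`` pings by
    ``window_depth_m`` metres.  All-missing windows stay missing;
    trailing partial windows are averaged over available samples.
    """
    if window_pings < 1 or window_depth_m <= 0:
        raise ValueError("window dimensions must be >= 1")
    dz = np.diff(echogram.depth_m)
    sample_dz = float(dz[0]) if dz.size else window_depth_m
    rows = max(1, int(round(window_depth_m / sample_dz)))
    with np.errstate(divide="ignore", invalid="ignore"):
        mvbs = _block_reduce_linear(echogram.sv_db, rows, window_pings)
    n_out_r, n_out_c = mvbs.shape
    # window-center coordinates
    depth0 = echogram.depth_m[0] - 0.5 * sample_dz
    depths = depth0 + (np.arange(n_out_r) + 0.5) * rows * sample_dz
    track = np.array(
        [
            echogram.along_track_nmi[min(j * window_pings + window_pings // 2, echogram.shape[1] - 1)]
            for j in range(n_out_c)
        ]
    )
    return EchogramGrid(mvbs, depths, track, echogram.frequency_khz)


def db_difference_classify(
    mvbs120: EchogramGrid,
    mvbs38: EchogramGrid,
    low_db: float = 10.0,
    high_db: float = 16.3,
) -> np.ndarray:
    """Boolean mask of cells whose MVBS(120) - MVBS(38) falls in
    ``[low_db, high_db]`` (closed interval, both ends inclusive).

    Cells missing in either frequency classify as False.
    """
    if mvbs120.shape != mvbs38.shape:
        raise ValueError("MVBS grids are not co-registered")
    diff = mvbs120.sv_db - mvbs38.sv_db
    with np.errstate(invalid="ignore"):
        mask = (diff >= low_db) & (diff <= high_db)
    return np.where(np.isfinite(diff), mask, False)


def echo_integrate_nasc(
    sv: EchogramGrid,
    mask: np.ndarray,
    depth_min_m: float = 50.0,
    depth_max_m: float = 300.0,
    bin_nmi: float = 0.5,
) -> pd.DataFrame:
    """Integrate masked backscatter into NASC per along-track bin.

    Per bin, ``NASC = 4*pi*1852**2 * mean over pings of
    sum_depth(10^(Sv/10) * dz)`` restricted to masked cells inside
    ``[depth_min_m, depth_max_m]``.  Bins with no masked cells get
    NASC = 0 — a valid absence observation.  Returns a DataFrame with
    columns ``bin_index, along_track_nmi, nasc``.
    """
    if depth_min_m >= depth_max_m:
        raise ValueError("depth_min_m must be < depth_max_m")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sv.shape:
        raise ValueError("mask is not co-registered with the echogram")
    if sv.sv_db.size == 0:
        return pd.DataFrame(columns=["bin_index", "along_track_nmi", "nasc"])

    depths = sv.depth_m
    dz = np.empty_like(depths)
    if depths.size > 1:
        dz[:-1] = np.diff(depths)
        dz[-1] = dz[-2]
    else:
        dz[:] = 1.0
    in_window = (depths >= depth_min_m) & (depths <= depth_max_m)

    lin = np.where(mask & np.isfinite(sv.sv_db), 10.0 ** (sv.sv_db / 10.0), 0.0)
    lin = lin * in_window[:, None]
    per_ping = (lin * dz[:, None]).sum(axis=0)  # integrated s_v per ping

    bins = np.floor(sv.along_track_nmi / bin_nmi).astype(int)
    records = []
    for b in np.unique(bins):
        sel = bins == b
        nasc = NASC_CONSTANT * per_ping[sel].mean()
        records.append(
            {
                "bin_index": int(b),
                "along_track_nmi": (b + 0.5) * bin_nmi,
                "nasc": float(nasc),
            }
        )
    return pd.DataFrame.from_records(records)
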