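"""Epoch-level acceleration to day-level nine-band minutes, plus wear screening.

Raw wrist acceleration is summarised per 1-s epoch by ENMO (Euclidean norm of
the three axes minus 1 g, negatives truncated to zero, in mg).  Epochs within
the standardised 07:00-23:00 day are classified into nine intensity bands —
50 mg increments up to 350 mg, then 350-700 mg and >=700 mg — and per-day band
minutes are averaged over valid days and closed to 960 min to form each
participant's composition.

Wear screening follows the validity rules of the source protocol: a day is
valid when it holds >= 600 worn minutes, and a participant is retained when
they have >= 3 valid days and a post-calibration error <= 10 mg.

Autocalibration, non-wear detection and imputation belong to the upstream
device-processing pipeline and are out of scope here: unworn epochs simply
contribute nothing and partial days are handled by closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, close

__all__ = [
    "BandScheme",
    "NINE_BAND_SCHEME",
    "BAND_LABELS",
    "EpochSeries",
    "WearSummary",
    "enmo",
    "band_minutes",
    "screen_wear",
    "average_composition",
    "read_epoch_csv",
]

#: Minimum worn minutes for a day to count as valid wear.
VALID_DAY_MINUTES = 600.0
#: Minimum number of valid days for a participant to be retained.
MIN_VALID_DAYS = 3
#: Maximum tolerated post-calibration error (mg).
MAX_CALIBRATION_ERROR_MG = 10.0


@dataclass(frozen=True)
class BandScheme:
    """Ordered acceleration thresholds (mg) partitioning [0, inf) into bands.

    ``edges`` are the D finite lower bounds (first must be 0, strictly
    increasing); the last band is unbounded above.  Bands are half-open,
    lower-inclusive: band j covers [edges[j], edges[j+1]) and the top band
    [edges[-1], inf), so the ">=700 mg" band includes exactly 700 mg.
    """

    edges: tuple
    labels: tuple = None

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 3:
            raise ValueError("a band scheme needs at least 3 bands")
        if edges[0] != 0:
            raise ValueError("the first band edge must be 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        labels = self.labels
        if labels is None:
            fin = [f"{int(a)}-{int(b)}" for a, b in zip(edges, edges[1:])]
            labels = tuple(fin + [f"{int(edges[-1])}+"])
        elif len(labels) != len(edges):
            raise ValueError("need one label per band")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_bands(self) -> int:
        return len(self.edges)

    def assign(self, enmo_mg) -> np.ndarray:
        """Band index (0-based) of each ENMO value; lower-inclusive intervals."""
        x = np.asarray(enmo_mg, dtype=float)
        if np.any(x < 0):
            raise ValueError("ENMO values must be non-negative")
        return np.minimum(
            np.searchsorted(self.edges, x, side="right") - 1, self.n_bands - 1
        )


#: The nine-band scheme: 50 mg increments to 350 mg, then 350-700 and >=700.
NINE_BAND_SCHEME = BandScheme(edges=(0, 50, 100, 150, 200, 250, 300, 350, 700))
BAND_LABELS = NINE_BAND_SCHEME.labels


@dataclass
class EpochSeries:
    """One day's epoch-level ENMO stream within the 960-min window."""

    day: object
    enmo_mg: np.ndarray
    worn: np.ndarray = None
    epoch_seconds: float = 1.0

    def __post_init__(self):
        self.enmo_mg = np.asarray(self.enmo_mg, dtype=float)
        if self.worn is None:
            self.worn = np.ones_like(self.enmo_mg, dtype=bool)
        else:
            self.worn = np.asarray(self.worn, dtype=bool)
        if self.worn.shape != self.enmo_mg.shape:
            raise ValueError("worn flags and ENMO series must align")
        max_epochs = int(round(DAY_MINUTES * 60 / self.epoch_seconds))
        if self.enmo_mg.size > max_epochs:
            raise ValueError(
                f"series has {self.enmo_mg.size} epochs; the 960-min day holds "
                f"at most {max_epochs} at {self.epoch_seconds}-s epochs"
            )


@dataclass
class WearSummary:
    """Per-participant wear metadata used by the inclusion screen."""

    participant_id: object
    worn_minutes_per_day: np.ndarray
    calibration_error_mg: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.worn_minutes_per_day, dtype=float)
        if np.any((w < 0) | (w > DAY_MINUTES)):
            raise ValueError("worn minutes per day must lie in [0, 960]")
        if self.calibration_error_mg < 0:
            raise ValueError("calibration error must be non-negative")
        self.worn_minutes_per_day = w

    @property
    def valid_days(self) -> int:
        return int(np.sum(self.worn_minutes_per_day >= VALID_DAY_MINUTES))


def enmo(x, y, z):
    """ENMO in mg: ``max(0, ||(x, y, z)|| - 1) * 1000`` with inputs in g.

    Zero for any vector of magnitude <= 1 g (a stationary device reads the
    1-g gravity vector), continuous and non-decreasing in magnitude.
    """
    mag = np.sqrt(np.square(x) + np.square(y) + np.square(z))
    return np.maximum(0.0, mag - 1.0) * 1000.0


def band_minutes(series: EpochSeries, scheme: BandScheme = NINE_BAND_SCHEME) -> np.ndarray:
    """Minutes per band for one day: worn epochs classified by the scheme.

    Every worn epoch lands in exactly one band; unworn epochs contribute
    nothing.  Minutes are exact epoch counts x epoch length / 60, unrounded.
    """
    idx = scheme.assign(series.enmo_mg[series.worn])
    counts = np.bincount(idx, minlength=scheme.n_bands).astype(float)
    return counts * (series.epoch_seconds / 60.0)


def screen_wear(summary: WearSummary) -> tuple[bool, str]:
    """Inclusion decision for one participant, with the failed rule(s) named.

    Included iff >= 3 valid days (>= 600 worn min each) and calibration error
    <= 10 mg.
    """
    reasons = []
    if summary.valid_days < MIN_VALID_DAYS:
        reasons.append(
            f"insufficient valid days ({summary.valid_days} < {MIN_VALID_DAYS})"
        )
    if summary.calibration_error_mg > MAX_CALIBRATION_ERROR_MG:
        reasons.append(
            f"calibration error ({summary.calibration_error_mg:g} mg > "
            f"{MAX_CALIBRATION_ERROR_MG:g} mg)"
        )
    if reasons:
        return False, "; ".join(reasons)
    return True, "included"


def average_composition(per_day, total: float = DAY_MINUTES) -> np.ndarray:
    """Average valid days' band minutes and close to the 960-min day.

    ``per_day`` is an (n_days, D) array of band minutes from valid days.
    Partial wear (day sums < 960) is rescaled by the closure.
    """
    m = np.asarray(per_day, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[0] == 0:
        raise ValueError("no valid days to average")
    return close(m.mean(axis=0), total)


def read_epoch_csv(path, scheme: BandScheme = NINE_BAND_SCHEME) -> pd.DataFrame:
    """Read an epoch-level CSV and return per-participant-day band minutes.

    Expected columns: participant_id, day, epoch_index, worn (0/1) and either
    enmo_mg or the tri-axial x_g, y_g, z_g.  Returns a tidy frame with one row
    per (participant_id, day) and one column per band label.
    """
    df = pd.read_csv(path)
    if "enmo_mg" not in df.columns:
        for c in ("x_g", "y_g", "z_g"):
            if c not in df.columns:
                raise ValueError("epoch CSV needs enmo_mg or x_g/y_g/z_g columns")
        df["enmo_mg"] = enmo(df["x_g"], df["y_g"], df["z_g"])
    if "worn" not in df.columns:
        df["worn"] = 1
    rows = []
    for (pid, day), g in df.groupby(["participant_id", "day"], sort=True):
        series = EpochSeries(day=day, enmo_mg=g["enmo_mg"].to_numpy(),
                             worn=g["worn"].to_numpy().astype(bool))
        mins = band_minutes(series, scheme)
        rows.append({"participant_id": pid, "day": day,
                     **dict(zip(scheme.labels, mins))})
    return pd.DataFrame(rows)
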