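"""MIC calling from OD600 growth matrices over an antibiotic dilution series.

Growth of each (strain, mutant, replicate) well at antibiotic concentration
``c`` is normalized against the matched unselected (0 µg/ml) well; the MIC
is the lowest tested concentration at which mean normalized growth drops
below a threshold (default 0.1, i.e. near-complete inhibition).  Mutant MICs
are then expressed as percent of the wild-type reference MIC within the same
strain, which cancels strain-intrinsic antibiotic sensitivity.

MICs are reported on the tested concentration grid (no interpolation),
matching how serial-dilution assays are read; wells that never drop below
threshold are censored as ``> max(concentration)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._exceptions import DataError

__all__ = [
    "GrowthMatrix",
    "Mic",
    "normalize_growth",
    "call_mic",
    "percent_mic",
    "mic_table",
]

GROWTH_COLUMNS = ("strain", "mutant", "replicate", "concentration", "od600")
DEFAULT_THRESHOLD = 0.1
DEFAULT_OD_FLOOR = 0.05


@dataclass
class GrowthMatrix:
    """Long-form OD600 table: strain, mutant, replicate, concentration, od600.

    ``wt_mutant`` names the wild-type reference present in every strain.
    """

    od: pd.DataFrame
    wt_mutant: str = "Wt"

    def __post_init__(self):
        missing = set(GROWTH_COLUMNS) - set(self.od.columns)
        if missing:
            raise DataError(f"growth table missing columns {sorted(missing)}")
        if (self.od["od600"] < 0).any():
            raise DataError("OD600 values must be >= 0")
        if (self.od["concentration"] < 0).any():
            raise DataError("concentrations must be >= 0")
        for strain, sub in self.od.groupby("strain"):
            if self.wt_mutant not in set(sub["mutant"]):
                raise DataError(f"strain {strain!r} lacks the {self.wt_mutant!r} reference")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.od["concentration"].unique())

    @classmethod
    def from_file(cls, path, wt_mutant: str = "Wt") -> "GrowthMatrix":
        return cls(pd.read_csv(path, sep="\t"), wt_mutant=wt_mutant)


@dataclass(frozen=True)
class Mic:
    """A MIC call: value on the tested grid, or censored above it."""

    value: Optional[float]      # µg/ml; None when censored
    censored: bool
    max_tested: float
    threshold: float

    def __str__(self) -> str:
        return f">{self.max_tested:g}" if self.censored else f"{self.value:g}"


def normalize_growth(
    matrix: GrowthMatrix, od_floor: float = DEFAULT_OD_FLOOR
) -> pd.DataFrame:
    """Normalize OD600 against the matched unselected (0 µg/ml) well.

    Returns a long DataFrame (strain, mutant, replicate, concentration,
    fraction) plus replicate means in ``mean_fraction``.  Unselected wells
    with OD below ``od_floor`` cannot anchor a normalization and raise a
    :class:`DataError` naming the well.
    """
    od = matrix.od
    base = od[od["concentration"] == 0].rename(columns={"od600": "od0"})
    if len(base) == 0:
        raise DataError("no unselected (0 concentration) measurements found")
    low = base[base["od0"] < od_floor]
    if len(low):
        w = low.iloc[0]
        raise DataError(
            f"unselected OD600 {w['od0']:.3g} below floor {od_floor:g} for "
            f"strain {w['strain']!r} mutant {w['mutant']!r} replicate {w['replicate']!r}"
        )
    keys = ["strain", "mutant", "replicate"]
    merged = od.merge(base[keys + ["od0"]], on=keys, how="left", validate="m:1")
    if merged["od0"].isna().any():
        w = merged[merged["od0"].isna()].iloc[0]
        raise DataError(
            f"no unselected well for strain {w['strain']!r} mutant "
            f"{w['mutant']!r} replicate {w['replicate']!r}"
        )
    merged["fraction"] = merged["od600"] / merged["od0"]
    means = (
        merged.groupby(["strain", "mutant", "concentration"])["fraction"]
        .mean().rename("mean_fraction").reset_index()
    )
    return merged[keys + ["concentration", "fraction"]].merge(
        means, on=["strain", "mutant", "concentration"]
    )


def call_mic(
    fractions, threshold: float = DEFAULT_THRESHOLD
) -> Mic:
    """Call the MIC from mean growth fractions keyed by concentration.

    ``fractions`` maps concentration (µg/ml) -> mean normalized growth.  The
    MIC is the smallest tested concentration whose fraction falls below
    ``threshold``; if growth never drops below threshold the call is
    censored above the highest tested concentration.
    """
    s = pd.Series(fractions, dtype=float).sort_index()
    if len(s) == 0:
        raise ValueError("empty growth-fraction series")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    below = s[s < threshold]
    max_tested = float(s.index.max())
    if len(below) == 0:
        return Mic(value=None, censored=True, max_tested=max_tested,
                   threshold=threshold)
    return Mic(value=float(below.index.min()), censored=False,
               max_tested=max_tested, threshold=threshold)


def percent_mic(mutant_mic: Mic, wt_mic: Mic) -> Optional[float]:
    """Mutant MIC as a percentage of the wild-type MIC (same strain).

    Returns ``None`` when either MIC is censored — a ratio of censored
    values carries no information.
    """
    if mutant_mic.censored or wt_mic.censored:
        return None
    return 100.0 * mutant_mic.value / wt_mic.value


def mic_table(
    matrix: GrowthMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> pd.DataFrame:
    """Full MIC pipeline: one row per (strain, mutant).

    Columns: ``mic`` (string; censored values rendered as ``>max``),
    ``mic_value`` (float, NaN when censored), ``percent_mic`` (relative to
    the strain's wild-type; NaN when either side is censored), ``censored``
    and ``threshold``.  Replicates are averaged before the MIC scan;
    per-replicate MICs are in ``replicate_mics`` (JSON-ish string) for
    dispersion checks.
    """
    norm = normalize_growth(matrix, od_floor=od_floor)
    rows = []
    for (strain, mutant), sub in norm.groupby(["strain", "mutant"]):
        means = sub.drop_duplicates(["concentration"]).set_index("concentration")[
            "mean_fraction"
        ]
        mic = call_mic(means, threshold=threshold)
        rep_mics = {}
        for rep, rsub in sub.groupby("replicate"):
            rep_mic = call_mic(
                rsub.set_index("concentration")["fraction"], threshold=threshold
            )
            rep_mics[str(rep)] = str(rep_mic)
        rows.append({
            "strain": strain, "mutant": mutant, "mic_obj": mic,
            "replicate_mics": ";".join(f"{k}={v}" for k, v in sorted(rep_mics.items())),
        })
    df = pd.DataFrame(rows)
    wt = {
        r["strain"]: r["mic_obj"]
        for _, r in df[df["mutant"] == matrix.wt_mutant].iterrows()
    }
    df["mic"] = df["mic_obj"].map(str)
    df["mic_value"] = df["mic_obj"].map(lambda m: np.nan if m.censored else m.value)
    df["censored"] = df["mic_obj"].map(lambda m: m.censored)
    df["percent_mic"] = [
        np.nan if (p := percent_mic(r["mic_obj"], wt[r["strain"]])) is None else p
        for _, r in df.iterrows()
    ]
    df["threshold"] = threshold
    return df.drop(columns="mic_obj")[
        ["strain", "mutant", "mic", "mic_value", "percent_mic", "censored",
         "threshold", "replicate_mics"]
    ]
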