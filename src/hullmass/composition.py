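"""Segment composition: how hull volume is distributed around the skeleton.

Each segment's hull volume is expressed as a fraction of the whole-body
(with-feet) total, and a fossil's fraction for a given segment can be
compared against the extant sample with a one-sample t-test. The test tail
is always an explicit argument: whether a fossil is expected to fall below
or above the extant mean is a scientific choice, not something inferred
from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientData, ZeroVariance
from .geometry import HullVolumeTable

TAILS = ("less", "greater", "two_sided")


@dataclass
class SegmentFractionTable:
    """Per-segment fractions of a specimen's total hull volume."""

    specimen_id: str
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for seg, f in self.fractions.items():
            if not 0 < f <= 1:
                raise ValueError(f"fraction for {seg!r} must lie in (0, 1], got {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"specimen": self.specimen_id, "segment": seg, "fraction": f}
                for seg, f in self.fractions.items()
            ]
        )


def segment_fractions(table: HullVolumeTable) -> SegmentFractionTable:
    """Fractions of the with-feet total contributed by each segment."""
    total = table.total_with_feet
    if not total > 0:
        raise ValueError("total hull volume must be positive")
    if len(table.volumes) == 1:
        # a single segment trivially carries the whole volume
        (seg,) = table.volumes
        return SegmentFractionTable(table.specimen_id, {seg: 1.0})
    fractions = {seg: v / total for seg, v in table.volumes.items()}
    return SegmentFractionTable(table.specimen_id, fractions)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    tail: str


def one_sample_t(sample, reference: float, tail: str = "two_sided") -> TTestResult:
    """One-sample t-test of a fraction sample against a reference value.

    t = (mean − reference) / (sd / √n) with n − 1 degrees of freedom; the
    p-value comes from the requested tail ("less": P(T ≤ t), "greater":
    P(T ≥ t), or two-sided).
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    x = np.asarray(list(sample), dtype=float)
    if x.size < 2:
        raise InsufficientData("one-sample t-test needs at least 2 observations")
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVariance("sample has zero variance")
    n = x.size
    t = float((x.mean() - reference) / (sd / np.sqrt(n)))
    df = n - 1
    if tail == "less":
        p = float(stats.t.cdf(t, df))
    elif tail == "greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, df=df, tail=tail)


def compare_fractions(
    extant: list[SegmentFractionTable],
    reference: dict[str, float],
    tail: str = "two_sided",
) -> pd.DataFrame:
    """t-test every shared segment's extant fractions against a reference.

    ``reference`` maps segment name to the fossil's fraction; segments
    missing from either side are skipped.
    """
    rows = []
    for seg, ref in reference.items():
        values = [t.fractions[seg] for t in extant if seg in t.fractions]
        if len(values) < 2:
            continue
        res = one_sample_t(values, ref, tail=tail)
        rows.append({"segment": seg, "t": res.t, "df": res.df, "p": res.p, "tail": res.tail})
    return pd.DataFrame(rows)
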