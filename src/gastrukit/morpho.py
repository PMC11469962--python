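"""Rule-based morphometric classification and boundary-intensity analysis.

Implements the measurement-table side of gastruloid morphometrics: whole-body
or neural-tube length-to-width summaries (widths taken at the 10%, 50% and
90% positions and averaged), the paired-somite rule (left/right somites
matched by their order from the posterior end are "paired" when their area
ratio lies within 70-130%, and a gastruloid is "paired" when at least two of
three randomly sampled putative pairs are), and rostrocaudal boundary
detection from two anti-phase marker intensity tracks (locally weighted
smoothing, per-channel mean normalization, peak calling on the difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import IntensityProfile

__all__ = [
    "MorphometricSummary",
    "summarize_morphometrics",
    "classify_pairing",
    "detect_boundaries",
]

PAIR_RATIO_LOW = 0.70
PAIR_RATIO_HIGH = 1.30
DEFAULT_LOESS_SPAN = 0.075
DEFAULT_MIN_PEAK_DISTANCE = 60


@dataclass
class MorphometricSummary:
    gastruloid_id: str
    total_length: float
    widths_10_50_90: tuple
    avg_width: float
    lw_ratio: float


def summarize_morphometrics(
    length: float, widths, gastruloid_id: str = ""
) -> MorphometricSummary:
    """Length-to-width summary from a length and three standardized widths."""
    widths = tuple(float(w) for w in widths)
    if len(widths) != 3:
        raise ValueError("expected widths at the 10%, 50% and 90% positions")
    if length <= 0 or any(w <= 0 for w in widths):
        raise ValueError("length and widths must be positive")
    avg = sum(widths) / 3.0
    return MorphometricSummary(
        gastruloid_id=gastruloid_id,
        total_length=float(length),
        widths_10_50_90=widths,
        avg_width=avg,
        lw_ratio=float(length) / avg,
    )


def _pair_ratio(area_left: float, area_right: float, symmetric: bool) -> float:
    if symmetric:
        return min(area_left, area_right) / max(area_left, area_right)
    return area_left / area_right


def classify_pairing(
    table: pd.DataFrame,
    n_sampled_pairs: int = 3,
    seed: int = 0,
    symmetric: bool = False,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Paired-somite classification per gastruloid.

    Left and right somites are matched by ``order_from_posterior``; a matched
    pair is "paired" when its area ratio (left/right as given, or min/max
    with ``symmetric=True``) lies in [0.70, 1.30] inclusive.  Per gastruloid,
    ``n_sampled_pairs`` matched pairs are drawn uniformly without replacement
    (seeded) and the gastruloid is "paired" when at least two of the three
    sampled pairs are; ``all_pairs=True`` instead evaluates every matched
    pair with a >= 2/3 majority rule.  Gastruloids with fewer than two
    matched pairs are flagged unevaluable.
    """
    rng = np.random.default_rng(seed)
    records = []
    for gid, sub in table.groupby("gastruloid_id", sort=True):
        wide = sub.pivot_table(
            index="order_from_posterior", columns="side", values="area", aggfunc="first"
        )
        have_both = (
            wide.dropna(subset=["left", "right"])
            if {"left", "right"} <= set(wide.columns)
            else wide.iloc[0:0]
        )
        n_matched = len(have_both)
        pairs = []
        for order, row in have_both.iterrows():
            ratio = _pair_ratio(row["left"], row["right"], symmetric)
            pairs.append(
                {
                    "order": int(order),
                    "area_left": float(row["left"]),
                    "area_right": float(row["right"]),
                    "ratio": ratio,
                    "paired": PAIR_RATIO_LOW <= ratio <= PAIR_RATIO_HIGH,
                }
            )
        if n_matched < 2:
            records.append(
                {
                    "gastruloid_id": gid,
                    "n_matched_pairs": n_matched,
                    "evaluated_pairs": pairs,
                    "gastruloid_paired": pd.NA,
                    "unevaluable": True,
                }
            )
            continue
        if all_pairs:
            chosen = pairs
        else:
            k = min(n_sampled_pairs, n_matched)
            idx = sorted(rng.choice(n_matched, size=k, replace=False))
            chosen = [pairs[i] for i in idx]
        n_paired = sum(p["paired"] for p in chosen)
        verdict = n_paired / len(chosen) >= 2.0 / 3.0
        records.append(
            {
                "gastruloid_id": gid,
                "n_matched_pairs": n_matched,
                "evaluated_pairs": chosen,
                "gastruloid_paired": bool(verdict),
                "unevaluable": False,
            }
        )
    return pd.DataFrame(records).set_index("gastruloid_id")


def detect_boundaries(
    profile: IntensityProfile,
    channels: tuple = ("ch1", "ch2"),
    span: float = DEFAULT_LOESS_SPAN,
    min_distance: int = DEFAULT_MIN_PEAK_DISTANCE,
) -> pd.DataFrame:
    """Rostrocaudal boundary positions from two marker intensity tracks.

    Each channel is smoothed by locally weighted regression (span = fraction
    of points), normalized to its own mean, and the difference (first minus
    second channel) is scanned for local maxima separated by at least
    ``min_distance`` positions.  Returns peak positions with prominences.
    """
    if len(profile.positions) < 200:
        raise ValueError("need at least 200 positions")
    c1, c2 = channels
    x = profile.positions.astype(float)
    smoothed = {}
    for ch in (c1, c2):
        y = profile.intensity[ch].to_numpy(float)
        s = lowess(y, x, frac=span, return_sorted=False)
        m = s.mean()
        if m <= 0:
            s = np.zeros_like(s)  # constant-zero channel: flat after normalization
        else:
            s = s / m
        smoothed[ch] = s
    diff = smoothed[c1] - smoothed[c2]
    peaks, props = find_peaks(diff, distance=min_distance, prominence=1e-9)
    return pd.DataFrame(
        {
            "position": profile.positions[peaks],
            "height": diff[peaks],
            "prominence": props["prominences"],
        }
    )
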