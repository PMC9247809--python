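"""Funnel and end-to-end capture accounting for the two-phase method.

The funnel tracks record counts through cleaning and the two topic-modeling
stages as signed deltas against an initial collection count, with each
running total expressed as a percentage of the initial count.  The
effectiveness estimate extrapolates a classifier's positive-class recall and
precision over the positives that survived filtering, and converts the topic
filter's capture rate into an estimate of how many positives existed in the
raw stream.

All percentages are rounded half-away-from-zero at 2 decimals and counts to
the nearest integer; when published estimates are stated as counts (not as
rounded rates), the count form is accepted directly, since re-deriving a
count from a 3-decimal rate does not in general reproduce it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 0.125 -> 0.13 at 2 decimals, -0.125 -> -0.13)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_pct(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    return round_half_away(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True)
class FunnelStage:
    name: str
    delta: int
    running_total: int
    pct_of_initial: float


@dataclass(frozen=True)
class FunnelLedger:
    initial: int
    stages: tuple[FunnelStage, ...]

    @property
    def final(self) -> int:
        return self.stages[-1].running_total if self.stages else self.initial

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "stages": [
                {
                    "name": s.name,
                    "delta": s.delta,
                    "running_total": s.running_total,
                    "pct_of_initial": s.pct_of_initial,
                }
                for s in self.stages
            ],
        }

    def render(self) -> str:
        """Text table with thousands separators, one row per stage."""
        width = max([len("initial")] + [len(s.name) for s in self.stages]) + 2
        lines = [f"{'initial':<{width}}{self.initial:>12,} (100)"]
        for s in self.stages:
            lines.append(
                f"{s.name:<{width}}{s.running_total:>12,} ({s.pct_of_initial:.2f})"
                f"   [delta {s.delta:+,}]"
            )
        return "\n".join(lines)


def build_funnel(initial: int, deltas: Sequence[tuple[str, int]]) -> FunnelLedger:
    """Running totals and percent-of-initial for an ordered list of stage deltas."""
    if initial <= 0:
        raise ValueError("initial count must be positive")
    total = initial
    stages = []
    for name, delta in deltas:
        total += delta
        if total < 0:
            raise ValueError(f"running total negative after stage {name!r}")
        stages.append(
            FunnelStage(
                name=name,
                delta=int(delta),
                running_total=total,
                pct_of_initial=ratio_pct(total, initial),
            )
        )
    return FunnelLedger(initial=initial, stages=tuple(stages))


@dataclass(frozen=True)
class EffectivenessEstimate:
    """End-to-end capture arithmetic.

    V, N: positive/negative counts after filtering; r, p: classifier recall
    and precision; c: topic-filter capture rate (share of all true positives
    that survived filtering).  ``tp_after_pipeline`` is the externally
    estimated count of positives surviving the *whole* pipeline, used for
    the capture percentage when supplied.
    """

    V: int
    N: int
    r: float
    p: float
    c: float
    tp_est: int
    predicted_pos: int
    fp_est: int
    v_original_est: int
    tp_pct_of_v: float
    fp_pct_of_n: float
    capture_pct: float | None
    elimination_pct: float | None
    identified_pct_of_initial: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def estimate_effectiveness(
    V: int,
    N: int,
    r: float,
    p: float,
    c: float,
    initial: int | None = None,
    tp_count: int | None = None,
    predicted_pos_count: int | None = None,
    tp_after_pipeline: int | None = None,
) -> EffectivenessEstimate:
    """Extrapolate classifier performance over the filtered stream.

    ``tp_est = round(r * V)``; ``predicted_pos = round(tp_est / p)``;
    ``fp_est = predicted_pos - tp_est``; ``v_original_est = round(V / c)``.
    When published figures are stated as counts, pass ``tp_count`` /
    ``predicted_pos_count`` and they are used directly (rates printed at 3
    decimals do not invert to the underlying counts).  The capture
    percentage uses ``tp_after_pipeline`` when given, else ``tp_est``.
    """
    if not (0 < r <= 1 and 0 < p <= 1 and 0 < c <= 1):
        raise ValueError("r, p, c must be in (0, 1]")
    if V < 0 or N < 0:
        raise ValueError("V and N must be non-negative")
    tp_est = tp_count if tp_count is not None else int(round_half_away(r * V, 0))
    if tp_est > V:
        raise ValueError("estimated true positives exceed V")
    predicted_pos = (
        predicted_pos_count
        if predicted_pos_count is not None
        else int(round_half_away(tp_est / p, 0))
    )
    fp_est = predicted_pos - tp_est
    if fp_est < 0:
        raise ValueError("predicted positives below estimated true positives")
    v_original_est = int(round_half_away(V / c, 0))
    tp_final = tp_after_pipeline if tp_after_pipeline is not None else tp_est
    capture_pct = ratio_pct(tp_final, v_original_est) if v_original_est else None
    elimination_pct = None
    identified_pct = None
    if initial is not None:
        elimination_pct = ratio_pct(initial - tp_final, initial)
        identified_pct = ratio_pct(tp_final, initial)
    return EffectivenessEstimate(
        V=V,
        N=N,
        r=r,
        p=p,
        c=c,
        tp_est=tp_est,
        predicted_pos=predicted_pos,
        fp_est=fp_est,
        v_original_est=v_original_est,
        tp_pct_of_v=ratio_pct(tp_est, V) if V else 0.0,
        fp_pct_of_n=ratio_pct(fp_est, N) if N else 0.0,
        capture_pct=capture_pct,
        elimination_pct=elimination_pct,
        identified_pct_of_initial=identified_pct,
    )
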