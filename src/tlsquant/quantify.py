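"""Per-lane translesion-synthesis statistics from gel band intensities.

All statistics are ratios of cumulative band intensities. Writing I(N) for
the band intensity at product index N and cum(N) = sum of I(M) for M >= N:

* termination(N) = I(N) / cum(N) — fraction of molecules that reached N and
  stopped there;
* insertion(N)   = cum(N) / cum(N-1) — fraction of molecules at >= N-1 that
  incorporated at N;
* extension(N)   = cum(N+1) / cum(N) — fraction of molecules at >= N that
  were extended further;
* bypass(N)      = cum(N+1) / cum(N-1) = insertion(N) x extension(N) —
  probability of both inserting opposite N and extending past it;
* bypass efficiency = 100 x bypass(damaged) / bypass(undamaged), the
  damaged and undamaged substrates differing only in the lesion.

Zero denominators make a statistic *undefined*, which is propagated as
``None`` (or NaN in array form) with a reason code, never silently as 0.
Probabilities are fractions internally; percent formatting (one decimal,
round half up) happens only in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AggregationError, EfficiencyUndefinedError

logger = logging.getLogger(__name__)

#: Reason code attached to statistics whose denominator vanished.
REASON_ZERO_DENOMINATOR = "zero denominator"


@dataclass
class Lane:
    """One gel lane: band intensities indexed by N (0..K) plus metadata."""

    lane_id: str
    enzyme: str
    substrate_name: str
    time_min: float
    replicate: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(f"lane {self.lane_id!r}: intensities must be 1-D")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError(
                f"lane {self.lane_id!r}: intensities must be finite and >= 0"
            )
        self.intensities = arr
        if self.time_min <= 0:
            raise ValueError(f"lane {self.lane_id!r}: time_min must be positive")

    @classmethod
    def from_band_dict(
        cls,
        bands: Mapping[int, float],
        k: int,
        *,
        lane_id: str = "lane",
        enzyme: str = "enzyme",
        substrate_name: str = "substrate",
        time_min: float = 1.0,
        replicate: int = 1,
    ) -> "Lane":
        """Build a lane from a sparse {N index: intensity} mapping; absent
        indices are zero."""
        arr = np.zeros(k + 1)
        for n, v in bands.items():
            if not 0 <= int(n) <= k:
                raise ValueError(f"band index {n} outside 0..{k}")
            arr[int(n)] = v
        return cls(lane_id, enzyme, substrate_name, time_min, replicate, arr)

    @property
    def k(self) -> int:
        return self.intensities.size - 1

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def cumulative(self) -> np.ndarray:
        """cum(N) = sum of intensities at indices >= N, for N = 0..K."""
        return np.cumsum(self.intensities[::-1])[::-1]


def cumulative_at_least(lane: Lane, n: int) -> float:
    """Total intensity in bands of index >= n (n = 0 gives the lane total)."""
    if not 0 <= n <= lane.k:
        raise ValueError(f"N index {n} outside 0..{lane.k}")
    return float(lane.intensities[n:].sum())


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def termination_probability(lane: Lane, n: int) -> Optional[float]:
    """I(n) / cum(n); None when no molecules reached n."""
    return _ratio(float(lane.intensities[n]), cumulative_at_least(lane, n))


def insertion_probability(lane: Lane, n: int) -> Optional[float]:
    """cum(n) / cum(n-1) for n >= 1; None when cum(n-1) = 0."""
    if not 1 <= n <= lane.k:
        raise ValueError(f"insertion index {n} outside 1..{lane.k}")
    return _ratio(cumulative_at_least(lane, n), cumulative_at_least(lane, n - 1))


def extension_probability(lane: Lane, n: int) -> Optional[float]:
    """cum(n+1) / cum(n) for 0 <= n <= K-1; None when cum(n) = 0."""
    if not 0 <= n <= lane.k - 1:
        raise ValueError(f"extension index {n} outside 0..{lane.k - 1}")
    return _ratio(cumulative_at_least(lane, n + 1), cumulative_at_least(lane, n))


def bypass_probability(lane: Lane, n: int) -> Optional[float]:
    """cum(n+1) / cum(n-1) for 1 <= n <= K-1; equals insertion x extension."""
    if not 1 <= n <= lane.k - 1:
        raise ValueError(f"bypass index {n} outside 1..{lane.k - 1}")
    return _ratio(cumulative_at_least(lane, n + 1), cumulative_at_least(lane, n - 1))


def percent_extension(lane: Lane) -> float:
    """Percent of total product extended beyond the unextended primer:
    100 x (1 - I(N0)/total). Errors on an all-zero lane."""
    total = lane.total
    if total == 0:
        raise ValueError(f"lane {lane.lane_id!r}: zero total intensity")
    return 100.0 * (1.0 - float(lane.intensities[0]) / total)


def bypass_efficiency(damaged_bypass: float, undamaged_bypass: float) -> float:
    """100 x damaged / undamaged, as a percent.

    Both arguments are bypass probabilities on the same scale (fractions or
    percents). Raises :class:`EfficiencyUndefinedError` when the undamaged
    bypass probability is zero.
    """
    if damaged_bypass < 0 or undamaged_bypass < 0:
        raise ValueError("bypass probabilities must be >= 0")
    if undamaged_bypass == 0:
        raise EfficiencyUndefinedError(
            "bypass efficiency undefined: undamaged bypass probability is 0"
        )
    return 100.0 * damaged_bypass / undamaged_bypass


@dataclass
class PositionStats:
    """Per-position statistics of one lane, NaN where undefined.

    Arrays are indexed by N (length K+1); entries outside each statistic's
    domain (insertion at N0, extension at NK, bypass at N0/NK) are NaN too.
    ``undefined`` lists (statistic, N, reason) for in-domain entries whose
    denominator vanished.
    """

    lane_id: str
    k: int
    termination: np.ndarray
    insertion: np.ndarray
    extension: np.ndarray
    bypass: np.ndarray
    undefined: list[tuple[str, int, str]] = field(default_factory=list)


def position_stats(lane: Lane) -> PositionStats:
    """All four statistics at every in-domain N for one lane."""
    k = lane.k
    arrays = {
        name: np.full(k + 1, np.nan)
        for name in ("termination", "insertion", "extension", "bypass")
    }
    undefined: list[tuple[str, int, str]] = []

    def put(name: str, n: int, value: Optional[float]) -> None:
        if value is None:
            undefined.append((name, n, REASON_ZERO_DENOMINATOR))
        else:
            arrays[name][n] = value

    for n in range(0, k + 1):
        put("termination", n, termination_probability(lane, n))
        if n >= 1:
            put("insertion", n, insertion_probability(lane, n))
        if n <= k - 1:
            put("extension", n, extension_probability(lane, n))
        if 1 <= n <= k - 1:
            put("bypass", n, bypass_probability(lane, n))
    return PositionStats(lane.lane_id, k, undefined=undefined, **arrays)


@dataclass
class BypassSummary:
    """Replicate-aggregated statistics at one evaluation position.

    Means and SDs are fractions; the efficiency fields are percents and are
    populated only by :func:`efficiency_from_summaries` (they require an
    undamaged partner). Dispersion is the sample SD across lanes.
    """

    enzyme: str
    substrate_name: str
    lesion_n: int
    n_lanes: int
    insertion_mean: float
    insertion_sd: float
    extension_mean: float
    extension_sd: float
    bypass_mean: float
    bypass_sd: float
    n_excluded: int = 0
    efficiency_pct: Optional[float] = None
    efficiency_sd_pct: Optional[float] = None


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def aggregate(
    lanes: Sequence[Lane],
    eval_n: int,
    *,
    pooling: str = "lanes",
) -> BypassSummary:
    """Mean and SD of insertion/extension/bypass at ``eval_n`` across lanes.

    All lanes must share enzyme and substrate. Lanes where any of the three
    statistics is undefined are excluded (count logged and recorded).
    ``pooling="lanes"`` treats every lane as one observation (the default:
    time points and experiments pooled); ``pooling="by_experiment"``
    averages the time points within each replicate/experiment first, then
    takes mean and SD across experiments.
    """
    if not lanes:
        raise AggregationError("no lanes to aggregate")
    enzymes = {ln.enzyme for ln in lanes}
    substrates = {ln.substrate_name for ln in lanes}
    if len(enzymes) != 1 or len(substrates) != 1:
        raise AggregationError(
            f"lanes mix enzymes {sorted(enzymes)} / substrates {sorted(substrates)}"
        )
    if pooling not in ("lanes", "by_experiment"):
        raise ValueError(f"unknown pooling mode {pooling!r}")

    rows = []  # (replicate, insertion, extension, bypass)
    excluded = 0
    for ln in lanes:
        ins = insertion_probability(ln, eval_n)
        ext = extension_probability(ln, eval_n)
        byp = bypass_probability(ln, eval_n)
        if ins is None or ext is None or byp is None:
            excluded += 1
            continue
        rows.append((ln.replicate, ins, ext, byp))
    if excluded:
        logger.info(
            "aggregate: excluded %d/%d lanes with undefined statistics at N%d",
            excluded, len(lanes), eval_n,
        )
    if not rows:
        raise AggregationError(
            f"no lane has defined statistics at N{eval_n} "
            f"(all {len(lanes)} lanes excluded)"
        )
    if len(rows) == 1:
        logger.warning("aggregate: single quantifiable lane; SD reported as 0")

    if pooling == "lanes":
        groups = [[r] for r in rows]
    else:
        by_rep: dict[int, list[tuple]] = {}
        for r in rows:
            by_rep.setdefault(r[0], []).append(r)
        groups = list(by_rep.values())
    obs = np.array(
        [[float(np.mean([r[i] for r in g])) for i in (1, 2, 3)] for g in groups]
    )
    (ins_m, ins_s) = _mean_sd(obs[:, 0])
    (ext_m, ext_s) = _mean_sd(obs[:, 1])
    (byp_m, byp_s) = _mean_sd(obs[:, 2])
    return BypassSummary(
        enzyme=lanes[0].enzyme,
        substrate_name=lanes[0].substrate_name,
        lesion_n=eval_n,
        n_lanes=len(rows),
        insertion_mean=ins_m,
        insertion_sd=ins_s,
        extension_mean=ext_m,
        extension_sd=ext_s,
        bypass_mean=byp_m,
        bypass_sd=byp_s,
        n_excluded=excluded,
    )


def efficiency_from_summaries(
    damaged: BypassSummary, undamaged: BypassSummary
) -> BypassSummary:
    """Attach bypass efficiency (percent) to the damaged summary.

    Efficiency is the ratio of the replicate-mean bypass probabilities
    (ratio of means); its SD comes from first-order error propagation,
    eff x sqrt((sd_d/mean_d)^2 + (sd_u/mean_u)^2).
    """
    if damaged.enzyme != undamaged.enzyme:
        raise ValueError(
            f"enzyme mismatch: {damaged.enzyme!r} vs {undamaged.enzyme!r}"
        )
    if damaged.substrate_name == undamaged.substrate_name:
        raise ValueError("damaged and undamaged summaries use the same substrate")
    eff = bypass_efficiency(damaged.bypass_mean, undamaged.bypass_mean)
    if damaged.bypass_mean > 0:
        rel = math.sqrt(
            (damaged.bypass_sd / damaged.bypass_mean) ** 2
            + (undamaged.bypass_sd / undamaged.bypass_mean) ** 2
        )
        eff_sd = eff * rel
    else:
        eff_sd = 0.0
    return replace(damaged, efficiency_pct=eff, efficiency_sd_pct=eff_sd)


def format_percent(value: float, decimals: int = 1) -> str:
    """Round-half-up percent formatting used in reports (e.g. 17.99 -> '18.0')."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
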