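"""Replicate reproducibility (the ENCODE overlap rule) and sequencing-depth
saturation analysis.

The ENCODE rule: truncate both replicate peak lists to the length of the
shorter, then require that ~80% of the top 40% of either truncated list
overlaps the other truncated list (in both directions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PeakSet, TagLibrary
from .peaks import call_peaks

__all__ = ["ReproReport", "SaturationCurve", "encode_overlap_check", "saturation_curve"]


@dataclass(frozen=True)
class ReproReport:
    truncated_length: int
    fraction_a_in_b: float
    fraction_b_in_a: float
    top_fraction: float
    threshold: float
    passed: bool


def _directional_fraction(top: list, other: PeakSet) -> float:
    hits = sum(1 for p in top if other.overlaps_any(p.interval))
    return hits / len(top)


def encode_overlap_check(
    rep_a: PeakSet,
    rep_b: PeakSet,
    top_fraction: float = 0.40,
    threshold: float = 0.80,
    against_truncated: bool = True,
) -> ReproReport:
    """Apply the replicate-overlap rule to two score-ranked peak lists.

    Both lists are truncated to the shorter length L; the top
    ``ceil(top_fraction * L)`` peaks of each are overlapped against the
    other (truncated by default; set ``against_truncated=False`` to overlap
    against the full partner list).  Passing requires both directional
    fractions to reach ``threshold``.
    """
    if len(rep_a) == 0 or len(rep_b) == 0:
        raise ValueError("both replicate peak sets must be nonempty")
    L = min(len(rep_a), len(rep_b))
    trunc_a = rep_a.top(L)
    trunc_b = rep_b.top(L)
    n_top = math.ceil(top_fraction * L)
    target_a = trunc_b if against_truncated else rep_b
    target_b = trunc_a if against_truncated else rep_a
    frac_a = _directional_fraction(trunc_a.ranked()[:n_top], target_a)
    frac_b = _directional_fraction(trunc_b.ranked()[:n_top], target_b)
    return ReproReport(
        truncated_length=L,
        fraction_a_in_b=frac_a,
        fraction_b_in_a=frac_b,
        top_fraction=top_fraction,
        threshold=threshold,
        passed=frac_a >= threshold and frac_b >= threshold,
    )


@dataclass
class SaturationCurve:
    fractions: list[float]
    mean_counts: list[float]
    sd_counts: list[float]

    def as_rows(self) -> list[tuple[float, float, float]]:
        return list(zip(self.fractions, self.mean_counts, self.sd_counts))


def saturation_curve(
    chip: TagLibrary,
    input_lib: TagLibrary,
    call_params: dict | None = None,
    fractions: list[float] | None = None,
    reps: int = 3,
    seed: int = 0,
) -> SaturationCurve:
    """Peak count as a function of subsampled sequencing depth.

    For each fraction f, ``reps`` independent subsamples (without
    replacement) of ``floor(f * total)`` ChIP tags are drawn and peaks are
    called with ``call_params``; at f = 1.0 the full library is used once
    per rep (sd 0).  Deterministic under a fixed seed.
    """
    call_params = dict(call_params or {})
    if fractions is None:
        fractions = [round(0.1 * i, 1) for i in range(1, 11)]
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
        if f * chip.total < 1:
            raise ValueError(f"fraction {f} keeps fewer than one tag")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for f in fractions:
        counts = []
        for _ in range(reps):
            sub = chip.subsample(f, rng)
            counts.append(len(call_peaks(sub, input_lib, **call_params)))
        means.append(float(np.mean(counts)))
        sds.append(float(np.std(counts)))
    return SaturationCurve(fractions=list(fractions), mean_counts=means, sd_counts=sds)
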