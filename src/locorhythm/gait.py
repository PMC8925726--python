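"""Footprint gait quantification: stride lengths and the L/R ratio.

For each stride of the right paw (distance R between successive right
prints), L is the along-track distance from the stride's starting right
print to the left print placed within that stride.  The raw ratio L/R is
folded into [0, 0.5] so that 0 means the left print lands on top of the
right one (hopping/synchronous gait) and 0.5 means it lands exactly
midway (perfectly alternating gait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simgen import FootprintRun

__all__ = ["GaitRatioResult", "stride_lengths", "gait_ratio"]

_LIMB_SETS = {"hind": ("LH", "RH"), "fore": ("LF", "RF")}


@dataclass
class GaitRatioResult:
    """Per-stride L, R and folded ratio plus the per-run mean."""

    run_id: str
    limb_set: str
    L_cm: np.ndarray
    R_cm: np.ndarray
    ratios: np.ndarray          # folded to [0, 0.5]
    mean_ratio: float
    n_skipped: int = 0
    flags: list[str] = field(default_factory=list)


def stride_lengths(run: FootprintRun, paw: str) -> np.ndarray:
    """Successive along-track distances of one paw's prints."""
    x = run.paw_x(paw)
    if len(x) < 2:
        raise ValueError(f"need at least 2 prints of paw {paw}")
    return np.diff(x)


def _fold(r: np.ndarray) -> np.ndarray:
    r = np.mod(r, 1.0)
    return np.minimum(r, 1.0 - r)


def gait_ratio(
    run: FootprintRun,
    limb_set: str = "hind",
    mode: str = "nearest",
) -> GaitRatioResult:
    """Folded L/R ratio of a run for the hind or fore limb pair.

    For each right-paw stride [x_i, x_{i+1}), candidate left prints are
    those with x in that interval; mode "nearest" takes the one closest
    to x_i (smallest L), mode "midpoint" the one closest to the stride
    midpoint.  Strides without a left print are skipped and flagged.
    """
    if limb_set not in _LIMB_SETS:
        raise ValueError("limb_set must be 'hind' or 'fore'")
    left_paw, right_paw = _LIMB_SETS[limb_set]
    right = run.paw_x(right_paw)
    left = run.paw_x(left_paw)
    if len(right) < 2:
        raise ValueError(f"need at least 2 {right_paw} prints")
    if len(left) < 1:
        raise ValueError(f"need at least 1 {left_paw} print")

    Ls, Rs = [], []
    skipped = 0
    for x0, x1 in zip(right[:-1], right[1:]):
        cand = left[(left >= x0) & (left < x1)]
        if len(cand) == 0:
            skipped += 1
            continue
        if mode == "nearest":
            pick = cand[np.argmin(cand - x0)]
        elif mode == "midpoint":
            pick = cand[np.argmin(np.abs(cand - 0.5 * (x0 + x1)))]
        else:
            raise ValueError("mode must be 'nearest' or 'midpoint'")
        Ls.append(pick - x0)
        Rs.append(x1 - x0)

    L = np.asarray(Ls)
    R = np.asarray(Rs)
    ratios = _fold(L / R) if len(L) else np.array([])
    flags = ["strides-skipped"] if skipped else []
    mean_ratio = float(ratios.mean()) if len(ratios) else float("nan")
    return GaitRatioResult(
        run_id=run.run_id, limb_set=limb_set, L_cm=L, R_cm=R,
        ratios=ratios, mean_ratio=mean_ratio, n_skipped=skipped, flags=flags,
    )


def per_animal_ratio(results: list[GaitRatioResult]) -> float:
    """Animal-level value: mean of per-run mean ratios (typically 3 runs)."""
    if not results:
        raise ValueError("need at least one run result")
    return float(np.mean([r.mean_ratio for r in results]))
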