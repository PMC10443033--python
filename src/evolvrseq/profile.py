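"""Per-position mutation-frequency profiles from pileups.

The mutation frequency at a reference position is the fraction of aligned
reads carrying a nonreference base there (deletions count as nonreference;
insertion starts and N calls do not). Treated-sample profiles are corrected
by subtracting the aggregated parental-control profile, clipping at zero,
and flooring values below a detection threshold (default 1e-4) to zero.
Samples whose window-median depth falls below a minimum (default 40000) are
discarded outright; low-quality end regions are excluded by trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import PileupTable

MIN_DEPTH = 40_000
FLOOR = 1e-4


@dataclass
class MutationProfile:
    """Per-position nonreference proportions for one sample.

    ``raw`` is the observed proportion, ``background`` the aggregated
    parental proportion, ``adjusted`` the corrected value (zero until
    :func:`subtract_background` has run). ``retained`` masks trimmed ends
    and zero-depth positions.
    """

    sample_id: str
    positions: np.ndarray  # 0-based
    ref_bases: np.ndarray
    depth: np.ndarray
    raw: np.ndarray
    retained: np.ndarray
    background: np.ndarray | None = None
    adjusted: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions + 1,  # 1-based in reports
                "ref": self.ref_bases,
                "depth": self.depth,
                "raw": self.raw,
                "retained": self.retained,
            }
        )
        if self.background is not None:
            df["background"] = self.background
        if self.adjusted is not None:
            df["adjusted"] = self.adjusted
        return df


def depth_filter(pileups: dict[str, PileupTable], min_depth: int = MIN_DEPTH,
                 window: tuple[int, int] | None = None) -> tuple[dict[str, PileupTable], list[str]]:
    """Drop samples whose window-median depth is below ``min_depth``.

    Returns the retained pileups and the names of discarded samples. All
    samples discarded is fatal: nothing remains to analyze.
    """
    kept: dict[str, PileupTable] = {}
    discarded: list[str] = []
    for sid, pt in pileups.items():
        lo, hi = window or pt.reference.window
        if np.median(pt.depth[lo:hi]) < min_depth:
            discarded.append(sid)
        else:
            kept[sid] = pt
    if not kept:
        raise RuntimeError(
            f"depth filter (min_depth={min_depth}) discarded every sample: {discarded}"
        )
    return kept, discarded


def mutation_frequency(pileup: PileupTable, sample_id: str | None = None) -> MutationProfile:
    """Raw per-position nonreference proportion for one pileup.

    Zero-depth positions are dropped from the retained mask with a warning;
    their proportion is undefined.
    """
    depth = pileup.depth
    length = len(depth)
    retained = depth > 0
    if not retained.all():
        warnings.warn(
            f"sample {pileup.sample_id!r}: {int((~retained).sum())} zero-depth "
            "positions dropped",
            stacklevel=2,
        )
    raw = np.zeros(length)
    np.divide(depth - pileup.ref_count, depth, out=raw, where=retained)
    return MutationProfile(
        sample_id=sample_id or pileup.sample_id,
        positions=np.arange(length),
        ref_bases=np.array(list(pileup.reference.seq)),
        depth=depth.astype(np.int64),
        raw=raw,
        retained=retained,
    )


def trim_ends(profile: MutationProfile, left_trim: int = 10, right_trim: int = 10) -> MutationProfile:
    """Mask low-quality end regions: positions outside
    ``[left_trim, L - right_trim)`` are dropped from the retained set."""
    length = len(profile)
    if left_trim < 0 or right_trim < 0:
        raise ValueError("trims must be nonnegative")
    if left_trim + right_trim >= length:
        raise ValueError(
            f"trims ({left_trim}, {right_trim}) leave no positions of {length}"
        )
    retained = profile.retained.copy()
    retained[:left_trim] = False
    if right_trim:
        retained[length - right_trim :] = False
    return MutationProfile(
        sample_id=profile.sample_id,
        positions=profile.positions,
        ref_bases=profile.ref_bases,
        depth=profile.depth,
        raw=profile.raw,
        retained=retained,
        background=profile.background,
        adjusted=profile.adjusted,
    )


def subtract_background(sample_profile: MutationProfile,
                        parental_profiles: list[MutationProfile],
                        floor: float = FLOOR, agg: str = "mean") -> MutationProfile:
    """Correct a treated profile by its parental controls.

    The parental proportions are aggregated across replicates (mean by
    default, median selectable), subtracted positionwise, negatives clipped
    to zero, and values below ``floor`` set to zero.
    """
    if not parental_profiles:
        raise RuntimeError(
            f"sample {sample_profile.sample_id!r}: no parental profile available "
            "for background subtraction"
        )
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    stack = np.vstack([p.raw for p in parental_profiles])
    background = stack.mean(axis=0) if agg == "mean" else np.median(stack, axis=0)
    adjusted = np.clip(sample_profile.raw - background, 0.0, None)
    adjusted[adjusted < floor] = 0.0
    retained = sample_profile.retained.copy()
    for p in parental_profiles:
        retained &= p.retained
    adjusted[~retained] = 0.0
    return MutationProfile(
        sample_id=sample_profile.sample_id,
        positions=sample_profile.positions,
        ref_bases=sample_profile.ref_bases,
        depth=sample_profile.depth,
        raw=sample_profile.raw,
        retained=retained,
        background=background,
        adjusted=adjusted,
    )
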