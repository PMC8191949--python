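"""Axial GFP intensity profiles and localization phenotype calls.

A cell's reporter distribution is summarised by sampling the GFP channel
along the cell's long axis, resampling to a fixed number of points so the
position coordinate is a fraction of cell length, and dividing by the mean
intensity at the initial measured end.  On this scale 1.0 is the end
(cytoplasmic) level: a reporter imported into the phage nucleus peaks
above 1 at midcell, an excluded reporter dips below 1, and a uniform
reporter stays flat.  A per-cell score — mean over a central window
divided by the pooled mean over both end windows — turns the profile into
a categorical call (imported / excluded / mixed-ambiguous).

Because the spherocylinder pole caps dim the signal near the very ends of
the axis under PSF blur (a purely geometric effect), profile extraction
accepts a ``pole_margin_px`` inset: the sampled span is pulled in from
each pole by that many pixels (typically the cap radius, i.e. half the
cell width) so the end anchor measures cytoplasm rather than the
boundary roll-off.  An inset of 0 samples strictly pole to pole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import (
    ClassificationError,
    EmptyPopulationError,
    EnsembleError,
    NormalizationError,
    ProfileError,
)
from .segment import CellROI

CALLS = ("imported", "excluded", "mixed_ambiguous")


@dataclass
class AxialProfile:
    """GFP intensity along a cell's long axis.

    ``positions`` are evenly spaced in [0, 1] (fraction of the sampled
    span of the cell length); ``values_norm`` is ``values_raw`` divided by
    ``anchor``, the mean raw intensity over the first ``anchor_frac`` of
    positions (the initial measured end).  ``anchor`` is NaN until
    :func:`normalize_profile` has run.
    """

    cell_id: int
    positions: np.ndarray
    values_raw: np.ndarray
    values_norm: np.ndarray | None = None
    anchor: float = float("nan")

    @property
    def n_points(self) -> int:
        return len(self.positions)


@dataclass
class PhenotypeCall:
    """Per-cell localization verdict with the score and thresholds used."""

    cell_id: int
    score: float
    call: str
    t_hi: float
    t_lo: float


@dataclass
class ProfileEnsemble:
    """Positionwise mean and sd over the normalized profiles of one group."""

    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def central_value(self, center_frac: float = 0.2) -> float:
        """Mean of the ensemble mean over the central window."""
        window = np.abs(self.positions - 0.5) <= center_frac / 2.0
        return float(self.mean[window].mean())


def extract_profile(
    gfp: np.ndarray,
    roi: CellROI,
    n_points: int = 101,
    line_width: int = 1,
    pole_margin_px: float = 0.0,
) -> AxialProfile:
    """Sample the GFP image along the ROI's long axis (bilinear).

    ``n_points`` samples are placed evenly on the segment from
    ``axis_p0 + pole_margin_px`` to ``axis_p1 - pole_margin_px`` (along the
    axis).  With ``line_width > 1``, each sample averages ``line_width``
    bilinear reads spaced 1 px apart perpendicular to the axis, centred on
    the line — the equivalent of a wide line tool.

    Raises
    ------
    ProfileError
        if the ROI has no axis, the axis is shorter than 3 px, or the
        inset leaves no span to sample.
    """
    if roi.axis_p0 is None or roi.axis_p1 is None:
        raise ProfileError("ROI has no long axis")
    if n_points < 3:
        raise ProfileError("n_points must be >= 3")
    p0 = np.asarray(roi.axis_p0, dtype=float)
    p1 = np.asarray(roi.axis_p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length < 3.0:
        raise ProfileError(f"axis length {length:.2f} px < 3 px")
    span = length - 2.0 * pole_margin_px
    if span < 1.0:
        raise ProfileError("pole margin leaves no axial span to sample")
    u = (p1 - p0) / length
    a = p0 + pole_margin_px * u
    t = np.linspace(0.0, span, n_points)
    pts = a[None, :] + t[:, None] * u[None, :]
    gfp = np.asarray(gfp, dtype=float)
    if line_width > 1:
        perp = np.array([-u[1], u[0]])
        offsets = (np.arange(line_width) - (line_width - 1) / 2.0)[:, None, None]
        stack = pts[None, :, :] + offsets * perp[None, None, :]
        vals = ndi.map_coordinates(
            gfp, [stack[..., 0].ravel(), stack[..., 1].ravel()], order=1, mode="nearest"
        ).reshape(line_width, n_points)
        values = vals.mean(axis=0)
    else:
        values = ndi.map_coordinates(gfp, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    return AxialProfile(
        cell_id=roi.cell_id,
        positions=np.linspace(0.0, 1.0, n_points),
        values_raw=values,
    )


def normalize_profile(profile: AxialProfile, anchor_frac: float = 0.05) -> AxialProfile:
    """Divide the raw profile by its initial-end intensity.

    The anchor is the mean of ``values_raw`` over the first
    ``max(1, ceil(anchor_frac * n_points))`` positions, so by construction
    the mean of ``values_norm`` over that window is exactly 1.

    Raises
    ------
    NormalizationError
        if the anchor is not positive (the cell should be skipped).
    """
    m = max(1, int(np.ceil(anchor_frac * profile.n_points)))
    anchor = float(profile.values_raw[:m].mean())
    if anchor <= 0:
        raise NormalizationError(f"anchor {anchor} <= 0 for cell {profile.cell_id}")
    profile.anchor = anchor
    profile.values_norm = profile.values_raw / anchor
    return profile


def classify_localization(
    profile: AxialProfile,
    center_frac: float = 0.2,
    end_frac: float = 0.1,
    t_hi: float = 1.2,
    t_lo: float = 0.8,
) -> PhenotypeCall:
    """Call the phenotype from the centre-versus-ends intensity ratio.

    score = mean(values_norm over the central ``center_frac`` of positions)
    / mean(values_norm over the first and last ``end_frac`` of positions,
    pooled).  score >= t_hi -> imported; score <= t_lo -> excluded;
    otherwise mixed_ambiguous.  Pooling both ends makes the score invariant
    to profile reversal.

    Raises
    ------
    ClassificationError
        if the profile is not normalized or the end mean is not positive.
    """
    if profile.values_norm is None:
        raise ClassificationError("profile must be normalized first")
    if not t_lo < 1.0 < t_hi:
        raise ClassificationError("thresholds must satisfy t_lo < 1 < t_hi")
    v = profile.values_norm
    n = profile.n_points
    center = np.abs(profile.positions - 0.5) <= center_frac / 2.0
    m = max(1, int(np.ceil(end_frac * n)))
    ends = np.concatenate([v[:m], v[-m:]])
    denom = float(ends.mean())
    if denom <= 0:
        raise ClassificationError("non-positive end intensity")
    score = float(v[center].mean()) / denom
    if score >= t_hi:
        call = "imported"
    elif score <= t_lo:
        call = "excluded"
    else:
        call = "mixed_ambiguous"
    return PhenotypeCall(cell_id=profile.cell_id, score=score, call=call, t_hi=t_hi, t_lo=t_lo)


def orient_profiles(
    profiles: list[AxialProfile], brighter_end_first: bool = False
) -> list[AxialProfile]:
    """Optionally flip profiles so the brighter end half comes first.

    Cells have no intrinsic polarity, so the direction of the initial
    measured end is arbitrary; with ``brighter_end_first`` each profile is
    reversed in place when its second half is brighter than its first.
    Classification is orientation-invariant either way.
    """
    if not profiles:
        return profiles
    if not brighter_end_first:
        return profiles
    for p in profiles:
        half = p.n_points // 2
        if p.values_raw[-half:].mean() > p.values_raw[:half].mean():
            p.values_raw = p.values_raw[::-1].copy()
            if p.values_norm is not None:
                p.values_norm = p.values_norm[::-1].copy()
    return profiles


def average_profiles(members: list[AxialProfile]) -> ProfileEnsemble:
    """Positionwise arithmetic mean and sd of normalized profiles.

    Raises
    ------
    EnsembleError
        if the members disagree on ``n_points`` or any is unnormalized.
    EmptyPopulationError
        if there are no members.
    """
    if not members:
        raise EmptyPopulationError("no profiles to average")
    n_points = members[0].n_points
    for m in members:
        if m.n_points != n_points:
            raise EnsembleError("profiles have mismatched n_points")
        if m.values_norm is None:
            raise EnsembleError(f"profile {m.cell_id} is not normalized")
    stack = np.stack([m.values_norm for m in members])
    return ProfileEnsemble(
        positions=members[0].positions.copy(),
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        n=len(members),
    )


def population_fractions(calls: list[PhenotypeCall]) -> dict:
    """Fractions of each call in a population, plus n.

    Raises
    ------
    EmptyPopulationError
        on empty input.
    """
    if not calls:
        raise EmptyPopulationError("no phenotype calls")
    n = len(calls)
    out = {"n": n}
    for c in CALLS:
        out[c] = sum(1 for call in calls if call.call == c) / n
    return out


# ---------------------------------------------------------------------------
# tables


def profile_table(profiles: list[AxialProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for i in range(p.n_points):
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "position": p.positions[i],
                    "value_raw": p.values_raw[i],
                    "value_norm": p.values_norm[i] if p.values_norm is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def call_table(calls: list[PhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cell_id": c.cell_id, "score": c.score, "call": c.call} for c in calls]
    )


def ensemble_table(ens: ProfileEnsemble) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": ens.positions,
            "mean": ens.mean,
            "sd": ens.sd,
            "n": ens.n,
        }
    )
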