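"""Frame-to-frame linking of foci into tracks.

A focus in frame t may link to at most one focus in frame t+1.  A pair is
admissible iff the fractional area overlap of the two detection disks
(radius = PSF FWHM, centred on each centroid) lies within the overlap bounds
(default 75-100 %) and the intensity ratio I_{t+1}/I_t lies within the ratio
bounds (default 50-200 %).  Admissible pairs are resolved greedily by
decreasing overlap, then intensity-ratio closeness to 1, then lexicographic
order — fully deterministic.  There is no gap closing: adjacent frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .detect import Focus

__all__ = ["Track", "disk_overlap_fraction", "link_foci"]


@dataclass
class Track:
    """A frame-linked sequence of foci from one assembly."""

    id: int
    foci: list[Focus] = field(default_factory=list)
    I0: float | None = None          # extrapolated initial intensity (counts)
    stoichiometry: float | None = None
    excluded: bool = False           # excluded from stoichiometry estimates

    @property
    def start_frame(self) -> int:
        return self.foci[0].frame

    @property
    def length(self) -> int:
        return len(self.foci)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.intensity for f in self.foci])

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.foci])

    def mean_position(self) -> tuple[float, float]:
        return (float(np.mean([f.x for f in self.foci])),
                float(np.mean([f.y for f in self.foci])))


def disk_overlap_fraction(d: np.ndarray, radius: float) -> np.ndarray:
    """Area of the intersection of two equal disks at centre distance ``d``,
    normalized by one disk's area (1 at d=0, 0 at d >= 2r)."""
    d = np.asarray(d, dtype=float)
    r = float(radius)
    u = np.clip(d / (2.0 * r), 0.0, 1.0)
    lens = 2.0 * r * r * np.arccos(u) - (d / 2.0) * np.sqrt(
        np.maximum(4.0 * r * r - d * d, 0.0))
    return np.clip(lens / (np.pi * r * r), 0.0, 1.0)


def link_foci(
    foci_by_frame: list[list[Focus]],
    overlap_bounds: tuple[float, float] = (0.75, 1.00),
    ratio_bounds: tuple[float, float] = (0.50, 2.00),
    disk_radius_px: float = 180.0 / 53.0,
) -> list[Track]:
    """Link per-frame foci into tracks.

    ``foci_by_frame`` holds the foci of consecutive frames (index = offset
    from the first frame analysed; each focus also carries its absolute frame
    index).  Every focus ends up in exactly one track.
    """
    n_frames = len(foci_by_frame)
    # successor[(t, i)] = index of the linked focus in frame t+1
    successor: dict[tuple[int, int], int] = {}
    has_pred: set[tuple[int, int]] = set()

    for t in range(n_frames - 1):
        a, b = foci_by_frame[t], foci_by_frame[t + 1]
        if not a or not b:
            continue
        pairs = []
        for i, fa in enumerate(a):
            for j, fb in enumerate(b):
                d = np.hypot(fb.x - fa.x, fb.y - fa.y)
                ov = float(disk_overlap_fraction(d, disk_radius_px))
                if not overlap_bounds[0] <= ov <= overlap_bounds[1]:
                    continue
                if fa.intensity <= 0:
                    continue
                ratio = fb.intensity / fa.intensity
                if not ratio_bounds[0] <= ratio <= ratio_bounds[1]:
                    continue
                pairs.append((-ov, abs(np.log(ratio)), i, j))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for negov, _, i, j in sorted(pairs):
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            successor[(t, i)] = j
            has_pred.add((t + 1, j))

    tracks: list[Track] = []
    starts = []
    for t in range(n_frames):
        for i, f in enumerate(foci_by_frame[t]):
            if (t, i) not in has_pred:
                starts.append((t, i, f))
    # deterministic track ids: by (start frame, y, x)
    starts.sort(key=lambda s: (s[0], s[2].y, s[2].x))
    for tid, (t, i, _) in enumerate(starts):
        chain = [foci_by_frame[t][i]]
        cur = (t, i)
        while cur in successor:
            j = successor[cur]
            chain.append(foci_by_frame[cur[0] + 1][j])
            cur = (cur[0] + 1, j)
        tracks.append(Track(id=tid, foci=chain))
    return tracks


def deduplicate_tracks(tracks: list[Track],
                       radius_px: float) -> list[Track]:
    """Collapse co-located track fragments of immobile assemblies.

    A missed link (localization jitter or a large bleach step tripping the
    intensity-ratio gate) splits one immobile assembly into several track
    fragments at the same position; counting each fragment once would
    duplicate that assembly in the stoichiometry distribution.  Tracks whose
    mean positions fall within ``radius_px`` of an earlier-starting accepted
    track are dropped (ties: longer track first).  Appropriate only for
    immobile-emitter data.
    """
    order = sorted(tracks, key=lambda t: (t.start_frame, -t.length, t.id))
    kept: list[Track] = []
    pos: list[tuple[float, float]] = []
    for t in order:
        x, y = t.mean_position()
        if all((x - px) ** 2 + (y - py) ** 2 >= radius_px ** 2
               for px, py in pos):
            kept.append(t)
            pos.append((x, y))
    return sorted(kept, key=lambda t: t.id)


def link_tracks(foci_by_frame: list[list[Focus]], config: RunConfig) -> list[Track]:
    """Linking with the disk radius and gates taken from the run config."""
    return link_foci(
        foci_by_frame,
        overlap_bounds=config.link_overlap_bounds,
        ratio_bounds=config.link_ratio_bounds,
        disk_radius_px=config.psf_fwhm_px,
    )
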