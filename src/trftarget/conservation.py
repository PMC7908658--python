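"""Conservation-based independent predictor.

Consumes a user-provided per-base conservation score track (phastCons
style, values in [0, 1]) given in transcript coordinates, summarizes it
over the seed region, 35 nt upstream, 15 nt downstream and the whole
3'-UTR, and calls a site a predicted target when the mean seed-region
score reaches a cutoff (0.5 by default, boundary inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq import Interval

logger = logging.getLogger(__name__)


@dataclass
class ScoreTrack:
    """Dense per-base scores per sequence; NaN marks missing positions."""

    scores: dict[str, np.ndarray]

    def coverage(self, seq_id: str, start: int, end: int) -> float:
        arr = self.scores[seq_id][start:end]
        return float(np.mean(~np.isnan(arr))) if len(arr) else 0.0


@dataclass(frozen=True)
class SiteConservation:
    trf_id: str
    transcript_id: str
    site: Interval
    mean_seed: float
    mean_up35: float
    mean_down15: float
    mean_utr: float
    coverage_seed: float


class TrackParseError(ValueError):
    pass


def _check_score(value: float, lineno: int) -> float:
    if not 0.0 <= value <= 1.0:
        raise TrackParseError(f"line {lineno}: score {value} outside [0, 1]")
    return value


def load_score_track(path: str | Path, seq_lengths: dict[str, int]) -> ScoreTrack:
    """Read a fixedStep wiggle or bedGraph file into dense arrays.

    The format is sniffed per block.  Wiggle coordinates are 1-based
    (per the format), bedGraph 0-based half-open.  Overlapping blocks
    (any position written twice) are an error.
    """
    arrays = {sid: np.full(n, np.nan) for sid, n in seq_lengths.items()}
    written = {sid: np.zeros(n, dtype=bool) for sid, n in seq_lengths.items()}

    def fill(sid: str, pos: int, span: int, value: float, lineno: int) -> None:
        if sid not in arrays:
            raise TrackParseError(f"line {lineno}: unknown sequence {sid!r}")
        if pos < 0 or pos + span > len(arrays[sid]):
            raise TrackParseError(f"line {lineno}: position outside {sid}")
        if written[sid][pos : pos + span].any():
            raise TrackParseError(f"line {lineno}: overlapping blocks at {sid}:{pos}")
        arrays[sid][pos : pos + span] = value
        written[sid][pos : pos + span] = True

    chrom, step, span, pos = None, 1, 1, 0
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixedStep"
                continue
            fields = line.split()
            if mode == "fixedStep" and len(fields) == 1:
                fill(chrom, pos, span, _check_score(float(fields[0]), lineno), lineno)
                pos += step
            elif len(fields) == 4:
                sid, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                fill(sid, start, end - start, _check_score(value, lineno), lineno)
            else:
                raise TrackParseError(f"line {lineno}: unrecognized record {line!r}")
    return ScoreTrack(arrays)


def _window_mean(arr: np.ndarray, start: int, end: int) -> float:
    start, end = max(0, start), min(len(arr), end)
    if end <= start:
        return math.nan
    vals = arr[start:end]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else math.nan


def site_conservation(
    track: ScoreTrack, trf_id: str, utr_id: str, site: Interval
) -> SiteConservation:
    """Mean conservation over the seed region and its standard windows."""
    arr = track.scores[utr_id]
    return SiteConservation(
        trf_id=trf_id,
        transcript_id=utr_id,
        site=site,
        mean_seed=_window_mean(arr, site.start, site.end),
        mean_up35=_window_mean(arr, site.start - 35, site.start),
        mean_down15=_window_mean(arr, site.end, site.end + 15),
        mean_utr=_window_mean(arr, 0, len(arr)),
        coverage_seed=track.coverage(utr_id, site.start, site.end),
    )


def conservation_predict(
    sites: list[SiteConservation], cutoff: float = 0.5
) -> list[tuple[SiteConservation, bool]]:
    """Predicted target <=> mean seed-region score >= cutoff.

    Sites with no seed coverage are excluded (logged), not called.
    """
    out = []
    for s in sites:
        if math.isnan(s.mean_seed):
            logger.info(
                "site %s:%d-%d has no conservation coverage; excluded",
                s.transcript_id, s.site.start, s.site.end,
            )
            continue
        out.append((s, s.mean_seed >= cutoff))
    return out
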