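"""Seed-match location and typing in 3'-UTRs.

A seed match is the exact reverse complement of tRF positions 2-7 found
in a 3'-UTR.  Each match is typed by the bases flanking it: a "position 8
match" extends complementarity to tRF position 8 (the UTR base
immediately 5' of the match, because the duplex is antiparallel), and a
"position 1 match" / "position 1 A" describe the UTR base immediately 3'
of the match, which sits opposite tRF position 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seq import Interval, TranscriptRecord, TrfRecord, reverse_complement

logger = logging.getLogger(__name__)

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _complements(a: str, b: str) -> bool:
    return _WC.get(a) == b


@dataclass(frozen=True)
class SeedMatchSite:
    """One located seed match with its type flags and end distances."""

    trf_id: str
    transcript_id: str
    site: Interval  # 6 nt on the 3'-UTR, 0-based half-open
    pos8_match: bool
    pos1_match: bool
    pos1A: bool
    dist5: int
    dist3: int

    @property
    def dist_nearest(self) -> int:
        return min(self.dist5, self.dist3)


@dataclass(frozen=True)
class UtrIsoform:
    transcript_id: str
    utr3: str
    tag_count: int = 0


def classify_site_type(
    trf: TrfRecord, utr: str, site: Interval
) -> tuple[bool, bool, bool]:
    """Type flags (pos8_match, pos1_match, pos1A) for a verified seed match.

    Flanking bases that fall outside the UTR (site at an edge) yield False.
    """
    seq = trf.sequence.residues
    pos8_match = False
    if site.start >= 1 and len(seq) >= 8:
        pos8_match = _complements(seq[7], utr[site.start - 1])
    pos1_match = False
    pos1A = False
    if site.end < len(utr):
        adj = utr[site.end]
        pos1_match = _complements(seq[0], adj)
        pos1A = adj == "A"
    return pos8_match, pos1_match, pos1A


def scan_seed_matches(trf: TrfRecord, utr: str, transcript_id: str) -> list[SeedMatchSite]:
    """All (possibly overlapping) seed matches of a tRF in one 3'-UTR.

    Matches may not overlap an N.  Sites are reported left to right.
    """
    motif = reverse_complement(trf.seed)
    out: list[SeedMatchSite] = []
    start = utr.find(motif)
    while start != -1:
        site = Interval(transcript_id, start, start + 6)
        pos8, pos1, pos1a = classify_site_type(trf, utr, site)
        out.append(
            SeedMatchSite(
                trf_id=trf.trf_id,
                transcript_id=transcript_id,
                site=site,
                pos8_match=pos8,
                pos1_match=pos1,
                pos1A=pos1a,
                dist5=start,
                dist3=len(utr) - (start + 6),
            )
        )
        start = utr.find(motif, start + 1)
    return out


def select_utr_isoform(isoforms: list[UtrIsoform]) -> UtrIsoform:
    """Pick the isoform with the most 3P-seq tags.

    Ties go to the longest UTR, then to input order.
    """
    if not isoforms:
        raise ValueError("no isoforms supplied")
    best = max(
        range(len(isoforms)),
        key=lambda i: (isoforms[i].tag_count, len(isoforms[i].utr3), -i),
    )
    if len(isoforms) > 1:
        logger.debug(
            "selected isoform %d of %d for %s (tags=%d)",
            best, len(isoforms), isoforms[best].transcript_id, isoforms[best].tag_count,
        )
    return isoforms[best]


def build_background(
    trfs: list[TrfRecord],
    transcripts: list[TranscriptRecord],
    positive_pairs,
) -> list["InteractionPair"]:
    """Background pairs: seed matches on transcripts with no positive pair.

    Exclusion is at the transcript level — every transcript hosting any
    positive pair for any tRF is removed before scanning.
    """
    from .chimera import InteractionPair  # local import to avoid a cycle

    positive_transcripts = {p.site.transcript_id for p in positive_pairs}
    out: list[InteractionPair] = []
    for t in transcripts:
        if t.transcript_id in positive_transcripts or not t.utr3:
            continue
        for trf in trfs:
            for site in scan_seed_matches(trf, t.utr3, t.transcript_id):
                out.append(
                    InteractionPair(
                        trf_id=trf.trf_id,
                        transcript_id=t.transcript_id,
                        site=site,
                        label="background",
                        source="scan",
                    )
                )
    return out
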