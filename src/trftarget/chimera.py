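"""Decomposition of AGO chimeric reads into tRF + target fragment.

CLASH / CLEAR-CLIP ligate an AGO-bound small RNA to its target within
one RISC, so each chimeric read is a concatenation of a tRF and a
fragment of the target mRNA.  Reads are decomposed by exact longest
prefix-or-suffix match against the tRF catalog (no mismatches or bulges),
the remaining fragment is mapped exactly to the 3'-UTR set, and pairs are
kept only when the mapped fragment contains a perfect Watson-Crick seed
match for that tRF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seq import Interval, NucleotideSequence, TranscriptRecord, TrfRecord
from .sites import SeedMatchSite, scan_seed_matches

logger = logging.getLogger(__name__)

MIN_FRAGMENT = 6


@dataclass(frozen=True)
class Decomposition:
    read_id: str
    trf_id: str
    trf_span: Interval  # on the read
    target_fragment: str
    orientation: str  # "trf_first" | "trf_last"


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_trf_match | fragment_too_short | ambiguous


@dataclass(frozen=True)
class InteractionPair:
    trf_id: str
    transcript_id: str
    site: SeedMatchSite
    label: str  # positive | background | negative
    source: str  # CLASH | CLEAR_CLIP | scan
    multi_mapping: bool = False

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.trf_id, self.transcript_id, self.site.site.start, self.site.site.end)


def collapse_duplicates(reads: list[NucleotideSequence]) -> list[NucleotideSequence]:
    """Optional exact-duplicate collapser (reads assumed adapter-trimmed)."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.residues not in seen:
            seen.add(r.residues)
            out.append(r)
    return out


def decompose_read(
    read: NucleotideSequence, trf_catalog: list[TrfRecord]
) -> Decomposition | Rejection:
    """Split a read into catalog tRF + target fragment by exact end match.

    The longest catalog tRF equal to a full prefix or suffix of the read
    wins; the leftover fragment must be >= 6 nt.  Distinct tRFs matching
    equally well at both ends make the read ambiguous.
    """
    seq = read.residues
    best_len = 0
    hits: list[tuple[TrfRecord, str]] = []
    for trf in trf_catalog:
        t = trf.sequence.residues
        n = len(t)
        if n > len(seq):
            continue
        for orientation, matched in (
            ("trf_first", seq.startswith(t)),
            ("trf_last", seq.endswith(t)),
        ):
            if not matched:
                continue
            if n > best_len:
                best_len = n
                hits = [(trf, orientation)]
            elif n == best_len:
                hits.append((trf, orientation))
    if not hits:
        return Rejection(read.id, "no_trf_match")
    distinct = {(t.trf_id, o) for t, o in hits}
    if len({t.trf_id for t, _ in hits}) > 1 or len(distinct) > 1:
        return Rejection(read.id, "ambiguous")
    trf, orientation = hits[0]
    n = len(trf.sequence.residues)
    if orientation == "trf_first":
        span = Interval(read.id, 0, n)
        fragment = seq[n:]
    else:
        span = Interval(read.id, len(seq) - n, len(seq))
        fragment = seq[: len(seq) - n]
    if len(fragment) < MIN_FRAGMENT:
        return Rejection(read.id, "fragment_too_short")
    return Decomposition(read.id, trf.trf_id, span, fragment, orientation)


def map_target_fragment(
    fragment: str, transcripts: list[TranscriptRecord]
) -> list[tuple[str, Interval]]:
    """All exact occurrences of the fragment in any 3'-UTR."""
    hits: list[tuple[str, Interval]] = []
    for t in transcripts:
        start = t.utr3.find(fragment)
        while start != -1:
            hits.append((t.transcript_id, Interval(t.transcript_id, start, start + len(fragment))))
            start = t.utr3.find(fragment, start + 1)
    return hits


def build_interaction_pairs(
    reads: list[NucleotideSequence],
    trf_catalog: list[TrfRecord],
    transcripts: list[TranscriptRecord],
    source: str = "CLASH",
    keep_multi_mapping: bool = True,
) -> tuple[list[InteractionPair], list[Rejection]]:
    """Chimeric reads -> deduplicated positive interaction pairs.

    A pair is retained only when the mapped fragment interval contains a
    perfect seed match (reverse complement of tRF positions 2-7); the
    seed match must lie strictly within the fragment interval.
    """
    utr3 = {t.transcript_id: t.utr3 for t in transcripts}
    trf_by_id = {t.trf_id: t for t in trf_catalog}
    pairs: dict[tuple, InteractionPair] = {}
    rejections: list[Rejection] = []
    for read in reads:
        dec = decompose_read(read, trf_catalog)
        if isinstance(dec, Rejection):
            rejections.append(dec)
            continue
        hits = map_target_fragment(dec.target_fragment, transcripts)
        if not hits:
            rejections.append(Rejection(read.id, "fragment_unmapped"))
            continue
        multi = len(hits) > 1
        if multi and not keep_multi_mapping:
            rejections.append(Rejection(read.id, "multi_mapping"))
            continue
        trf = trf_by_id[dec.trf_id]
        any_seed = False
        for transcript_id, interval in hits:
            for site in scan_seed_matches(trf, utr3[transcript_id], transcript_id):
                if site.site.start >= interval.start and site.site.end <= interval.end:
                    any_seed = True
                    pair = InteractionPair(
                        trf_id=trf.trf_id,
                        transcript_id=transcript_id,
                        site=site,
                        label="positive",
                        source=source,
                        multi_mapping=multi,
                    )
                    pairs.setdefault(pair.key, pair)
        if not any_seed:
            rejections.append(Rejection(read.id, "no_seed_match"))
    return list(pairs.values()), rejections
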