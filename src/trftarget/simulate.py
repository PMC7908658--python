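"""Synthetic reference data with known ground truth.

The generator emulates the study conditions every stage is tested
against: transcripts with 5'-UTR/CDS/3'-UTR regions; a small tRF catalog
with tRFdb-like length subclasses (tRF-3 ending in CCA); "functional"
seed-match sites implanted into positive transcripts that differ from
background sites in exactly three feature families — extended duplex
complementarity (lower duplex MFE), position-8 match rate, and
AU-enriched flanks; neutral seed matches implanted elsewhere as
background; chimeric reads formed by concatenating a catalog tRF with a
fragment spanning its implanted site; 3P-seq-style tag counts; extra
seed-match copies in designated transcripts for enrichment recovery; and
a fixedStep conservation track scoring implanted sites from a high Beta
mode and everything else from a low one.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq import NucleotideSequence, TranscriptRecord, TrfRecord

BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic reference.

    Effect sizes: ``delta_mfe`` is the target duplex-stability gap
    between functional and background sites in kcal/mol (realized as
    extended complementarity of about ``delta_mfe / 2`` nt beyond the
    seed, the mean stack being about -2 kcal/mol under the bundled
    energy model); ``pos8_rate`` is the fraction of functional sites
    whose 5'-adjacent base complements tRF position 8 (background sits
    at the 0.25 chance level); ``flank_au`` is the AU fraction of
    functional-site flanks (background 1 - gc).
    """

    n_transcripts: int = 150
    utr3_len: tuple[int, int] = (150, 350)
    cds_len: tuple[int, int] = (150, 400)
    utr5_len: tuple[int, int] = (30, 120)
    gc: float = 0.5
    n_trf3: int = 4
    n_trf5: int = 2
    n_positive_pairs: int = 60
    background_implants_per_transcript: int = 4
    delta_mfe: float = 12.0
    ext_rate: float = 0.75
    pos8_rate: float = 0.8
    flank_au: float = 0.75
    flank_width: int = 15
    n_enriched_transcripts: int = 10
    extra_matches: int = 3
    reads_per_pair: int = 1
    n_decoy_reads: int = 10
    conservation_high: tuple[float, float] = (8.0, 2.0)
    conservation_low: tuple[float, float] = (2.0, 8.0)
    max_tag_count: int = 500
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """What was implanted, for verification by the downstream stages."""

    positives: list[tuple[str, str, int, int]]  # (trf_id, transcript_id, start, end)
    enriched_pairs: list[tuple[str, str]]
    informative_families: dict[str, list[str]]
    fragments: dict[tuple[str, str, int, int], str] = field(default_factory=dict)


INFORMATIVE_FAMILIES = {
    "duplex_mfe": ["duplex_mfe", "duplex_paired", "duplex_paired_nonseed"],
    "pos8_match": ["pos8_match"],
    "flank_au": ["s_au_up35", "s_au_up25ex10", "s_au_down15"],
}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(BASES, size=length, p=p))


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _make_trfs(cfg: SyntheticConfig, rng: np.random.Generator) -> list[TrfRecord]:
    trfs: list[TrfRecord] = []
    seeds_used: set[str] = set()
    specs = [("tRF-3", [18, 22][i % 2]) for i in range(cfg.n_trf3)]
    specs += [("tRF-5", [15, 22, 31][i % 3]) for i in range(cfg.n_trf5)]
    for i, (cls, length) in enumerate(specs, start=1):
        while True:
            body = "".join(_random_seq(rng, length, 0.55))
            if cls == "tRF-3":
                body = body[:-3] + "CCA"
            seed = body[1:7]
            if seed not in seeds_used:
                seeds_used.add(seed)
                break
        num = f"{i:03d}"
        trf_id = f"tRF-{cls[-1]}{num}a"
        trfs.append(TrfRecord(trf_id, NucleotideSequence(trf_id, body), cls))
    return trfs


def generate_reference(
    cfg: SyntheticConfig | None = None,
) -> tuple[list[TranscriptRecord], list[TrfRecord], GroundTruth, dict[str, int]]:
    """Build transcripts, tRF catalog, ground truth and 3P-seq tag counts."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    trfs = _make_trfs(cfg, rng)
    motifs = {t.trf_id: _rc(t.seed) for t in trfs}

    n_pos = cfg.n_positive_pairs
    if n_pos > cfg.n_transcripts:
        raise ValueError("more positive pairs than transcripts")
    ext_nt = max(1, int(round(cfg.delta_mfe / 2.0)))
    min_utr = 35 + 6 + 20 + ext_nt
    if cfg.utr3_len[0] < min_utr:
        raise ValueError(f"utr3_len must allow at least {min_utr} nt")

    transcripts: list[TranscriptRecord] = []
    truth = GroundTruth([], [], dict(INFORMATIVE_FAMILIES))
    tag_counts: dict[str, int] = {}
    positive_ids = set(range(n_pos))  # first n_pos transcripts host positives
    enriched_ids = set(range(n_pos, n_pos + cfg.n_enriched_transcripts))

    for idx in range(cfg.n_transcripts):
        tid = f"NM_{100000 + idx}"
        gene = f"GENE{idx:04d}"
        utr5 = "".join(_random_seq(rng, int(rng.integers(*cfg.utr5_len)), cfg.gc))
        cds = "".join(_random_seq(rng, int(rng.integers(*cfg.cds_len)), cfg.gc))
        ulen = int(rng.integers(*cfg.utr3_len))
        if idx in positive_ids:
            trf = trfs[idx % len(trfs)]
            utr3, start = _implant_positive(rng, cfg, ulen, trf, ext_nt)
            truth.positives.append((trf.trf_id, tid, start, start + 6))
        else:
            utr3 = _random_seq(rng, ulen, cfg.gc)
            n_impl = int(rng.integers(1, cfg.background_implants_per_transcript + 1))
            for _ in range(n_impl):
                trf = trfs[int(rng.integers(len(trfs)))]
                pos = int(rng.integers(0, ulen - 6))
                utr3[pos : pos + 6] = list(motifs[trf.trf_id])
            if idx in enriched_ids:
                trf = trfs[int(rng.integers(len(trfs)))]
                for _ in range(cfg.extra_matches):
                    pos = int(rng.integers(0, ulen - 6))
                    utr3[pos : pos + 6] = list(motifs[trf.trf_id])
                truth.enriched_pairs.append((trf.trf_id, tid))
            utr3 = "".join(utr3)
        transcripts.append(TranscriptRecord(tid, gene, utr5, cds, utr3))
        tag_counts[tid] = int(rng.integers(0, cfg.max_tag_count))

    _attach_fragments(rng, cfg, transcripts, truth)
    return transcripts, trfs, truth, tag_counts


def _implant_positive(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    ulen: int,
    trf: TrfRecord,
    ext_nt: int,
) -> tuple[str, int]:
    """One functional site: seed match + AU flanks + pos8 + extended pairing.

    Redrawn until the chimeric-fragment neighbourhood of the site holds
    exactly one occurrence of the seed-match motif, so read decomposition
    can never yield a pair that was not implanted.
    """
    for _ in range(50):
        utr3, start = _implant_positive_once(rng, cfg, ulen, trf, ext_nt)
        motif = _rc(trf.sequence.residues[1:7])
        lo, hi = max(0, start - 44), min(ulen, start + 6 + 40)
        region = utr3[lo:hi]
        count = sum(
            1 for k in range(len(region) - 5) if region[k : k + 6] == motif
        )
        if count == 1:
            return utr3, start
    raise RuntimeError("could not implant a clean functional site")


def _implant_positive_once(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    ulen: int,
    trf: TrfRecord,
    ext_nt: int,
) -> tuple[str, int]:
    utr3 = _random_seq(rng, ulen, cfg.gc)
    lo = 35 + ext_nt
    hi = ulen - 6 - 12
    start = int(rng.integers(lo, hi))
    # AU-enriched flanks first, then the complementarity blocks on top
    w = cfg.flank_width
    for pos in range(max(0, start - w), min(ulen, start + 6 + w)):
        if rng.random() < cfg.flank_au:
            utr3[pos] = "A" if rng.random() < 0.5 else "U"
        else:
            utr3[pos] = "G" if rng.random() < 0.5 else "C"
    seq = trf.sequence.residues
    utr3[start : start + 6] = list(_rc(seq[1:7]))
    if rng.random() < cfg.pos8_rate:
        utr3[start - 1] = _COMP[seq[7]]
    if rng.random() < cfg.ext_rate:
        # tRF positions 9..8+ext pair antiparallel immediately 5' of position 8
        ext = min(ext_nt, len(seq) - 8)
        if ext > 0:
            utr3[start - 1 - ext : start - 1] = list(_rc(seq[8 : 8 + ext]))
    return "".join(utr3), start


def _attach_fragments(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    transcripts: list[TranscriptRecord],
    truth: GroundTruth,
) -> None:
    """Choose a uniquely-mapping target fragment around each implanted site.

    The fragment must contain the seed match exactly once and occur
    exactly once across all 3'-UTRs, so chimeric-read decomposition can
    recover the implanted pair and nothing else; it is widened until
    unique.
    """
    utrs = {t.transcript_id: t.utr3 for t in transcripts}
    for key in truth.positives:
        trf_id, tid, start, end = key
        utr = utrs[tid]
        up, down = 8, 4
        while True:
            fstart, fend = max(0, start - up), min(len(utr), end + down)
            frag = utr[fstart:fend]
            occurrences = sum(u.count(frag) for u in utrs.values())
            if occurrences == 1:
                break
            up += 3
            down += 3
            if up > 40:  # pathological; regenerating flanks is not worth it
                raise RuntimeError(f"cannot make fragment unique for {key}")
        truth.fragments[key] = frag


def generate_chimeric_reads(
    truth: GroundTruth,
    trfs: list[TrfRecord],
    cfg: SyntheticConfig | None = None,
) -> list[NucleotideSequence]:
    """Chimeric reads: catalog tRF concatenated with its target fragment.

    Orientation (tRF first or last) is randomized; decoy reads contain
    no catalog tRF at either end.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    trf_by_id = {t.trf_id: t for t in trfs}
    reads: list[NucleotideSequence] = []
    n = 0
    for key in truth.positives:
        trf_id = key[0]
        frag = truth.fragments[key]
        for _ in range(cfg.reads_per_pair):
            n += 1
            tseq = trf_by_id[trf_id].sequence.residues
            if rng.random() < 0.5:
                residues = tseq + frag
            else:
                residues = frag + tseq
            reads.append(NucleotideSequence(f"read_{n:05d}", residues))
    ends = {t.sequence.residues for t in trfs}
    for _ in range(cfg.n_decoy_reads):
        while True:
            residues = "".join(_random_seq(rng, 40, cfg.gc))
            if not any(residues.startswith(e) or residues.endswith(e) for e in ends):
                break
        n += 1
        reads.append(NucleotideSequence(f"read_{n:05d}", residues))
    return reads


def generate_conservation_track(
    truth: GroundTruth,
    transcripts: list[TranscriptRecord],
    cfg: SyntheticConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-UTR conservation scores: high Beta mode over implanted sites."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    positive_spans: dict[str, list[tuple[int, int]]] = {}
    for _, tid, start, end in truth.positives:
        positive_spans.setdefault(tid, []).append((start, end))
    tracks: dict[str, np.ndarray] = {}
    a_lo, b_lo = cfg.conservation_low
    a_hi, b_hi = cfg.conservation_high
    for t in transcripts:
        arr = rng.beta(a_lo, b_lo, size=len(t.utr3))
        for start, end in positive_spans.get(t.transcript_id, []):
            arr[start:end] = rng.beta(a_hi, b_hi, size=end - start)
        tracks[t.transcript_id] = arr
    return tracks


def write_conservation_wiggle(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(tracks):
            fh.write(f"fixedStep chrom={sid} start=1 step=1\n")
            for v in tracks[sid]:
                fh.write(f"{v:.4f}\n")


def write_tag_counts(tag_counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttag_count\n")
        for tid in sorted(tag_counts):
            fh.write(f"{tid}\t{tag_counts[tid]}\n")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\ttrf_id\ttranscript_id\tstart\tend\n")
        for trf_id, tid, start, end in truth.positives:
            fh.write(f"positive\t{trf_id}\t{tid}\t{start}\t{end}\n")
        for trf_id, tid in truth.enriched_pairs:
            fh.write(f"enriched\t{trf_id}\t{tid}\t.\t.\n")
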