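"""Sequence and coordinate primitives shared by every pipeline stage.

All sequences are held internally in the RNA alphabet {A, C, G, U}; DNA
input (T) is converted on read.  Coordinates are 0-based half-open on the
transcript's 5'->3' strand; 1-based inclusive coordinates appear only in
user-facing reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALLOWED = set("ACGTUacgtuNn")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: canonical tRFdb length subclasses; anything else is "other"
TRF_SUBCLASS_LENGTHS = {
    ("tRF-3", 18): "3a",
    ("tRF-3", 22): "3b",
    ("tRF-5", 15): "5a",
    ("tRF-5", 22): "5b",
    ("tRF-5", 31): "5c",
}


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad residues, duplicate ids...)."""


def normalize_sequence(raw: str) -> str:
    """Map raw sequence text to the canonical RNA alphabet.

    Uppercases, converts T->U, and rejects anything outside
    {A,C,G,T,U,N} (case-insensitive) with the offending 0-based position.
    """
    if not raw:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(raw):
        if ch not in _ALLOWED:
            raise SequenceError(f"disallowed character {ch!r} at position {pos}")
    return raw.upper().replace("T", "U")


def reverse_complement(s: str) -> str:
    """Antiparallel complement in the RNA alphabet (A<->U, C<->G)."""
    return s.translate(_COMPLEMENT)[::-1]


def gc_percent(s: str) -> float:
    """GC content as a percentage of non-N residues.

    N residues are excluded from the denominator; an all-N (or empty)
    input has no defined composition and raises.
    """
    eff = len(s) - s.count("N")
    if eff == 0:
        raise SequenceError("GC percentage undefined: no non-N residues")
    return 100.0 * (s.count("G") + s.count("C")) / eff


@dataclass(frozen=True)
class Interval:
    """0-based half-open span on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TrfRecord:
    """A catalog tRF with its class, length subclass and seed.

    The seed is positions 2-7 (1-based, as the field numbers tRF
    nucleotides), i.e. ``sequence[1:7]``.
    """

    trf_id: str
    sequence: NucleotideSequence
    trf_class: str  # "tRF-3" or "tRF-5"

    def __post_init__(self) -> None:
        if self.trf_class not in ("tRF-3", "tRF-5"):
            raise ValueError(f"unknown tRF class {self.trf_class!r}")
        if len(self.sequence) < 8:
            raise SequenceError(
                f"{self.trf_id}: tRF must be >= 8 nt so positions 1-8 exist"
            )

    @property
    def seed(self) -> str:
        return self.sequence.residues[1:7]

    @property
    def length_subclass(self) -> str:
        return TRF_SUBCLASS_LENGTHS.get(
            (self.trf_class, len(self.sequence)), "other"
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA with its three regions; any region but the 3'-UTR may be empty."""

    transcript_id: str
    gene_symbol: str
    utr5: str
    cds: str
    utr3: str

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass(frozen=True)
class Window:
    """An extracted flank with a truncation flag."""

    residues: str
    truncated: bool


def window_extract(
    seq: str, site: Interval, up: int, down: int
) -> tuple[Window, Window]:
    """Extract up to ``up`` nt 5' of a site and ``down`` nt 3' of it.

    Windows truncated at the sequence boundary are returned as-is and
    flagged, never padded.
    """
    if site.end > len(seq):
        raise ValueError("site extends beyond sequence")
    u_start = max(0, site.start - up)
    upstream = Window(seq[u_start : site.start], site.start - u_start < up)
    d_end = min(len(seq), site.end + down)
    downstream = Window(seq[site.end : d_end], d_end - site.end < down)
    return upstream, downstream


# ---------------------------------------------------------------------------
# file I/O


def load_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized records; ids must be unique."""
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta-2line")


def load_trf_catalog(path: str | Path) -> list[TrfRecord]:
    """Read a tRF FASTA whose headers carry the class.

    The class is taken from a ``class=tRF-3`` / ``class=tRF-5`` key in the
    description, or inferred from a ``tRF-3``/``tRF-5`` substring of the id
    (tRFdb-style ids such as ``tRF-3001a`` begin with the class).
    """
    out: list[TrfRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate tRF id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if "class=tRF-3" in desc or rec.id.startswith("tRF-3"):
            cls = "tRF-3"
        elif "class=tRF-5" in desc or rec.id.startswith("tRF-5"):
            cls = "tRF-5"
        else:
            raise SequenceError(f"{rec.id}: cannot determine tRF class")
        out.append(
            TrfRecord(rec.id, NucleotideSequence(rec.id, normalize_sequence(str(rec.seq))), cls)
        )
    return out


def load_transcripts(
    fasta_path: str | Path, region_table_path: str | Path
) -> list[TranscriptRecord]:
    """Combine a transcript FASTA with a TSV region table.

    The table columns are transcript_id, gene_symbol, utr5_len, cds_len,
    utr3_len; region lengths must sum to the FASTA sequence length.
    """
    seqs = {r.id: r.residues for r in load_fasta(fasta_path)}
    out: list[TranscriptRecord] = []
    with open(region_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "gene_symbol", "utr5_len", "cds_len", "utr3_len"]
        if header != expected:
            raise SequenceError(f"region table header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tid, gene, l5, lc, l3 = line.rstrip("\n").split("\t")
            l5, lc, l3 = int(l5), int(lc), int(l3)
            if tid not in seqs:
                raise SequenceError(f"line {lineno}: {tid} absent from FASTA")
            seq = seqs[tid]
            if l5 + lc + l3 != len(seq):
                raise SequenceError(
                    f"line {lineno}: region lengths {l5}+{lc}+{l3} != {len(seq)}"
                )
            out.append(
                TranscriptRecord(tid, gene, seq[:l5], seq[l5 : l5 + lc], seq[l5 + lc :])
            )
    return out


def write_transcripts(
    transcripts: Iterable[TranscriptRecord],
    fasta_path: str | Path,
    region_table_path: str | Path,
) -> None:
    transcripts = list(transcripts)
    write_fasta(
        [NucleotideSequence(t.transcript_id, t.sequence) for t in transcripts],
        fasta_path,
    )
    with open(region_table_path, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tutr5_len\tcds_len\tutr3_len\n")
        for t in transcripts:
            fh.write(
                f"{t.transcript_id}\t{t.gene_symbol}\t{len(t.utr5)}\t{len(t.cds)}\t{len(t.utr3)}\n"
            )
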