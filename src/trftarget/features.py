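"""The per-site feature roster: sequence context, transcript, tRF and
duplex/accessibility features for every candidate interaction.

Features fall into four families mirroring what is known to shape
small-RNA targeting: the local sequence context of the seed match
(match-type flags, flanking base identities, AU/GC content weighted by
distance, positional distances), global transcript properties, tRF
properties (length, GC, target-site abundance), and thermodynamics of
the tRF:mRNA duplex and of the site's local secondary structure.

The distance-weighted AU score of a flank is

    S_AU = sum over A/U bases of 1/d,

where d is the base's distance (in nt, nearest = 1) to the seed match.
Scores are computed for 35 nt upstream, 15 nt downstream, and upstream
excluding the 10 nt immediately adjacent (where pairing of the tRF 3'
region, not AU context, dominates).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .chimera import InteractionPair
from .seq import Interval, TranscriptRecord, TrfRecord, gc_percent, reverse_complement, window_extract
from .sites import SeedMatchSite
from .thermo import EnergyModel, accessibility_features, duplex_mfe

logger = logging.getLogger(__name__)

BASES = "ACGU"
DINUCS = ["".join(p) for p in itertools.product(BASES, repeat=2)]

#: how much target context around the site enters the duplex calculation:
#: the tRF 3' region pairs 5' of the seed match, position 1 just 3' of it
DUPLEX_UP = 30
DUPLEX_DOWN = 5


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature roster; the GA operates on whatever roster is active."""

    entries: tuple[tuple[str, str], ...]  # (name, family)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def version(self) -> str:
        import hashlib

        return hashlib.sha1("|".join(self.names).encode()).hexdigest()[:12]

    def family(self, name: str) -> str:
        return dict(self.entries)[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["name", "family"])


def default_registry() -> FeatureRegistry:
    entries: list[tuple[str, str]] = []

    def add(names, family):
        entries.extend((n, family) for n in names)

    add(["pos8_match", "pos1_match", "pos1A"], "site_sequence")
    for pos in ("up1", "up2", "down1", "down2"):
        add([f"flank_{pos}_{b}" for b in BASES], "site_sequence")
    add(["gc_up35", "gc_up25ex10", "gc_down15"], "site_sequence")
    add(["s_au_up35", "s_au_up25ex10", "s_au_down15"], "site_sequence")
    add([f"comp_up35_{b}" for b in BASES], "site_sequence")
    add([f"dinuc_up35_{d}" for d in DINUCS], "site_sequence")
    add([f"comp_down15_{b}" for b in BASES], "site_sequence")
    add([f"dinuc_down15_{d}" for d in DINUCS], "site_sequence")
    add(["dist5", "dist3", "dist_nearest"], "site_sequence")

    add(["utr3_len", "utr3_gc", "utr3_seed_freq"], "transcript")
    add([f"comp_utr3_{b}" for b in BASES], "transcript")
    add([f"dinuc_utr3_{d}" for d in DINUCS], "transcript")
    add(["cds_len", "cds_gc", "cds_seed_freq"], "transcript")
    add(["utr5_len", "utr5_gc", "utr5_seed_freq"], "transcript")

    add(["trf_len", "trf_gc", "seed_gc", "ta_3utr", "ta_genome"], "trf")

    add(
        ["duplex_mfe", "duplex_paired", "duplex_paired_nonseed",
         "exposed_at_site", "exposed_flanks", "opening_energy"],
        "duplex_thermo",
    )
    return FeatureRegistry(tuple(entries))


# ---------------------------------------------------------------------------
# primitives


def flank_au_score(window_nearest_first: str, exclude_first: int = 0) -> float:
    """Distance-weighted AU score; position 1 is the base adjacent to the site."""
    s = 0.0
    for d, base in enumerate(window_nearest_first, start=1):
        if d <= exclude_first:
            continue
        if base in "AU":
            s += 1.0 / d
    return s


def window_composition(window: str) -> dict[str, float]:
    """Mononucleotide and dinucleotide fractions plus GC percent.

    Fractions are over N-free counts; windows too short for a family
    leave that family missing (NaN).
    """
    out: dict[str, float] = {}
    eff = [c for c in window if c != "N"]
    n = len(eff)
    for b in BASES:
        out[f"comp_{b}"] = eff.count(b) / n if n else math.nan
    out["gc"] = gc_percent(window) if n else math.nan
    dinuc_counts = {d: 0 for d in DINUCS}
    total = 0
    for a, b in zip(window, window[1:]):
        if a != "N" and b != "N":
            dinuc_counts[a + b] += 1
            total += 1
    for d in DINUCS:
        out[f"dinuc_{d}"] = dinuc_counts[d] / total if total else math.nan
    return out


def _count_occurrences(text: str, motif: str) -> int:
    count, start = 0, text.find(motif)
    while start != -1:
        count += 1
        start = text.find(motif, start + 1)
    return count


def seed_match_frequency(region: str, seed: str) -> float:
    """Occurrences of the seed's reverse complement per 1000 nt of region."""
    if not region:
        return math.nan
    return 1000.0 * _count_occurrences(region, reverse_complement(seed)) / len(region)


# ---------------------------------------------------------------------------
# family providers


def site_features(trf: TrfRecord, utr: str, site: SeedMatchSite) -> dict[str, float]:
    iv = site.site
    if iv.end > len(utr):
        raise ValueError("site outside UTR")
    vals: dict[str, float] = {
        "pos8_match": float(site.pos8_match),
        "pos1_match": float(site.pos1_match),
        "pos1A": float(site.pos1A),
    }
    flank_bases = {
        "up1": utr[iv.start - 1] if iv.start >= 1 else None,
        "up2": utr[iv.start - 2] if iv.start >= 2 else None,
        "down1": utr[iv.end] if iv.end < len(utr) else None,
        "down2": utr[iv.end + 1] if iv.end + 1 < len(utr) else None,
    }
    for pos, base in flank_bases.items():
        for b in BASES:
            vals[f"flank_{pos}_{b}"] = float(base == b)
    up35, down15 = window_extract(utr, iv, 35, 15)
    up_nf = up35.residues[::-1]  # nearest-first
    down_nf = down15.residues
    vals["gc_up35"] = gc_percent(up35.residues) if up35.residues.strip("N") else math.nan
    up25 = up35.residues[:-10] if len(up35.residues) > 10 else ""
    vals["gc_up25ex10"] = gc_percent(up25) if up25.strip("N") else math.nan
    vals["gc_down15"] = gc_percent(down_nf) if down_nf.strip("N") else math.nan
    vals["s_au_up35"] = flank_au_score(up_nf)
    vals["s_au_up25ex10"] = flank_au_score(up_nf, exclude_first=10)
    vals["s_au_down15"] = flank_au_score(down_nf)
    for key, window in (("up35", up35.residues), ("down15", down_nf)):
        comp = window_composition(window)
        for b in BASES:
            vals[f"comp_{key}_{b}"] = comp[f"comp_{b}"]
        for d in DINUCS:
            vals[f"dinuc_{key}_{d}"] = comp[f"dinuc_{d}"]
    vals["dist5"] = float(site.dist5)
    vals["dist3"] = float(site.dist3)
    vals["dist_nearest"] = float(site.dist_nearest)
    return vals


def transcript_features(transcript: TranscriptRecord, trf: TrfRecord) -> dict[str, float]:
    vals: dict[str, float] = {}
    for key, region in (("utr3", transcript.utr3), ("cds", transcript.cds), ("utr5", transcript.utr5)):
        vals[f"{key}_len"] = float(len(region)) if region else math.nan
        vals[f"{key}_gc"] = gc_percent(region) if region.strip("N") else math.nan
        vals[f"{key}_seed_freq"] = seed_match_frequency(region, trf.seed)
    comp = window_composition(transcript.utr3)
    for b in BASES:
        vals[f"comp_utr3_{b}"] = comp[f"comp_{b}"]
    for d in DINUCS:
        vals[f"dinuc_utr3_{d}"] = comp[f"dinuc_{d}"]
    return vals


def trf_features(
    trf: TrfRecord,
    transcripts: list[TranscriptRecord],
    genome: list[str] | None = None,
) -> dict[str, float]:
    motif = reverse_complement(trf.seed)
    ta_3utr = sum(_count_occurrences(t.utr3, motif) for t in transcripts)
    ta_genome = (
        float(sum(_count_occurrences(g, motif) for g in genome))
        if genome is not None
        else math.nan
    )
    return {
        "trf_len": float(len(trf.sequence)),
        "trf_gc": gc_percent(trf.sequence.residues),
        "seed_gc": gc_percent(trf.seed),
        "ta_3utr": float(ta_3utr),
        "ta_genome": ta_genome,
    }


def thermo_features(
    trf: TrfRecord, utr: str, site: Interval, model: EnergyModel
) -> dict[str, float]:
    rstart = max(0, site.start - DUPLEX_UP)
    rend = min(len(utr), site.end + DUPLEX_DOWN)
    duplex = duplex_mfe(trf.sequence.residues, utr[rstart:rend], model)
    nonseed = sum(1 for trf_pos, _ in duplex.pairing_map if not 1 <= trf_pos <= 6)
    acc = accessibility_features(utr, site, model)
    return {
        "duplex_mfe": duplex.mfe,
        "duplex_paired": float(duplex.paired_count),
        "duplex_paired_nonseed": float(nonseed),
        "exposed_at_site": float(acc.exposed_at_site),
        "exposed_flanks": float(acc.exposed_flanks),
        "opening_energy": acc.opening_energy,
    }


# ---------------------------------------------------------------------------
# assembly


def assemble_feature_matrix(
    pairs: list[InteractionPair],
    trfs: list[TrfRecord],
    transcripts: list[TranscriptRecord],
    model: EnergyModel | None = None,
    genome: list[str] | None = None,
    registry: FeatureRegistry | None = None,
) -> pd.DataFrame:
    """One feature row per interaction pair, columns in registry order.

    Missing values stay NaN here; imputation (training-partition medians
    only) happens inside the classifier fit so no test-fold information
    leaks into it.
    """
    model = model or EnergyModel()
    registry = registry or default_registry()
    trf_by_id = {t.trf_id: t for t in trfs}
    tx_by_id = {t.transcript_id: t for t in transcripts}
    trf_cache: dict[str, dict[str, float]] = {}
    tx_cache: dict[tuple[str, str], dict[str, float]] = {}
    rows, index = [], []
    for pair in pairs:
        try:
            trf = trf_by_id[pair.trf_id]
            tx = tx_by_id[pair.transcript_id]
            if trf.trf_id not in trf_cache:
                trf_cache[trf.trf_id] = trf_features(trf, transcripts, genome)
            tkey = (trf.trf_id, tx.transcript_id)
            if tkey not in tx_cache:
                tx_cache[tkey] = transcript_features(tx, trf)
            vals: dict[str, float] = {}
            vals.update(site_features(trf, tx.utr3, pair.site))
            vals.update(tx_cache[tkey])
            vals.update(trf_cache[trf.trf_id])
            vals.update(thermo_features(trf, tx.utr3, pair.site.site, model))
        except Exception as exc:  # drop the row, keep the run alive
            logger.warning("dropping pair %s: %s", pair.key, exc)
            continue
        rows.append([vals[name] for name in registry.names])
        index.append(pair.key)
    return pd.DataFrame(
        rows,
        columns=registry.names,
        index=pd.MultiIndex.from_tuples(
            index, names=["trf_id", "transcript_id", "start", "end"]
        ),
    )
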