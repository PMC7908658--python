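"""Independent probabilistic predictor: binomial overrepresentation of
seed matches against an order-1 Markov background.

For each tRF / 3'-UTR pair, the chance P of the 6-nt seed match arising
at any one position is computed from a first-order Markov chain fitted
to the base composition of the sequence; the observed match count f over
the l - k + 1 possible positions (k = 6) is then scored with an exact
upper-tail binomial probability

    Ps = sum_{i=f}^{l-k+1} C(l-k+1, i) P^i (1-P)^(l-k+1-i),

and Ps values are adjusted across all tested pairs with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seq import TranscriptRecord, TrfRecord, reverse_complement

logger = logging.getLogger(__name__)

_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}
SEED_LEN = 6


@dataclass(frozen=True)
class MarkovBackground:
    initial: np.ndarray  # length 4
    transition: np.ndarray  # 4x4 row-stochastic
    fitted_on: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass(frozen=True)
class BinomialEnrichment:
    trf_id: str
    transcript_id: str
    P: float
    l: int
    f: int
    Ps: float
    k: int = SEED_LEN
    ps_adjusted: float = float("nan")
    fdr_flag: bool = False


def fit_markov_background(seq: str, seq_id: str = "") -> MarkovBackground:
    """Empirical order-1 Markov chain over {A,C,G,U} from one sequence.

    N residues are ignored for counting.  A base never observed as a
    transition source falls back to a uniform row.
    """
    if len(seq) < 2:
        raise ValueError("need >= 2 residues to fit transitions")
    counts = np.zeros(4)
    trans = np.zeros((4, 4))
    prev = -1
    for ch in seq:
        cur = _IDX.get(ch, -1)
        if cur >= 0:
            counts[cur] += 1
            if prev >= 0:
                trans[prev, cur] += 1
        prev = cur
    if counts.sum() == 0:
        raise ValueError("no canonical residues")
    initial = counts / counts.sum()
    rowsum = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        transition = np.where(rowsum > 0, trans / np.where(rowsum > 0, rowsum, 1), 0.25)
    if np.any(rowsum == 0):
        logger.debug("uniform fallback rows in Markov fit of %s", seq_id)
    return MarkovBackground(initial, transition, (seq_id,) if seq_id else ())


def fit_pooled_background(seqs: list[str]) -> MarkovBackground:
    """Markov background pooled over a whole transcript set (config option)."""
    joined = fit_markov_background("N".join(seqs))  # N breaks cross-sequence transitions
    return joined


def seed_match_probability(bg: MarkovBackground, motif: str) -> float:
    """Chain probability of a 6-mer under the background model."""
    if len(motif) != SEED_LEN:
        raise ValueError("motif must be 6 nt")
    idx = [_IDX[c] for c in motif]
    p = bg.initial[idx[0]]
    for a, b in zip(idx, idx[1:]):
        p *= bg.transition[a, b]
    return float(p)


def binomial_enrichment(P: float, l: int, f: int, k: int = SEED_LEN) -> float:
    """Exact upper-tail binomial Ps with n = l - k + 1 trials."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    n = l - k + 1
    if n < 1:
        raise ValueError("target shorter than the seed")
    if not 0 <= f <= n:
        raise ValueError(f"f={f} outside [0, {n}]")
    if f == 0:
        return 1.0
    return float(stats.binom.sf(f - 1, n, P))


def bh_adjust(ps_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserving, capped at 1."""
    if not ps_values:
        return []
    _, adj, _, _ = multipletests(ps_values, method="fdr_bh")
    return [float(v) for v in adj]


def enrichment_scan(
    trfs: list[TrfRecord],
    transcripts: list[TranscriptRecord],
    per_utr_background: bool = True,
    fdr_cutoff: float = 0.05,
) -> list[BinomialEnrichment]:
    """Ps for every tRF x 3'-UTR pair, BH-adjusted over the whole family.

    The background is fitted per tested 3'-UTR by default (its own base
    composition); a pooled-transcriptome background is the alternative.
    """
    pooled = None
    if not per_utr_background:
        pooled = fit_pooled_background([t.utr3 for t in transcripts if t.utr3])
    raw: list[BinomialEnrichment] = []
    for t in transcripts:
        if len(t.utr3) < SEED_LEN:
            continue
        bg = pooled if pooled is not None else fit_markov_background(t.utr3, t.transcript_id)
        for trf in trfs:
            motif = reverse_complement(trf.seed)
            P = seed_match_probability(bg, motif)
            f, start = 0, t.utr3.find(motif)
            while start != -1:
                f += 1
                start = t.utr3.find(motif, start + 1)
            Ps = binomial_enrichment(P, len(t.utr3), f)
            raw.append(BinomialEnrichment(trf.trf_id, t.transcript_id, P, len(t.utr3), f, Ps))
    adjusted = bh_adjust([r.Ps for r in raw])
    return [
        BinomialEnrichment(
            r.trf_id, r.transcript_id, r.P, r.l, r.f, r.Ps,
            ps_adjusted=a, fdr_flag=a < fdr_cutoff,
        )
        for r, a in zip(raw, adjusted)
    ]


def rank_overrepresented(
    pairs: list[BinomialEnrichment], fdr_cutoff: float = 0.05
) -> list[BinomialEnrichment]:
    """Stable sort ascending by adjusted Ps; flag pairs under the cutoff."""
    ranked = sorted(pairs, key=lambda r: r.ps_adjusted)
    return [
        BinomialEnrichment(
            r.trf_id, r.transcript_id, r.P, r.l, r.f, r.Ps,
            ps_adjusted=r.ps_adjusted, fdr_flag=r.ps_adjusted < fdr_cutoff,
        )
        for r in ranked
    ]
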