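"""End-to-end orchestration: synthetic reference -> chimeric-read
decomposition -> features -> SVM-GA training -> predictions, plus the
two independent predictors.  Used by the command-line interface and by
the reproducibility script; every stage is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chimera, classify, conservation, features, probmodel, simulate, sites
from .classify import GaConfig, TargetSiteClassifier
from .thermo import EnergyModel


@dataclass
class PipelineResult:
    """Quantities measured by one full synthetic round trip."""

    n_implanted: int
    n_recovered: int
    recovery_exact: bool
    heldout_auc: float
    permuted_auc_mean: float
    ga_selected: list[str]
    informative_families_recovered: int
    transcript_recall: float
    enrichment_median_implanted: float
    enrichment_median_other: float
    conservation_detection_rate: float
    conservation_background_rate: float
    results: "classify.TargetSiteClassifierResults | None" = None
    feature_table: pd.DataFrame | None = None


def permuted_auc(
    X: np.ndarray, y: np.ndarray, n_permutations: int = 10, rng_seed: int = 0
) -> float:
    """Mean held-out CV AUC after label permutation (null check)."""
    rng = np.random.default_rng(rng_seed)
    mask = np.ones(X.shape[1], dtype=bool)
    aucs = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        folds = classify.make_folds(yp, rng_seed=int(rng.integers(2**31 - 1)))
        aucs.append(classify._cv_auc(X, yp, folds, mask, {"C": 1.0, "gamma": "scale"}))
    return float(np.mean(aucs))


def run_synthetic_pipeline(
    cfg: simulate.SyntheticConfig | None = None,
    ga_generations: int = 20,
    ga_population: int = 50,
    n_permutations: int = 10,
    rng_seed: int = 0,
    keep_artifacts: bool = False,
) -> PipelineResult:
    """The full round trip on synthetic data with known ground truth."""
    cfg = cfg or simulate.SyntheticConfig(rng_seed=rng_seed)
    transcripts, trfs, truth, tag_counts = simulate.generate_reference(cfg)
    energy = EnergyModel()

    # --- chimeric reads -> positive pairs
    reads = simulate.generate_chimeric_reads(truth, trfs, cfg)
    positives, _ = chimera.build_interaction_pairs(reads, trfs, transcripts)
    implanted = {(t, x, s, e) for t, x, s, e in truth.positives}
    recovered = {p.key for p in positives}
    recovery_exact = recovered == implanted

    # --- background and negatives
    background = sites.build_background(trfs, transcripts, positives)
    negatives = classify.sample_negatives(
        background, tag_counts, len(positives), rng_seed=rng_seed
    )

    # --- features and SVM-GA
    model_spec = TargetSiteClassifier.from_pairs(
        positives, negatives, trfs, transcripts, model=energy, rng_seed=rng_seed
    )
    ga = GaConfig(
        iterations=ga_generations,
        population_size=ga_population,
        rng_seed=rng_seed,
    )
    results = model_spec.fit(ga=ga)
    selected = set(results.selected_features)
    fam_hits = sum(
        1
        for members in truth.informative_families.values()
        if selected.intersection(members)
    )
    null_auc = permuted_auc(
        model_spec.X.to_numpy(dtype=float),
        model_spec.y,
        n_permutations=n_permutations,
        rng_seed=rng_seed,
    )

    # --- transcript-level recall on the implanted pairs
    pos_keys = {(t, x) for t, x, _, _ in truth.positives}
    tx_by_id = {t.transcript_id: t for t in transcripts}
    trf_by_id = {t.trf_id: t for t in trfs}
    scan_pairs = []
    for trf_id, tid in sorted(pos_keys):
        for site in sites.scan_seed_matches(
            trf_by_id[trf_id], tx_by_id[tid].utr3, tid
        ):
            scan_pairs.append(
                chimera.InteractionPair(trf_id, tid, site, "positive", "scan")
            )
    X_scan = features.assemble_feature_matrix(scan_pairs, trfs, transcripts, model=energy)
    tx_preds = results.predict_transcripts(X_scan)
    hit = sum(1 for p in tx_preds if (p.trf_id, p.transcript_id) in pos_keys and p.is_target)
    recall = hit / len(pos_keys)

    # --- probabilistic model: enrichment recovery
    enr = probmodel.enrichment_scan(trfs, transcripts)
    enriched_set = set(truth.enriched_pairs)
    imp = [e.ps_adjusted for e in enr if (e.trf_id, e.transcript_id) in enriched_set]
    oth = [e.ps_adjusted for e in enr if (e.trf_id, e.transcript_id) not in enriched_set]
    med_imp = float(np.median(imp)) if imp else float("nan")
    med_oth = float(np.median(oth)) if oth else float("nan")

    # --- conservation predictor on implanted vs background sites
    tracks = simulate.generate_conservation_track(truth, transcripts, cfg)
    track = conservation.ScoreTrack(tracks)
    cons_pos = [
        conservation.site_conservation(track, t, x, chimera.Interval(x, s, e))
        for t, x, s, e in truth.positives
    ]
    calls_pos = conservation.conservation_predict(cons_pos)
    cons_bg = [
        conservation.site_conservation(
            track, p.trf_id, p.transcript_id, p.site.site
        )
        for p in background[:200]
    ]
    calls_bg = conservation.conservation_predict(cons_bg)
    det = sum(1 for _, flag in calls_pos if flag) / max(1, len(calls_pos))
    det_bg = sum(1 for _, flag in calls_bg if flag) / max(1, len(calls_bg))

    return PipelineResult(
        n_implanted=len(implanted),
        n_recovered=len(recovered & implanted),
        recovery_exact=recovery_exact,
        heldout_auc=results.heldout_auc,
        permuted_auc_mean=null_auc,
        ga_selected=sorted(selected),
        informative_families_recovered=fam_hits,
        transcript_recall=recall,
        enrichment_median_implanted=med_imp,
        enrichment_median_other=med_oth,
        conservation_detection_rate=det,
        conservation_background_rate=det_bg,
        results=results if keep_artifacts else None,
        feature_table=model_spec.X if keep_artifacts else None,
    )


def end_to_end(
    trained: "classify.TrainedModel",
    trfs,
    transcripts,
    track: "conservation.ScoreTrack | None" = None,
    energy: EnergyModel | None = None,
    fdr_cutoff: float = 0.05,
    conservation_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Scan -> features -> predict with a saved model, all three criteria.

    One row per (tRF, transcript) with at least one seed match, carrying
    the SVM noisy-OR probability, the BH-adjusted overrepresentation Ps,
    and the conservation call (best seed-region mean across the
    transcript's sites; NaN without a track), so candidates can be
    ranked by any of the three predictors.
    """
    energy = energy or EnergyModel()
    pairs = [
        chimera.InteractionPair(t.trf_id, x.transcript_id, s, "background", "scan")
        for x in transcripts
        if x.utr3
        for t in trfs
        for s in sites.scan_seed_matches(t, x.utr3, x.transcript_id)
    ]
    if not pairs:
        return pd.DataFrame(
            columns=["trf_id", "transcript_id", "n_sites", "P", "is_target",
                     "ps_adjusted", "fdr_flag", "cons_mean_seed", "cons_predicted"]
        )
    X = features.assemble_feature_matrix(pairs, trfs, transcripts, model=energy)
    if list(X.columns) != trained.feature_names:
        raise ValueError("feature registry does not match the trained model")
    probs = classify.predict_site_matrix(trained, X.to_numpy(dtype=float))
    grouped: dict[tuple[str, str], list[classify.SitePrediction]] = {}
    cons_best: dict[tuple[str, str], float] = {}
    for (trf_id, tid, start, end), p in zip(X.index, probs):
        key = (trf_id, tid)
        grouped.setdefault(key, []).append(
            classify.SitePrediction(trf_id, tid, start, end, float(p))
        )
        if track is not None:
            sc = conservation.site_conservation(
                track, trf_id, tid, chimera.Interval(tid, start, end)
            )
            prev = cons_best.get(key, float("nan"))
            if not np.isnan(sc.mean_seed) and not sc.mean_seed <= prev:
                cons_best[key] = sc.mean_seed
    enr = {
        (e.trf_id, e.transcript_id): e
        for e in probmodel.enrichment_scan(trfs, transcripts, fdr_cutoff=fdr_cutoff)
    }
    rows = []
    for key, site_preds in grouped.items():
        agg = classify.aggregate_transcript(site_preds)
        e = enr.get(key)
        cm = cons_best.get(key, float("nan"))
        rows.append(
            {
                "trf_id": key[0],
                "transcript_id": key[1],
                "n_sites": agg.n_sites,
                "P": agg.P,
                "is_target": int(agg.is_target),
                "ps_adjusted": e.ps_adjusted if e else float("nan"),
                "fdr_flag": int(e.fdr_flag) if e else 0,
                "cons_mean_seed": cm,
                "cons_predicted": int(cm >= conservation_cutoff) if cm == cm else 0,
            }
        )
    return pd.DataFrame(rows).sort_values(["trf_id", "transcript_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV writers shared by the CLI


def pairs_to_frame(pairs: list[chimera.InteractionPair]) -> pd.DataFrame:
    rows = [
        {
            "trf_id": p.trf_id,
            "transcript_id": p.transcript_id,
            "site_start": p.site.site.start,
            "site_end": p.site.site.end,
            "pos8": int(p.site.pos8_match),
            "pos1": int(p.site.pos1_match),
            "pos1A": int(p.site.pos1A),
            "dist5": p.site.dist5,
            "dist3": p.site.dist3,
            "label": p.label,
            "source": p.source,
            "multi_mapping": int(p.multi_mapping),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def enrichment_to_frame(entries: list[probmodel.BinomialEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trf_id": e.trf_id,
                "transcript_id": e.transcript_id,
                "P": e.P,
                "l": e.l,
                "f": e.f,
                "Ps": e.Ps,
                "ps_adjusted": e.ps_adjusted,
                "fdr_flag": int(e.fdr_flag),
            }
            for e in entries
        ]
    )


def transcript_predictions_to_frame(
    preds: list[classify.TranscriptPrediction],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trf_id": p.trf_id,
                "transcript_id": p.transcript_id,
                "n_sites": p.n_sites,
                "P": p.P,
                "is_target": int(p.is_target),
            }
            for p in preds
        ]
    )
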