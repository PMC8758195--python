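"""Stage orchestration: simulate -> features -> pigment -> stats -> infer.

Each stage reads the previous stage's CSV outputs from the run directory and
writes its own, so a run is resumable and individual stages can be rerun.
Every CSV carries a provenance comment header (package version, config hash,
seed); reruns with identical configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (FeatureConfig, FeatureSet, build_match_graph,
                       extract_features, feature_table, within_clutch_match_rate)
from .imageprep import (QualityThresholds, load_egg_image, quality_filter,
                        segment_egg, to_grayscale)
from .infer import (TierParams, classify_link, compute_pair_evidence,
                    read_nest_csv, report, tier_screen)
from .pigment import PigmentParams, RoiError, pigment_score
from .stats import (assemble_feature_vectors, build_dissimilarity_matrix,
                    lda_classify, nmds, permanova)
from .synth import ScenarioConfig, generate_population, write_dataset

log = logging.getLogger("eggmatch")

__all__ = ["RunConfig", "run_simulate", "run_features", "run_pigment",
           "run_stats", "run_infer", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one pipeline run."""

    dataset_dir: Path
    output_dir: Path
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    pigment_params: PigmentParams = field(default_factory=PigmentParams)
    tier_params: TierParams = field(default_factory=TierParams)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    batch_by: str = "region"  # "region" | "year" | "all"
    n_perm: int = 999
    seed: int = 0

    def hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("dataset_dir")
        payload.pop("output_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# eggmatch {__version__} config_hash={cfg.hash()} seed={cfg.seed}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_simulate(cfg: ScenarioConfig, outdir: Path) -> Path:
    """Generate a synthetic dataset on disk."""
    ds = generate_population(cfg)
    write_dataset(ds, outdir)
    log.info("simulated %d eggs in %d nests -> %s",
             len(ds.eggs), len(ds.nests), outdir)
    return outdir


def _load_images(cfg: RunConfig) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Load every readable egg image; unreadable files become exclusions."""
    manifest = pd.read_csv(cfg.dataset_dir / "manifest.csv", comment="#")
    images = {}
    errors = []
    for row in manifest.itertuples(index=False):
        path = cfg.dataset_dir / "images" / f"{row.egg_id}.png"
        try:
            images[str(row.egg_id)] = load_egg_image(
                path, mm_per_px=float(row.mm_per_px),
                egg_id=str(row.egg_id), clutch_id=str(row.clutch_id))
        except Exception as exc:  # noqa: BLE001 - a bad file is an exclusion
            errors.append({"egg_id": str(row.egg_id), "reason": f"unreadable: {exc}"})
    return manifest, images, errors


def run_features(cfg: RunConfig) -> pd.DataFrame:
    """Segment, quality-filter and extract features for every egg.

    Writes the per-egg feature table, the exclusion log, and per-batch match
    CSVs.  Corrupt or unreadable eggs are excluded and logged, never fatal.
    """
    manifest, images, exclusions = _load_images(cfg)
    feature_sets: dict[str, FeatureSet] = {}
    for egg_id, img in images.items():
        try:
            gray = to_grayscale(img)
            mask = segment_egg(gray)
            decision = quality_filter(gray, cfg.quality, mask)
            if not decision.keep:
                exclusions.append({"egg_id": egg_id, "reason": decision.reason})
                continue
            feature_sets[egg_id] = extract_features(gray, mask, cfg.feature_config)
        except Exception as exc:  # noqa: BLE001 - any bad egg is an exclusion
            exclusions.append({"egg_id": egg_id, "reason": f"error: {exc}"})
    ftab = feature_table(list(feature_sets.values()))
    _write_csv(ftab, cfg.output_dir / "features.csv", cfg)
    _write_csv(pd.DataFrame(exclusions, columns=["egg_id", "reason"]),
               cfg.output_dir / "exclusions.csv", cfg)

    nests = {n.nest_id: n for n in read_nest_csv(cfg.dataset_dir / "nests.csv")}
    clutch_of = dict(zip(manifest.egg_id.astype(str), manifest.clutch_id.astype(str)))
    batches = _batches(manifest, nests, clutch_of, cfg.batch_by)
    match_rows = []
    for label, egg_ids in batches.items():
        pool = [feature_sets[e] for e in egg_ids if e in feature_sets]
        if len(pool) < 2:
            continue
        graph = build_match_graph(pool, batch_label=label)
        for egg, ranked in graph.ranked.items():
            for rank, (other, d) in enumerate(ranked, start=1):
                match_rows.append({"egg_id": egg, "rank": rank,
                                   "matched_egg_id": other, "dissimilarity": d,
                                   "batch_label": label})
    _write_csv(pd.DataFrame(match_rows), cfg.output_dir / "matches.csv", cfg)
    np.savez_compressed(cfg.output_dir / "feature_cache.npz",
                        **{e: fs.descriptors for e, fs in feature_sets.items()})
    return ftab


def _batches(manifest: pd.DataFrame, nests, clutch_of, batch_by: str) -> dict:
    eggs = manifest.egg_id.astype(str).tolist()
    if batch_by == "all":
        return {"all": eggs}
    key = {}
    for egg in eggs:
        nest = nests[clutch_of[egg]]
        key[egg] = str(nest.region) if batch_by == "region" else str(nest.year)
    out: dict[str, list[str]] = {}
    for egg, label in key.items():
        out.setdefault(label, []).append(egg)
    return out


def run_pigment(cfg: RunConfig) -> pd.DataFrame:
    """Bernsen threshold + standard large-pole oval for every retained egg."""
    manifest, images, _ = _load_images(cfg)
    excluded = set(pd.read_csv(cfg.output_dir / "exclusions.csv", comment="#")
                   .egg_id.astype(str)) if (cfg.output_dir / "exclusions.csv").exists() else set()
    rows = []
    for egg_id, img in images.items():
        if egg_id in excluded:
            continue
        try:
            gray = to_grayscale(img)
            mask = segment_egg(gray)
            res = pigment_score(gray.pixels, mask, img.mm_per_px, egg_id,
                                cfg.pigment_params)
            rows.append({"egg_id": egg_id, "percent_black": res.percent_black,
                         "roi_area_px": res.roi_area_px,
                         "window_radius_px": res.window_radius_px,
                         "contrast_limit": res.contrast_limit})
        except RoiError as exc:
            rows.append({"egg_id": egg_id, "percent_black": np.nan,
                         "roi_area_px": 0,
                         "window_radius_px": cfg.pigment_params.window_radius_px,
                         "contrast_limit": cfg.pigment_params.contrast_limit})
            log.info("pigment ROI failed for %s: %s", egg_id, exc)
    out = pd.DataFrame(rows)
    _write_csv(out, cfg.output_dir / "pigment.csv", cfg)
    return out


def run_stats(cfg: RunConfig) -> dict:
    """Clutch/year discrimination statistics on the assembled egg vectors."""
    manifest = pd.read_csv(cfg.dataset_dir / "manifest.csv", comment="#")
    manifest["egg_id"] = manifest.egg_id.astype(str)
    pigment = pd.read_csv(cfg.output_dir / "pigment.csv", comment="#")
    features = pd.read_csv(cfg.output_dir / "features.csv", comment="#")
    vectors, dropped = assemble_feature_vectors(manifest, pigment, features)
    nests = {n.nest_id: n for n in read_nest_csv(cfg.dataset_dir / "nests.csv")}
    vectors["year"] = [nests[c].year for c in vectors.clutch_id.astype(str)]
    matches = pd.read_csv(cfg.output_dir / "matches.csv", comment="#")
    clutch_of = dict(zip(manifest.egg_id, manifest.clutch_id.astype(str)))
    rate = _match_rate_from_table(matches, clutch_of)

    D = build_dissimilarity_matrix(vectors)
    out: dict = {"n_eggs": int(len(vectors)), "excluded_missing_data": dropped,
                 "within_clutch_match_rate": rate}
    for label in ("clutch_id", "year"):
        groups = vectors[label].astype(str)
        if groups.nunique() < 2:
            continue
        res = permanova(D, groups, n_perm=cfg.n_perm, seed=cfg.seed,
                        grouping_label=label)
        out[f"permanova_{label}"] = {
            "pseudo_F": res.pseudo_F, "R_squared": res.R_squared,
            "p_value": res.p_value, "n_permutations": res.n_permutations}
    ord_res = nmds(D, seed=cfg.seed)
    out["nmds_stress"] = ord_res.stress
    out["nmds_converged"] = ord_res.converged
    sizes = vectors.groupby("clutch_id").size()
    keep = vectors.clutch_id.isin(sizes[sizes >= 2].index)
    lda = lda_classify(vectors[keep], vectors.loc[keep, "clutch_id"].astype(str))
    out["lda_percent_correct_resubstitution"] = lda.mean_correct_resub
    out["lda_percent_correct_loo"] = lda.mean_correct_loo
    (cfg.output_dir / "stats.json").write_text(json.dumps(out, indent=2, default=str))
    return out


def _match_rate_from_table(matches: pd.DataFrame, clutch_of: dict) -> float:
    best = matches[matches["rank"] == 1]
    if best.empty:
        return float("nan")
    hits = [clutch_of[str(e)] == clutch_of[str(m)]
            for e, m in zip(best.egg_id, best.matched_egg_id)]
    return float(np.mean(hits))


def run_infer(cfg: RunConfig) -> pd.DataFrame:
    """Evidence assembly, tier screening and link classification per batch."""
    manifest = pd.read_csv(cfg.dataset_dir / "manifest.csv", comment="#")
    matches = pd.read_csv(cfg.output_dir / "matches.csv", comment="#")
    nests = {n.nest_id: n for n in read_nest_csv(cfg.dataset_dir / "nests.csv")}
    clutch_of = dict(zip(manifest.egg_id.astype(str), manifest.clutch_id.astype(str)))
    results = []
    evid_rows = []
    for label, sub in matches.groupby("batch_label"):
        graph = _graph_from_table(sub, label)
        evidence = compute_pair_evidence(graph, clutch_of, nests, k=cfg.tier_params.k)
        evid_rows.extend(dataclasses.asdict(ev) for ev in evidence)
        for res in tier_screen(evidence, cfg.tier_params):
            results.append(classify_link(res, cfg.tier_params))
    _write_csv(pd.DataFrame(evid_rows), cfg.output_dir / "evidence.csv", cfg)
    rep = report(results)
    _write_csv(rep, cfg.output_dir / "report.csv", cfg)
    return rep


def _graph_from_table(matches: pd.DataFrame, label: str):
    """Rebuild a MatchGraph from the matches CSV (ranked lists per egg)."""
    from .features import MatchGraph

    ranked: dict[str, list[tuple[str, float]]] = {}
    for egg, sub in matches.groupby("egg_id"):
        sub = sub.sort_values("rank")
        ranked[str(egg)] = [(str(m), float(d))
                            for m, d in zip(sub.matched_egg_id, sub.dissimilarity)]
    ids = sorted(ranked)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for egg, lst in ranked.items():
        for other, d in lst:
            mat.loc[egg, other] = d
    return MatchGraph(batch_label=label, egg_ids=ids, dissimilarity=mat,
                      ranked=ranked)


def run_all(cfg: RunConfig) -> pd.DataFrame:
    """Run every stage in order, reusing existing stage outputs."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    if not (cfg.output_dir / "features.csv").exists():
        run_features(cfg)
    if not (cfg.output_dir / "pigment.csv").exists():
        run_pigment(cfg)
    if not (cfg.output_dir / "stats.json").exists():
        run_stats(cfg)
    return run_infer(cfg)
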