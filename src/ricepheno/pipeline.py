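"""End-to-end orchestration: simulate -> segment -> extract -> analyze.

A :class:`RunConfig` fully determines a run; every stochastic stage
consumes an explicit seed derived from it, so re-running a persisted
config reproduces the output CSVs byte for byte. Every CSV written by
the pipeline starts with a ``# config_hash=...`` provenance comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, registry, stats, temporal
from .organ_traits import (
    compute_culm_traits,
    compute_panicle_traits,
    compute_plant_traits,
    load_grain_traits,
)
from .render import render_culm_image, render_plant_image
from .segmentation import PlantImage, SegmentationConfig, segment_panicle, segment_plant
from .synthetic import (
    DEFAULT_DAYS,
    CohortSpec,
    _sample_grain_row,
    culm_organ_traits,
    sample_ground_truth,
)
from .temporal import TraitTimeSeries

log = logging.getLogger("ricepheno")


@dataclass
class RunConfig:
    """Serializable settings for one pipeline run."""

    out_dir: str = "ricepheno_run"
    seed: int = 0
    n_plants: int = 6
    days: tuple[int, ...] = DEFAULT_DAYS
    scale_mm_per_px: float = 2.0
    canvas: tuple[int, int] = (720, 460)
    heading_threshold_mm2: float = temporal.HEADING_THRESHOLD_MM2
    families: tuple[str, ...] = models.FAMILIES
    cv_k: int = 5
    entry_p: float = stats.DEFAULT_ENTRY_P
    removal_p: float = stats.DEFAULT_REMOVAL_P
    n_perm: int = 999
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    force: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            seg = d["segmentation"]
            for k in ("green_hue_deg", "yellow_hue_deg"):
                if k in seg:
                    seg[k] = tuple(seg[k])
            d["segmentation"] = SegmentationConfig(**seg)
        for k in ("days", "families", "canvas"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash}\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def _cohort_ground_truths(cfg: RunConfig):
    """Plants with group labels and latitudes, deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    spec = CohortSpec(n_plants=cfg.n_plants, seed=cfg.seed)
    labels = list(spec.groups)
    fracs = np.array([spec.groups[g].get("fraction", 1.0) for g in labels])
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * cfg.n_plants).astype(int)
    while counts.sum() < cfg.n_plants:
        counts[int(np.argmax(fracs * cfg.n_plants - counts))] += 1
    out = []
    i = 0
    for g, n_g in zip(labels, counts):
        lat_mu, lat_sd = spec.groups[g].get("latitude", (30.0, 8.0))
        for _ in range(n_g):
            gt = sample_ground_truth(rng, f"P{i:03d}")
            out.append((gt, g, float(rng.normal(lat_mu, lat_sd)), _sample_grain_row(rng)))
            i += 1
    return out


def run_simulate(cfg: RunConfig) -> Path:
    """Emit a synthetic dataset: images, manifest, grain and metadata CSVs."""
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not cfg.force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True/--force to overwrite")
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    rows = []
    gts = []
    grain_rows = {}
    meta_rows = []
    for gt, group, lat, grain in _cohort_ground_truths(cfg):
        gts.append(gt)
        grain_rows[gt.plant_id] = grain
        meta_rows.append({"plant_id": gt.plant_id, "group": group, "latitude": lat})
        for day in cfg.days:
            if day > gt.harvest_day:
                continue
            import zlib

            img_seed = (cfg.seed + zlib.crc32(f"{gt.plant_id}:{day}".encode())) % 2**31
            img, _truth = render_plant_image(
                gt, canvas=cfg.canvas, scale=cfg.scale_mm_per_px, seed=img_seed, day=day,
            )
            rel = f"images/{gt.plant_id}_d{day:03d}_plant.png"
            Image.fromarray(img.rgb).save(out / rel)
            rows.append({"path": rel, "plant_id": gt.plant_id, "day": day,
                         "organ_view": "plant", "mm_per_px": cfg.scale_mm_per_px})
        cimg, _ = render_culm_image(gt, canvas=cfg.canvas, scale=cfg.scale_mm_per_px, seed=cfg.seed + 7)
        rel = f"images/{gt.plant_id}_culm.png"
        Image.fromarray(cimg.rgb).save(out / rel)
        rows.append({"path": rel, "plant_id": gt.plant_id, "day": gt.harvest_day,
                     "organ_view": "culm", "mm_per_px": cfg.scale_mm_per_px})

    _write_csv(pd.DataFrame.from_records(rows), manifest_path, cfg, index=False)
    grain_df = pd.DataFrame.from_dict(grain_rows, orient="index")
    grain_df.index.name = "plant_id"
    _write_csv(grain_df, out / "grain.csv", cfg)
    _write_csv(pd.DataFrame.from_records(meta_rows).set_index("plant_id"), out / "metadata.csv", cfg)
    # planted ground truth for recovery checks
    gt_rows = []
    for gt in gts:
        gt_rows.append({
            "plant_id": gt.plant_id,
            "tpa_a": gt.tpa_coeffs[0], "tpa_b": gt.tpa_coeffs[1], "tpa_c": gt.tpa_coeffs[2],
            "ypar_a": gt.ypar_coeffs[0], "ypar_b": gt.ypar_coeffs[1], "ypar_c": gt.ypar_coeffs[2],
            "heading_day": gt.heading_day, "harvest_day": gt.harvest_day,
            "height_max_mm": gt.height_max_mm, "height_peak_day": gt.height_peak_day,
            "culm_height_mm": gt.culm_height_mm, "culm_tpa_mm2": gt.culm_tpa_mm2,
            "culm_ypar": gt.culm_ypar,
        })
    _write_csv(pd.DataFrame.from_records(gt_rows).set_index("plant_id"), out / "ground_truth.csv", cfg)
    cfg.to_json(out / "config.json")
    log.info("simulated %d plants -> %s", cfg.n_plants, out)
    return out


def run_extract(cfg: RunConfig) -> Path:
    """Segment every manifest image and derive the 58-trait table."""
    out = Path(cfg.out_dir)
    manifest = _read_csv(out / "manifest.csv")
    from PIL import Image

    per_plant: dict[str, dict[int, object]] = {}
    culm_segs: dict[str, object] = {}
    scales: dict[str, float] = {}
    ts_rows = []
    qc: list[dict] = []
    for rec in manifest.to_dict("records"):
        path = out / rec["path"]
        try:
            rgb = np.asarray(Image.open(path).convert("RGB"))
        except Exception as e:  # unreadable image: skip the row, keep the run
            log.warning("skipping unreadable image %s: %s", path, e)
            qc.append({"plant_id": rec["plant_id"], "day": rec["day"], "issue": f"unreadable: {e}"})
            continue
        img = PlantImage(rgb, plant_id=str(rec["plant_id"]), day=int(rec["day"]),
                         organ_view=rec["organ_view"], mm_per_px=float(rec["mm_per_px"]))
        seg = segment_plant(img, cfg.segmentation)
        if not seg.plant_mask.any():
            qc.append({"plant_id": img.plant_id, "day": img.day, "issue": "empty segmentation"})
            continue
        if img.organ_view == "culm":
            culm_segs[img.plant_id] = seg
            scales[img.plant_id] = img.mm_per_px
            continue
        seg.panicle_mask = segment_panicle(img, seg, cfg.segmentation)
        t = compute_plant_traits(seg, img.mm_per_px, img.plant_id, img.day)
        t = compute_panicle_traits(seg, img.mm_per_px, t)
        per_plant.setdefault(img.plant_id, {})[img.day] = t
        scales[img.plant_id] = img.mm_per_px
        ts_rows.append({"plant_id": img.plant_id, "day": img.day, **{
            k: getattr(t, k) for k in ("PlantH", "PlantTPA", "PlantHWr", "PlantTPAHr",
                                        "PlantYpar", "PlantYPA", "PlantGPA", "PanicleTPA",
                                        "PanicleTpar", "PanicleYpar", "PanicleYPA")}})

    plant_rows = {}
    harvest = max(cfg.days)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, obs in per_plant.items():
            series = TraitTimeSeries(pid, dict(sorted(obs.items())), harvest_day=harvest)
            culm = None
            if pid in culm_segs:
                plant_h = max(o.PlantH for o in obs.values())
                culm = compute_culm_traits(culm_segs[pid], scales[pid], plant_h, pid)
            plant_rows[pid] = temporal.derive_plant_row(series, culm, cfg.heading_threshold_mm2)
            if np.isnan(plant_rows[pid]["HS"]):
                qc.append({"plant_id": pid, "day": -1, "issue": "no heading detected"})

    grain_path = out / "grain.csv"
    grain = load_grain_traits(grain_path) if grain_path.exists() else None
    table = temporal.assemble_itrait_table(plant_rows, grain)
    _write_csv(table, out / "itraits.csv", cfg)
    _write_csv(pd.DataFrame.from_records(ts_rows), out / "organ_timeseries.csv", cfg, index=False)
    _write_csv(pd.DataFrame.from_records(qc or [{"plant_id": "", "day": -1, "issue": "none"}]),
               out / "qc_report.csv", cfg, index=False)
    log.info("extracted %d plants x %d traits -> %s", len(table), table.shape[1], out / "itraits.csv")
    return out / "itraits.csv"


def run_analyze(cfg: RunConfig, table: pd.DataFrame | None = None) -> Path:
    """Growth-model comparison plus the full statistical report bundle."""
    out = Path(cfg.out_dir)
    if table is None:
        path = out / "itraits.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found; run extract first")
        table = _read_csv(path, index_col="plant_id")
    missing = [c for c in registry.trait_names() if c not in table.columns]
    if missing:
        raise ValueError(f"trait table schema mismatch; missing columns: {missing}")

    # growth-trend model comparison on the cohort-mean trajectories
    ts_path = out / "organ_timeseries.csv"
    if ts_path.exists():
        ts = _read_csv(ts_path)
        recs = []
        trends = [("plant_growth", "PlantTPA", False), ("plant_senescence", "PlantYpar", False),
                  ("panicle_growth", "PanicleTPA", True), ("panicle_maturation", "PanicleYpar", True)]
        for name, col, post_only in trends:
            sub = ts[ts[col] > 0] if post_only else ts
            mean_traj = sub.groupby("day")[col].mean()
            if len(mean_traj) < 6:
                continue
            x, y = mean_traj.index.to_numpy(float), mean_traj.to_numpy(float)
            if np.std(y) <= 1e-9 * max(abs(float(np.mean(y))), 1.0):
                continue  # degenerate (constant) trend; nothing to model
            ranked = models.compare_models(x, y, cfg.families, seed=cfg.seed,
                                           cv_k=cfg.cv_k if len(x) >= cfg.cv_k else None)
            for rank, r in enumerate(ranked, start=1):
                recs.append({"trend": name, "rank": rank, "family": r.family, "success": r.success,
                             "r2": r.r2, "mape": r.mape, "rmse": r.rmse, "mae": r.mae,
                             "cv_r2_mean": r.cv.mean["r2"] if r.cv else np.nan,
                             "cv_rmse_mean": r.cv.mean["rmse"] if r.cv else np.nan,
                             "params": ";".join(f"{p:.6g}" for p in r.params)})
        _write_csv(pd.DataFrame.from_records(recs), out / "model_comparison.csv", cfg, index=False)

    y = table["W"]
    ok = y.notna()
    results_ok = ok.sum() >= 3 and y[ok].nunique() > 1
    if results_ok:
        group_r2 = stats.variance_explained_by_group(table[ok], y[ok], entry_p=cfg.entry_p, removal_p=cfg.removal_p)
        _write_csv(group_r2, out / "yield_group_r2.csv", cfg)
        pooled_cols = [c for g in registry.YIELD_PREDICTOR_GROUPS for c in registry.traits_in_group(g)]
        sub = table.loc[ok, pooled_cols].dropna()
        sw = stats.stepwise_regression(sub, y.loc[sub.index], cfg.entry_p, cfg.removal_p)
        _write_csv(pd.DataFrame(sw.trace, columns=["step", "trait", "p"]), out / "stepwise_trace.csv", cfg, index=False)
        _write_csv(pd.Series(sw.coefficients, name="coefficient").to_frame(), out / "stepwise_coefficients.csv", cfg)
        mantel = stats.mantel_by_group(table, n_perm=cfg.n_perm, seed=cfg.seed)
        _write_csv(mantel, out / "mantel.csv", cfg)

    # group comparisons when metadata is available
    meta_path = out / "metadata.csv"
    if meta_path.exists():
        meta = _read_csv(meta_path, index_col="plant_id")
        groups = meta["group"].reindex(table.index)
        kw_recs, pw_frames = [], []
        for trait in registry.trait_names():
            v = table[trait]
            okv = v.notna() & groups.notna()
            sub_g = groups[okv]
            if sub_g.nunique() < 2 or sub_g.value_counts().min() < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H, p = stats.kruskal_wallis(v[okv].to_numpy(), sub_g.to_numpy())
                kw_recs.append({"trait": trait, "H": H, "p": p})
                pw = stats.pairwise_wilcoxon(v[okv].to_numpy(), sub_g.to_numpy())
            if len(pw):
                pw.insert(0, "trait", trait)
                pw_frames.append(pw)
        _write_csv(pd.DataFrame.from_records(kw_recs), out / "kruskal_wallis.csv", cfg, index=False)
        pw_all = pd.concat(pw_frames, ignore_index=True) if pw_frames else pd.DataFrame(
            columns=["trait", "group1", "group2", "n1", "n2", "statistic", "p", "p_adjusted"])
        _write_csv(pw_all, out / "pairwise_wilcoxon.csv", cfg, index=False)

    # PCA in the two dimensions (complete cases)
    for tag, fname in (("Organ_PC", "pca_organ"), ("Time_PC", "pca_time")):
        cols = registry.ORGAN_PC_TRAITS if tag == "Organ_PC" else registry.TIME_PC_TRAITS
        sub = table[list(cols)].dropna()
        sd = sub.std(ddof=1)
        usable = [c for c in sub.columns if sd[c] > 0]
        if len(sub) < 3 or len(usable) < 2:
            continue
        res = stats.pca_traits(sub, tag, columns=usable)
        _write_csv(res.loadings, out / f"{fname}_loadings.csv", cfg)
        _write_csv(res.scores, out / f"{fname}_scores.csv", cfg)
        _write_csv(pd.DataFrame({"component": res.loadings.columns,
                                 "variance_fraction": res.variance_fraction}),
                   out / f"{fname}_variance.csv", cfg, index=False)

    import ricepheno

    summary = [
        f"ricepheno {getattr(ricepheno, '__version__', 'dev')}",
        f"config_hash: {cfg.config_hash}",
        f"seed: {cfg.seed}",
        f"n_plants: {len(table)}",
        f"entry_p/removal_p: {cfg.entry_p}/{cfg.removal_p}",
        f"mantel permutations: {cfg.n_perm}",
        f"families: {','.join(cfg.families)}",
    ]
    (out / "run_summary.txt").write_text("\n".join(summary) + "\n")
    return out
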