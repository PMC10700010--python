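"""End-to-end orchestration: images -> CNN -> saliency -> regions -> counts -> DE.

One call runs the full loop on synthetic data: render two training image
sets (one per camera profile) and a test cohort shot by both cameras, train
models A and B, predict the cohort with both, combine confidences and pick
extreme-confidence fruits, explain the predictions with guided Grad-CAM,
reduce relevance to contour-distance geometry and sampling windows, draw an
NB count matrix whose group structure is conditioned on the selected
fruits, and run both differential-expression criteria.

Every stage writes plain-text artifacts into the run directory and is
recorded in a JSON manifest with content hashes; a rerun with the same
config and seed reproduces the deterministic artifacts bit-exactly.  The
single run seed is fanned out to one child seed per stage through
``numpy.random.SeedSequence(seed).generate_state``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import diffexp as dx
from . import ensemble as ens
from . import geometry as geo
from . import relevance as rel
from .images import DEFAULT_PLACEMENT, SceneConfig, generate_dataset, save_dataset
from .simcounts import CountSimConfig, simulate_counts

__all__ = ["PipelineConfig", "run_pipeline", "report", "STAGES"]

STAGES = ("simulate_images", "train", "ensemble", "explain", "regions",
          "simulate_counts", "diffexp")

PLACEMENTS = {
    "apex": ((1.0, 0.75, 1.0),),
    "periphery": ((1.0, 0.0, 0.1),),
    "mixed": DEFAULT_PLACEMENT,
}


@dataclass
class PipelineConfig:
    """Desk-scale defaults: a complete run in a few minutes on one CPU."""

    image_side: int = 96
    blemish_amplitude: float = 0.25  # separable regime; see docs/methods.md
    blemish_placement: str = "apex"  # apex | periphery | mixed
    n_train_pos: int = 60
    n_train_neg: int = 60
    n_test_pos: int = 25
    n_test_neg: int = 25
    block_widths: tuple[int, ...] = (8, 16, 32)
    epochs: int = 40
    batch_size: int = 16
    min_positive_precision: float = 0.8
    k_pos: int = 10
    k_neg: int = 10
    window_frac: float = 0.14  # window side as a fraction of image side
    n_r: int = 20
    n_d: int = 20
    n_genes: int = 2000
    n_paired: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "block_widths" in raw:
            raw["block_widths"] = tuple(raw["block_widths"])
        return cls(**raw)

    def scene(self) -> SceneConfig:
        return SceneConfig(image_side=self.image_side,
                           blemish_amplitude=self.blemish_amplitude,
                           blemish_placement=PLACEMENTS[self.blemish_placement])


def _stage_seeds(seed: int, n: int = len(STAGES)) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]  # keep below 2**31


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, out_dir, seed: int = 0) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_yaml(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _stage_seeds(seed)))
    manifest = {"seed": seed, "config": dataclasses.asdict(cfg), "stages": []}
    state: dict = {}

    for name in STAGES:
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        try:
            _RUNNERS[name](cfg, stage_dir, seeds[name], state)
        except Exception as exc:
            _finish_manifest(manifest, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({
            "name": name,
            "seed": seeds[name],
            "artifacts": {str(p.relative_to(out)): _sha256(p)
                          for p in sorted(stage_dir.rglob("*")) if p.is_file()},
        })
    _finish_manifest(manifest, out)
    return manifest


def _finish_manifest(manifest, out: Path):
    _write_json(manifest, out / "manifest.json")


# ---------------------------------------------------------------------------
# stage runners (each: (cfg, stage_dir, seed, shared state) -> None)


def _stage_images(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    scene = cfg.scene()
    sub = _stage_seeds(seed, 3)
    st["train_A"] = generate_dataset(scene, cfg.n_train_pos, cfg.n_train_neg, "A", sub[0])
    st["train_B"] = generate_dataset(scene, cfg.n_train_pos, cfg.n_train_neg, "B", sub[1])
    # the test cohort is photographed by both cameras: same fruits, same seed
    st["test_A"] = generate_dataset(scene, cfg.n_test_pos, cfg.n_test_neg, "A", sub[2])
    st["test_B"] = generate_dataset(scene, cfg.n_test_pos, cfg.n_test_neg, "B", sub[2])
    for key in ("train_A", "train_B", "test_A", "test_B"):
        save_dataset(st[key], d / key)


def _stage_train(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    spec = clf.ModelSpec(input_side=cfg.image_side, block_widths=cfg.block_widths)
    sub = _stage_seeds(seed, 4)
    st["models"] = {}
    for i, mid in enumerate(("A", "B")):
        tr, va = clf.split_train_val(st[f"train_{mid}"], seed=sub[2 * i])
        tcfg = clf.TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               seed=sub[2 * i + 1])
        model, curves = clf.train_classifier(tr, va, spec, tcfg)
        st["models"][mid] = model
        curves.to_csv(d / f"curves_{mid}.csv", index=False)
        clf.save_model(model, d / f"model_{mid}.npz")
        val_records = clf.predict(model, va, model_id=mid)
        metrics = clf.evaluate(val_records)
        _write_json(metrics, d / f"val_metrics_{mid}.json")


def _stage_ensemble(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    rec_a = clf.predict(st["models"]["A"], st["test_A"], model_id="A")
    rec_b = clf.predict(st["models"]["B"], st["test_B"], model_id="B")
    st["records_A"], st["records_B"] = rec_a, rec_b
    rec_a.to_csv(d / "predictions_A.tsv", sep="\t", index=False)
    rec_b.to_csv(d / "predictions_B.tsv", sep="\t", index=False)
    r = ens.confidence_correlation(rec_a, rec_b)
    search = ens.threshold_search(rec_a, rec_b, cfg.min_positive_precision)
    n = len(rec_a)
    k_pos = min(cfg.k_pos, n - cfg.k_neg)
    k_neg = min(cfg.k_neg, n - k_pos)
    pos_ids, neg_ids = ens.select_extreme_samples(rec_a, rec_b, k_pos, k_neg)
    st["pos_ids"], st["neg_ids"] = pos_ids, neg_ids
    _write_json({"confidence_correlation": r, "threshold_search": search,
                 "selected_positive": pos_ids, "selected_negative": neg_ids,
                 "test_metrics_A": clf.evaluate(rec_a),
                 "test_metrics_B": clf.evaluate(rec_b)},
                d / "ensemble.json")


def _stage_explain(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    """Guided Grad-CAM at the shallow conv layer, target class positive, for
    every test fruit under camera A / model A."""
    model = st["models"]["A"]
    maps = {}
    for im in st["test_A"]:
        m = rel.guided_grad_cam(model, im.pixels, clf.POSITIVE, "conv_shallow")
        maps[im.fruit_id] = m.values.astype(np.float32)
    st["maps"] = maps
    predicted_pos = set(st["records_A"].loc[st["records_A"]["predicted_label"] == 1,
                                            "fruit_id"])
    st["xai_cohort"] = sorted(predicted_pos)
    np.savez(d / "guided_gradcam_maps.npz", **maps)
    _write_json({"method": "guided_grad_cam", "layer": "conv_shallow",
                 "target_class": "positive", "n_maps": len(maps),
                 "xai_cohort": st["xai_cohort"]}, d / "explain.json")


def _stage_regions(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    by_id = {im.fruit_id: im for im in st["test_A"]}
    window = max(4, int(round(cfg.window_frac * cfg.image_side)))
    masks, dmaps = {}, {}
    for fid, im in by_id.items():
        fm = geo.segment_fruit(im.pixels)
        masks[fid] = fm
        dmaps[fid] = geo.normalized_contour_distance(fm)

    cohort = st["xai_cohort"]
    hist = geo.relevance_histogram([st["maps"][f] for f in cohort],
                                   [dmaps[f] for f in cohort],
                                   [masks[f] for f in cohort],
                                   n_r=cfg.n_r, n_d=cfg.n_d)
    bands = geo.band_relevance_summary(hist) if cohort else None

    regions = []
    for fid in st["pos_ids"]:
        fm, dm, mp = masks[fid], dmaps[fid], st["maps"][fid]
        feat = geo.extract_featured_region(mp, fm, window, dmap=dm,
                                           category="RS-F", fruit_id=fid)
        regions.append(feat)
        try:
            regions.append(geo.extract_nonfeatured_region(
                mp, fm, window, feat, dmap=dm, fruit_id=fid))
        except ValueError:
            pass  # small fruit: no admissible non-featured window
    for fid in st["neg_ids"]:
        regions.append(geo.extract_featured_region(
            st["maps"][fid], masks[fid], window, dmap=dmaps[fid],
            category="C-F", fruit_id=fid))
    st["regions"] = regions
    st["hist"], st["bands"] = hist, bands

    pd.DataFrame([dataclasses.asdict(r) for r in regions]).to_csv(
        d / "regions.tsv", sep="\t", index=False)
    hdf = pd.DataFrame(hist.counts,
                       index=[f"r[{a:.3f},{b:.3f})" for a, b in
                              zip(hist.r_edges[:-1], hist.r_edges[1:])],
                       columns=[f"d[{a:.3f},{b:.3f})" for a, b in
                                zip(hist.d_edges[:-1], hist.d_edges[1:])])
    hdf.to_csv(d / "relevance_histogram.tsv", sep="\t")
    _write_json({"n_pixels": hist.n_pixels, "band_high_relevance_mass": bands,
                 "window_side": window, "xai_cohort_size": len(cohort)},
                d / "geometry.json")


def _stage_counts(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    n_rs = len(st["pos_ids"])
    n_c = len(st["neg_ids"])
    sim_cfg = CountSimConfig(n_genes=cfg.n_genes, n_fruits_rs=n_rs,
                             n_paired=min(cfg.n_paired, n_rs),
                             n_fruits_c=n_c, seed=seed)
    cm, truth = simulate_counts(sim_cfg)
    st["counts"], st["truth"] = cm, truth
    cm.counts.to_csv(d / "counts.tsv", sep="\t")
    cm.gene_lengths.to_csv(d / "gene_lengths.tsv", sep="\t")
    cm.sample_meta.to_csv(d / "sample_meta.tsv", sep="\t", index=False)
    # simulated RS fruits map one-to-one onto the selected image fruits
    mapping = pd.DataFrame({
        "sim_fruit": [f"RS{i:02d}" for i in range(n_rs)] + [f"C{i:02d}" for i in range(n_c)],
        "image_fruit": st["pos_ids"] + st["neg_ids"],
    })
    mapping.to_csv(d / "fruit_mapping.tsv", sep="\t", index=False)
    _write_json(dataclasses.asdict(truth), d / "sim_truth.json")


def _stage_diffexp(cfg: PipelineConfig, d: Path, seed: int, st: dict):
    cm = st["counts"]
    groups = cm.sample_meta.set_index("sample_id")["group"].loc[cm.counts.columns]
    libs = cm.counts.sum(axis=0)
    rp = dx.rpkm(cm.counts, cm.gene_lengths, libs)

    keep_i = dx.filter_expressed(rp, groups, compare=("RS-F", "C-F"))
    tab_i = dx.de_unpaired(cm.counts.loc[keep_i], groups)
    keep_ii = dx.filter_expressed(rp, groups, compare=("RS-F", "RS-NF"))
    tab_ii = dx.de_paired(cm.counts.loc[keep_ii], cm.sample_meta)
    up, down, r = dx.overlap_and_concordance(tab_i, tab_ii)
    var_frac, scores, pc_tests = dx.pca_expression(rp, groups)

    truth = st["truth"]
    gene_sets = {"planted_i_up": truth.degs_i_up, "planted_i_down": truth.degs_i_down,
                 "planted_ii_up": truth.degs_ii_up, "planted_ii_down": truth.degs_ii_down}
    rng = np.random.default_rng(seed)
    for k in range(4):
        gene_sets[f"random_{k}"] = sorted(
            rng.choice(cm.counts.index, size=len(truth.degs_i_up) or 10, replace=False))
    deg_up_i = list(tab_i.index[(tab_i["pvalue"] < 0.05) & (tab_i["direction"] == "up")])
    enr = dx.enrichment_hypergeometric(deg_up_i, gene_sets, cm.counts.index)

    tab_i.to_csv(d / "deg_criteria_i.tsv", sep="\t")
    tab_ii.to_csv(d / "deg_criteria_ii.tsv", sep="\t")
    scores.to_csv(d / "pca_scores.tsv", sep="\t")
    pc_tests.to_csv(d / "pca_group_tests.tsv", sep="\t", index=False)
    enr.to_csv(d / "enrichment.tsv", sep="\t", index=False)
    st["de_summary"] = {
        "n_deg_i_up": int(((tab_i["pvalue"] < 0.05) & (tab_i["direction"] == "up")).sum()),
        "n_deg_i_down": int(((tab_i["pvalue"] < 0.05) & (tab_i["direction"] == "down")).sum()),
        "n_deg_ii_up": int(((tab_ii["fdr"] < 0.1) & (tab_ii["direction"] == "up")).sum()),
        "n_deg_ii_down": int(((tab_ii["fdr"] < 0.1) & (tab_ii["direction"] == "down")).sum()),
        "common_up": up, "common_down": down, "lfc_correlation": r,
        "pc1_variance_fraction": float(var_frac[0]),
        "pc2_variance_fraction": float(var_frac[1]),
    }
    _write_json(st["de_summary"], d / "de_summary.json")


_RUNNERS = {
    "simulate_images": _stage_images,
    "train": _stage_train,
    "ensemble": _stage_ensemble,
    "explain": _stage_explain,
    "regions": _stage_regions,
    "simulate_counts": _stage_counts,
    "diffexp": _stage_diffexp,
}


# ---------------------------------------------------------------------------
# report


def report(run_dir) -> Path:
    """Render a markdown summary (plus PNG figures) from a completed run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    manifest = json.loads((run / "manifest.json").read_text())
    done = {s["name"] for s in manifest["stages"]}
    missing = [s for s in STAGES if s not in done]
    if missing:
        raise ValueError(f"run incomplete; missing stages: {missing}")
    fig_dir = run / "report"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# softspot run report", ""]
    savefig = dict(dpi=100, metadata={"Software": "softspot"})

    ensj = json.loads((run / "ensemble" / "ensemble.json").read_text())
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, mid in zip(axes, ("A", "B")):
        roc = ensj[f"test_metrics_{mid}"]["roc"]
        ax.plot(roc["fpr"], roc["tpr"])
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_title(f"model {mid} (AUC={ensj[f'test_metrics_{mid}']['auc']:.3f})")
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
    fig.tight_layout()
    fig.savefig(fig_dir / "roc.png", **savefig)
    plt.close(fig)

    pa = pd.read_csv(run / "ensemble" / "predictions_A.tsv", sep="\t")
    pb = pd.read_csv(run / "ensemble" / "predictions_B.tsv", sep="\t")
    m = pa.merge(pb, on="fruit_id", suffixes=("_a", "_b"))
    fig, ax = plt.subplots(figsize=(4, 4))
    for lab, sub in m.groupby("true_label_a"):
        ax.scatter(sub["confidence_positive_a"], sub["confidence_positive_b"],
                   label=f"true={int(lab)}", s=18)
    ax.set_xlabel("confidence A")
    ax.set_ylabel("confidence B")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "confidence_scatter.png", **savefig)
    plt.close(fig)
    lines += [f"- confidence correlation A vs B: r = "
              f"{ensj['confidence_correlation']:.3f}",
              f"- threshold search: {ensj['threshold_search']}", ""]

    geoj = json.loads((run / "regions" / "geometry.json").read_text())
    if geoj["xai_cohort_size"] == 0:
        lines.append("**warning: empty XAI cohort — no fruits predicted positive**")
    else:
        hist = pd.read_csv(run / "regions" / "relevance_histogram.tsv",
                           sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(np.log1p(hist.to_numpy()), origin="lower", aspect="auto",
                       extent=[0, 1, 0, 1], cmap="viridis")
        ax.set_xlabel("normalized contour distance d")
        ax.set_ylabel("relevance r")
        fig.colorbar(im, label="log(1+count)")
        fig.tight_layout()
        fig.savefig(fig_dir / "relevance_histogram.png", **savefig)
        plt.close(fig)
        lines += [f"- H(r,d) pooled over {geoj['xai_cohort_size']} predicted "
                  f"positives, {geoj['n_pixels']} pixels",
                  f"- high-relevance mass per d-band: "
                  f"{geoj['band_high_relevance_mass']}", ""]

    de = json.loads((run / "diffexp" / "de_summary.json").read_text())
    ti = pd.read_csv(run / "diffexp" / "deg_criteria_i.tsv", sep="\t", index_col=0)
    tii = pd.read_csv(run / "diffexp" / "deg_criteria_ii.tsv", sep="\t", index_col=0)
    shared = ti.index.intersection(tii.index)
    sig = shared[(ti.loc[shared, "pvalue"] < 0.05) | (tii.loc[shared, "fdr"] < 0.1)]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ti.loc[shared, "log2fc"], tii.loc[shared, "log2fc"],
               s=6, c="lightgrey")
    ax.scatter(ti.loc[sig, "log2fc"], tii.loc[sig, "log2fc"], s=10, c="crimson")
    ax.axhline(0, c="k", lw=0.5)
    ax.axvline(0, c="k", lw=0.5)
    ax.set_xlabel("log2FC criteria (i) RS-F vs C-F")
    ax.set_ylabel("log2FC criteria (ii) RS-F vs RS-NF")
    fig.tight_layout()
    fig.savefig(fig_dir / "overlap_scatter.png", **savefig)
    plt.close(fig)
    lines += [f"- DEGs criteria (i) P<0.05: {de['n_deg_i_up']} up / "
              f"{de['n_deg_i_down']} down",
              f"- DEGs criteria (ii) FDR<0.1: {de['n_deg_ii_up']} up / "
              f"{de['n_deg_ii_down']} down",
              f"- direction-matched common DEGs: {de['common_up']} up / "
              f"{de['common_down']} down; log2FC correlation r = "
              f"{de['lfc_correlation']:.3f}",
              f"- PC1 / PC2 variance fractions: "
              f"{de['pc1_variance_fraction']:.3f} / "
              f"{de['pc2_variance_fraction']:.3f}", ""]

    out = run / "report" / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
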