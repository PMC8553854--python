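"""End-to-end orchestration: data -> ERPs -> clustering -> TANOVA -> post-hoc.

The pipeline reproduces the full analysis chain from a single config:
subject x condition ERPs are computed and GFP-normalized, pooled into the
grand-grandmean that defines the microstate segmentation, and every
configured condition comparison is tested globally (permutation TANOVA per
microstate, alpha / n_microstates) and, where significant, localized
(channel-wise paired t-tests, alpha / n_channels). Every seed, restart
count and permutation count is recorded so any run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as mc
from . import erp as ec
from . import posthoc as ph
from . import tanova as tv
from .io import read_bundle
from .synthetic import TruthManifest, simulate_dataset


@dataclass
class PipelineConfig:
    """Everything a run needs; either a synthetic manifest or a bundle dir."""

    manifest: TruthManifest | None = None
    input_dir: str | None = None
    baseline_window_ms: tuple[float, float] | None = None
    k: int | None = None
    k_range: tuple[int, int] = (2, 20)
    use_elbow_suggestion: bool = False
    n_restarts: int = 50
    max_iter: int = 100
    n_perm: int = tv.DEFAULT_N_PERM
    alpha: float = 0.05
    comparisons: list[tuple[str, str]] | None = None  # default: all label pairs
    renormalize_grandmean: bool = False
    clustering_seed: int = 0
    tanova_seed: int = 0
    posthoc_seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        manifest = None
        if "manifest_json" in raw:
            manifest = TruthManifest.from_json(
                Path(raw.pop("manifest_json")).read_text()
            )
        if "comparisons" in raw and raw["comparisons"] is not None:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        for key in ("baseline_window_ms", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(manifest=manifest, **raw)

    def settings_hash(self) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("manifest", "out_dir")
        }
        if self.manifest is not None:
            payload["manifest"] = self.manifest.to_json()
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    config: PipelineConfig
    cluster_model: mc.ClusterModel
    segmentation: mc.Segmentation
    condition_vectors: dict[str, np.ndarray]  # label -> (n_microstates, n_ch)
    tanova_results: dict[tuple[str, str], tv.TanovaResult]
    posthoc_tables: dict[tuple[str, str], ph.PosthocTable]
    sweep: mc.SweepResult | None
    provenance: dict


def _pool_condition(epoch_sets, label: str) -> np.ndarray:
    mats = [es.data for es in epoch_sets if es.condition == label]
    if not mats:
        raise ValueError(f"no epochs found for condition {label!r}")
    return np.concatenate(mats, axis=0)


def _pool_subject_ids(epoch_sets, label: str) -> np.ndarray:
    ids = [
        np.repeat(es.subject_id, es.n_epochs)
        for es in epoch_sets
        if es.condition == label
    ]
    return np.concatenate(ids)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage; any failure aborts naming the stage."""
    stage = "load"
    try:
        if config.manifest is not None:
            epoch_sets = simulate_dataset(config.manifest)
        elif config.input_dir is not None:
            epoch_sets = read_bundle(config.input_dir)
        else:
            raise ValueError("config needs a synthetic manifest or an input_dir")
        if not epoch_sets:
            raise ValueError("no epoch sets")
        ref = epoch_sets[0]
        labels = sorted({es.condition for es in epoch_sets})

        if config.baseline_window_ms is not None:
            stage = "baseline"
            for es in epoch_sets:
                for i in range(es.n_epochs):
                    es.data[i] = ec.baseline_correct(
                        es.data[i], es.time_ms, config.baseline_window_ms
                    )

        stage = "erp"
        norm_erps = [ec.normalize_by_gfp(ec.average_epochs(es)) for es in epoch_sets]
        ggm = ec.grand_grandmean(norm_erps, renormalize=config.renormalize_grandmean)

        stage = "clustering"
        sweep = None
        k = config.k
        if k is None:
            if not config.use_elbow_suggestion:
                raise ValueError(
                    "no k configured; set k explicitly or opt in to the elbow "
                    "suggestion (use_elbow_suggestion=True)"
                )
            sweep = mc.sweep_k(
                ggm,
                range(config.k_range[0], config.k_range[1] + 1),
                config.n_restarts,
                config.max_iter,
                config.clustering_seed,
            )
            k = sweep.suggest_k_elbow()
        model = mc.kmeans_topographies(
            ggm, k, config.n_restarts, config.max_iter, config.clustering_seed
        )
        segmentation = mc.segment_microstates(model.labels, ggm.time_ms)

        stage = "condition vectors"
        pools = {lab: _pool_condition(epoch_sets, lab) for lab in labels}
        condition_vectors = {
            lab: tv.microstate_vectors(pools[lab], segmentation, ref.time_ms)
            for lab in labels
        }

        stage = "tanova"
        comparisons = config.comparisons
        if comparisons is None:
            comparisons = list(itertools.combinations(labels, 2))
        for a, b in comparisons:
            for lab in (a, b):
                if lab not in pools:
                    raise ValueError(f"comparison references unknown condition {lab!r}")
        tanova_results = {}
        for i, (a, b) in enumerate(comparisons):
            tanova_results[(a, b)] = tv.tanova_test(
                pools[a],
                pools[b],
                segmentation,
                ref.time_ms,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=config.tanova_seed + i,
                comparison=(a, b),
            )

        stage = "posthoc"
        posthoc_tables = {}
        for i, ((a, b), res) in enumerate(tanova_results.items()):
            sig = res.significant_microstates
            if not sig:
                continue
            eq_a, eq_b = ph.equalize_epochs(
                pools[a], pools[b], seed=config.posthoc_seed + i
            )
            posthoc_tables[(a, b)] = ph.channel_ttests(
                eq_a,
                eq_b,
                segmentation,
                ref.time_ms,
                sig,
                ref.montage,
                alpha=config.alpha,
                seed=config.posthoc_seed + i,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    provenance = {
        "settings_hash": config.settings_hash(),
        "seeds": {
            "clustering": config.clustering_seed,
            "tanova": config.tanova_seed,
            "posthoc": config.posthoc_seed,
        },
        "k": int(model.k),
        "n_microstates": len(segmentation),
        "n_restarts": config.n_restarts,
        "max_iter": config.max_iter,
        "n_reseeds": model.n_reseeds,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "conditions": labels,
        "comparisons": [list(c) for c in comparisons],
    }
    bundle = ResultsBundle(
        config=config,
        cluster_model=model,
        segmentation=segmentation,
        condition_vectors=condition_vectors,
        tanova_results=tanova_results,
        posthoc_tables=posthoc_tables,
        sweep=sweep,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_results(bundle, config.out_dir, montage=ref.montage)
    return bundle


def summarize(bundle: ResultsBundle) -> dict[str, pd.DataFrame]:
    """Deterministic report tables: durations, TANOVA, post-hoc."""
    seg = bundle.segmentation
    durations = pd.DataFrame(
        {
            "microstate": [m.index for m in seg.microstates],
            "start_ms": [m.start_ms for m in seg.microstates],
            "end_ms": [m.end_ms for m in seg.microstates],
            "cluster_id": [m.cluster_id for m in seg.microstates],
            "duration_ms": [m.duration_ms for m in seg.microstates],
        }
    )
    tanova_frames = []
    for (a, b), res in bundle.tanova_results.items():
        f = res.to_frame()
        f.insert(0, "comparison", f"{a} vs {b}")
        tanova_frames.append(f)
    tanova = (
        pd.concat(tanova_frames, ignore_index=True)
        if tanova_frames
        else pd.DataFrame()
    )
    posthoc_frames = []
    for (a, b), tbl in bundle.posthoc_tables.items():
        f = tbl.table.copy()
        f.insert(0, "comparison", f"{a} vs {b}")
        posthoc_frames.append(f)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame()
    )
    return {"durations": durations, "tanova": tanova, "posthoc": posthoc}


def report_text(bundle: ResultsBundle) -> str:
    """Human-readable run report."""
    tables = summarize(bundle)
    seg = bundle.segmentation
    lines = [
        f"Microstate segmentation: k = {bundle.cluster_model.k} clusters, "
        f"{len(seg)} microstates over [{seg.window[0]:g}, {seg.window[1]:g}) ms",
        "",
        tables["durations"].to_string(index=False),
        "",
    ]
    any_sig = False
    for (a, b), res in bundle.tanova_results.items():
        lines.append(
            f"TANOVA {a} vs {b}: alpha_adj = {res.alpha_adj:.4f} "
            f"({res.alpha:g}/{len(seg)}), {res.n_perm} permutations"
        )
        f = res.to_frame()
        lines.append(f.to_string(index=False))
        sig = res.significant_microstates
        if sig:
            any_sig = True
            lines.append(f"significant microstates: {sig}")
        lines.append("")
    if not any_sig:
        lines.append("No comparison reached significance at the adjusted level.")
    for (a, b), tbl in bundle.posthoc_tables.items():
        lines.append(
            f"Post-hoc {a} vs {b}: alpha_adj = {tbl.alpha_adj:.4f} "
            f"(paired t-tests, n = {tbl.n_equalized} equalized epochs)"
        )
        sig_rows = tbl.table[tbl.table["significant"]]
        if sig_rows.empty:
            lines.append(
                "no single channel survives the channel-adjusted threshold"
            )
        else:
            lines.append(sig_rows.to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def write_results(
    bundle: ResultsBundle, out_dir: str | Path, montage=None
) -> Path:
    """Write CSV/JSON outputs of a run into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = summarize(bundle)
    tables["durations"].to_csv(out / "microstates.csv", index=False)
    if not tables["tanova"].empty:
        tables["tanova"].to_csv(out / "tanova.csv", index=False)
    if not tables["posthoc"].empty:
        tables["posthoc"].to_csv(out / "posthoc.csv", index=False)
    (out / "segmentation.json").write_text(
        json.dumps(bundle.segmentation.to_json_dict(), indent=1)
    )
    if bundle.sweep is not None:
        t = bundle.sweep.table.copy()
        t["durations_ms"] = t["durations_ms"].map(json.dumps)
        t.to_csv(out / "k_sweep.csv", index=False)
    if montage is not None:
        cent = pd.DataFrame(
            bundle.cluster_model.centroids.T,
            index=list(montage),
            columns=[f"cluster_{i + 1}" for i in range(bundle.cluster_model.k)],
        )
        cent.to_csv(out / "centroids.tsv", sep="\t")
        for lab, vecs in bundle.condition_vectors.items():
            df = pd.DataFrame(
                vecs.T,
                index=list(montage),
                columns=[f"MS{i + 1}" for i in range(vecs.shape[0])],
            )
            df.to_csv(out / f"microstate_vectors_{lab}.tsv", sep="\t")
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=1))
    (out / "report.txt").write_text(report_text(bundle))
    return out
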