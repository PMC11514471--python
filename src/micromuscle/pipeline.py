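"""End-to-end orchestration from a single YAML config.

Stages: (optional) simulation, read preprocessing, hairpin quantification,
baseMean filtering, differential expression (Wald contrast and/or LRT time
course), isomiR profiling, regulation inference and the development
analyses.  Every run writes its outputs plus a manifest recording the
resolved parameters and SHA-256 checksums of each output, so a rerun with
the same config and seed is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import development, diffexp, io as mio, isomir, preprocess, quantify, regulation
from .core import ConfigurationError, CountMatrix
from .synthetic import IsomirProfile, PlantedEffect, SimulationConfig
from . import synthetic


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a YAML mapping")
    return cfg


def simulation_config_from_dict(block: dict) -> SimulationConfig:
    block = dict(block)
    effects = [
        PlantedEffect(
            scope=e["scope"],
            target_id=e["target_id"],
            log2fc=float(e["log2fc"]),
            groups_affected=tuple(e["groups_affected"]),
        )
        for e in block.pop("planted_effects", [])
    ]
    profile = block.pop("isomir_profile", None)
    if isinstance(profile, dict) and profile and isinstance(next(iter(profile.values())), dict):
        profile = {g: IsomirProfile(**p) for g, p in profile.items()}
    elif isinstance(profile, dict):
        profile = IsomirProfile(**profile)
    kwargs = dict(block, planted_effects=effects)
    if profile is not None:
        kwargs["isomir_profile"] = profile
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    return SimulationConfig(**kwargs)


def validate_inputs(hairpins, samples: pd.DataFrame | None = None) -> list[str]:
    """Cross-reference checks; returns a list of violations (empty = clean)."""
    violations = []
    seen_h = set()
    for h in hairpins:
        if h.hairpin_id in seen_h:
            violations.append(f"duplicate hairpin id {h.hairpin_id}")
        seen_h.add(h.hairpin_id)
        if not (set(h.sequence) <= set("ACGTN")):
            violations.append(f"hairpin {h.hairpin_id}: non-DNA characters")
    seen_m = set()
    for h in hairpins:
        for m in h.matures:
            if m.mature_id in seen_m:
                violations.append(f"duplicate mature id {m.mature_id}")
            seen_m.add(m.mature_id)
            if m.end > len(h.sequence) or m.start < 0:
                violations.append(
                    f"mature {m.mature_id}: coordinates outside hairpin {h.hairpin_id}"
                )
    if samples is not None:
        if "condition" not in samples.columns:
            violations.append("sample sheet missing 'condition' column")
        if not samples.index.is_unique:
            violations.append("duplicate sample ids in sample sheet")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run every enabled stage; returns the manifest dict (also written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    written: dict[str, Path] = {}

    def emit(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        written[name] = p

    # --- inputs: simulate or load --------------------------------------
    stage = "simulate"
    try:
        if "simulate" in config:
            sim_cfg = simulation_config_from_dict({"seed": seed, **config["simulate"]})
            fasta, gff3, truth = synthetic.generate_annotation(sim_cfg)
            cm_true = synthetic.simulate_counts(sim_cfg, truth)
            fastqs = synthetic.simulate_reads(sim_cfg, truth, cm_true)
            emit("hairpins.fa", fasta)
            emit("annotation.gff3", gff3)
            emit("truth.tsv", truth.to_tsv())
            for sample, text in fastqs.items():
                emit(f"reads_{sample}.fastq", text)
            hairpins = truth.hairpins
            samples_meta = cm_true.samples
            adapter = sim_cfg.adapter
            flank_n = sim_cfg.random_flank_n
        else:
            paths = config["paths"]
            hairpins = mio.read_hairpins(paths["hairpin_fasta"], paths["gff3"])
            samples_meta = pd.read_csv(paths["sample_sheet"], sep="\t", index_col=0, dtype=str)
            fastqs = {
                s: Path(paths["fastq_dir"]) / f"{s}.fastq" for s in samples_meta.index
            } if "fastq_dir" in paths else None
            adapter = config.get("adapter", synthetic.DEFAULT_ADAPTER)
            flank_n = int(config.get("flank_trim_n", 0))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    violations = validate_inputs(hairpins, samples_meta)
    emit("validation.txt", "\n".join(violations) + ("\n" if violations else "clean\n"))
    if violations:
        raise StageError("validate", ConfigurationError("; ".join(violations)))

    # --- preprocess + quantify -----------------------------------------
    stage = "quantify"
    try:
        if "counts_tsv" in config.get("paths", {}):
            cm = CountMatrix(
                pd.read_csv(config["paths"]["counts_tsv"], sep="\t", index_col=0),
                samples_meta,
            )
        else:
            quant_params = preprocess.PreprocessParams(
                adapter=adapter, mode="quant", flank_trim_n=flank_n
            )
            collapsed = {}
            stats_rows = []
            for sample in samples_meta.index:
                src = fastqs[sample]
                reads, st = preprocess.preprocess_fastq(src, quant_params)
                collapsed[sample] = reads
                stats_rows.append({"sample": sample, **dataclasses.asdict(st)})
            pd.DataFrame(stats_rows).drop(columns="extra").to_csv(
                outdir / "preprocess_stats.tsv", sep="\t", index=False
            )
            written["preprocess_stats.tsv"] = outdir / "preprocess_stats.tsv"
            cm = quantify.quantify_sample_set(collapsed, hairpins, samples_meta)
        cm.to_tsv(outdir / "counts_raw.tsv")
        written["counts_raw.tsv"] = outdir / "counts_raw.tsv"
        cm_filt, base_mean = quantify.base_mean_filter(
            cm, float(config.get("min_base_mean", 10.0))
        )
        emit("base_mean.tsv", base_mean.rename_axis("mature_id").to_csv(sep="\t"))
        cm_filt.to_tsv(outdir / "counts_filtered.tsv")
        written["counts_filtered.tsv"] = outdir / "counts_filtered.tsv"
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    results: dict[str, object] = {"counts": cm, "counts_filtered": cm_filt}

    # --- differential expression ---------------------------------------
    de = None
    if stages.get("diffexp", True) and "contrast" in config:
        stage = "diffexp"
        try:
            contrast = tuple(config["contrast"])
            de = diffexp.wald_test(cm_filt, contrast)
            emit("de_wald.tsv", de.to_csv(sep="\t"))
            results["de"] = de
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- isomiR profiling ----------------------------------------------
    if stages.get("isomir", True) and "counts_tsv" not in config.get("paths", {}):
        stage = "isomir"
        try:
            iso_params = preprocess.PreprocessParams(
                adapter=adapter, mode="isomir", flank_trim_n=flank_n
            )
            profiles = {}
            call_frames = []
            for sample in samples_meta.index:
                reads, _ = preprocess.preprocess_fastq(fastqs[sample], iso_params)
                calls = isomir.classify_sample(reads, hairpins)
                profiles[sample] = isomir.aggregate_profile(
                    calls, int(config.get("isomir_min_count", 2))
                )
                call_frames.append(
                    pd.DataFrame([dataclasses.asdict(c) for c in calls]).assign(sample=sample)
                )
            prof_tab = isomir.profile_table(profiles)
            emit("isomir_profiles.tsv", prof_tab.to_csv(sep="\t"))
            if call_frames:
                pd.concat(call_frames).to_csv(outdir / "isomir_calls.tsv", sep="\t", index=False)
                written["isomir_calls.tsv"] = outdir / "isomir_calls.tsv"
            results["isomir_profiles"] = prof_tab
            groups = samples_meta["condition"].unique()
            if len(groups) == 2:
                ga = prof_tab.loc[samples_meta.index[samples_meta["condition"] == groups[0]]]
                gb = prof_tab.loc[samples_meta.index[samples_meta["condition"] == groups[1]]]
                comp = isomir.compare_profiles(ga, gb)
                emit("isomir_comparison.tsv", comp.to_csv(sep="\t"))
                results["isomir_comparison"] = comp
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- regulation inference ------------------------------------------
    if stages.get("regulation", True) and de is not None:
        stage = "regulation"
        try:
            clusters = regulation.build_clusters(
                hairpins, int(config.get("cluster_gap_bp", 50_000))
            )
            emit(
                "clusters.tsv",
                pd.DataFrame(
                    [dataclasses.asdict(c) | {"members": ",".join(c.members)} for c in clusters]
                ).to_csv(sep="\t", index=False),
            )
            calls = regulation.classify_regulation(de, hairpins, clusters, alpha)
            emit("regulation_calls.tsv", calls.to_csv(sep="\t"))
            results["regulation_calls"] = calls
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- development ----------------------------------------------------
    if stages.get("development", False) and "timepoint" in samples_meta.columns:
        stage = "development"
        try:
            lrt = diffexp.lrt_timecourse(cm_filt)
            emit("de_lrt.tsv", lrt.to_csv(sep="\t"))
            k = int(config.get("trajectory_k", 6))
            clusters_t = development.cluster_trajectories(cm_filt, lrt, k=k, alpha=alpha)
            emit(
                "trajectory_clusters.tsv",
                development.cluster_membership(clusters_t)
                .rename_axis("mature_id")
                .to_csv(sep="\t"),
            )
            results["lrt"] = lrt
            results["trajectory_clusters"] = clusters_t
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "outputs": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
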