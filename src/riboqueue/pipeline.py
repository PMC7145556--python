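"""End-to-end pipeline: simulate -> process -> metagene -> queue -> enrich
-> readthrough, driven by one YAML config, with provenance capture.

Every output table starts with comment lines recording the package
version, a hash of the resolved configuration, the seed and the offset
table used, so any intermediate file can be regenerated from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .metagene import metagene_profile, wave_period
from .orfs import load_annotation
from .processing import (
    assign_psites,
    default_offset_table,
    load_alignments,
    load_offsets,
    normalize_rpm,
    pool_libraries,
    write_bedgraph,
)
from .queuing import (
    PeakLayout,
    QueuingConfig,
    group_by_cterm,
    score_all,
    zscore_select,
)
from .enrichment import (
    background_frequencies,
    cterm_window,
    positional_logodds,
    stop_codon_context,
    stop_identity_association,
)
from .readthrough import pooled_utr_frame_test, score_readthrough
from .simulate import SimConfig, simulate_experiment, write_dataset

log = logging.getLogger("riboqueue")

STAGE_ORDER = ["simulate", "process", "metagene", "queue", "enrich", "readthrough"]


class PipelineConfig:
    """Resolved pipeline configuration (see ``from_yaml``)."""

    def __init__(self, raw: Mapping[str, Any]):
        self.raw = dict(raw)
        self.stages: list[str] = list(raw.get("stages", STAGE_ORDER))
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        self.seed: int = int(raw.get("seed", 0))
        self.out_dir = raw.get("out_dir")
        sim = dict(raw.get("simulate", {}))
        self.design = sim.pop("design", None)
        self.n_replicates = int(sim.pop("n_replicates", 2))
        sim.pop("seed", None)
        for key in ("orf_length_range", "frame_weights", "queue_cterm_aas"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        self.sim_config = SimConfig(**sim, seed=self.seed) if "simulate" in self.stages else None
        self.inputs = dict(raw.get("inputs", {}))
        self.pooling: bool = bool(raw.get("pooling", True))
        q = dict(raw.get("queuing", {}))
        layout = PeakLayout(
            peak_windows=tuple(map(tuple, q["peak_windows"])),
            inter_windows=tuple(map(tuple, q["inter_windows"])),
        ) if "peak_windows" in q else PeakLayout()
        self.queuing = QueuingConfig(
            layout=layout,
            min_coverage_rpm=float(q.get("min_coverage_rpm", 10.0)),
            zscore_cutoff=float(q.get("zscore_cutoff", 1.0)),
            conditions=tuple(q["conditions"]) if q.get("conditions") else None,
        )
        e = dict(raw.get("enrichment", {}))
        self.enrich_n_codons = int(e.get("n_codons", 7))
        self.enrich_alpha = float(e.get("alpha", 0.05))
        self.enrich_condition = e.get("condition")
        m = dict(raw.get("metagene", {}))
        self.metagene_window = tuple(m.get("window", (-120, 60)))
        self.metagene_min_rpm = float(m.get("min_window_mean_rpm", 0.0))
        self._validate_stages()

    def _validate_stages(self) -> None:
        order = STAGE_ORDER if "simulate" in self.stages or not self.inputs else STAGE_ORDER[1:]
        wanted = [s for s in order if s in self.stages]
        if wanted != self.stages:
            raise PipelineError(f"stages must follow the order {order}")
        for i, stage in enumerate(order):
            if stage in self.stages:
                missing = [s for s in order[:i] if s not in self.stages]
                if missing:
                    raise PipelineError(
                        f"stage {stage!r} requires {missing[0]!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _condition_of(library_name: str) -> str:
    return library_name.rsplit("_rep", 1)[0] if "_rep" in library_name else library_name


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the requested stages in order; returns the result bundle."""
    bundle: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "log": [],
    }

    if "simulate" in config.stages:
        orfs, truth, libraries, logs = simulate_experiment(
            config.sim_config, design=config.design, n_replicates=config.n_replicates
        )
        bundle.update(annotation=orfs, truth=truth, libraries=libraries)
        for name, l in logs.items():
            bundle["log"].append(
                f"simulate {name}: {l['sampled_total']} reads sampled, "
                f"{l['dropped_reads']} dropped"
            )
    elif config.inputs:
        orfs = load_annotation(config.inputs["annotation"], config.inputs.get("fasta"))
        libraries = {
            name: load_alignments(path)
            for name, path in config.inputs.get("alignments", {}).items()
        }
        bundle.update(annotation=orfs, truth=None, libraries=libraries)
    else:
        raise PipelineError("stage 'process' requires 'simulate' or input paths")

    if "process" not in config.stages:
        return bundle

    offsets = (
        load_offsets(config.inputs["offsets"])
        if config.inputs.get("offsets")
        else default_offset_table()
    )
    bundle["offsets"] = offsets
    tx_lengths = {o.transcript_id: o.tx_len for o in orfs}
    tracks_by_library, stats_by_library = {}, {}
    for name, aln in libraries.items():
        tracks, stats = assign_psites(aln, offsets, tx_lengths)
        tracks_by_library[name] = tracks
        stats_by_library[name] = stats
        bundle["log"].append(
            f"process {name}: {stats.assigned_reads} assigned, "
            f"{stats.dropped_reads} dropped"
        )
    bundle["library_stats"] = stats_by_library

    tracks_by_condition: dict[str, dict] = {}
    if config.pooling:
        by_cond: dict[str, list] = {}
        for name, tracks in tracks_by_library.items():
            by_cond.setdefault(_condition_of(name), []).append(tracks)
        for cond, reps in by_cond.items():
            tracks_by_condition[cond] = pool_libraries(reps, condition=cond)
    else:
        for name, tracks in tracks_by_library.items():
            tracks_by_condition[name] = normalize_rpm(tracks)
    bundle["tracks_by_condition"] = tracks_by_condition

    if "metagene" in config.stages:
        profiles, periods = {}, {}
        for cond, tracks in tracks_by_condition.items():
            prof = metagene_profile(
                tracks, orfs, window=config.metagene_window,
                min_window_mean_rpm=config.metagene_min_rpm,
            )
            profiles[cond] = prof
            periods[cond] = wave_period(prof)
        bundle.update(metagene_profiles=profiles, wave_periods=periods)

    if "queue" in config.stages:
        scores = score_all(tracks_by_condition, orfs, config.queuing)
        bundle["scores"] = scores
        bundle["cterm_groups"] = group_by_cterm(scores)
        bundle["log"].append(
            f"queue: {scores['orf_id'].nunique()} ORFs pass the coverage filter"
        )

    if "enrich" in config.stages:
        scores = bundle["scores"]
        cond = config.enrich_condition or _pick_enrich_condition(scores)
        selected = zscore_select(scores, config.queuing.zscore_cutoff, condition=cond)
        by_id = {o.transcript_id: o for o in orfs}
        universe = [by_id[i] for i in scores["orf_id"].unique()]
        fg_orfs = [by_id[i] for i in selected["orf_id"]]
        bg = background_frequencies(universe, n_codons=config.enrich_n_codons)
        fg_windows = [
            w for o in fg_orfs
            if (w := cterm_window(o, config.enrich_n_codons)) is not None
        ]
        bundle["enrichment_condition"] = cond
        bundle["enrichment"] = positional_logodds(
            fg_windows, bg, alpha=config.enrich_alpha
        ) if fg_windows else None
        bundle["stop_context"] = (
            stop_codon_context(fg_orfs, universe, alpha=config.enrich_alpha)
            if fg_orfs else None
        )
        try:
            bundle["stop_identity"] = {
                c: stop_identity_association(scores, condition=c)
                for c in scores["condition"].unique()
            }
        except Exception as exc:
            bundle["stop_identity"] = None
            bundle["log"].append(f"enrich: stop-identity test skipped ({exc})")

    if "readthrough" in config.stages:
        rt = {}
        pooled_frames = {}
        for cond, tracks in tracks_by_condition.items():
            rt[cond] = score_readthrough(tracks, orfs)
            pooled_frames[cond] = pooled_utr_frame_test(tracks, orfs)
        bundle["readthrough"] = rt
        bundle["utr_frame_tests"] = pooled_frames

    return bundle


def _pick_enrich_condition(scores: pd.DataFrame) -> str:
    """Default foreground condition: the one with the highest mean Q."""
    means = scores.dropna(subset=["Q"]).groupby("condition")["Q"].mean()
    return str(means.idxmax())


def _provenance_header(bundle: dict[str, Any]) -> str:
    off = bundle.get("offsets")
    lines = [
        f"# riboqueue {bundle['version']}",
        f"# config_hash {bundle['config_hash']}",
        f"# seed {bundle['seed']}",
    ]
    if off is not None:
        lines.append(f"# offsets {off.provenance}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def write_reports(bundle: dict[str, Any], out_dir: str | Path) -> Path:
    """Write result tables, coverage tracks and a checksummed manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance_header(bundle)
    written: list[Path] = []

    if bundle.get("annotation") is not None and bundle.get("truth") is not None:
        paths = write_dataset(
            bundle["annotation"], bundle.get("libraries", {}), bundle["truth"], out / "dataset"
        )
        written += list(paths.values())

    for cond, tracks in bundle.get("tracks_by_condition", {}).items():
        p = out / f"coverage_{cond}.bedgraph"
        write_bedgraph(tracks, p)
        written.append(p)

    if "library_stats" in bundle:
        rows = [
            {"library": name, "total_reads": s.total_reads,
             "assigned_reads": s.assigned_reads, "dropped_reads": s.dropped_reads,
             "short_fraction": s.short_fraction, "long_fraction": s.long_fraction}
            for name, s in bundle["library_stats"].items()
        ]
        p = out / "library_stats.tsv"
        _write_tsv(pd.DataFrame(rows), p, header)
        written.append(p)

    for cond, prof in bundle.get("metagene_profiles", {}).items():
        p = out / f"metagene_{cond}.tsv"
        period = bundle.get("wave_periods", {}).get(cond)
        _write_tsv(prof.to_frame(), p, header + f"# wave_period {period}\n")
        written.append(p)

    if bundle.get("scores") is not None:
        p = out / "queuing_scores.tsv"
        _write_tsv(bundle["scores"], p, header)
        written.append(p)
        p = out / "queuing_by_cterm.tsv"
        _write_tsv(bundle["cterm_groups"].drop(columns=["q_values"]), p, header)
        written.append(p)

    for key, name in [("enrichment", "enrichment.tsv"), ("stop_context", "stop_context.tsv")]:
        mat = bundle.get(key)
        if mat is not None:
            p = out / name
            _write_tsv(mat.table, p, header + f"# threshold {mat.threshold:.4f}\n")
            written.append(p)

    for cond, df in bundle.get("readthrough", {}).items():
        p = out / f"readthrough_{cond}.tsv"
        _write_tsv(df, p, header)
        written.append(p)

    manifest = {
        "version": bundle["version"],
        "config_hash": bundle["config_hash"],
        "seed": bundle["seed"],
        "wave_periods": bundle.get("wave_periods"),
        "utr_frame_tests": bundle.get("utr_frame_tests"),
        "stop_identity": {
            k: list(v) for k, v in (bundle.get("stop_identity") or {}).items()
        } or None,
        "log": bundle["log"],
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in written
        },
    }
    if not written:
        log.warning("empty bundle: manifest lists no artifacts")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
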