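"""Stage orchestration: configuration, provenance, and the synthetic demo.

Each stage is runnable standalone from files on disk; stages communicate
only through their written outputs, so re-running a stage with identical
inputs is byte-identical.  A provenance JSON (input hashes, parameters,
seed, package version) is written next to every stage's output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    Chain,
    ChainMap,
    classify_location,
    annotate_regulatory,
    liftover,
    overlap,
)
from .dmr import DMRParams, call_dmrs, dmrs_to_frame
from .evaluate import edge_f1, score_recovery
from .io import (
    GenomicInterval,
    merge_symmetric_cpg,
    qc_report,
    read_bed,
    read_cytosine_report,
    read_genome,
    write_bed,
)
from .motifs import build_background, enrich, read_jaspar, scan, screen_enrichment
from .network import build_network, edges_to_frame, write_graphml
from .segmentation import (
    SegmentationParams,
    SegmentCall,
    segment_methylome,
    segments_to_bed,
    timepoint_specific,
)
from .synthetic import (
    SyntheticSpec,
    generate_expression,
    generate_genome,
    generate_methylomes,
    write_dataset,
)
from .targets import assign_targets, read_interactions, summarize_targets

__all__ = [
    "PipelineConfig",
    "PipelineDataError",
    "run_stage",
    "compare_transitions",
    "STAGES",
]


class PipelineDataError(RuntimeError):
    """An input file is missing or inconsistent (exit code 2 at the CLI)."""


_MOTIF_DEFAULTS = {
    "enrich_alpha_regions": 1e-10,  # screen gate for LMR/UMR motif sets
    "enrich_alpha_network": 0.01,  # gate for network motifs
    "rpkm_min": 1.0,
    "n_bg_per_fg": 4,
}
_ANNOT_DEFAULTS = {
    "promoter_halfwidth": 2000,
    "distal_min": 5000,
    "min_bp": 1,
    "liftover_min_match": 0.95,
    "liftover_shift": 1000,
    "r2_min": 0.5,
    "ld_max_distance": 500_000,
}
_NETWORK_DEFAULTS = {"deg_alpha": 0.05, "require_hit": True}


@dataclass
class PipelineConfig:
    """Flat, serialisable pipeline configuration.

    Section dicts override the corresponding parameter dataclasses
    (``simulate`` -> SyntheticSpec, ``segmentation`` -> SegmentationParams,
    ``dmr`` -> DMRParams) plus the motif/annotation/network defaults above.
    Unknown keys are rejected on construction.
    """

    seed: int = 0
    outdir: str = "methdyn_out"
    dataset_dir: str | None = None
    simulate: dict[str, Any] = field(default_factory=dict)
    segmentation: dict[str, Any] = field(default_factory=dict)
    dmr: dict[str, Any] = field(default_factory=dict)
    motifs: dict[str, Any] = field(default_factory=dict)
    annotation: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys("simulate", self.simulate, {f.name for f in dataclasses.fields(SyntheticSpec)} - {"seed"})
        _check_keys("segmentation", self.segmentation, {f.name for f in dataclasses.fields(SegmentationParams)} - {"seed"})
        _check_keys("dmr", self.dmr, {f.name for f in dataclasses.fields(DMRParams)})
        _check_keys("motifs", self.motifs, set(_MOTIF_DEFAULTS))
        _check_keys("annotation", self.annotation, set(_ANNOT_DEFAULTS))
        _check_keys("network", self.network, set(_NETWORK_DEFAULTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    # section accessors -----------------------------------------------------
    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(seed=self.seed, **self.simulate)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(seed=self.seed, **self.segmentation)

    def dmr_params(self, **extra: Any) -> DMRParams:
        return DMRParams(**{**self.dmr, **extra})

    def motif_params(self) -> dict[str, Any]:
        return {**_MOTIF_DEFAULTS, **self.motifs}

    def annotation_params(self) -> dict[str, Any]:
        return {**_ANNOT_DEFAULTS, **self.annotation}

    def network_params(self) -> dict[str, Any]:
        return {**_NETWORK_DEFAULTS, **self.network}

    @property
    def dataset(self) -> Path:
        return Path(self.dataset_dir) if self.dataset_dir else Path(self.outdir) / "dataset"


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineDataError(
            f"missing input {path}; produce it with the {producer!r} stage"
        )
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _provenance(
    stage: str, outdir: Path, inputs: list[Path], params: Mapping[str, Any], seed: int
) -> None:
    payload = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": {k: params[k] for k in sorted(params)},
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
    }
    (outdir / f"provenance_{stage}.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def _timepoints(config: PipelineConfig) -> list[str]:
    manifest = config.dataset / "manifest.json"
    if manifest.exists():
        return list(json.loads(manifest.read_text())["spec"]["timepoints"])
    return list(SyntheticSpec().timepoints)


def compare_transitions(timepoints: list[str]) -> list[tuple[str, str, str]]:
    """Transition labels over consecutive time points.

    Three time points yield the developmental (first -> second) and
    maturation (second -> third) transitions; with only two a single
    developmental bundle is emitted with a warning.
    """
    if len(timepoints) < 2:
        raise PipelineDataError("need at least two time points")
    names = ["DevTrans", "MatTrans"] + [
        f"transition{k}" for k in range(2, len(timepoints) - 1)
    ]
    if len(timepoints) < 3:
        warnings.warn("fewer than three time points; emitting available transitions only")
    return [
        (names[k], timepoints[k], timepoints[k + 1])
        for k in range(len(timepoints) - 1)
    ]


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: PipelineConfig) -> dict[str, Any]:
    spec = config.synthetic_spec()
    genome = generate_genome(spec)
    methylomes, truth, lambda_calls = generate_methylomes(spec, genome)
    expression = generate_expression(spec, truth, genome)
    out = write_dataset(
        config.dataset, spec, genome, methylomes, truth, lambda_calls, expression
    )
    _provenance("simulate", out, [], dataclasses.asdict(spec), config.seed)
    return {"dataset": str(out), "timepoints": list(spec.timepoints)}


def _read_calls(config: PipelineConfig, tp: str) -> pd.DataFrame:
    path = _require(config.dataset / f"calls_{tp}.tsv", "simulate")
    return read_cytosine_report(path)


def stage_qc(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "qc"
    outdir.mkdir(parents=True, exist_ok=True)
    genome_path = _require(config.dataset / "genome.fa", "simulate")
    genome = read_genome(genome_path)
    genome_size = sum(len(s) for s in genome.values())
    lambda_path = config.dataset / "calls_lambda.tsv"
    lambda_calls = read_cytosine_report(lambda_path) if lambda_path.exists() else None
    read_length = 100
    results = {}
    inputs = [genome_path]
    for tp in _timepoints(config):
        calls = _read_calls(config, tp)
        inputs.append(config.dataset / f"calls_{tp}.tsv")
        aligned_bases = float((calls["n_meth"] + calls["n_unmeth"]).sum()) * (
            genome_size / max(len(calls), 1)
        )
        report = qc_report(
            calls,
            genome_size,
            n_aligned_reads=int(round(aligned_bases / read_length)),
            read_length=read_length,
            lambda_calls=lambda_calls,
        )
        report.to_json(outdir / f"qc_{tp}.json")
        results[tp] = report.fold_coverage
    _provenance("qc", outdir, inputs, {"read_length": read_length}, config.seed)
    return {"fold_coverage": results}


def _segment_timepoint(config: PipelineConfig, tp: str) -> list[SegmentCall]:
    calls = merge_symmetric_cpg(_read_calls(config, tp))
    params = config.segmentation_params()
    return segment_methylome(calls, params, timepoint=tp)


def stage_segment(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "segments"
    outdir.mkdir(parents=True, exist_ok=True)
    tps = _timepoints(config)
    by_tp: dict[str, list[SegmentCall]] = {}
    inputs = []
    for tp in tps:
        segs = _segment_timepoint(config, tp)
        by_tp[tp] = segs
        inputs.append(config.dataset / f"calls_{tp}.tsv")
        write_bed(segments_to_bed(segs), outdir / f"segments_{tp}.bed")
    if len(tps) >= 2:
        specific = timepoint_specific(by_tp)
        rows = [
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "seg_type": s.seg_type,
                "specific_to": s.specific_to,
                **{f"status_{tp}": v for tp, v in sorted(s.status_at_other_timepoints.items())},
            }
            for s in specific
        ]
        pd.DataFrame(rows).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    _provenance(
        "segment", outdir, inputs, dataclasses.asdict(config.segmentation_params()), config.seed
    )
    return {tp: len(segs) for tp, segs in by_tp.items()}


def stage_dmr(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "dmr"
    outdir.mkdir(parents=True, exist_ok=True)
    tps = _timepoints(config)
    counts = {}
    inputs = []
    for tname, tp_a, tp_b in compare_transitions(tps):
        calls_a = merge_symmetric_cpg(_read_calls(config, tp_a))
        calls_b = merge_symmetric_cpg(_read_calls(config, tp_b))
        inputs += [config.dataset / f"calls_{t}.tsv" for t in (tp_a, tp_b)]
        dmrs = call_dmrs(calls_a, calls_b, config.dmr_params(), transition=tname)
        dmrs_to_frame(dmrs).to_csv(outdir / f"dmrs_{tname}.tsv", sep="\t", index=False)
        counts[tname] = len(dmrs)
    _provenance("dmr", outdir, sorted(set(inputs)), dataclasses.asdict(config.dmr_params()), config.seed)
    return counts


def _read_segments(config: PipelineConfig, tp: str, seg_type: str) -> list[GenomicInterval]:
    path = _require(
        Path(config.outdir) / "segments" / f"segments_{tp}.bed", "segment"
    )
    return [iv for iv in read_bed(path) if iv.name == seg_type]


def stage_annotate(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "annotate"
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.annotation_params()
    genome = read_genome(_require(config.dataset / "genome.fa", "simulate"))
    tracks = {
        name: read_bed(_require(config.dataset / "tracks" / f"{name}.bed", "simulate"))
        for name in ("tss", "cgi", "dhs", "ctcf", "h3k4me1", "vista")
    }
    motifs = read_jaspar(_require(config.dataset / "motifs.jaspar", "simulate"))
    ctcf = next((m for m in motifs if m.name.lower().startswith("ctcf")), None)
    summary: dict[str, Any] = {}
    for tp in _timepoints(config):
        lmrs = _read_segments(config, tp, "LMR")
        hits = [
            bool(ctcf and scan(genome[iv.chrom][iv.start : iv.end], ctcf))
            for iv in lmrs
        ]
        classes, ov = annotate_regulatory(
            lmrs, tracks["dhs"], tracks["ctcf"], tracks["h3k4me1"], hits, p["min_bp"]
        )
        pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in lmrs],
                "start": [iv.start for iv in lmrs],
                "end": [iv.end for iv in lmrs],
                "class": classes,
            }
        ).to_csv(outdir / f"regulatory_{tp}.tsv", sep="\t", index=False)
        gene_models = _read_gene_models(config)
        loc = classify_location(
            lmrs, gene_models, tracks["cgi"], p["promoter_halfwidth"], p["distal_min"]
        )
        loc.to_csv(outdir / f"location_lmr_{tp}.tsv", sep="\t", index=False)
        _, vista_flags = overlap(tracks["vista"], lmrs, p["min_bp"])
        summary[tp] = {
            "dhs_percent": ov.percent,
            "partition": ov.partition,
            "vista_recovered": int(sum(vista_flags)),
            "vista_total": len(tracks["vista"]),
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _provenance("annotate", outdir, [config.dataset / "genome.fa"], p, config.seed)
    return summary


def _read_gene_models(config: PipelineConfig):
    from .annotation import GeneModel

    path = _require(config.dataset / "genes.tsv", "simulate")
    models = []
    for line in path.read_text().splitlines():
        chrom, start, end, strand, name, exons = line.split("\t")
        exon_list = tuple(
            tuple(int(x) for x in e.split("-")) for e in exons.split(";") if e
        )
        models.append(GeneModel(chrom, int(start), int(end), strand, name, exon_list))
    return models


def stage_liftover(config: PipelineConfig) -> dict[str, Any]:
    """Lift segment coordinates to a shifted synthetic assembly.

    A constant-shift chain per chromosome stands in for a cross-species
    chain file; variants are then intersected with the lifted LMRs.
    """
    outdir = Path(config.outdir) / "liftover"
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.annotation_params()
    genome = read_genome(_require(config.dataset / "genome.fa", "simulate"))
    shift = int(p["liftover_shift"])
    chains = [
        Chain(
            score=1000.0,
            t_name=chrom,
            t_size=len(seq),
            t_start=0,
            t_end=len(seq),
            q_name=f"{chrom}_target",
            q_size=len(seq) + shift,
            q_strand="+",
            q_start=shift,
            q_end=len(seq) + shift,
            chain_id=str(i + 1),
            blocks=[(0, len(seq), shift)],
        )
        for i, (chrom, seq) in enumerate(genome.items())
    ]
    chain_map = ChainMap(chains)
    chain_map.to_file(outdir / "synthetic.chain")
    counts = {}
    for tp in _timepoints(config):
        lmrs = _read_segments(config, tp, "LMR")
        result = liftover(lmrs, chain_map, p["liftover_min_match"])
        write_bed(result.mapped_intervals, outdir / f"lifted_lmrs_{tp}.bed")
        counts[tp] = {"mapped": len(result.mapped), "unmapped": len(result.unmapped)}
    _provenance("liftover", outdir, [config.dataset / "genome.fa"], p, config.seed)
    return counts


def stage_motifs(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "motifs"
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.motif_params()
    genome = read_genome(_require(config.dataset / "genome.fa", "simulate"))
    motifs = read_jaspar(_require(config.dataset / "motifs.jaspar", "simulate"))
    expression = pd.read_csv(_require(config.dataset / "expression.tsv", "simulate"), sep="\t")
    out: dict[str, Any] = {}
    for tp in _timepoints(config):
        lmrs = _read_segments(config, tp, "LMR")
        if not lmrs:
            out[tp] = []
            continue
        bg = build_background(lmrs, genome, n_per_fg=p["n_bg_per_fg"], seed=config.seed)
        results = enrich(lmrs, bg, genome, motifs, expression, p["rpkm_min"])
        passing = set(screen_enrichment(results, p["enrich_alpha_regions"]))
        frame = pd.DataFrame([r.__dict__ for r in results])
        frame["passes_screen"] = frame["motif"].isin(passing)
        frame.to_csv(outdir / f"enrichment_lmr_{tp}.tsv", sep="\t", index=False)
        out[tp] = sorted(passing)
    _provenance("motifs", outdir, [config.dataset / "motifs.jaspar"], p, config.seed)
    return out


def stage_targets(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "targets"
    outdir.mkdir(parents=True, exist_ok=True)
    interactions = read_interactions(_require(config.dataset / "interactions.tsv", "simulate"))
    rows = []
    for tp in _timepoints(config):
        path = Path(config.outdir) / "segments" / f"segments_{tp}.bed"
        segs = read_bed(_require(path, "segment"))
        assignments = assign_targets(
            segs,
            interactions,
            region_classes=[iv.name or "?" for iv in segs],
            timepoints=[tp] * len(segs),
        )
        rows.extend(assignments)
    summary = summarize_targets(rows)
    summary.to_csv(outdir / "target_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in rows],
            "start": [a.region.start for a in rows],
            "end": [a.region.end for a in rows],
            "gene": [a.gene for a in rows],
            "evidence": [a.evidence for a in rows],
            "region_class": [a.region_class for a in rows],
            "timepoint": [a.timepoint for a in rows],
        }
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    _provenance("targets", outdir, [config.dataset / "interactions.tsv"], {}, config.seed)
    return {"n_assignments": len(rows)}


def stage_network(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir) / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    mp = config.motif_params()
    np_ = config.network_params()
    ap = config.annotation_params()
    genome = read_genome(_require(config.dataset / "genome.fa", "simulate"))
    motifs = read_jaspar(_require(config.dataset / "motifs.jaspar", "simulate"))
    expression = pd.read_csv(_require(config.dataset / "expression.tsv", "simulate"), sep="\t")
    interactions = read_interactions(_require(config.dataset / "interactions.tsv", "simulate"))
    gene_models = _read_gene_models(config)
    tps = _timepoints(config)
    all_edges = []
    for tname, tp_a, tp_b in compare_transitions(tps):
        dmr_path = _require(Path(config.outdir) / "dmr" / f"dmrs_{tname}.tsv", "dmr")
        frame = pd.read_csv(dmr_path, sep="\t")
        from .dmr import DMRCall

        dmrs = [
            DMRCall(
                GenomicInterval(r.chrom, int(r.start), int(r.end)),
                r.name,
                float(r.delta),
                float(r.p),
                float(r.q),
                int(r.n_cpg),
                tname,
            )
            for r in frame.itertuples(index=False)
        ]
        if not dmrs:
            continue
        enrichment_by_direction = {}
        for direction in ("hyper", "hypo"):
            fg = [d.interval for d in dmrs if d.direction == direction]
            if not fg:
                enrichment_by_direction[direction] = []
                continue
            bg = build_background(
                fg, genome, n_per_fg=mp["n_bg_per_fg"], seed=config.seed + 3
            )
            enrichment_by_direction[direction] = enrich(
                fg, bg, genome, motifs, expression, mp["rpkm_min"]
            )
        dmr_hits = {
            i: {
                m.name
                for m in motifs
                if scan(genome[d.interval.chrom][d.interval.start : d.interval.end], m)
            }
            for i, d in enumerate(dmrs)
        }
        assignment_map = {
            i: assign_targets([d.interval], interactions)
            for i, d in enumerate(dmrs)
        }
        edges = build_network(
            dmrs,
            enrichment_by_direction,
            dmr_hits,
            assignment_map,
            expression,
            tname,
            (tp_a, tp_b),
            enrich_alpha=mp["enrich_alpha_network"],
            deg_alpha=np_["deg_alpha"],
            rpkm_min=mp["rpkm_min"],
            require_hit=np_["require_hit"],
        )
        edges_to_frame(edges).to_csv(outdir / f"edges_{tname}.tsv", sep="\t", index=False)
        if edges:
            write_graphml(edges, outdir / f"network_{tname}.graphml")
        all_edges.extend(edges)
    _provenance("network", outdir, [config.dataset / "expression.tsv"], {**mp, **np_}, config.seed)
    return {"n_edges": len(all_edges)}


def stage_demo(config: PipelineConfig) -> dict[str, Any]:
    """Synthetic spec -> full pipeline -> recovery report."""
    stage_simulate(config)
    stage_qc(config)
    stage_segment(config)
    stage_dmr(config)
    stage_annotate(config)
    stage_liftover(config)
    stage_motifs(config)
    stage_targets(config)
    stage_network(config)

    # score recovery against the planted truth
    truth_umrs = read_bed(config.dataset / "truth" / "umrs.bed")
    truth_lmrs = read_bed(config.dataset / "truth" / "lmrs.bed")
    truth_dmr_rows = [
        line.split("\t")
        for line in (config.dataset / "truth" / "dmrs.tsv").read_text().splitlines()
    ]
    truth_dmr_ivs = [GenomicInterval(r[0], int(r[1]), int(r[2])) for r in truth_dmr_rows]
    tps = _timepoints(config)
    tp0 = tps[0]
    umrs = _read_segments(config, tp0, "UMR")
    lmrs = _read_segments(config, tp0, "LMR")
    umr_score = score_recovery(umrs, truth_umrs, ignore=truth_dmr_ivs)
    lmr_score = score_recovery(lmrs, truth_lmrs, ignore=truth_dmr_ivs)

    truth_edges = [
        tuple(line.split("\t"))
        for line in (config.dataset / "truth" / "edges.tsv").read_text().splitlines()
    ]
    pred_edges = []
    for tname, _, _ in compare_transitions(tps):
        path = Path(config.outdir) / "network" / f"edges_{tname}.tsv"
        if path.exists():
            frame = pd.read_csv(path, sep="\t")
            pred_edges += [
                (r.tf, r.gene, r.transition) for r in frame.itertuples(index=False)
            ]
    precision, recall, f1 = edge_f1(pred_edges, truth_edges)

    report = {
        "umr_recall": umr_score.recall,
        "umr_precision": umr_score.precision,
        "lmr_recall": lmr_score.recall,
        "lmr_precision": lmr_score.precision,
        "edge_precision": precision,
        "edge_recall": recall,
        "edge_f1": f1,
    }
    out = Path(config.outdir)
    (out / "recovery_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


STAGES: dict[str, Callable[[PipelineConfig], dict[str, Any]]] = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "segment": stage_segment,
    "dmr": stage_dmr,
    "annotate": stage_annotate,
    "liftover": stage_liftover,
    "motifs": stage_motifs,
    "targets": stage_targets,
    "network": stage_network,
    "demo": stage_demo,
}


def run_stage(name: str, config: PipelineConfig) -> dict[str, Any]:
    """Run one named stage; returns its summary dict."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    return STAGES[name](config)
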