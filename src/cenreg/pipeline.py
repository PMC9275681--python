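"""End-to-end orchestration: simulate -> peaks -> degs -> regulon -> motif,
with a validated configuration, a provenance manifest, and evaluation
against the simulation truth table.

Randomness is owned here: the configuration seed is passed down to every
stage; stages never read global random state, so a rerun with an
identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .expression import aggregate_to_tus, call_genes
from .io_formats import (
    DEFAULT_STRAIN_CLASSES,
    write_annotations,
    write_de_table,
    write_genome,
    write_peak_table,
)
from .motif import MotifSite, discover_zoops, extract_upstream, write_meme
from .peaks import assign_to_tss, cluster_replicate_peaks, filter_by_support
from .regulon import build_regulon_table, intersect_candidates, regulon_to_dataframe
from .synthetic_data import SimulationConfig, TruthTable, simulate_all

__all__ = [
    "PipelineConfig",
    "StageFailure",
    "run_all",
    "evaluate_against_truth",
    "load_config",
]

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig(BaseModel):
    """Single source of configuration for a run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    simulate: dict = {}
    min_replicates: int = 3
    cluster_distance: int = 100
    window_upstream: int = 300
    window_downstream: int = 100
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    min_strains: int = 2
    strain_classes: dict[str, str] = dict(DEFAULT_STRAIN_CLASSES)
    upstream_length: int = 200
    upstream_anchor: str = "translation_start"
    motif_width_min: int = 10
    motif_width_max: int = 20
    motif_restarts: int = 5
    motif_pseudocount: float = 1.0

    @field_validator("simulate")
    @classmethod
    def _valid_simulate(cls, v: dict) -> dict:
        try:
            SimulationConfig(**{k: tuple(x) if isinstance(x, list) else x for k, x in v.items()})
        except TypeError as exc:
            raise ValueError(f"unknown simulate key: {exc}") from exc
        return v

    def simulation_config(self) -> SimulationConfig:
        params = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.simulate.items()
        }
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_truth(truth: TruthTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tu_id\tis_direct_target\trole\tsite_start\tsite_end\tsite_strand\t"
            "site_seq\trel_center\tgenes\n"
        )
        for e in truth.entries:
            site = e.site
            fh.write(
                "\t".join(
                    [
                        e.tu_id,
                        "1" if e.is_direct_target else "0",
                        e.role or ".",
                        str(site.start) if site else ".",
                        str(site.end) if site else ".",
                        site.strand if site else ".",
                        e.site_seq or ".",
                        str(e.rel_center) if e.rel_center is not None else ".",
                        ",".join(e.genes),
                    ]
                )
                + "\n"
            )


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage into ``out_dir``; returns the run directory.

    A stage failure aborts with the failing stage named; outputs written
    so far are retained next to a ``FAILED_<stage>`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.model_dump(), fh, sort_keys=True)

        stage = "simulate"
        sim_cfg = config.simulation_config()
        data = simulate_all(sim_cfg)
        write_genome(data.genome, out / "genome.fa")
        write_annotations(data.tus, out / "annotations.gff3")
        for (strain, rep), plist in data.peaks.items():
            write_peak_table(plist, out / f"peaks_{strain}_{rep}.tsv")
        for comp, records in data.de.items():
            write_de_table(records, out / f"de_{comp}.tsv")
        _write_truth(data.truth, out / "truth.tsv")

        stage = "peaks"
        consensus = cluster_replicate_peaks(data.all_peaks(), config.cluster_distance)
        kept = filter_by_support(consensus, config.min_replicates)
        assignments = assign_to_tss(
            kept, data.tus, config.window_upstream, config.window_downstream
        )
        with open(out / "consensus_peaks.tsv", "w") as fh:
            fh.write("replicon\tcenter\tsupport\tper_strain_enrichment\n")
            for c in kept:
                enrich = ";".join(f"{s}={v:.3f}" for s, v in c.per_strain_enrichment.items())
                fh.write(f"{c.replicon}\t{c.center}\t{c.support}\t{enrich}\n")
        with open(out / "assignments.tsv", "w") as fh:
            fh.write("replicon\tcenter\ttu_id\tdistance_to_tss\tclassification\tshared\n")
            for a in assignments:
                fh.write(
                    f"{a.peak.replicon}\t{a.peak.center}\t{a.tu_id or '.'}\t"
                    f"{a.distance_to_tss if a.distance_to_tss is not None else '.'}\t"
                    f"{a.classification}\t{int(a.shared)}\n"
                )

        stage = "degs"
        records = data.all_de_records()
        gene_calls = call_genes(
            records,
            config.strain_classes,
            config.lfc_threshold,
            config.fdr_threshold,
            config.min_strains,
        )
        summaries = aggregate_to_tus(gene_calls, data.tus, records, config.strain_classes)
        with open(out / "gene_calls.tsv", "w") as fh:
            fh.write("gene\tis_deg\tn_significant_strains\topposing\tdirection_hyper\tambiguous\n")
            for c in sorted(gene_calls, key=lambda c: c.gene):
                fh.write(
                    f"{c.gene}\t{int(c.is_deg)}\t{c.n_significant_strains}\t"
                    f"{int(c.opposing)}\t{c.direction_hyper}\t{int(c.ambiguous)}\n"
                )
        with open(out / "tu_summary.tsv", "w") as fh:
            fh.write("tu_id\tmember_genes\tany_opposing\tdirection_hyper\n")
            for s in sorted(summaries, key=lambda s: s.tu_id):
                fh.write(
                    f"{s.tu_id}\t{','.join(s.member_genes)}\t{int(s.any_opposing)}\t"
                    f"{s.direction_hyper}\n"
                )

        stage = "regulon"
        candidates = intersect_candidates(assignments, summaries)
        tu_map = {tu.tu_id: tu for tu in data.tus}

        stage = "motif"
        sites: dict[str, MotifSite | None] = {}
        discovery = None
        if len(candidates) >= 2:
            upstream = extract_upstream(
                data.genome,
                [tu_map[c.tu_id] for c in candidates],
                config.upstream_length,
                config.upstream_anchor,
            )
            discovery = discover_zoops(
                upstream,
                w_min=config.motif_width_min,
                w_max=config.motif_width_max,
                n_restarts=config.motif_restarts,
                seed=config.seed,
                pseudocount=config.motif_pseudocount,
            )
            write_meme(discovery.pwm, out / "motif.meme", name="discovered")
            for c in candidates:
                site = discovery.sites.get(c.tu_id)
                if site is not None:
                    tu = tu_map[c.tu_id]
                    anchor = (
                        tu.translation_start
                        if config.upstream_anchor == "translation_start"
                        else tu.tss
                    )
                    anchor_rel = tu.to_relative(anchor)
                    center_in_window = site.offset + len(site.site_seq) // 2
                    rel_center = center_in_window - len(upstream[c.tu_id]) + anchor_rel
                    site = MotifSite(
                        site.source_seq_id,
                        site.offset,
                        site.strand,
                        site.site_seq,
                        site.score,
                        position_vs_tss=rel_center,
                    )
                sites[c.tu_id] = site

        core, expanded, warn = build_regulon_table(
            candidates, sites, tu_map, {c.gene: c for c in gene_calls}
        )
        regulon_to_dataframe(core).to_csv(out / "regulon_core.tsv", sep="\t", index=False)
        regulon_to_dataframe(expanded).to_csv(
            out / "regulon_expanded.tsv", sep="\t", index=False
        )
        (out / "warnings.log").write_text("".join(w + "\n" for w in warn))

        stage = "evaluate"
        metrics = evaluate_against_truth(expanded, data.truth)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "manifest"
        outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "parameters": config.model_dump(),
            "simulation": asdict(sim_cfg) | {
                "strain_classes": dict(sim_cfg.strain_classes),
                "enrichment_means": dict(sim_cfg.enrichment_means),
            },
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        (out / f"FAILED_{stage}").write_text(str(exc) + "\n")
        raise StageFailure(stage, exc) from exc
    return out


def recover_candidates(dataset, config: PipelineConfig | None = None):
    """Peak-filtering + DE-intersection candidate recovery on an
    in-memory simulated dataset; returns (candidate (tu_id, role) list,
    truth-evaluation metrics)."""
    from .regulon import assign_role

    config = config or PipelineConfig()
    consensus = cluster_replicate_peaks(dataset.all_peaks(), config.cluster_distance)
    kept = filter_by_support(consensus, config.min_replicates)
    assignments = assign_to_tss(
        kept, dataset.tus, config.window_upstream, config.window_downstream
    )
    records = dataset.all_de_records()
    gene_calls = call_genes(
        records,
        config.strain_classes,
        config.lfc_threshold,
        config.fdr_threshold,
        config.min_strains,
    )
    summaries = aggregate_to_tus(gene_calls, dataset.tus, records, config.strain_classes)
    candidates = intersect_candidates(assignments, summaries)

    class _Entry:
        def __init__(self, tu_id, role):
            self.tu_id, self.role = tu_id, role

    entries = [_Entry(c.tu_id, assign_role(c.summary)[0]) for c in candidates]
    return entries, evaluate_against_truth(entries, dataset.truth)


def evaluate_against_truth(
    predicted: Sequence, truth: TruthTable
) -> dict[str, float | None]:
    """Precision/recall of the predicted regulon against planted truth,
    plus role accuracy over the intersection.

    ``predicted`` holds RegulonEntry-like objects with tu_id and role.
    An empty predicted set reports precision as undefined (None), not 0.
    """
    predicted_roles = {e.tu_id: e.role for e in predicted}
    predicted_ids = set(predicted_roles)
    true_roles = {e.tu_id: e.role for e in truth.direct_targets()}
    true_ids = set(true_roles)
    inter = predicted_ids & true_ids
    precision = len(inter) / len(predicted_ids) if predicted_ids else None
    recall = len(inter) / len(true_ids) if true_ids else None
    role_acc = (
        sum(predicted_roles[t] == true_roles[t] for t in inter) / len(inter)
        if inter
        else None
    )
    return {
        "n_predicted": len(predicted_ids),
        "n_true": len(true_ids),
        "precision": precision,
        "recall": recall,
        "role_accuracy": role_acc,
    }
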