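"""End-to-end orchestration: filter -> recurrence -> propagation ->
prioritization -> enrichment -> panel (-> expression), with a run manifest.

Every stage writes its artifact into the output directory; the manifest
records the configuration hash, seeds, per-stage row counts and package
version so a run can be reproduced and audited. All randomness flows from
the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from . import io as mio
from .enrichment import GeneSetCollection, enrich_collection, results_to_frame
from .exceptions import MdprioError
from .expression import LabeledExpression, celltype_percentiles, compare_gene_sets
from .filtering import (
    FilterConfig,
    filter_rare_damaging,
    summarize_filtering,
    ufv_filter,
)
from .network import (
    InteractionNetwork,
    PrioritizationConfig,
    PropagationConfig,
    network_scores_from_ufvs,
    prioritize,
    write_score_table,
)
from .panel import build_panel_curve, rank_genes_by_recurrence, write_panel_curve
from .recurrence import (
    RecurrenceConfig,
    gene_recurrence,
    write_recurrence_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageFailure", "run_pipeline"]


class StageFailure(MdprioError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    variants: str
    network: str
    outdir: str
    gmt: str | None = None
    expression_matrix: str | None = None
    expression_genes: str | None = None
    expression_cells: str | None = None
    cell_labels: str | None = None
    n_samples: int | None = None  # inferred from carrier ids when omitted
    filter: FilterConfig = field(default_factory=FilterConfig)
    recurrence: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    panel_top_k: int = 50
    recovery_target: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("filter", FilterConfig),
            ("recurrence", RecurrenceConfig),
            ("propagation", PropagationConfig),
            ("prioritization", PrioritizationConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Any stage failure aborts the run with :class:`StageFailure` after
    writing a partial manifest recording the completed stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    config.propagation.rng_seed = config.seed

    def finish_stage(name: str, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    def fail(stage: str, exc: BaseException):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise StageFailure(stage, exc) from exc

    # --- filter ---
    try:
        variants = mio.read_variant_table(config.variants)
        n_samples = config.n_samples
        if n_samples is None:
            n_samples = len({s for v in variants for s in v.carriers})
            logger.warning(
                "cohort size not given; inferred %d samples from carrier ids",
                n_samples,
            )
        rare_damaging = filter_rare_damaging(variants, config.filter)
        ufvs = ufv_filter(rare_damaging, n_samples, config.filter)
        summary = summarize_filtering(variants, rare_damaging, ufvs)
        mio.write_variant_table(ufvs, outdir / "ufv.tsv")
        with open(outdir / "filter_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail("filter", exc)
    finish_stage(
        "filter",
        n_input=summary.n_input,
        n_rare_damaging=summary.n_after_rare_damaging,
        n_ufv=summary.n_ufv,
    )

    # --- recurrence ---
    try:
        recurrence = gene_recurrence(ufvs, n_samples)
        write_recurrence_table(recurrence, outdir / "recurrence.tsv")
    except Exception as exc:
        fail("recurrence", exc)
    finish_stage("recurrence", n_genes=len(recurrence))

    # --- network propagation ---
    try:
        network = InteractionNetwork.from_edges(mio.read_edge_list(config.network))
        netscores, _profiles = network_scores_from_ufvs(
            ufvs, network, config.propagation
        )
        write_score_table(netscores, outdir / "network_scores.tsv")
        off_network = sorted(
            {r.gene for r in recurrence} - set(network.nodes)
        )
        mio.write_gene_list(off_network, outdir / "genes_not_in_network.txt")
    except Exception as exc:
        fail("netprop", exc)
    finish_stage(
        "netprop",
        n_network_genes=network.n_nodes,
        n_edges=network.n_edges,
        n_off_network=len(off_network),
        n_null=config.propagation.n_null,
    )

    # --- prioritization ---
    try:
        sets = prioritize(recurrence, netscores, config.prioritization)
        for name, genes in sets.items():
            mio.write_gene_list(sorted(genes), outdir / f"genes_{name}.txt")
    except Exception as exc:
        fail("prioritize", exc)
    finish_stage("prioritize", **{f"n_{k}": len(v) for k, v in sets.items()})

    # --- enrichment ---
    if config.gmt:
        try:
            gmt_sets = mio.read_gmt(config.gmt)
            variant_genes = {v.gene for v in variants}
            collection = GeneSetCollection(
                name=Path(config.gmt).stem,
                sets=gmt_sets,
                universe=set().union(*gmt_sets.values()) | variant_genes,
            )
            results = enrich_collection(sets, collection, universe=variant_genes)
            results_to_frame(results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
        except Exception as exc:
            fail("enrich", exc)
        finish_stage("enrich", n_results=len(results))
    else:
        manifest["stages"]["enrich"] = "skipped"

    # --- panel ---
    try:
        ranked = rank_genes_by_recurrence(recurrence)[: config.panel_top_k]
        cohort = sorted({s for v in variants for s in v.carriers})
        curve = build_panel_curve(ranked, ufvs, cohort)
        write_panel_curve(curve, outdir / "panel_curve.tsv")
        k_target = curve.smallest_k_reaching(config.recovery_target)
    except Exception as exc:
        fail("panel", exc)
    finish_stage(
        "panel",
        n_ranked=len(ranked),
        k_reaching_target=k_target,
        recovery_target=config.recovery_target,
    )

    # --- expression ---
    if config.expression_matrix:
        try:
            genes, cells, matrix = mio.read_expression_matrix(
                config.expression_matrix,
                config.expression_genes,
                config.expression_cells,
            )
            labels = mio.read_cell_labels(config.cell_labels)
            expr = LabeledExpression(
                genes=genes,
                cells=cells,
                matrix=matrix,
                cell_types=[labels[c] for c in cells],
            )
            pct = celltype_percentiles(expr)
            baseline = {v.gene for v in variants}
            tests = compare_gene_sets(pct, sets["intersection"], baseline)
            tests.to_csv(outdir / "expression_tests.tsv", sep="\t", index=False)
        except Exception as exc:
            fail("expression", exc)
        finish_stage("expression", n_cell_types=len(tests))
    else:
        manifest["stages"]["expression"] = "skipped"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
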