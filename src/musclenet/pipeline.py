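"""End-to-end orchestration: matrix → filter → DE → discriminant top-K →
per-group correlation networks → comparison → optional enrichment.

Every run writes a flat directory of TSV/GraphML outputs plus a
machine-readable JSON manifest recording all parameters, the seed and
input checksums, so a run is reproducible byte for byte from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .de import ModeratedTTest, iqr_filter, select_de_from_printed
from .enrich import fisher_enrichment
from .errors import ConfigurationError, PipelineError
from .io import (
    ExpressionMatrix,
    SampleAnnotation,
    load_fixture_tables,
    read_annotation,
    read_expression_matrix,
    read_gene_sets,
)
from .network import (
    GeneNetwork,
    ThresholdCalibration,
    build_network,
    calibrate_threshold,
    default_grid,
    network_summary,
    pearson_matrix,
)
from .pca import (
    classical_mds,
    rank_genes_by_score,
    select_discriminant_component,
    transpose_pca,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_fixture_checks"]

log = logging.getLogger("musclenet")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run.

    ``case_group`` names the annotation label treated as the case group;
    it is never inferred from label strings.  ``correlation_scope``
    selects whether each group's network uses only that group's samples
    (``"per-group"``, default) or the pooled population (``"pooled"``).
    ``calibration_group`` picks whose matrix calibrates the shared
    threshold; ``fallback_tau`` is applied when no grid point qualifies.
    """

    case_group: str
    matrix_path: Optional[str] = None
    annotation_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    out_dir: str = "musclenet_run"
    iqr_min: float = 0.25
    min_abs_log2fc: float = 1.0
    max_adj_p: float = 0.05
    top_k: int = 100
    mds_dims: int = 3
    tau_min: float = 0.50
    tau_max: float = 0.99
    tau_step: float = 0.01
    n_surrogates: int = 1000
    margin: float = 0.10
    surrogate_quantile: Optional[float] = 0.99
    threshold_selection: str = "largest"
    edge_rule: str = "positive"
    correlation_scope: str = "per-group"
    calibration_group: str = "case"
    fallback_tau: float = 0.95
    exclude_first_component: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigurationError("top_k must be ≥ 1")
        if self.correlation_scope not in ("per-group", "pooled"):
            raise ConfigurationError("correlation_scope must be 'per-group' or 'pooled'")
        if self.calibration_group not in ("case", "control"):
            raise ConfigurationError("calibration_group must be 'case' or 'control'")
        if not 0 < self.fallback_tau < 1:
            raise ConfigurationError("fallback_tau must lie in (0, 1)")

    def grid(self) -> np.ndarray:
        return default_grid(self.tau_min, self.tau_max, self.tau_step)


@dataclass
class PipelineReport:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    filtered_matrix: ExpressionMatrix
    de_results: object
    de_selected: pd.DataFrame
    mds_coordinates: pd.DataFrame
    decomposition: object
    discriminant: object
    top_genes: pd.DataFrame
    calibration: ThresholdCalibration
    tau: float
    network_case: GeneNetwork
    network_control: GeneNetwork
    comparison: pd.DataFrame
    enrichment: Optional[object]
    manifest: dict
    out_dir: Path


def _sha256(path: Optional[str]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(
    config: PipelineConfig,
    matrix: Optional[ExpressionMatrix] = None,
    annotation: Optional[SampleAnnotation] = None,
    gene_sets=None,
) -> PipelineReport:
    """Execute every stage in order and write the report bundle.

    Inputs may be passed in memory; otherwise they are read from the
    paths in ``config``.  Any stage failure raises
    :class:`~musclenet.errors.PipelineError` naming the stage, and an
    ``INCOMPLETE`` marker file is left in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")

    stage = "load_inputs"
    try:
        if matrix is None:
            if config.matrix_path is None:
                raise ConfigurationError("matrix_path required when no matrix is passed")
            matrix = read_expression_matrix(config.matrix_path)
        if annotation is None:
            if config.annotation_path is None:
                raise ConfigurationError("annotation_path required when no annotation is passed")
            annotation = read_annotation(config.annotation_path)
        if gene_sets is None and config.gene_sets_path is not None:
            gene_sets = read_gene_sets(config.gene_sets_path)
        annotation.check_covers(matrix)
        labels = annotation.group_labels
        if config.case_group not in labels:
            raise ConfigurationError(
                f"case_group {config.case_group!r} not among annotation groups {labels}"
            )
        control_group = labels[0] if config.case_group == labels[1] else labels[1]
        case_samples = [s for s in matrix.sample_ids
                        if s in set(annotation.samples_in(config.case_group))]
        control_samples = [s for s in matrix.sample_ids
                           if s in set(annotation.samples_in(control_group))]
        log.info("inputs: %d genes × %d samples (%d case / %d control)",
                 matrix.n_genes, matrix.n_samples, len(case_samples), len(control_samples))

        stage = "iqr_filter"
        filtered = iqr_filter(matrix, config.iqr_min)
        _write_tsv(
            pd.DataFrame(
                {
                    "n_genes_input": [matrix.n_genes],
                    "n_genes_kept": [filtered.n_genes],
                    "iqr_min": [config.iqr_min],
                }
            ),
            out / "filter_summary.tsv",
        )
        log.info("iqr_filter: kept %d of %d genes", filtered.n_genes, matrix.n_genes)

        stage = "differential_expression"
        de_results = ModeratedTTest(filtered, annotation, case=config.case_group).fit()
        de_table = de_results.table.copy()
        de_table.index.name = "gene_id"
        _write_tsv(de_table, out / "de_results.tsv", index=True)
        volcano = pd.DataFrame(
            {
                "log2_fc": de_table["log2_fc"],
                "neg_log10_p": -np.log10(np.maximum(de_table["p_value"], 1e-300)),
            },
            index=de_table.index,
        )
        _write_tsv(volcano, out / "volcano.tsv", index=True)
        de_selected = de_results.select(config.min_abs_log2fc, config.max_adj_p)
        sel = de_selected.copy()
        sel.index.name = "gene_id"
        _write_tsv(sel, out / "de_selected.tsv", index=True)
        log.info("differential_expression: %d genes pass cutoffs", len(de_selected))

        stage = "mds_qc"
        mds = classical_mds(matrix, n_dims=config.mds_dims)
        _write_tsv(mds, out / "mds_coordinates.tsv", index=True)

        stage = "pca_discriminant"
        decomp = transpose_pca(matrix)
        _write_tsv(decomp.summary(), out / "pca_summary.tsv")
        selection = select_discriminant_component(
            decomp, annotation, exclude_first=config.exclude_first_component
        )
        sep = selection.separations.rename_axis("component").reset_index()
        sep["selected"] = sep["component"] == selection.component
        _write_tsv(sep, out / "discriminant_selection.tsv")
        top = rank_genes_by_score(decomp, selection.component, k=config.top_k)
        _write_tsv(top, out / "discriminant_genes.tsv")
        log.info("pca_discriminant: component %d selected (PC1 fraction %.3f)",
                 selection.component, decomp.variance_fractions[0])

        stage = "threshold_calibration"
        top_ids = list(top["gene_id"])
        sub = matrix.select_genes(top_ids)
        scope_samples = {
            "case": case_samples,
            "control": control_samples,
        }
        calib_samples = (
            matrix.sample_ids
            if config.correlation_scope == "pooled"
            else scope_samples[config.calibration_group]
        )
        calibration = calibrate_threshold(
            sub.select_samples(calib_samples),
            grid=config.grid(),
            n_surrogates=config.n_surrogates,
            margin=config.margin,
            seed=config.seed,
            edge_rule=config.edge_rule,
            surrogate_quantile=config.surrogate_quantile,
            selection=config.threshold_selection,
        )
        _write_tsv(calibration.to_frame(), out / "calibration.tsv")
        tau = calibration.selected if calibration.selected is not None else config.fallback_tau
        log.info("threshold_calibration: %s → τ = %.2f", calibration.summary(), tau)

        stage = "network_construction"
        if config.correlation_scope == "pooled":
            corr_case = corr_control = pearson_matrix(sub)
        else:
            corr_case = pearson_matrix(sub.select_samples(case_samples))
            corr_control = pearson_matrix(sub.select_samples(control_samples))
        net_case = build_network(corr_case, tau, config.edge_rule)
        net_control = build_network(corr_control, tau, config.edge_rule)
        for name, net in (("case", net_case), ("control", net_control)):
            net.to_graphml(out / f"network_{name}.graphml")
            _write_tsv(net.edge_table(), out / f"network_{name}_edges.tsv")
        comparison = network_summary(net_case, net_control)
        comp_out = comparison.rename_axis("statistic").reset_index()
        _write_tsv(comp_out, out / "network_summary.tsv")
        log.info("network_construction: case %s | control %s",
                 net_case.summary(), net_control.summary())

        stage = "enrichment"
        enrichment = None
        if gene_sets is not None:
            enrichment = fisher_enrichment(
                top_ids, gene_sets, background=matrix.gene_ids
            )
            _write_tsv(enrichment.table, out / "enrichment.tsv")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "parameters": {
                k: (v if not isinstance(v, Path) else str(v))
                for k, v in asdict(config).items()
            },
            "seed": config.seed,
            "selected_threshold": calibration.selected,
            "applied_threshold": tau,
            "inputs": {
                "matrix_sha256": _sha256(config.matrix_path)
                or hashlib.sha256(matrix.data.to_csv().encode()).hexdigest(),
                "annotation_sha256": _sha256(config.annotation_path)
                or hashlib.sha256(annotation.table.to_csv().encode()).hexdigest(),
                "gene_sets_sha256": _sha256(config.gene_sets_path),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    marker.unlink(missing_ok=True)
    return PipelineReport(
        config=config,
        filtered_matrix=filtered,
        de_results=de_results,
        de_selected=de_selected,
        mds_coordinates=mds,
        decomposition=decomp,
        discriminant=selection,
        top_genes=top,
        calibration=calibration,
        tau=tau,
        network_case=net_case,
        network_control=net_control,
        comparison=comparison,
        enrichment=enrichment,
        manifest=manifest,
        out_dir=out,
    )


def run_fixture_checks(seed: int = 0) -> dict[str, dict]:
    """Recompute the desk-scale checks bound to the packaged fixtures.

    Returns a report mapping check names to observed/expected values and
    a pass flag; failures are reported, never raised.
    """
    report: dict[str, dict] = {}

    def record(name: str, observed, expected, passed: bool) -> None:
        report[name] = {"observed": observed, "expected": expected, "passed": bool(passed)}

    tables = load_fixture_tables()

    sel = select_de_from_printed(tables.de_genes)
    n_down = int((sel["direction"] == "down").sum())
    n_up = int((sel["direction"] == "up").sum())
    record("printed_de_refilter_total", len(sel), 96, len(sel) == 96)
    record("printed_de_refilter_down", n_down, 16, n_down == 16)
    record("printed_de_refilter_up", n_up, 80, n_up == 80)

    ages = tables.cohort.groupby("group")["age_years"].median()
    record("median_age_control", float(ages["control"]), 64.0, ages["control"] == 64)
    record("median_age_case", float(ages["ALS"]), 64.0, ages["ALS"] == 64)

    n = 100
    record("potential_connections_100_genes", n * (n - 1) // 2, 4950, n * (n - 1) // 2 == 4950)

    # AD identity on a randomly generated network
    from .simulate import SyntheticConfig, generate_two_group_dataset

    cfg = SyntheticConfig(n_genes=60, n_per_group=5, n_de=0, blocks=(), seed=seed)
    m, _, _ = generate_two_group_dataset(cfg)
    net = build_network(pearson_matrix(m), 0.6)
    handshake = int(net.degrees.sum()) == 2 * net.n_edges
    identity = handshake and net.average_degree == 2 * net.n_edges / net.n_nodes
    record("ad_identity", net.average_degree, 2 * net.n_edges / net.n_nodes, identity)

    return report
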