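"""End-to-end analysis runs: load, dispatch, report.

A run is a pure function of (input files, config, seed): a single
master seed drives every stage through deterministically derived
sub-seeds, so any reported number can be reproduced from the config
alone.  Reports land in the output directory as ``report.json`` plus,
depending on the analysis, per-group diagram TSVs, a per-set TSV and
the raw permutation null values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .distances import drop_constant_genes, pearson_dissimilarity
from .errors import ValidationError
from .invariants import summarize
from .io import read_expression, read_gmt, read_metadata, split_by_group
from .mahalanobis import ssmd_geneset_test, ssmd_label_permutation_test
from .permutation import (
    GroupStatistic,
    filter_genesets,
    geneset_topology_scan,
    label_permutation_test,
)
from .persistence import (
    lazy_witness_persistence,
    rips_persistence,
    select_landmarks,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run"]

ANALYSES = ("sample-topology", "gene-topology", "geneset-topology",
            "mahalanobis", "geneset-mahalanobis")


@dataclass
class RunConfig:
    expression_path: str
    metadata_path: str
    analysis: str = "sample-topology"
    geneset_path: str | None = None
    statistic: str = "sdt0"
    max_dim: int | None = None
    landmark_size: int = 20
    nu: int = 1
    n_perm: int = 1000
    n_random_sets: int = 100
    sided: str = "two"
    seed: int = 0
    case_label: str | None = None
    drop_constant: bool = False
    output_dir: str = "topohet_out"

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValidationError(
                f"analysis must be one of {ANALYSES}, got {self.analysis!r}")


@dataclass
class RunReport:
    config: RunConfig
    results: dict
    wall_clock_s: float
    version: str = field(default_factory=lambda: __version__)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "config": dataclasses.asdict(self.config),
            "results": self.results,
            "version": self.version,
            "wall_clock_s": self.wall_clock_s,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def _summary_dict(summary) -> dict:
    return json.loads(summary.to_json())


def _group_diagrams(expr, meta, stat: GroupStatistic, seed: int, out: Path) -> dict:
    """Observed per-group diagrams + summaries, exported as TSV."""
    (out / "diagrams").mkdir(parents=True, exist_ok=True)
    results = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(meta.groups)) % (2 ** 31)
    for g, lseed in zip(meta.groups, seeds):
        sub = expr.subset_samples([s for s in expr.sample_ids
                                   if meta.assignment[s] == g])
        if stat.level == "sample":
            dmat = pearson_dissimilarity(sub, axis="samples")
            diagram = rips_persistence(dmat, max_dim=stat.effective_max_dim)
        else:
            dmat = pearson_dissimilarity(sub, axis="genes")
            lm = select_landmarks(dmat, min(stat.landmark_size, dmat.n_points),
                                  method=stat.landmark_method,
                                  seed=int(lseed), nu=stat.nu)
            diagram = lazy_witness_persistence(dmat, lm,
                                               max_dim=stat.effective_max_dim)
        diagram.to_tsv(out / "diagrams" / f"{g}.tsv")
        results[g] = _summary_dict(summarize(diagram))
    return results


def run(config: RunConfig) -> RunReport:
    """Execute one analysis and write its report files."""
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = read_expression(config.expression_path)
    meta = read_metadata(config.metadata_path)
    meta.validate_against(expr)
    if config.drop_constant:
        before = expr.n_genes
        expr = drop_constant_genes(expr)
        if expr.n_genes < before:
            logger.info("dropped %d constant genes (of %d)",
                        before - expr.n_genes, before)

    level = "gene" if config.analysis == "gene-topology" else "sample"
    stat = GroupStatistic(config.statistic, level, config.max_dim,
                          config.landmark_size, nu=config.nu)
    results: dict = {}

    if config.analysis in ("sample-topology", "gene-topology"):
        results["per_group_summary"] = _group_diagrams(expr, meta, stat,
                                                       config.seed, out)
        res = label_permutation_test(expr, meta, stat, n_perm=config.n_perm,
                                     seed=config.seed, sided=config.sided,
                                     case_label=config.case_label)
        np.savetxt(out / "null_values.tsv", res.null_values)
        results["permutation"] = {
            "observed_D": res.observed,
            "fdr": res.fdr,
            "n_perm": res.n_perm,
            "sided": res.sided,
            "note": "permutation FDR (as defined in the source analysis); "
                    "operationally an empirical permutation p-value",
        }
    elif config.analysis == "geneset-topology":
        sets = filter_genesets(read_gmt(_require_gmt(config)), expr)
        scan = geneset_topology_scan(expr, meta, sets, stat,
                                     n_random=config.n_random_sets,
                                     seed=config.seed, sided=config.sided,
                                     case_label=config.case_label)
        scan.to_tsv(out / "genesets.tsv")
        results["geneset_scan"] = _scan_dict(scan)
    elif config.analysis == "mahalanobis":
        res = ssmd_label_permutation_test(expr, meta, n_perm=config.n_perm,
                                          seed=config.seed,
                                          case_label=config.case_label)
        np.savetxt(out / "null_values.tsv", res.null_values)
        results["ssmd"] = {
            "ssmd_observed": res.ssmd_observed,
            "per_sample_md": res.per_sample_md,
            "fdr": res.fdr,
            "n_perm": res.n_perm,
        }
    elif config.analysis == "geneset-mahalanobis":
        sets = filter_genesets(read_gmt(_require_gmt(config)), expr)
        scan = ssmd_geneset_test(expr, meta, sets,
                                 n_random=config.n_random_sets,
                                 seed=config.seed,
                                 case_label=config.case_label)
        scan.to_tsv(out / "genesets.tsv")
        results["geneset_scan"] = _scan_dict(scan)

    report = RunReport(config, results, round(time.perf_counter() - t0, 3))
    report.to_json(out / "report.json")
    return report


def _require_gmt(config: RunConfig) -> str:
    if config.geneset_path is None:
        raise ValidationError(f"analysis {config.analysis!r} needs a GMT file")
    return config.geneset_path


def _scan_dict(scan) -> dict:
    return {
        "n_random_sets": scan.n_random_sets,
        "n_sets_tested": len(scan.per_set),
        "skipped": list(scan.skipped),
        "per_set": {
            name: {"set_size_used": e.set_size_used,
                   "observed_D": e.observed_d, "fdr": e.fdr}
            for name, e in scan.per_set.items()
        },
    }
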