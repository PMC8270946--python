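"""End-to-end pipeline entry point used by the CLI and the acceptance runs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as mio
from .config import PipelineConfig
from .datatypes import ParcellatedTimeseries, StageLabels
from .model import BrainStateManifold, ManifoldResults

logger = logging.getLogger(__name__)


def run_pipeline(
    config: PipelineConfig,
    timeseries: list[ParcellatedTimeseries],
    labels: list[StageLabels],
    out_dir: str | Path | None = None,
    run_surrogates: bool = False,
) -> dict:
    """Run the full analysis and (optionally) write all artefacts.

    Returns the JSON-serialisable report. Repeated runs with identical
    config, inputs and seed produce byte-identical reports.
    """
    model = BrainStateManifold(timeseries, labels, config)
    results = model.fit(
        run_surrogates=run_surrogates,
        n_perm=config.n_perm if run_surrogates else None,
    )
    report = results.to_report()
    if out_dir is not None:
        write_artifacts(results, report, Path(out_dir))
    return report


def write_artifacts(
    results: ManifoldResults, report: dict, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for art in results.subjects:
        mio.write_embedding(
            out_dir / f"embedding_{art.subject_id}.tsv", art.embedding, art.labels
        )
        mio.write_edges(out_dir / f"edges_{art.subject_id}.tsv", art.graph)
    if results.aligned is not None:
        mio.write_group_embedding(
            out_dir / "group_embedding.tsv",
            results.aligned,
            [a.labels for a in results.subjects],
        )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("wrote artefacts to %s", out_dir)
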