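"""Shared configuration for the analysis scripts.

One seed and one study configuration drive every step, so each numbered
script can deterministically re-derive the upstream state it needs
without shipping multi-megabyte intermediate rasters.
"""

from pathlib import Path

from bearshield import PipelineConfig, StudyConfig

SEED = 20160906
RESULTS = Path(__file__).resolve().parent.parent / "results"


def pipeline_config(out_dir: Path | None = None) -> PipelineConfig:
    return PipelineConfig(
        study=StudyConfig(),
        seed=SEED,
        out_dir=out_dir or RESULTS / "pipeline",
        write_figures=True,
    )
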