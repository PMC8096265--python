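"""End-to-end screen pipeline with plain-text configuration and provenance.

A run takes either FASTQ files plus a manifest, or a pre-computed count
matrix, and executes count -> normalise -> enrichment -> gene scores ->
P-values -> ranked table, writing every intermediate table, a log, and the
echoed configuration into the results directory.  Outputs are pure
functions of the inputs and the configuration: re-running an identical
setup reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ChecsError, FormatError, ParameterError
from .manifest import read_manifest, write_manifest
from .quant import count_samples, parse_sample_name, read_counts, write_counts
from .screen import ScreenModel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the screen pipeline, loadable from key=value text."""

    manifest: str = ""
    counts: str = ""                 # pre-computed count matrix (TSV)
    fastq_dir: str = ""              # directory of <sample>.fastq[.gz] files
    out_dir: str = "results"
    seed: int = 0
    offset: str = "scan"             # guide window: integer or "scan"
    orientation: str = "forward"
    floor: float = 1e-3
    cap: float = 1e3
    gene_score_mode: str = "sum"

    _FLOATS = ("floor", "cap")
    _INTS = ("seed",)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ParameterError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in cls._FLOATS:
                kwargs[key] = float(value)
            elif key in cls._INTS:
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def echo(self) -> str:
        pairs = [
            (f.name, getattr(self, f.name))
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        ]
        return "\n".join(f"{k} = {v}" for k, v in pairs) + "\n"


def run_screen_pipeline(config: RunConfig):
    """Execute the configured screen run; returns the fitted ScreenResults."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(config.echo())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("checs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except ChecsError as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path):
    if not config.manifest:
        raise ParameterError("config requires a manifest path")
    manifest = read_manifest(config.manifest)
    write_manifest(manifest, out / "manifest.tsv")

    if config.counts:
        counts = read_counts(config.counts)
        log.info("stage count: loaded %s", config.counts)
    elif config.fastq_dir:
        offset = config.offset if config.offset == "scan" else int(config.offset)
        fastqs = {}
        for path in sorted(Path(config.fastq_dir).iterdir()):
            name = path.name
            for suffix in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
                if name.endswith(suffix):
                    sid = name[: -len(suffix)]
                    parse_sample_name(sid)
                    fastqs[sid] = path
                    break
        if not fastqs:
            raise ParameterError(f"no FASTQ files found in {config.fastq_dir}")
        log.info("stage count: matching %d samples", len(fastqs))
        counts = count_samples(
            fastqs, manifest, offset=offset, orientation=config.orientation
        )
    else:
        raise ParameterError("config requires either counts or fastq_dir")
    write_counts(counts, out / "counts.tsv")

    model = ScreenModel(
        counts, manifest,
        floor=config.floor, cap=config.cap,
        gene_score_mode=config.gene_score_mode,
    )
    log.info("stage score: %d guides, %d samples",
             len(counts.counts), counts.counts.shape[1])
    results = model.fit()
    results.save(out)
    results.normalized.rename_axis("guide_id").to_csv(
        out / "normalized_counts.tsv", sep="\t"
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
    log.info("stage rank: %d genes scored", len(results.gene_table))
    return results
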