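"""End-to-end orchestration: simulate/load -> filter -> pool -> align -> call.

A pipeline run is described by a :class:`PipelineConfig` (built directly or
from a YAML/JSON file): a list of loci, a list of samples (each either a
pair of FASTQ paths or a simulation block), and the shared analysis
parameters.  ``run_pipeline`` executes every sample against every locus,
writes per-read call tables and per-sample summaries under the output
directory, and returns a :class:`RunReport` whose numeric content is
deterministic under a fixed seed (timestamps live only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from .align import ScoringScheme, cigar_string, smith_waterman
from .classify import EditCall, EditingSummary, classify_read, summarize_editing
from .densitometry import GelBands, hindiii_hdr, t7e1_total_editing
from .locus import ReferenceWindow, TargetLocus, build_reference_window, load_locus
from .preprocess import (
    FilterReport,
    SequencingRead,
    pool_pairs,
    quality_trim_and_filter,
    read_fastq,
    write_fasta,
)
from .simulate import IndelSizeDistribution, QualityModel, SimulationConfig, emit_fastq_pairs

log = logging.getLogger("ampliquant")


def _version() -> str:
    try:
        return metadata.version("ampliquant")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and sample."""


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSpec:
    """One sample: either FASTQ inputs or a simulation block (not both)."""

    name: str
    r1: str | None = None
    r2: str | None = None
    simulate: dict | None = None

    def __post_init__(self) -> None:
        has_files = self.r1 is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                f"sample {self.name}: exactly one of FASTQ paths or a "
                "simulation block must be supplied"
            )
        if has_files and self.r2 is None:
            raise ValueError(f"sample {self.name}: r2 path missing")


@dataclass(frozen=True)
class PipelineConfig:
    loci: tuple[tuple[TargetLocus, str], ...]  # (locus, window-frame insert)
    samples: tuple[SampleSpec, ...]
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    q_threshold: int = 30
    trim_window: int = 4
    flank: int = 15
    outdir: str = "ampliquant_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("at least one locus is required")
        if not self.samples:
            raise ValueError("at least one sample is required")
        for s in self.samples:
            if s.r1 is not None and not Path(s.r1).exists():
                raise FileNotFoundError(f"sample {s.name}: {s.r1} does not exist")
            if s.r2 is not None and not Path(s.r2).exists():
                raise FileNotFoundError(f"sample {s.name}: {s.r2} does not exist")

    @classmethod
    def from_dict(cls, data: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        loci = tuple(load_locus(spec, base_dir) for spec in data["loci"])
        samples = tuple(
            SampleSpec(
                name=s["name"],
                r1=str(Path(base_dir) / s["r1"]) if "r1" in s else None,
                r2=str(Path(base_dir) / s["r2"]) if "r2" in s else None,
                simulate=s.get("simulate"),
            )
            for s in data["samples"]
        )
        scheme = ScoringScheme(**data.get("scoring", {}))
        return cls(
            loci=loci,
            samples=samples,
            scheme=scheme,
            q_threshold=data.get("q_threshold", 30),
            trim_window=data.get("trim_window", 4),
            flank=data.get("flank", 15),
            outdir=str(Path(base_dir) / data.get("outdir", "ampliquant_out")),
            seed=data.get("seed", 0),
            log_level=data.get("log_level", "INFO"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data, base_dir=path.parent)

    def echo(self) -> dict:
        """JSON-serialisable config echo sufficient to reproduce the run."""
        return {
            "loci": [
                {"name": loc.name, "protospacer": loc.protospacer, "pam": loc.pam,
                 "strand": loc.strand, "expected_insert": ins,
                 "amplicon_len": len(loc.amplicon)}
                for loc, ins in self.loci
            ],
            "samples": [dataclasses.asdict(s) for s in self.samples],
            "scoring": dataclasses.asdict(self.scheme),
            "q_threshold": self.q_threshold,
            "trim_window": self.trim_window,
            "flank": self.flank,
            "seed": self.seed,
        }


@dataclass
class RunReport:
    summaries: dict[str, dict[str, EditingSummary]]  # sample -> locus -> summary
    filter_reports: dict[str, dict]  # sample -> counts
    version: str
    config_echo: dict
    timestamp: str

    def as_dict(self, include_timestamp: bool = False) -> dict:
        out = {
            "version": self.version,
            "config": self.config_echo,
            "filter_reports": self.filter_reports,
            "summaries": {
                sample: {locus: s.as_dict() for locus, s in by_locus.items()}
                for sample, by_locus in self.summaries.items()
            },
        }
        if include_timestamp:
            out["timestamp"] = self.timestamp
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")


def quantify_reads(
    pool: list[SequencingRead],
    window: ReferenceWindow,
    scheme: ScoringScheme | None = None,
    call_hdr: bool = True,
) -> tuple[list[EditCall], EditingSummary, list]:
    """Align and classify a pooled read set against one window."""
    scheme = scheme or ScoringScheme()
    calls, alignments = [], []
    for read in pool:
        aln = smith_waterman(read.sequence, window, scheme)
        alignments.append(aln)
        calls.append(classify_read(aln, window, read_id=read.id, call_hdr=call_hdr))
    return calls, summarize_editing(calls), alignments


def _sample_reads(
    sample: SampleSpec, config: PipelineConfig, outdir: Path
) -> tuple[list[SequencingRead], list[SequencingRead]]:
    if sample.simulate is not None:
        sim = sample.simulate
        locus_name = sim.get("locus", config.loci[0][0].name)
        locus = next((l for l, _ in config.loci if l.name == locus_name), None)
        if locus is None:
            raise PipelineError(f"simulate: sample {sample.name}: unknown locus {locus_name}")
        kwargs = {k: v for k, v in sim.items() if k not in ("locus",)}
        if "indel_size_distribution" in kwargs:
            kwargs["indel_size_distribution"] = IndelSizeDistribution(
                **kwargs["indel_size_distribution"]
            )
        if "quality_model" in kwargs:
            kwargs["quality_model"] = QualityModel(**kwargs["quality_model"])
        kwargs.setdefault("seed", config.seed)
        sim_config = SimulationConfig(locus=locus, **kwargs)
        r1_path = outdir / f"{sample.name}_R1.fastq"
        r2_path = outdir / f"{sample.name}_R2.fastq"
        emit_fastq_pairs(sim_config, r1_path, r2_path, outdir / f"{sample.name}_truth.tsv")
    else:
        r1_path, r2_path = Path(sample.r1), Path(sample.r2)
    r1 = list(read_fastq(r1_path, mate="R1"))
    r2 = list(read_fastq(r2_path, mate="R2"))
    return r1, r2


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every sample against every locus; write outputs under ``outdir``.

    Outputs per sample: pooled FASTA, filter report TSV; per sample x locus:
    per-read calls TSV and a summary JSON.  A combined ``summary.json``
    (timestamp-free, fixed 4-decimal percentages) captures the whole run.
    """
    logging.basicConfig(level=config.log_level, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, dict[str, EditingSummary]] = {}
    filter_reports: dict[str, dict] = {}
    for sample in config.samples:
        stage = "input"
        try:
            r1, r2 = _sample_reads(sample, config, outdir)
            stage = "preprocess"
            r1_kept, rep1 = quality_trim_and_filter(r1, config.q_threshold, config.trim_window)
            r2_kept, rep2 = quality_trim_and_filter(r2, config.q_threshold, config.trim_window)
            pool = pool_pairs(r1_kept, r2_kept)
            write_fasta(pool, outdir / f"{sample.name}_pooled.fasta")
            filter_reports[sample.name] = {
                "R1": dataclasses.asdict(rep1),
                "R2": dataclasses.asdict(rep2),
                "pooled": len(pool),
            }
            log.info(
                "%s: %d/%d R1 and %d/%d R2 reads passed Q%d filtering",
                sample.name, rep1.n_survived, rep1.n_input,
                rep2.n_survived, rep2.n_input, config.q_threshold,
            )
            summaries[sample.name] = {}
            for locus, insert in config.loci:
                stage = f"align/quantify locus {locus.name}"
                window = build_reference_window(locus, config.flank, insert)
                calls, summary, alignments = quantify_reads(
                    pool, window, config.scheme, call_hdr=bool(insert)
                )
                summaries[sample.name][locus.name] = summary
                rows = [
                    {
                        "read_id": call.read_id,
                        "category": call.category,
                        "ref_coverage": call.ref_coverage,
                        "gap_count": call.gap_count,
                        "insert_match": call.insert_match,
                        "score": aln.score,
                        "strand": aln.strand_used,
                        "cigar": cigar_string(aln),
                    }
                    for call, aln in zip(calls, alignments)
                ]
                pd.DataFrame(rows).to_csv(
                    outdir / f"{sample.name}_{locus.name}_calls.tsv", sep="\t", index=False
                )
                log.info(
                    "%s x %s: TE %.4f%%, HDR %.4f%% (%d informative, %d filtered)",
                    sample.name, locus.name, summary.te_pct, summary.hdr_pct,
                    summary.n_informative, summary.n_filtered,
                )
        except Exception as exc:
            raise PipelineError(f"sample {sample.name}, stage '{stage}': {exc}") from exc

    report = RunReport(
        summaries=summaries,
        filter_reports=filter_reports,
        version=_version(),
        config_echo=config.echo(),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    report.to_json(outdir / "summary.json")
    summary_rows = [
        {"sample": sample, "locus": locus, **s.as_dict()}
        for sample, by_locus in summaries.items()
        for locus, s in by_locus.items()
    ]
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return report


def compare_conditions(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Per-sample, per-locus deltas and fold changes between two runs.

    Fold changes against a zero baseline are reported as missing (NaN);
    deltas are always reported.  Both reports must cover identical
    sample x locus combinations.
    """
    keys_a = {(s, l) for s, d in report_a.summaries.items() for l in d}
    keys_b = {(s, l) for s, d in report_b.summaries.items() for l in d}
    if keys_a != keys_b:
        raise ComparisonError(
            f"reports cover different sample x locus sets: "
            f"{sorted(keys_a ^ keys_b)} not shared"
        )
    rows = []
    for sample, locus in sorted(keys_a):
        a = report_a.summaries[sample][locus]
        b = report_b.summaries[sample][locus]
        rows.append(
            {
                "sample": sample,
                "locus": locus,
                "te_pct_a": a.te_pct,
                "te_pct_b": b.te_pct,
                "delta_te_pct": b.te_pct - a.te_pct,
                "te_fold": (b.te_pct / a.te_pct) if a.te_pct > 0 else float("nan"),
                "hdr_pct_a": a.hdr_pct,
                "hdr_pct_b": b.hdr_pct,
                "delta_hdr_pct": b.hdr_pct - a.hdr_pct,
                "hdr_fold": (b.hdr_pct / a.hdr_pct) if a.hdr_pct > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def gel_estimates(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the gel estimators to a (sample, assay, a, b, c) table.

    ``assay`` selects the estimator: ``t7e1`` (square-root-corrected total
    editing) or ``rflp`` (direct HDR ratio).
    """
    rows = []
    for _, row in table.iterrows():
        bands = GelBands(float(row["a"]), float(row["b"]), float(row["c"]))
        assay = str(row["assay"]).lower()
        if assay == "t7e1":
            est = t7e1_total_editing(bands)
        elif assay == "rflp":
            est = hindiii_hdr(bands)
        else:
            raise ValueError(f"unknown assay {row['assay']!r} (want t7e1 or rflp)")
        rows.append({"sample": row["sample"], "assay": assay, "estimate_pct": round(est, 4)})
    return pd.DataFrame(rows)
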