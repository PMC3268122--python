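"""End-to-end pipeline orchestration with config and manifest.

The four stages: (1) consensus selection of DBG contigs from >= 2 de
novo assemblies, (2) input of comparative (A-) contig sets — one per
reference genome, produced externally or by the fixture generator,
(3) reliability filtering of A-contigs with DBG contigs, (4) overlap
merging into the hybrid assembly. Every stage writes its FASTA and TSV
report into the output directory; a manifest records the config, seed
and per-stage contig counts, so runs are byte-reproducible and stages
can be re-run from intermediates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .seqio import Assembly, read_fasta, write_fasta
from .mem_align import AlignParams
from .consensus import ConsensusParams, select_dbg_contigs, support_report
from .reliability import ReliabilityParams, select_reliable_acontigs, write_verdicts
from .merge import MergeParams, merge_assembly, write_joins
from .metrics import BonaFideParams, assembly_stats
from . import simulate


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; only the inputs (or a
    fixture block) are mandatory, every parameter defaults to the
    pipeline's standard value."""

    outdir: str = "reconasm_out"
    seed: int = 0
    assemblies: list[str] = field(default_factory=list)
    acontig_sets: list[str] = field(default_factory=list)
    truth_genome: str | None = None
    fixture: dict | None = None
    align: AlignParams = field(default_factory=AlignParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    reliability: ReliabilityParams = field(default_factory=ReliabilityParams)
    merge: MergeParams = field(default_factory=MergeParams)
    bona_fide: BonaFideParams = field(default_factory=BonaFideParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        align = AlignParams(**raw.get("align", {}))
        kwargs = dict(
            outdir=raw.get("outdir", "reconasm_out"),
            seed=int(raw.get("seed", 0)),
            assemblies=list(raw.get("assemblies", [])),
            acontig_sets=list(raw.get("acontig_sets", [])),
            truth_genome=raw.get("truth_genome"),
            fixture=raw.get("fixture"),
            align=align,
            consensus=ConsensusParams(**raw.get("consensus", {})),
            reliability=ReliabilityParams(**{"align": align, **raw.get("reliability", {})}),
            merge=MergeParams(**raw.get("merge", {})),
            bona_fide=BonaFideParams(**{"align": align, **raw.get("bona_fide", {})}),
        )
        return cls(**kwargs)


def _load_inputs(config: PipelineConfig):
    if config.fixture is not None:
        fx = simulate.build_fixture(seed=config.seed, **config.fixture)
        return fx.assemblies, fx.acontig_sets, fx.genome
    assemblies = [read_fasta(p) for p in config.assemblies]
    acontig_sets = [read_fasta(p) for p in config.acontig_sets]
    truth = None
    if config.truth_genome:
        truth_asm = read_fasta(config.truth_genome)
        truth = "".join(c.seq for c in truth_asm)
    return assemblies, acontig_sets, truth


def run_pipeline(config: PipelineConfig) -> tuple[Assembly, dict]:
    """Run all four stages; returns the hybrid assembly and a report
    dict (per-stage counts and stats)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assemblies, acontig_sets, truth = _load_inputs(config)

    if len(assemblies) < 2:
        raise PipelineError("consensus", "need at least 2 de novo assemblies")
    dbg = select_dbg_contigs(assemblies, config.consensus)
    if len(dbg) == 0:
        raise PipelineError(
            "consensus", "no contig reached the support threshold; nothing to build on"
        )
    write_fasta(dbg, outdir / "dbg.fa")
    support_report(assemblies, config.consensus, dbg, outdir / "dbg_support.tsv")

    if not acontig_sets:
        raise PipelineError("reliability", "no comparative contig sets supplied")
    reliable, verdicts = select_reliable_acontigs(
        acontig_sets, dbg, config.reliability
    )
    write_verdicts(verdicts, outdir / "verdicts.tsv")
    if len(reliable) > 0:
        write_fasta(reliable, outdir / "reliable.fa")

    hybrid, joins = merge_assembly(dbg, reliable, config.merge)
    write_fasta(hybrid, outdir / "hybrid.fa")
    write_joins(joins, outdir / "joins.tsv")

    report: dict = {
        "n_input_contigs": sum(len(a) for a in assemblies),
        "n_dbg": len(dbg),
        "n_acontigs": sum(len(a) for a in acontig_sets),
        "n_reliable": len(reliable),
        "n_excluded": sum(1 for v in verdicts if not v.reliable),
        "exclusion_reasons": {
            r: sum(1 for v in verdicts if v.reason == r)
            for r in ("too_short", "indel", "low_coverage")
        },
        "n_hybrid": len(hybrid),
        "n_joins": len(joins),
    }
    glen = len(truth) if truth else None
    stats_rows = []
    for name, asm in (("DBG", dbg), ("reliable_A", reliable), ("hybrid", hybrid)):
        if len(asm) == 0:
            continue
        st = assembly_stats(asm, genome_len=glen, truth_genome=truth, params=config.bona_fide)
        row = {"assembly": name, **asdict(st)}
        stats_rows.append(row)
        report[f"stats_{name}"] = row
    with open(outdir / "stats.tsv", "w") as fh:
        cols = [
            "assembly",
            "total_len",
            "n_contigs",
            "avg_len",
            "n50",
            "longest",
            "genome_fraction",
            "accuracy",
        ]
        fh.write("\t".join(cols) + "\n")
        for row in stats_rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "align": asdict(config.align),
            "consensus": asdict(config.consensus),
            "reliability": {
                k: v for k, v in asdict(config.reliability).items() if k != "align"
            },
            "merge": asdict(config.merge),
            "bona_fide": {
                k: v for k, v in asdict(config.bona_fide).items() if k != "align"
            },
            "fixture": config.fixture,
            "assemblies": config.assemblies,
            "acontig_sets": config.acontig_sets,
        },
        "report": report,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return hybrid, report
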