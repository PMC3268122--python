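"""Seeded validation suites exercising the pipeline end to end on the
standard synthetic study conditions.

Two suites:

* the comparative suite — repeat-bearing 100-kbp target genomes, three
  diverged references each in the 0.80-0.92 similarity band, a bona
  fide DBG tiling, and comparative contig sets carrying a
  reference-biased chimera at every divergent event. It measures the
  reliability filter's exclusion rate, the accuracy of the reliable
  set, and the accuracy of the merged hybrid assembly.
* the consensus suite — three de novo fixture assemblies per genome
  with independently planted chimeras; measures the accuracy of the
  consensus-selected DBG contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import build_fixture, generate_genome, make_fixture_assemblies
from .consensus import ConsensusParams, select_dbg_contigs
from .reliability import ReliabilityParams, select_reliable_acontigs
from .merge import merge_assembly
from .metrics import BonaFideParams, accuracy

DEFAULT_REPEATS = ((800, 3), (500, 2))


@dataclass
class ComparativeRecord:
    seed: int
    n_planted: int
    n_excluded: int
    n_dbg: int
    n_acontigs: int
    n_reliable: int
    n_hybrid: int
    reliable_accuracy: float
    hybrid_accuracy: float


def _suite_seed(base_seed: int, n_genomes: int, i: int) -> int:
    return (int(base_seed) - 1) * n_genomes + i + 1


def run_comparative_suite(
    base_seed: int = 1,
    n_genomes: int = 20,
    genome_len: int = 100_000,
    tau: float = 0.8,
    max_indel: int = 50,
) -> list[ComparativeRecord]:
    """Build one fixture per genome, run reliability filtering at the
    given threshold and merge, and measure exclusion and accuracies."""
    records = []
    params = ReliabilityParams(tau=tau, max_indel=max_indel)
    bf = BonaFideParams()
    for i in range(n_genomes):
        seed = _suite_seed(base_seed, n_genomes, i)
        fx = build_fixture(seed, genome_len=genome_len)
        reliable, verdicts = select_reliable_acontigs(fx.acontig_sets, fx.dbg, params)
        truth = {c.id: c.truth for aset in fx.acontig_sets for c in aset}
        planted = [cid for cid, t in truth.items() if t == "chimeric"]
        kept = set(reliable.ids())
        n_excluded = sum(1 for cid in planted if cid not in kept)
        rel_acc = accuracy(reliable, fx.genome, bf) if len(reliable) else 0.0
        hybrid, _joins = merge_assembly(fx.dbg, reliable)
        hyb_acc = accuracy(hybrid, fx.genome, bf)
        records.append(
            ComparativeRecord(
                seed=seed,
                n_planted=len(planted),
                n_excluded=n_excluded,
                n_dbg=len(fx.dbg),
                n_acontigs=sum(len(a) for a in fx.acontig_sets),
                n_reliable=len(reliable),
                n_hybrid=len(hybrid),
                reliable_accuracy=rel_acc,
                hybrid_accuracy=hyb_acc,
            )
        )
    return records


def pooled_exclusion_rate(records: list[ComparativeRecord]) -> float:
    planted = sum(r.n_planted for r in records)
    excluded = sum(r.n_excluded for r in records)
    return excluded / planted if planted else 0.0


def run_consensus_suite(
    base_seed: int = 1,
    n_genomes: int = 20,
    genome_len: int = 100_000,
    chimera_rate: float = 0.1,
) -> list[dict]:
    """Per genome: three fixture assemblies with independent chimeras,
    consensus selection at the default thresholds, accuracy of the
    selected set against the truth genome."""
    out = []
    bf = BonaFideParams()
    for i in range(n_genomes):
        seed = _suite_seed(base_seed, n_genomes, i)
        genome, _ann = generate_genome(genome_len, DEFAULT_REPEATS, seed)
        asms = make_fixture_assemblies(
            genome, n_assemblies=3, mean_contig_len=2000,
            chimera_rate=chimera_rate, seed=seed,
        )
        dbg = select_dbg_contigs(asms, ConsensusParams())
        n_chimeric = sum(1 for c in dbg if c.truth == "chimeric")
        out.append(
            {
                "seed": seed,
                "n_selected": len(dbg),
                "n_chimeric_selected": n_chimeric,
                "accuracy": accuracy(dbg, genome, bf),
            }
        )
    return out
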