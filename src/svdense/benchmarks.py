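"""Standard simulation benchmark protocols.

Desk-scale versions of the simulated benchmarking experiments: a 5 Mbp
diploid genome carrying ~400 SVs in the 50:50:5:5:1 type proportions
(DEL:INS:DUP:INV:TRA), the two-peak size model, a 2:1 het:hom ratio and
25x reads per haplotype; plus the ultra-large-insertion study (20
homozygous 20-30 kbp insertions on 2 Mbp at 50x total with 15 kbp mean
reads, so the events exceed the read length).  Both drive the caller on
oracle alignments, keeping the experiments aligner-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import EvalResult, compute_metrics, match_calls
from .pipeline import CallerConfig, call_svs
from .simulator import SimConfig, SizeModel, error_rng, simulate

BENCH_COUNTS = {"DEL": 180, "INS": 180, "DUP": 18, "INV": 18, "TRA": 4}


def discovery_benchmark_config(seed: int, preset: str = "pacbio-clr") -> SimConfig:
    """5 Mbp / ~400 SV discovery benchmark at 25x per haplotype."""
    return SimConfig(
        chrom_lengths={f"chr{i}": 1_250_000 for i in range(1, 5)},
        counts=dict(BENCH_COUNTS),
        depth=25.0,
        mean_read_length=15_000,
        preset=preset,
        seed=seed,
    )


def ultralarge_insertion_config(seed: int) -> SimConfig:
    """20 homozygous 20-30 kbp insertions vs 15 kbp mean reads at 50x."""
    return SimConfig(
        chrom_lengths={"chr1": 2_000_000},
        counts={"INS": 20},
        size_model=SizeModel(fixed_range=(20_000, 30_000)),
        het_fraction=0.0,
        depth=25.0,
        mean_read_length=15_000,
        preset="pacbio-clr",
        seed=seed,
    )


@dataclass
class BenchmarkRun:
    n_truth: int
    n_calls: int
    result: EvalResult

    @property
    def f1_percent(self) -> float:
        return 100 * self.result.overall.f1

    @property
    def exact_percent(self) -> float:
        return 100 * self.result.exact_fraction

    @property
    def within1_percent(self) -> float:
        return 100 * self.result.within1_fraction


def run_discovery_benchmark(
    cfg: SimConfig, caller: CallerConfig | None = None, min_size: int = 45
) -> BenchmarkRun:
    """Simulate, call on oracle alignments, and score with the TP rules."""
    res = simulate(cfg)
    records = res.records(cfg, error_rng(cfg))
    calls, _ = call_svs(records, res.genome, caller)
    passing = [c for c in calls if c.filter_status == "PASS"]
    ev = match_calls(res.truth, passing, min_size=min_size)
    return BenchmarkRun(len(res.truth), len(passing), ev)


def run_ultralarge_benchmark(cfg: SimConfig) -> BenchmarkRun:
    """INS recall restricted to the 20-30 kbp size bin."""
    res = simulate(cfg)
    records = res.records(cfg, error_rng(cfg))
    calls, _ = call_svs(records, res.genome)
    passing = [
        c for c in calls if c.filter_status == "PASS" and c.sv_type == "INS"
    ]
    big = [t for t in res.truth if 20_000 <= t.size <= 30_000]
    ev = match_calls(big, passing, min_size=45)
    return BenchmarkRun(len(big), len(passing), ev)
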