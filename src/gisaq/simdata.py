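"""Synthetic spike-in experiments with the statistical structure the method assumes.

The generator emulates the staggered mock-community benchmark used to
validate gradient spike-in quantification: ten organisms (five bacteria,
five fungi) and five internal standards spanning 10^4..10^8 copies per gram
in 10x steps, read counts log-linear in template amount with lognormal
noise,

    reads = round(10 ^ (a_true * log10(copies * recovery) + b_true + eps)),
    eps ~ Normal(0, sigma),

class-specific DNA-extraction recovery fractions drawn uniformly from the
observed per-class ranges, qPCR standard curves with Gaussian CT noise, and
error-bearing amplicon reads drawn from the standards' amplicon regions.
Everything is reproducible from a single integer seed.

What it does not emulate: PCR amplification bias, chimeras, sequencer
quality-score profiles, taxonomic misassignment. Results on synthetic data
demonstrate correctness of the estimator chain, not wet-lab performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .standards import InternalStandard, reverse_complement

# Staggered layouts: organism -> copies/g, mirroring the benchmark design
# (one decade per organism, bacteria and fungi interleaved over 1e4..1e8).
MOCK_BACTERIA = ["B_amyloliquefaciens", "L_fusiformis", "L_acetotolerans",
                 "W_paramesenteroides", "P_pentosaceus"]
MOCK_FUNGI = ["P_kudriavzevii", "N_castellii", "H_osmophila",
              "W_anomalus", "S_cerevisiae"]

DEFAULT_GRADIENT = {"IS1": 1e8, "IS2": 1e7, "IS3": 1e6, "IS4": 1e5, "IS5": 1e4}

# Per-class recovery-fraction ranges observed on solid substrate.
DEFAULT_RECOVERY = {
    "internal": (0.7002, 0.8390),
    "bacteria": (0.7187, 0.8710),
    "fungi": (0.7045, 0.8612),
}


def _staggered(names: Sequence[str], descending: bool) -> dict[str, float]:
    levels = [1e8, 1e7, 1e6, 1e5, 1e4]
    if not descending:
        levels = levels[::-1]
    return dict(zip(names, levels))


def default_taxa_truth() -> dict[str, dict[str, float]]:
    """Two staggered mock layouts: the second inverts the concentration order."""
    layout_a = {**_staggered(MOCK_BACTERIA, True), **_staggered(MOCK_FUNGI, True)}
    layout_b = {**_staggered(MOCK_BACTERIA, False), **_staggered(MOCK_FUNGI, False)}
    return {"mockA": layout_a, "mockB": layout_b}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic spike-in experiment.

    ``a_true``/``b_true`` define the log-log read-generation line; the
    default intercept puts the one-read detection limit near 10^4.2
    copies/g, inside the method's stated working range. ``sigma`` is the
    lognormal read noise in log10 units.
    """

    gradient: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GRADIENT))
    a_true: float = 0.95
    b_true: float = -4.0
    sigma: float = 0.1
    recovery: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY))
    taxa_truth: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_taxa_truth)
    read_length: int = 250
    substitution_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for lo, hi in self.recovery.values():
            if not (0.0 < lo <= hi <= 1.2):
                raise ValueError("recovery ranges must lie in (0, 1.2]")


@dataclass
class GroundTruth:
    """True copies/g behind a simulated experiment, for recovery studies."""

    taxa: pd.DataFrame        # taxa x samples, copies/g
    standards: pd.DataFrame   # standards x samples, copies/g
    params: dict


def _kingdom_of(taxon: str) -> str:
    if taxon in MOCK_FUNGI:
        return "fungi"
    if taxon in MOCK_BACTERIA:
        return "bacteria"
    return "bacteria"


def _draw_reads(copies: float, recovery: float, cfg: SimulationConfig,
                rng: np.random.Generator) -> int:
    eps = rng.normal(0.0, cfg.sigma) if cfg.sigma > 0 else 0.0
    log_reads = cfg.a_true * np.log10(copies * recovery) + cfg.b_true + eps
    return int(round(10.0 ** log_reads))


def simulate_mock_community(config: SimulationConfig,
                            ) -> tuple[GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Simulate feature-table counts for staggered mocks plus spike-ins.

    Returns ``(truth, community_table, standard_counts)``; both tables are
    features x samples with integer reads. Zero reads are possible at the
    low-concentration end, which exercises the detection-limit path.
    """
    rng = np.random.default_rng(config.seed)
    samples = list(config.taxa_truth)
    taxa = sorted({t for layout in config.taxa_truth.values() for t in layout})
    standards = list(config.gradient)

    truth_taxa = pd.DataFrame(0.0, index=taxa, columns=samples)
    truth_std = pd.DataFrame(0.0, index=standards, columns=samples)
    community = pd.DataFrame(0, index=taxa, columns=samples, dtype=int)
    std_counts = pd.DataFrame(0, index=standards, columns=samples, dtype=int)

    for s in samples:
        for sid in standards:
            copies = float(config.gradient[sid])
            truth_std.at[sid, s] = copies
            rec = rng.uniform(*config.recovery["internal"])
            std_counts.at[sid, s] = _draw_reads(copies, rec, config, rng)
        layout = config.taxa_truth[s]
        for taxon in taxa:
            copies = float(layout.get(taxon, 0.0))
            truth_taxa.at[taxon, s] = copies
            if copies <= 0:
                continue
            rec = rng.uniform(*config.recovery[_kingdom_of(taxon)])
            community.at[taxon, s] = _draw_reads(copies, rec, config, rng)

    truth = GroundTruth(taxa=truth_taxa, standards=truth_std,
                        params={"a_true": config.a_true, "b_true": config.b_true,
                                "sigma": config.sigma, "seed": config.seed})
    return truth, community, std_counts


def simulate_qpcr(true_curves: Mapping[str, tuple[float, float, str]],
                  sigma_ct: float, replicates: int,
                  gradient_log10: Sequence[float], seed: int) -> pd.DataFrame:
    """Gaussian-noise CT measurements on a dilution series.

    ``true_curves`` maps group -> (slope, intercept, kingdom). Returns a
    long-format table (group, kingdom, log10_conc, ct, replicate).
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, (slope, intercept, kingdom) in true_curves.items():
        for x in gradient_log10:
            for rep in range(replicates):
                ct = slope * x + intercept
                if sigma_ct > 0:
                    ct += rng.normal(0.0, sigma_ct)
                rows.append({"group": group, "kingdom": kingdom,
                             "log10_conc": float(x), "ct": float(ct),
                             "replicate": rep})
    return pd.DataFrame(rows)


def generate_reads(standards: Sequence[InternalStandard],
                   counts: Mapping[str, int], read_length: int = 250,
                   substitution_rate: float = 0.0, seed: int = 0,
                   region: str = "16S_V3V4") -> list[tuple[str, str]]:
    """Error-bearing reads drawn from standard amplicon regions.

    Each read is a random window of the amplicon on a random strand with iid
    substitutions; the true standard id is kept in the read identifier.
    Returns (read_id, sequence) pairs.
    """
    rng = np.random.default_rng(seed)
    by_id = {st.id: st for st in standards}
    reads: list[tuple[str, str]] = []
    for sid, n in counts.items():
        amplicon = by_id[sid].amplicon(region)
        if read_length > len(amplicon):
            raise ValueError(
                f"read_length {read_length} exceeds {sid} amplicon "
                f"({len(amplicon)} bp)")
        for i in range(int(n)):
            start = int(rng.integers(0, len(amplicon) - read_length + 1))
            seq = amplicon[start : start + read_length]
            if substitution_rate > 0:
                bases = list(seq)
                for j in range(len(bases)):
                    if rng.random() < substitution_rate:
                        bases[j] = str(rng.choice(
                            [b for b in "ACGT" if b != bases[j]]))
                seq = "".join(bases)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append((f"{sid}_read{i}", seq))
    return reads
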