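"""Tract-placement power simulations for the local-ancestry HMM.

Heterozygous donor tracts of fixed physical length are implanted at random
non-overlapping positions onto an unadmixed background genome, the HMM is run
on the result, and detection is scored at base-pair level.  Regions called
specialist in nearly all replicates are flagged: they behave like genuine
low-level specialist ancestry segregating in the "unadmixed" background
rather than artifacts of a particular placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import overlap_length, total_length
from .hmm import HMMParams, call_tracts, viterbi
from .synthetic import PanelPair

__all__ = ["PowerResult", "place_tracts", "run_power_experiment", "DEFAULT_TRACT_LENGTHS"]

DEFAULT_TRACT_LENGTHS = (500_000, 1_000_000, 2_000_000, 10_000_000)


@dataclass
class PowerResult:
    tract_length_bp: int
    n_replicates: int
    sensitivity: float  # fraction of truth tract bp recovered
    precision: float  # fraction of called bp inside truth
    recurrent_regions: pd.DataFrame  # chrom/start/end called in >= threshold of reps

    def __post_init__(self):
        if not (0 <= self.sensitivity <= 1 and 0 <= self.precision <= 1):
            raise ValueError("sensitivity/precision must be in [0, 1]")


def place_tracts(
    background: np.ndarray,
    donor_hap: np.ndarray,
    panel: PanelPair,
    tract_length: int,
    n_tracts: int = 5,
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
    background_haps: np.ndarray | None = None,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Implant heterozygous donor tracts onto an unadmixed background.

    ``n_tracts`` non-overlapping intervals of ``tract_length`` bp are drawn
    uniformly on each chromosome (rejection sampling).  Inside an interval the
    simulated genotype is one background allele plus the donor haplotype
    allele; the background allele comes from a randomly chosen background
    haplotype when ``background_haps`` (2, n_sites) is supplied, otherwise it
    is drawn Bernoulli(genotype/2).  Returns the simulated genotypes and the
    truth intervals (chrom, start, end; 0-based half-open).
    """
    rng = np.random.default_rng(seed)
    background = np.asarray(background)
    donor_hap = np.asarray(donor_hap)
    if background.shape != donor_hap.shape or background.ndim != 1:
        raise ValueError("background and donor must be 1-D on the same site grid")
    sim = background.copy()
    truth_rows = []
    slices = panel.chrom_slices()
    for chrom, sl in slices.items():
        pos = panel.sites["pos"].to_numpy(float)[sl]
        L = float(chrom_lengths[chrom]) if chrom_lengths else float(pos[-1])
        if tract_length > L:
            raise ValueError(f"tract length {tract_length} exceeds chromosome {chrom}")
        placed: list[tuple[float, float]] = []
        for _ in range(n_tracts):
            for attempt in range(max_attempts):
                start = float(rng.uniform(0, L - tract_length))
                end = start + tract_length
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise ValueError(
                    f"could not place {n_tracts} non-overlapping {tract_length}-bp "
                    f"tracts on {chrom}; use fewer or shorter tracts"
                )
        for start, end in sorted(placed):
            truth_rows.append((chrom, int(start), int(end)))
            inside = np.flatnonzero((pos - 1 >= start) & (pos - 1 < end)) + sl.start
            if inside.size == 0:
                continue
            if background_haps is not None:
                hap = int(rng.integers(2))
                bg_allele = np.asarray(background_haps)[hap, inside]
            else:
                bg_allele = (rng.random(inside.size) < background[inside] / 2.0).astype(np.int8)
            sim[inside] = bg_allele + donor_hap[inside]
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end"])
    return sim, truth


def run_power_experiment(
    background: np.ndarray,
    donor_hap: np.ndarray,
    panel: PanelPair,
    lengths=DEFAULT_TRACT_LENGTHS,
    n_replicates: int = 100,
    n_tracts: int = 5,
    params: HMMParams | None = None,
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
    background_haps: np.ndarray | None = None,
    recurrence_threshold: float = 0.95,
    min_sites: int = 2,
) -> list[PowerResult]:
    """Replicate tract-placement simulations and score HMM detection.

    Per tract length: ``n_replicates`` placements are simulated with
    per-replicate seeds split from the master seed, the Viterbi path is
    decoded, and bp-level sensitivity (truth bp recovered by heterozygous-or-
    better calls) and precision are pooled over replicates.  Sites called
    specialist in at least ``recurrence_threshold`` of replicates are emitted
    as recurrent regions.  Precision is 1 when nothing is called (no false
    positives).
    """
    params = params or HMMParams(T=50.0, alpha=0.1)
    results = []
    slices = panel.chrom_slices()
    ss_master = np.random.SeedSequence(seed)
    for li, length in enumerate(lengths):
        seeds = np.random.SeedSequence((seed if seed is not None else 0) + 7919 * li).spawn(
            n_replicates
        )
        truth_bp = called_bp = hit_bp = 0.0
        spec_counts = np.zeros(panel.n_sites)
        for rep_seed in seeds:
            sim, truth = place_tracts(
                background,
                donor_hap,
                panel,
                tract_length=int(length),
                n_tracts=n_tracts,
                seed=int(rep_seed.generate_state(1)[0] % (2**31)),
                chrom_lengths=chrom_lengths,
                background_haps=background_haps,
            )
            path = viterbi(sim, panel, params)
            spec_counts += path >= 1
            called = call_tracts(path, panel, min_sites=min_sites, chrom_lengths=chrom_lengths)
            for chrom, sl in slices.items():
                t = truth[truth["chrom"] == chrom]
                c = [x for x in called if x.chrom == chrom and x.dosage_class == "heterozygous"]
                cs = np.array([x.start_bp for x in c])
                ce = np.array([x.end_bp for x in c])
                truth_bp += total_length(t["start"], t["end"])
                called_bp += total_length(cs, ce)
                hit_bp += overlap_length(t["start"], t["end"], cs, ce)
        sensitivity = hit_bp / truth_bp if truth_bp else 1.0
        precision = hit_bp / called_bp if called_bp else 1.0
        freq = spec_counts / n_replicates
        results.append(
            PowerResult(
                tract_length_bp=int(length),
                n_replicates=n_replicates,
                sensitivity=float(sensitivity),
                precision=float(min(precision, 1.0)),
                recurrent_regions=_recurrent_regions(panel, freq >= recurrence_threshold),
            )
        )
    return results


def _recurrent_regions(panel: PanelPair, flagged: np.ndarray) -> pd.DataFrame:
    """Merge consecutive flagged sites into BED intervals."""
    rows = []
    for chrom, sl in panel.chrom_slices().items():
        pos = panel.sites["pos"].to_numpy(int)[sl]
        f = flagged[sl]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], f.astype(np.int8), [0]])))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            rows.append((chrom, int(pos[i0] - 1), int(pos[i1 - 1])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
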