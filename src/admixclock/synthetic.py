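"""Synthetic inputs with known ground truth for every pipeline stage.

Generators here emulate, at desk scale, the data the real analyses consume:

* differentiated allele-frequency panels (Balding-Nichols drift model),
* admixed diploid genomes whose ancestry tracts descend from a single
  admixture pulse T generations ago (exponential tract lengths in genetic
  distance -- exactly the process the local-ancestry HMM assumes),
* migration-rate trajectories manufactured from a calendar-time density
  under a known coalescent clock, so calibration can be validated by
  round-trip recovery,
* a unimodal historical-record stand-in on the 25-year 1500-1875 grid, and
* recombination maps (uniform or piecewise-heterogeneous).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import HistoricalRecord
from .coalescent import MigrationTrajectory, ScalingFactor

__all__ = [
    "RecombinationMap",
    "PanelPair",
    "AdmixtureTruth",
    "simulate_panel_freqs",
    "simulate_admixed_genomes",
    "generate_migration_trajectory",
    "generate_historical_record",
    "generate_recomb_map",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "DEFAULT_CHROM_LENGTHS",
]

# three chromosomes, desk-scale stand-ins for the three 400-Mb chromosomes
DEFAULT_CHROM_LENGTHS = {"1": 100_000_000, "2": 100_000_000, "3": 100_000_000}


@dataclass
class RecombinationMap:
    """Monotone bp -> centimorgan map per chromosome.

    ``points[chrom] = (pos_bp, cum_cM)`` with pos starting at 0 and ending at
    the chromosome length; cumulative cM strictly increasing (rates > 0), so
    the map is invertible.
    """

    points: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        clean = {}
        for chrom, (pos, cm) in self.points.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos[0] != 0 or np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must start at 0 and increase")
            if np.any(np.diff(cm) <= 0):
                raise ValueError(f"{chrom}: map must be strictly increasing")
            clean[chrom] = (pos, cm)
        self.points = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.points)

    def chrom_length(self, chrom: str) -> float:
        return float(self.points[chrom][0][-1])

    def total_morgans(self, chrom: str) -> float:
        return float(self.points[chrom][1][-1]) / 100.0

    def bp_to_morgans(self, chrom: str, pos) -> np.ndarray:
        p, cm = self.points[chrom]
        return np.interp(np.asarray(pos, dtype=float), p, cm) / 100.0

    def morgans_to_bp(self, chrom: str, morgans) -> np.ndarray:
        p, cm = self.points[chrom]
        return np.interp(np.asarray(morgans, dtype=float) * 100.0, cm, p)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for chrom, (pos, cm) in self.points.items():
            for x, c in zip(pos, cm):
                rows.append((chrom, int(x), c))
        pd.DataFrame(rows, columns=["chrom", "pos", "cM"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RecombinationMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        points = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            points[str(chrom)] = (sub["pos"].to_numpy(float), sub["cM"].to_numpy(float))
        return cls(points=points)


def generate_recomb_map(
    chrom_lengths_bp: dict[str, float] | None = None,
    rate_cM_per_Mb: float = 1.0,
    seed: int | None = None,
    n_pieces: int = 1,
    rate_sd: float = 0.0,
) -> RecombinationMap:
    """Recombination map, uniform or piecewise-heterogeneous.

    With ``n_pieces > 1`` and ``rate_sd > 0``, per-piece rates are drawn
    lognormally around ``rate_cM_per_Mb`` and then rescaled so the total map
    length of each chromosome equals that of the uniform map at the same mean
    rate.
    """
    if rate_cM_per_Mb <= 0:
        raise ValueError("rate must be positive")
    chrom_lengths_bp = dict(DEFAULT_CHROM_LENGTHS if chrom_lengths_bp is None else chrom_lengths_bp)
    if any(L <= 0 for L in chrom_lengths_bp.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    points = {}
    for chrom, L in chrom_lengths_bp.items():
        edges = np.linspace(0.0, float(L), n_pieces + 1)
        if n_pieces == 1 or rate_sd == 0:
            rates = np.full(n_pieces, rate_cM_per_Mb)
        else:
            rates = rate_cM_per_Mb * rng.lognormal(0.0, rate_sd, size=n_pieces)
            # preserve the uniform-map total at equal mean rate
            rates *= rate_cM_per_Mb * L / np.sum(rates * np.diff(edges))
        cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges) / 1e6)])
        points[chrom] = (edges, cm)
    return RecombinationMap(points=points)


@dataclass
class PanelPair:
    """Ancestry-informative sites with allele frequencies in two source panels.

    ``sites`` columns: chrom, pos (1-based bp), genetic_pos (Morgans),
    pA (specialist panel), pB (generalist panel), nA, nB (sampled alleles).
    """

    sites: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "pos", "genetic_pos", "pA", "pB", "nA", "nB"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        for col in ("pA", "pB"):
            v = self.sites[col].to_numpy(float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} outside [0, 1]")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if np.any(np.diff(sub["genetic_pos"].to_numpy()) < 0):
                raise ValueError(f"{chrom}: genetic positions decreasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Row slices per chromosome (sites are stored chromosome-major)."""
        out, start = {}, 0
        codes = self.sites["chrom"].to_numpy()
        for chrom in self.chromosomes:
            n = int(np.sum(codes == chrom))
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelPair":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def simulate_panel_freqs(
    n_sites: int,
    F: float,
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
    recomb_map: RecombinationMap | None = None,
    nA: int = 20,
    nB: int = 20,
) -> PanelPair:
    """Two allele-frequency panels diverged by a Balding-Nichols drift F.

    Ancestral frequencies are uniform on (0.05, 0.95); each panel frequency is
    an independent Beta(p(1-F)/F, (1-p)(1-F)/F) draw (F = 0 collapses to
    pA = pB = p exactly).  Site positions are uniform over the chromosomes.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0 <= F < 1):
        raise ValueError("F must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if recomb_map is None:
        recomb_map = generate_recomb_map(chrom_lengths, rate_cM_per_Mb=1.0)
    chroms = recomb_map.chromosomes
    lengths = np.array([recomb_map.chrom_length(c) for c in chroms])
    per_chrom = rng.multinomial(n_sites, lengths / lengths.sum())
    frames = []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        L = recomb_map.chrom_length(chrom)
        pos = np.sort(rng.choice(np.int64(L), size=n, replace=False)) + 1
        p = rng.uniform(0.05, 0.95, size=n)
        if F == 0:
            pA = pB = p
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            pA = rng.beta(a, b)
            pB = rng.beta(a, b)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "genetic_pos": recomb_map.bp_to_morgans(chrom, pos),
                    "pA": pA,
                    "pB": pB,
                    "nA": nA,
                    "nB": nB,
                }
            )
        )
    return PanelPair(sites=pd.concat(frames, ignore_index=True))


@dataclass
class AdmixtureTruth:
    """Ground truth of a single-pulse admixture simulation.

    ``tracts`` columns: individual, haplotype, chrom, start_bp, end_bp
    (0-based half-open), ancestry ("specialist" | "generalist"); tracts tile
    each haplotype's chromosome without overlap.
    """

    T_true: float
    alpha_true: float
    tracts: pd.DataFrame

    def specialist_fraction(self) -> float:
        t = self.tracts
        spans = t["end_bp"] - t["start_bp"]
        spec = spans[t["ancestry"] == "specialist"].sum()
        return float(spec / spans.sum())

    def specialist_tract_lengths_morgans(self, recomb_map: RecombinationMap) -> np.ndarray:
        t = self.tracts[self.tracts["ancestry"] == "specialist"]
        out = []
        for chrom, sub in t.groupby("chrom", sort=False):
            g0 = recomb_map.bp_to_morgans(chrom, sub["start_bp"].to_numpy())
            g1 = recomb_map.bp_to_morgans(chrom, sub["end_bp"].to_numpy())
            out.append(g1 - g0)
        return np.concatenate(out) if out else np.array([])

    def to_bed(self, path: str | Path, ancestry: str = "specialist") -> None:
        t = self.tracts[self.tracts["ancestry"] == ancestry]
        t = t.assign(name=t["individual"].astype(str) + "/" + t["haplotype"].astype(str))
        t[["chrom", "start_bp", "end_bp", "name"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "T_true": self.T_true,
                    "alpha_true": self.alpha_true,
                    "n_tracts": int(len(self.tracts)),
                    "specialist_fraction": self.specialist_fraction(),
                },
                fh,
                indent=2,
            )


def _sample_tracts(g_len: float, T: float, alpha: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Alternating exponential tract process on [0, g_len] Morgans.

    Returns (boundaries, states) where states[i] is True for specialist on
    [boundaries[i], boundaries[i+1]).  Specialist tracts are Exp((1-alpha)*T),
    generalist tracts Exp(alpha*T); the first state is Bernoulli(alpha).
    """
    state0 = bool(rng.random() < alpha)
    if alpha <= 0.0:
        return np.array([0.0, g_len]), np.array([False])
    if alpha >= 1.0:
        return np.array([0.0, g_len]), np.array([True])
    rate_s = (1 - alpha) * T
    rate_g = alpha * T
    mean_len = 0.5 / rate_s + 0.5 / rate_g
    n_guess = max(16, int(g_len / mean_len * 1.5) + 8)
    bounds = [0.0]
    states = []
    pos, state = 0.0, state0
    while pos < g_len:
        draws = rng.exponential(1.0, size=n_guess)
        for u in draws:
            length = u / (rate_s if state else rate_g)
            pos += length
            states.append(state)
            bounds.append(min(pos, g_len))
            state = not state
            if pos >= g_len:
                break
    return np.asarray(bounds), np.asarray(states, dtype=bool)


def simulate_admixed_genomes(
    panel: PanelPair,
    T: float,
    alpha: float,
    n_ind: int,
    error_rate: float = 0.01,
    seed: int | None = None,
    recomb_map: RecombinationMap | None = None,
) -> tuple[np.ndarray, AdmixtureTruth]:
    """Diploid genotypes from a single admixture pulse T generations ago.

    Per haplotype, ancestry along each chromosome is a two-state Markov
    process in genetic distance (exponential tract lengths); alleles are drawn
    from the local ancestry's panel frequency and flipped with ``error_rate``.
    Returns a (n_ind, n_sites) int8 genotype matrix (specialist-panel allele
    dosage) and the tract-level truth.
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if recomb_map is None:
        # linear fill-in consistent with the panel's own genetic positions
        points = {}
        for chrom, sl in panel.chrom_slices().items():
            sub = panel.sites.iloc[sl]
            L = float(sub["pos"].iloc[-1]) * 1.02
            G = float(sub["genetic_pos"].iloc[-1]) * 1.02 + 1e-9
            points[chrom] = (np.array([0.0, L]), np.array([0.0, G * 100]))
        recomb_map = RecombinationMap(points=points)

    n_sites = panel.n_sites
    genotypes = np.zeros((n_ind, n_sites), dtype=np.int8)
    tract_rows = []
    slices = panel.chrom_slices()
    pA_all = panel.sites["pA"].to_numpy(float)
    pB_all = panel.sites["pB"].to_numpy(float)
    for ind in range(n_ind):
        for hap in range(2):
            for chrom, sl in slices.items():
                g_len = recomb_map.total_morgans(chrom)
                bounds_m, states = _sample_tracts(g_len, T, alpha, rng)
                bounds_bp = recomb_map.morgans_to_bp(chrom, bounds_m)
                bounds_bp[0], bounds_bp[-1] = 0.0, recomb_map.chrom_length(chrom)
                site_g = panel.sites["genetic_pos"].to_numpy(float)[sl]
                idx = np.clip(np.searchsorted(bounds_m, site_g, side="right") - 1, 0, states.size - 1)
                is_spec = states[idx]
                p = np.where(is_spec, pA_all[sl], pB_all[sl])
                allele = (rng.random(p.size) < p).astype(np.int8)
                flip = rng.random(p.size) < error_rate
                allele[flip] = 1 - allele[flip]
                genotypes[ind, sl] += allele
                ib = np.rint(bounds_bp).astype(np.int64)
                ib[0], ib[-1] = 0, int(np.ceil(recomb_map.chrom_length(chrom)))
                for k in range(states.size):
                    if ib[k + 1] <= ib[k]:  # rounded away; skip zero-length tract
                        continue
                    tract_rows.append(
                        (
                            ind,
                            hap,
                            chrom,
                            int(ib[k]),
                            int(ib[k + 1]),
                            "specialist" if states[k] else "generalist",
                        )
                    )
    tracts = pd.DataFrame(
        tract_rows,
        columns=["individual", "haplotype", "chrom", "start_bp", "end_bp", "ancestry"],
    )
    return genotypes, AdmixtureTruth(T_true=float(T), alpha_true=float(alpha), tracts=tracts)


def generate_historical_record(
    shape: tuple[float, float] = (1775.0, 60.0),
    total: float = 100_000.0,
    seed: int | None = None,
) -> HistoricalRecord:
    """Unimodal stand-in record on the 25-year 1500-1875 grid.

    ``shape = (peak_year, width_years)`` parameterizes a Gaussian bump whose
    bin counts sum exactly to ``total`` (counts are real-valued; no rounding).
    The default peak late in the window mimics the documented crescendo of
    trans-Atlantic traffic in the 18th century.
    """
    peak_year, width = shape
    if not (1500 <= peak_year <= 1875):
        raise ValueError("peak_year must lie in [1500, 1875]")
    if width <= 0:
        raise ValueError("width must be positive")
    starts = 1500.0 + 25.0 * np.arange(15)
    centers = starts + 12.5
    w = np.exp(-0.5 * ((centers - peak_year) / width) ** 2)
    counts = total * w / w.sum()
    return HistoricalRecord(starts=starts, ends=starts + 25.0, counts=counts)


def generate_migration_trajectory(
    record_or_pulse: HistoricalRecord | tuple[float, float],
    s: ScalingFactor,
    n_segments: int = 32,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> MigrationTrajectory:
    """Migration trajectory whose calendar-time density is known exactly.

    The calendar density (a record's histogram, or a Gaussian pulse
    ``(center_year, width_years)``) is mapped to mutation-scaled time via
    t = years_BP * mu / g and integrated onto a piecewise-constant segment
    grid: the union of ``n_segments`` log-spaced boundaries with the images of
    the density's own bin edges, so that no segment straddles a calendar bin
    and the projection back onto the calendar grid is exact.  Cumulative
    migration reaches exactly 1 at the oldest boundary; multiplicative
    lognormal noise (``noise_sd``) perturbs the shape but the total is
    renormalized to 1.
    """
    if n_segments < 4:
        raise ValueError("n_segments must be >= 4")
    if isinstance(record_or_pulse, HistoricalRecord):
        edges_year = record_or_pulse.edges
        weights = record_or_pulse.counts / record_or_pulse.counts.sum()
    else:
        center, width = record_or_pulse
        if width <= 0:
            raise ValueError("pulse width must be positive")
        lo = max(center - 4 * width, 0.0)
        hi = min(center + 4 * width, s.present_year)
        edges_year = np.linspace(lo, hi, 65)
        c = 0.5 * (edges_year[:-1] + edges_year[1:])
        w = np.exp(-0.5 * ((c - center) / width) ** 2)
        weights = w / w.sum()
    if edges_year[-1] > s.present_year:
        raise ValueError("density extends past the present year")

    # calendar bin edges -> scaled time (older year -> larger t)
    t_edges = (s.present_year - edges_year[::-1]) * s.mu / s.g
    t_min, t_max = t_edges[0], t_edges[-1]
    log_grid = np.geomspace(max(t_min, t_max * 1e-4), t_max, n_segments + 1)
    bounds = np.unique(np.concatenate([t_edges, log_grid]))
    bounds = bounds[(bounds >= t_min) & (bounds <= t_max)]
    if t_min > 0:
        bounds = np.concatenate([[0.0], bounds])

    w_rev = weights[::-1]  # weight per calendar bin, oldest-last -> t ascending
    bin_of = np.clip(np.searchsorted(t_edges, bounds[:-1], side="right") - 1, 0, w_rev.size - 1)
    widths_t = np.diff(bounds)
    bin_widths_t = np.diff(t_edges)
    inside = (bounds[:-1] >= t_min - 1e-300) & (bounds[1:] <= t_max + 1e-300) & (bounds[:-1] >= t_min)
    mass = np.where(inside, w_rev[bin_of] * widths_t / bin_widths_t[bin_of], 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mass = mass * rng.lognormal(0.0, noise_sd, size=mass.size)
    mass = mass / mass.sum()
    m = np.where(widths_t > 0, mass / widths_t, 0.0)
    M = np.cumsum(mass)
    M[-1] = 1.0  # guard float drift at the plateau
    return MigrationTrajectory(left=bounds[:-1], right=bounds[1:], m=m, M=M)


# ---------------------------------------------------------------------------
# genotype serialization


def write_genotypes_tsv(path, genotypes: np.ndarray, panel: PanelPair, sample_names=None):
    """Site-major TSV: chrom, pos, then one dosage column per individual."""
    n_ind = genotypes.shape[0]
    names = sample_names or [f"ind{i}" for i in range(n_ind)]
    df = panel.sites[["chrom", "pos"]].copy()
    for i, name in enumerate(names):
        df[name] = genotypes[i]
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Inverse of :func:`write_genotypes_tsv`: (genotypes, site frame)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    genotypes = df[sample_cols].to_numpy(np.int8).T
    return genotypes, df[["chrom", "pos"]]


def write_genotypes_vcf(path, genotypes: np.ndarray, panel: PanelPair, sample_names=None):
    """Minimal GT-only VCF (unphased diploid dosages; ALT is the specialist-panel allele)."""
    import pysam

    n_ind = genotypes.shape[0]
    names = sample_names or [f"ind{i}" for i in range(n_ind)]
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, sl in panel.chrom_slices().items():
        end = int(panel.sites["pos"].iloc[sl].max()) + 1
        header.contigs.add(chrom, length=end)
    for name in names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(panel.sites.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, alleles=("A", "T")
            )
            for i in range(n_ind):
                g = int(genotypes[i, j])
                if g < 0:
                    rec.samples[names[i]]["GT"] = (None, None)
                else:
                    rec.samples[names[i]]["GT"] = (1, 1) if g == 2 else ((0, 1) if g == 1 else (0, 0))
            vcf.write(rec)


def read_genotypes_vcf(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a GT-only VCF into (dosage matrix, site frame); missing GT -> -1."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        rows, dosages = [], []
        for rec in vcf:
            rows.append((rec.contig, rec.pos))
            site = []
            for name in names:
                gt = rec.samples[name]["GT"]
                if gt is None or any(a is None for a in gt):
                    site.append(-1)
                else:
                    site.append(sum(gt))
            dosages.append(site)
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    return np.asarray(dosages, dtype=np.int8).T, sites
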