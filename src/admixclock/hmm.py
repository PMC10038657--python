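"""Diploid local-ancestry HMM with single-pulse admixture dating.

The model: all specialist gene flow into the focal population happened in a
single pulse T generations ago, contributing a proportion alpha of ancestry.
Each haplotype's ancestry along a chromosome is then a two-state Markov chain
in genetic distance with switch kernel

    Q(d) = exp(-d*T) * I + (1 - exp(-d*T)) * Pi,

Pi having stationary rows (alpha, 1-alpha).  An unphased diploid genome is
the product of two independent haploid chains collapsed to specialist-allele
dosage k in {0, 1, 2}; genotypes at ancestry-informative sites are emitted
from the source panels' allele frequencies with a symmetric error rate.

T is estimated by maximum likelihood over all individuals (the tract-length
signal: older pulses leave shorter tracts); confidence intervals come from a
block bootstrap over contiguous blocks of ancestry-informative sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from ._intervals import points_in_intervals, read_bed
from ._optim import grid_then_golden_max
from .synthetic import PanelPair

__all__ = [
    "HMMParams",
    "PulseTimeEstimate",
    "AncestryTract",
    "select_informative_sites",
    "transition_matrix",
    "emission_probs",
    "emission_matrix",
    "forward_backward",
    "viterbi",
    "pulse_loglik",
    "estimate_pulse_time",
    "bootstrap_pulse_time",
    "call_tracts",
    "estimate_alpha",
    "apply_mask",
    "AncestryPulseModel",
    "AncestryPulseResults",
]

MISSING = -1


@dataclass(frozen=True)
class HMMParams:
    """Single-pulse HMM parameters: pulse age T (generations), specialist
    proportion alpha, genotype error rate epsilon."""

    T: float
    alpha: float
    error_rate: float = 0.01

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("T must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def stationary(self) -> np.ndarray:
        a = self.alpha
        return np.array([(1 - a) ** 2, 2 * a * (1 - a), a**2])


@dataclass
class PulseTimeEstimate:
    """Per-chromosome admixture-pulse age with bootstrap CI."""

    chrom: str
    T_hat: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    alpha_used: float = np.nan
    n_sites: int = 0
    n_bootstrap: int = 0
    flat: bool = False

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.T_hat <= self.ci_high):
                raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class AncestryTract:
    """Called run of specialist ancestry, 0-based half-open."""

    chrom: str
    start_bp: int
    end_bp: int
    dosage_class: str  # "heterozygous" (dosage >= 1) or "homozygous" (dosage == 2)
    individual: str = "ind0"

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("tract end must exceed start")


# ---------------------------------------------------------------------------
# site selection


def select_informative_sites(
    panel: PanelPair,
    min_freq_diff: float = 0.3,
    min_alleles: int = 10,
    thin_bp: int = 10_000,
) -> PanelPair:
    """Ancestry-informative site filter with greedy physical thinning.

    Keeps sites with |pA - pB| strictly greater than ``min_freq_diff`` and at
    least ``min_alleles`` sampled alleles in each panel, then thins
    left-to-right within each chromosome so consecutive retained sites are at
    least ``thin_bp`` apart.
    """
    df = panel.sites
    n0 = len(df)
    diff_ok = (df["pA"] - df["pB"]).abs() > min_freq_diff
    n1 = int(diff_ok.sum())
    allele_ok = diff_ok & (df["nA"] >= min_alleles) & (df["nB"] >= min_alleles)
    n2 = int(allele_ok.sum())
    kept_idx = []
    for chrom, sub in df[allele_ok].groupby("chrom", sort=False):
        last = -np.inf
        for idx, pos in zip(sub.index, sub["pos"]):
            if pos - last >= thin_bp:
                kept_idx.append(idx)
                last = pos
    if not kept_idx:
        raise ValueError(
            "no sites survive selection "
            f"(input {n0}, after freq-diff filter {n1}, after allele-count filter {n2}, "
            "after thinning 0)"
        )
    return PanelPair(sites=df.loc[kept_idx].reset_index(drop=True))


# ---------------------------------------------------------------------------
# model primitives


def transition_matrix(d: float, params: HMMParams) -> np.ndarray:
    """Diploid dosage transition matrix over genetic distance d (Morgans).

    States are ordered by ascending specialist dosage (0, 1, 2); as d -> inf
    every row tends to the stationary ((1-a)^2, 2a(1-a), a^2).
    """
    if d < 0:
        raise ValueError("genetic distance must be >= 0")
    A = np.empty((3, 3))
    _kernels._fill_diploid_trans.py_func(np.exp(-d * params.T), params.alpha, A)
    return A


def emission_probs(g, k: int, pA: float, pB: float, eps: float) -> float:
    """P(genotype g | dosage k) under panel frequencies with error rate eps.

    ``g`` in {0, 1, 2} or missing (None / -1 / "missing"), which scores 1 for
    every dosage state.
    """
    if not (0 <= pA <= 1 and 0 <= pB <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    if g is None or g == MISSING or g == "missing":
        return 1.0
    if g not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {g!r}")
    a = pA * (1 - eps) + (1 - pA) * eps
    b = pB * (1 - eps) + (1 - pB) * eps
    if k == 2:
        row = [(1 - a) ** 2, 2 * a * (1 - a), a**2]
    elif k == 0:
        row = [(1 - b) ** 2, 2 * b * (1 - b), b**2]
    elif k == 1:
        row = [(1 - a) * (1 - b), a * (1 - b) + b * (1 - a), a * b]
    else:
        raise ValueError(f"invalid dosage state {k!r}")
    return float(row[g])


def emission_matrix(genotypes: np.ndarray, pA: np.ndarray, pB: np.ndarray, eps: float) -> np.ndarray:
    """Vectorized emissions, shape (n_ind, n_sites, 3); missing genotypes -> 1."""
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[None, :]
    a = pA * (1 - eps) + (1 - pA) * eps
    b = pB * (1 - eps) + (1 - pB) * eps
    # per-site emission rows for each dosage state
    rows = np.empty((3, len(a), 3))
    rows[0] = np.stack([(1 - b) ** 2, 2 * b * (1 - b), b**2], axis=1)
    rows[1] = np.stack([(1 - a) * (1 - b), a * (1 - b) + b * (1 - a), a * b], axis=1)
    rows[2] = np.stack([(1 - a) ** 2, 2 * a * (1 - a), a**2], axis=1)
    E = np.ones((g.shape[0], g.shape[1], 3))
    obs = g >= 0
    gi = np.clip(g, 0, 2)
    for k in range(3):
        Ek = np.take_along_axis(rows[k].T, gi, axis=0)  # (n_ind, n_sites) via broadcast
        E[:, :, k] = np.where(obs, Ek, 1.0)
    return E


def _chrom_data(genotypes: np.ndarray, panel: PanelPair, eps: float):
    """Per-chromosome (E, d) pairs for the kernels."""
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[None, :]
    if g.shape[1] != panel.n_sites:
        raise ValueError("genotype matrix does not match panel site count")
    out = {}
    pA = panel.sites["pA"].to_numpy(float)
    pB = panel.sites["pB"].to_numpy(float)
    gp = panel.sites["genetic_pos"].to_numpy(float)
    for chrom, sl in panel.chrom_slices().items():
        E = emission_matrix(g[:, sl], pA[sl], pB[sl], eps)
        d = np.diff(gp[sl])
        out[chrom] = (np.ascontiguousarray(E), d)
    return out


def forward_backward(
    genotypes: np.ndarray, panel: PanelPair, params: HMMParams, use_log: bool = False
) -> tuple[np.ndarray, float]:
    """Posterior dosage probabilities and log-likelihood for one individual.

    Chromosomes are independent chains started from the stationary
    distribution.  ``use_log`` switches to a pure log-space implementation
    (slow; used to validate the scaled recursion).
    """
    g = np.asarray(genotypes)
    if g.ndim != 1:
        raise ValueError("forward_backward expects one individual (1-D genotypes)")
    if g.size < 2:
        raise ValueError("need at least 2 sites")
    posts, loglik = [], 0.0
    for chrom, (E, d) in _chrom_data(g, panel, params.error_rate).items():
        if use_log:
            post, ll = _forward_backward_log(E[0], d, params)
        else:
            post, ll = _kernels.chain_forward_backward(E[0], d, params.T, params.alpha)
        if not np.isfinite(ll):
            raise ValueError(f"non-finite likelihood on chromosome {chrom}")
        posts.append(post)
        loglik += ll
    return np.vstack(posts), float(loglik)


def _forward_backward_log(E1: np.ndarray, d: np.ndarray, params: HMMParams):
    """Reference log-space forward-backward (one chain, one individual)."""
    n = E1.shape[0]
    with np.errstate(divide="ignore"):
        logE = np.log(E1)
        logpi = np.log(params.stationary)
        logA = [np.log(transition_matrix(x, params)) for x in d]
    la = np.empty((n, 3))
    la[0] = logpi + logE[0]
    for t in range(1, n):
        la[t] = logsumexp(la[t - 1][:, None] + logA[t - 1], axis=0) + logE[t]
    lb = np.zeros((n, 3))
    for t in range(n - 2, -1, -1):
        lb[t] = logsumexp(logA[t] + (logE[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(logsumexp(la[-1]))
    post = np.exp(la + lb - ll)
    post /= post.sum(axis=1, keepdims=True)
    return post, ll


def viterbi(genotypes: np.ndarray, panel: PanelPair, params: HMMParams) -> np.ndarray:
    """Most probable dosage path for one individual; ties go to lower dosage."""
    g = np.asarray(genotypes)
    if g.ndim != 1:
        raise ValueError("viterbi expects one individual (1-D genotypes)")
    paths = []
    for chrom, (E, d) in _chrom_data(g, panel, params.error_rate).items():
        path, score = _kernels.chain_viterbi(E[0], d, params.T, params.alpha)
        if not np.isfinite(score):
            raise ValueError(f"non-finite path score on chromosome {chrom}")
        paths.append(path)
    return np.concatenate(paths)


def pulse_loglik(
    genotypes: np.ndarray, panel: PanelPair, T: float, alpha: float, eps: float = 0.01
) -> float:
    """Total log-likelihood over all individuals and chromosomes at pulse age T."""
    total = 0.0
    for _, (E, d) in _chrom_data(genotypes, panel, eps).items():
        total += _kernels.chain_loglik(E, d, T, alpha)
    return float(total)


# ---------------------------------------------------------------------------
# pulse-time estimation


def apply_mask(genotypes: np.ndarray, panel: PanelPair, mask) -> tuple[np.ndarray, PanelPair]:
    """Drop sites inside BED mask intervals (0-based half-open).

    ``mask`` is a BED path or a DataFrame with chrom/start/end columns.
    """
    if mask is None:
        return genotypes, panel
    bed = read_bed(mask) if isinstance(mask, (str, Path)) else mask
    keep = np.ones(panel.n_sites, dtype=bool)
    pos0 = panel.sites["pos"].to_numpy(float) - 1.0  # 1-based site -> 0-based point
    for chrom, sub in bed.groupby("chrom", sort=False):
        in_chrom = (panel.sites["chrom"] == chrom).to_numpy()
        if not in_chrom.any():
            continue
        hit = points_in_intervals(
            pos0[in_chrom], sub["start"].to_numpy(float), sub["end"].to_numpy(float)
        )
        keep[np.flatnonzero(in_chrom)[hit]] = False
    g = np.asarray(genotypes)
    g2 = g[:, keep] if g.ndim == 2 else g[keep]
    return g2, PanelPair(sites=panel.sites[keep].reset_index(drop=True))


def estimate_pulse_time(
    genotypes: np.ndarray,
    panel: PanelPair,
    alpha: float,
    error_rate: float = 0.01,
    T_bounds: tuple[float, float] = (1.0, 10_000.0),
    mask=None,
    n_grid: int = 40,
    rel_tol: float = 1e-3,
    chrom: str = "all",
) -> PulseTimeEstimate:
    """Maximum-likelihood pulse age: coarse log-grid then golden-section.

    Deterministic for fixed inputs.  A likelihood flat to tolerance across the
    grid triggers a warning and returns the (geometric) midpoint, flagged.
    """
    genotypes, panel = apply_mask(genotypes, panel, mask)
    data = _chrom_data(genotypes, panel, error_rate)

    def objective(T: float) -> float:
        return sum(_kernels.chain_loglik(E, d, T, alpha) for E, d in data.values())

    grid = np.geomspace(T_bounds[0], T_bounds[1], n_grid)
    vals = np.array([objective(T) for T in grid])
    if np.nanmax(vals) - np.nanmin(vals) < 1e-6:
        warnings.warn("pulse-time likelihood is flat over T_bounds; returning midpoint")
        mid = float(np.sqrt(T_bounds[0] * T_bounds[1]))
        return PulseTimeEstimate(
            chrom=chrom, T_hat=mid, alpha_used=alpha, n_sites=panel.n_sites, flat=True
        )
    T_hat, _ = grid_then_golden_max(objective, grid, rel_tol=rel_tol, log_domain=True)
    return PulseTimeEstimate(
        chrom=chrom, T_hat=float(T_hat), alpha_used=alpha, n_sites=panel.n_sites
    )


def _site_blocks(panel: PanelPair, block_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous blocks of ``block_sites`` sites within each chromosome."""
    starts, stops = [], []
    for chrom, sl in panel.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        for s in range(lo, hi, block_sites):
            starts.append(s)
            stops.append(min(s + block_sites, hi))
    return np.asarray(starts, dtype=np.int64), np.asarray(stops, dtype=np.int64)


def bootstrap_pulse_time(
    genotypes: np.ndarray,
    panel: PanelPair,
    alpha: float,
    error_rate: float = 0.01,
    T_bounds: tuple[float, float] = (1.0, 10_000.0),
    block_sites: int = 1000,
    n_bootstrap: int = 80,
    seed: int | None = None,
    T_hat: float | None = None,
    mask=None,
    grid_size: int = 120,
) -> PulseTimeEstimate:
    """Block-bootstrap 95% CI for the pulse age.

    Sites are partitioned into contiguous blocks of ``block_sites`` within
    each chromosome; each of ``n_bootstrap`` replicates redraws that many
    blocks with replacement, scoring each resampled block as an independent
    chain (additive log-likelihood).  Replicate ages are re-estimated on a
    dense cached log-grid with parabolic refinement; the CI is the 2.5/97.5
    percentile interval, widened if needed to contain the full-data estimate.
    """
    genotypes, panel = apply_mask(genotypes, panel, mask)
    starts, stops = _site_blocks(panel, block_sites)
    n_blocks = starts.size
    if n_blocks < 2:
        raise ValueError(f"need at least 2 blocks, got {n_blocks}")
    # flatten chromosomes into one concatenated array; blocks never straddle
    # chromosome boundaries so junction distances are never used
    data = _chrom_data(genotypes, panel, error_rate)
    E = np.concatenate([E for E, _ in data.values()], axis=1)
    d = np.concatenate(
        [np.concatenate([dd, [0.0]]) for _, dd in data.values()]
    )[:-1]
    Tgrid = np.geomspace(T_bounds[0], T_bounds[1], grid_size)
    B = np.empty((grid_size, n_blocks))
    for i, T in enumerate(Tgrid):
        _kernels.block_logliks(E, d, starts, stops, T, alpha, B[i])
    logT = np.log(Tgrid)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for r in range(n_bootstrap):
        counts = np.bincount(rng.integers(0, n_blocks, n_blocks), minlength=n_blocks)
        obj = B @ counts
        k = int(np.argmax(obj))
        if 0 < k < grid_size - 1:
            y0, y1, y2 = obj[k - 1], obj[k], obj[k + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            reps[r] = np.exp(logT[k] + shift * (logT[1] - logT[0]))
        else:
            reps[r] = Tgrid[k]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    if T_hat is None:
        est = estimate_pulse_time(
            genotypes, panel, alpha, error_rate=error_rate, T_bounds=T_bounds
        )
        T_hat = est.T_hat
    return PulseTimeEstimate(
        chrom="all",
        T_hat=float(T_hat),
        ci_low=float(min(lo, T_hat)),
        ci_high=float(max(hi, T_hat)),
        alpha_used=alpha,
        n_sites=panel.n_sites,
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# tract calling and admixture proportion


def call_tracts(
    path: np.ndarray,
    panel: PanelPair,
    min_sites: int = 2,
    chrom_lengths: dict[str, float] | None = None,
    individual: str = "ind0",
) -> list[AncestryTract]:
    """Emit specialist-ancestry tracts from a decoded dosage path.

    Maximal runs of dosage >= 1 become heterozygous tracts and sub-runs of
    dosage 2 homozygous tracts (so homozygous tracts nest inside heterozygous
    ones).  Tract bounds are placed midway between the outermost inside-site
    and the first outside-site; runs touching a chromosome end extend to the
    chromosome bounds when ``chrom_lengths`` is given, else to the site.
    """
    path = np.asarray(path)
    tracts: list[AncestryTract] = []
    for chrom, sl in panel.chrom_slices().items():
        pos = panel.sites["pos"].to_numpy(float)[sl]
        sub = path[sl]
        L = None if chrom_lengths is None else float(chrom_lengths[chrom])

        def bounds(i0, i1):
            start = 0.0 if (i0 == 0 and L is not None) else (
                pos[i0] if i0 == 0 else 0.5 * (pos[i0 - 1] + pos[i0])
            )
            last = i1 - 1
            end = (
                L
                if (i1 == pos.size and L is not None)
                else (pos[last] if i1 == pos.size else 0.5 * (pos[last] + pos[i1]))
            )
            return int(start), int(np.ceil(end))

        for cls, pred in (("heterozygous", sub >= 1), ("homozygous", sub == 2)):
            edges = np.flatnonzero(np.diff(np.concatenate([[0], pred.view(np.int8), [0]])))
            for i0, i1 in zip(edges[::2], edges[1::2]):
                if i1 - i0 < min_sites:
                    continue
                s, e = bounds(i0, i1)
                if e > s:
                    tracts.append(AncestryTract(chrom, s, e, cls, individual))
    return tracts


def estimate_alpha(
    genotypes: np.ndarray,
    panel: PanelPair,
    error_rate: float = 0.01,
    T_bounds: tuple[float, float] = (1.0, 10_000.0),
    tol: float = 1e-4,
    max_iter: int = 50,
    n_grid: int = 20,
) -> tuple[float, float, list[float]]:
    """Admixture proportion by EM-style iteration of the HMM.

    Alternates a coarse-grid refresh of T with an update of alpha to the mean
    posterior dosage / 2; stops when |delta alpha| < tol.  Returns
    (alpha_hat, T_at_convergence, alpha_history); warns on non-convergence.
    """
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[None, :]
    if panel.n_sites < 100:
        raise ValueError("need at least 100 sites to estimate alpha")
    Tgrid = np.geomspace(T_bounds[0], T_bounds[1], n_grid)
    alpha = 0.5
    history = [alpha]
    T_cur = float(Tgrid[n_grid // 2])
    for _ in range(max_iter):
        data = _chrom_data(g, panel, error_rate)
        vals = [
            sum(_kernels.chain_loglik(E, d, T, alpha) for E, d in data.values())
            for T in Tgrid
        ]
        T_cur = float(Tgrid[int(np.argmax(vals))])
        dosage = 0.0
        for E, d in data.values():
            for i in range(g.shape[0]):
                post, _ = _kernels.chain_forward_backward(E[i], d, T_cur, alpha)
                dosage += float(post[:, 1].sum() + 2.0 * post[:, 2].sum())
        new_alpha = dosage / (2.0 * g.shape[0] * panel.n_sites)
        new_alpha = float(np.clip(new_alpha, 1e-4, 1 - 1e-4))
        history.append(new_alpha)
        done = abs(new_alpha - alpha) < tol
        alpha = new_alpha
        if done:
            break
    else:
        warnings.warn(f"alpha estimation did not converge; trajectory {history}")
    return alpha, T_cur, history


# ---------------------------------------------------------------------------
# model / results


class AncestryPulseModel:
    """Single-pulse local-ancestry model over ancestry-informative sites.

    Parameters
    ----------
    genotypes : (n_ind, n_sites) int array of specialist-allele dosages,
        -1 for missing, aligned with ``panel.sites`` rows.
    panel : PanelPair of ancestry-informative sites (already filtered).
    alpha : admixture proportion; a scalar, a {chrom: value} dict, or None to
        estimate per chromosome from the data.
    error_rate : genotype error rate epsilon.
    mask : optional BED (path or DataFrame) of regions excluded from *timing*
        estimation; tract decoding always runs unmasked.
    """

    def __init__(self, genotypes, panel: PanelPair, alpha=None, error_rate: float = 0.01, mask=None):
        self.genotypes = np.asarray(genotypes)
        if self.genotypes.ndim == 1:
            self.genotypes = self.genotypes[None, :]
        if self.genotypes.shape[1] != panel.n_sites:
            raise ValueError("genotypes/panel site mismatch")
        self.panel = panel
        self.alpha = alpha
        self.error_rate = float(error_rate)
        self.mask = mask

    @classmethod
    def from_files(
        cls, genotype_path, panel_path, map_path=None, mask=None, alpha=None,
        error_rate: float = 0.01, vcf: bool | None = None,
    ) -> "AncestryPulseModel":
        """Build from TSV/VCF genotypes + panel TSV (+ optional map TSV)."""
        from .synthetic import RecombinationMap, read_genotypes_tsv, read_genotypes_vcf

        panel = PanelPair.from_tsv(panel_path)
        if map_path is not None:
            rmap = RecombinationMap.from_tsv(map_path)
            panel.sites["genetic_pos"] = np.concatenate(
                [
                    rmap.bp_to_morgans(chrom, panel.sites["pos"].to_numpy(float)[sl])
                    for chrom, sl in panel.chrom_slices().items()
                ]
            )
        if vcf is None:
            vcf = str(genotype_path).endswith((".vcf", ".vcf.gz"))
        geno, sites = (read_genotypes_vcf if vcf else read_genotypes_tsv)(genotype_path)
        key_g = list(zip(sites["chrom"].astype(str), sites["pos"].astype(int)))
        key_p = list(zip(panel.sites["chrom"].astype(str), panel.sites["pos"].astype(int)))
        lookup = {k: i for i, k in enumerate(key_g)}
        idx = [lookup[k] for k in key_p if k in lookup]
        keep = [j for j, k in enumerate(key_p) if k in lookup]
        panel = PanelPair(sites=panel.sites.iloc[keep].reset_index(drop=True))
        return cls(geno[:, idx], panel, alpha=alpha, error_rate=error_rate, mask=mask)

    def _chrom_subset(self, chrom: str):
        sl = self.panel.chrom_slices()[chrom]
        sub = PanelPair(sites=self.panel.sites.iloc[sl].reset_index(drop=True))
        return self.genotypes[:, sl], sub

    def _alpha_for(self, chrom: str, genotypes, panel) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha[chrom])
        if self.alpha is not None:
            return float(self.alpha)
        a, _, _ = estimate_alpha(genotypes, panel, error_rate=self.error_rate)
        return a

    def loglike(self, T: float, alpha: float | None = None, chrom: str | None = None) -> float:
        """Masked log-likelihood at pulse age T (summed over individuals)."""
        g, p = (self.genotypes, self.panel) if chrom is None else self._chrom_subset(chrom)
        g, p = apply_mask(g, p, self.mask)
        if alpha is None:
            alpha = self._alpha_for(chrom or p.chromosomes[0], g, p)
        return pulse_loglik(g, p, T, alpha, self.error_rate)

    def fit(
        self,
        T_bounds: tuple[float, float] = (1.0, 10_000.0),
        block_sites: int = 1000,
        n_bootstrap: int = 80,
        seed: int | None = None,
    ) -> "AncestryPulseResults":
        """Per-chromosome ML pulse ages with block-bootstrap CIs."""
        seeds = np.random.SeedSequence(seed).spawn(len(self.panel.chromosomes))
        estimates = []
        for chrom, ss in zip(self.panel.chromosomes, seeds):
            g, p = self._chrom_subset(chrom)
            g, p = apply_mask(g, p, self.mask)
            alpha = self._alpha_for(chrom, g, p)
            point = estimate_pulse_time(
                g, p, alpha, error_rate=self.error_rate, T_bounds=T_bounds, chrom=chrom
            )
            # small chromosomes: shrink blocks so the jackknife-style resampling
            # still has at least ~8 blocks to draw from
            bs = block_sites if p.n_sites // block_sites >= 2 else max(1, p.n_sites // 8)
            boot = bootstrap_pulse_time(
                g,
                p,
                alpha,
                error_rate=self.error_rate,
                T_bounds=T_bounds,
                block_sites=bs,
                n_bootstrap=n_bootstrap,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                T_hat=point.T_hat,
            )
            estimates.append(replace(boot, chrom=chrom, flat=point.flat))
        return AncestryPulseResults(self, estimates)


class AncestryPulseResults:
    """Fitted pulse ages per chromosome plus unmasked local-ancestry decoding."""

    def __init__(self, model: AncestryPulseModel, estimates: list[PulseTimeEstimate]):
        self.model = model
        self.chrom_estimates = estimates

    @property
    def estimates(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": e.chrom,
                    "T_hat": e.T_hat,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "alpha": e.alpha_used,
                    "n_sites": e.n_sites,
                    "n_bootstrap": e.n_bootstrap,
                }
                for e in self.chrom_estimates
            ]
        )

    @property
    def mean_T(self) -> float:
        """Cross-chromosome mean pulse age (the thick-line summary)."""
        return float(np.mean([e.T_hat for e in self.chrom_estimates]))

    def conf_int(self) -> pd.DataFrame:
        return self.estimates[["chrom", "ci_low", "ci_high"]]

    def _params_for(self, chrom: str) -> HMMParams:
        e = next(x for x in self.chrom_estimates if x.chrom == chrom)
        return HMMParams(T=e.T_hat, alpha=e.alpha_used, error_rate=self.model.error_rate)

    def viterbi_paths(self) -> np.ndarray:
        """Unmasked Viterbi dosage paths, shape (n_ind, n_sites)."""
        out = np.empty_like(self.model.genotypes)
        for chrom in self.model.panel.chromosomes:
            sl = self.model.panel.chrom_slices()[chrom]
            sub = PanelPair(sites=self.model.panel.sites.iloc[sl].reset_index(drop=True))
            params = self._params_for(chrom)
            for i in range(self.model.genotypes.shape[0]):
                out[i, sl] = viterbi(self.model.genotypes[i, sl], sub, params)
        return out

    def posteriors(self, individual: int) -> np.ndarray:
        """Unmasked posterior dosage probabilities for one individual."""
        posts = []
        for chrom in self.model.panel.chromosomes:
            sl = self.model.panel.chrom_slices()[chrom]
            sub = PanelPair(sites=self.model.panel.sites.iloc[sl].reset_index(drop=True))
            post, _ = forward_backward(
                self.model.genotypes[individual, sl], sub, self._params_for(chrom)
            )
            posts.append(post)
        return np.vstack(posts)

    def tracts(self, min_sites: int = 2, chrom_lengths=None) -> list[AncestryTract]:
        paths = self.viterbi_paths()
        out = []
        for i in range(paths.shape[0]):
            out.extend(
                call_tracts(
                    paths[i],
                    self.model.panel,
                    min_sites=min_sites,
                    chrom_lengths=chrom_lengths,
                    individual=f"ind{i}",
                )
            )
        return out

    def ancestry_profile(self) -> np.ndarray:
        """Per-site specialist-ancestry proportion across individuals."""
        paths = self.viterbi_paths()
        return paths.sum(axis=0) / (2.0 * paths.shape[0])

    def summary(self) -> str:
        lines = [
            "Single-pulse admixture dating",
            "=============================",
            f"individuals             {self.model.genotypes.shape[0]}",
            f"ancestry-informative sites  {self.model.panel.n_sites}",
            "",
            self.estimates.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            f"mean pulse age across chromosomes: {self.mean_T:.1f} generations",
        ]
        return "\n".join(lines)

    def plot_tracts(self, chrom_lengths=None, ax=None):
        """Karyotype-style tract plot (purple heterozygous, red homozygous)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        chroms = self.model.panel.chromosomes
        n_ind = self.model.genotypes.shape[0]
        tracts = self.tracts(chrom_lengths=chrom_lengths)
        for t in tracts:
            row = int(t.individual.removeprefix("ind")) + chroms.index(t.chrom) * (n_ind + 1)
            color = "purple" if t.dosage_class == "heterozygous" else "red"
            z = 1 if t.dosage_class == "heterozygous" else 2
            ax.plot([t.start_bp, t.end_bp], [row, row], color=color, lw=3, zorder=z)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("individual x chromosome")
        return ax
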