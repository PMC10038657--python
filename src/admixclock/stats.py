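"""Admixture statistics: f3 test with block jackknife and the circular
chromosome permutation test for shared local-ancestry hotspots.

The f3 statistic f3(X; A, B) = E[(pX-pA)(pX-pB)] - hX/nX tests whether focal
allele frequencies are consistently intermediate between two candidate
sources; a significantly negative genome-wide mean is evidence of admixture
(a positive value is evidence neither for nor against).  The finite-sample
correction hX/nX = pX(1-pX)/(nX-1) removes the bias contributed by sampling
noise in the focal frequency estimate.  Standard errors come from a
delete-one block jackknife over contiguous SNP blocks, robust to linkage.

The circular permutation test asks whether two populations' per-site local
ancestry proportions co-vary along the genome more than chance allows: each
permutation rotates every chromosome of one profile by an independent uniform
offset, preserving within-chromosome autocorrelation while destroying the
cross-population alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "F3Result",
    "PermutationResult",
    "f3",
    "ancestry_profile",
    "circular_permutation_test",
]


@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    def __str__(self):
        return (
            f"f3 = {self.f3:.6g} +/- {self.se:.3g} (Z = {self.z:.2f}, "
            f"{self.n_sites} sites in {self.n_blocks} jackknife blocks)"
        )


def _freqs(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be (n_sites, 2) ref/alt allele counts")
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts[:, 1] / n
    return p, n


def f3(
    focal_counts: np.ndarray,
    sourceA_counts: np.ndarray,
    sourceB_counts: np.ndarray,
    block_size_sites: int = 500,
    maf: float = 0.05,
) -> F3Result:
    """Patterson-style f3(X; A, B) with block-jackknife Z score.

    Inputs are per-site (ref, alt) allele counts for the focal population and
    the two candidate sources.  Sites with a zero sample in any population
    are dropped, then a pooled minor-allele-frequency filter (> ``maf``) is
    applied.  Symmetric in the two sources.
    """
    px, nx = _freqs(focal_counts)
    pa, na = _freqs(sourceA_counts)
    pb, nb = _freqs(sourceB_counts)
    if not (px.size == pa.size == pb.size):
        raise ValueError("populations must share the site grid")
    ok = (nx > 0) & (na > 0) & (nb > 0) & (nx > 1)
    tot_alt = np.where(ok, px * nx + pa * na + pb * nb, 0.0)
    tot = np.where(ok, nx + na + nb, 1.0)
    pooled = tot_alt / tot
    ok &= np.minimum(pooled, 1 - pooled) > maf
    if ok.sum() < 2:
        raise ValueError("too few usable sites after filtering")
    px, nx, pa, pb = px[ok], nx[ok], pa[ok], pb[ok]
    stat = (px - pa) * (px - pb) - px * (1 - px) / (nx - 1)

    n_sites = stat.size
    edges = np.arange(0, n_sites + block_size_sites, block_size_sites)
    edges[-1] = min(edges[-1], n_sites)
    edges = np.unique(edges)
    m = edges.size - 1
    if m < 2:
        raise ValueError(f"need at least 2 jackknife blocks, got {m}")
    total = stat.sum()
    theta = total / n_sites
    loo = np.empty(m)
    for j in range(m):
        s, e = edges[j], edges[j + 1]
        loo[j] = (total - stat[s:e].sum()) / (n_sites - (e - s))
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    z = theta / se if se > 0 else np.inf * np.sign(theta)
    return F3Result(f3=float(theta), se=se, z=float(z), n_blocks=m, n_sites=n_sites)


def ancestry_profile(paths: np.ndarray) -> np.ndarray:
    """Per-site specialist-ancestry proportion from decoded dosage paths.

    ``paths``: (n_individuals, n_sites) dosage matrix for one population;
    returns sum(dosage)/(2*n_individuals) per site, in [0, 1].
    """
    paths = np.asarray(paths)
    if paths.ndim != 2:
        raise ValueError("paths must be (n_individuals, n_sites)")
    return paths.sum(axis=0) / (2.0 * paths.shape[0])


@dataclass
class PermutationResult:
    r_obs: float
    null_r: np.ndarray
    p: float
    n_perm: int
    seed: int | None = None

    def __str__(self):
        return f"r = {self.r_obs:.4f}, permutation p = {self.p:.4g} ({self.n_perm} permutations)"


def circular_permutation_test(
    profileA: np.ndarray,
    profileB: np.ndarray,
    chrom_labels: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Circular-chromosome permutation test of the Pearson correlation.

    Each permutation independently rotates each chromosome of ``profileB`` by
    a uniform random offset (the value multiset and internal spatial
    structure of each chromosome are preserved).  One-sided for positive
    correlation by default; ``alternative='two-sided'`` available.  The
    p-value uses the add-one convention: p = (1 + #{null >= obs})/(1+n_perm).
    """
    a = np.asarray(profileA, dtype=float)
    b = np.asarray(profileB, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and share the locus grid")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant profile: correlation undefined")
    if chrom_labels is None:
        chrom_labels = np.zeros(a.size, dtype=int)
    chrom_labels = np.asarray(chrom_labels)
    slices = []
    start = 0
    for lab in dict.fromkeys(chrom_labels.tolist()):
        n = int(np.sum(chrom_labels == lab))
        slices.append(slice(start, start + n))
        start += n
    rng = np.random.default_rng(seed)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    # all rotations materialized at once: perm[i, sl] = roll(b[sl], offset[i])
    perm = np.empty((n_perm, b.size))
    for sl in slices:
        seg = b[sl]
        offsets = rng.integers(seg.size, size=n_perm)
        idx = (np.arange(seg.size)[None, :] - offsets[:, None]) % seg.size
        perm[:, sl] = seg[idx]
    ac = a - a.mean()
    pc = perm - perm.mean(axis=1, keepdims=True)
    null = (pc @ ac) / np.sqrt((pc**2).sum(axis=1) * (ac**2).sum())
    if alternative == "greater":
        p = (1 + int(np.sum(null >= r_obs))) / (1 + n_perm)
    elif alternative == "two-sided":
        p = (1 + int(np.sum(np.abs(null) >= abs(r_obs)))) / (1 + n_perm)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return PermutationResult(r_obs=r_obs, null_r=null, p=float(p), n_perm=n_perm, seed=seed)
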