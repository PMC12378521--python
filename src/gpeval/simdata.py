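"""Simulation of diploid SNP panels and polygenic quantitative traits.

The generator emulates the statistical structure a whole-genome
resequencing panel of a farmed fish population presents to genomic
prediction: hundreds of individuals, thousands to millions of biallelic
SNPs over multiple chromosomes, a tunable minor-allele-frequency spectrum,
local linkage disequilibrium that decays with physical distance, optional
subpopulation structure, and a quantitative trait controlled by a chosen
number of QTLs at a chosen narrow-sense heritability.

Linkage disequilibrium is produced at the haplotype level by a first-order
latent-Gaussian process along each chromosome: adjacent markers at distance
``d`` bp have latent correlation ``exp(-ld_decay * d)``, haplotypes are then
paired into diploids.  Subpopulation differentiation follows the
Balding-Nichols construction (subpopulation allele frequencies drawn from a
Beta distribution around the ancestral frequency with variance
``fst * q * (1 - q)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import GenomeLayout, GenotypeMatrix, PhenotypeSet

__all__ = [
    "TraitArchitecture",
    "random_layout",
    "simulate_genotypes",
    "simulate_phenotypes",
]

#: Trait location/scale defaults: juvenile body weight in grams of a farmed
#: marine fish cohort (mean 655.64 g, sd 213.15 g).
TRAIT_MEAN = 655.64
TRAIT_SD = 213.15


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of the simulated quantitative trait.

    Parameters
    ----------
    n_qtl
        Number of causal loci, drawn from the typed markers.
    h2
        Target narrow-sense heritability in [0, 1].
    effect_distribution
        ``"gaussian"``, ``"laplace"``, ``"point-normal"`` (a fraction
        ``sparsity`` of the drawn QTL effects is set to zero), or ``"equal"``
        (fixed magnitude, random sign — the designed-power configuration
        where every QTL carries a detectable share of the variance).
    qtl_placement
        ``"random"`` (uniform without replacement) or ``"evenly"``
        (evenly spaced column indices).
    hide_qtl
        If True the causal columns are removed from the returned panel so
        markers only tag QTLs through LD.
    """

    n_qtl: int
    h2: float
    effect_distribution: str = "gaussian"
    qtl_placement: str = "random"
    sparsity: float = 0.0
    hide_qtl: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.effect_distribution not in ("gaussian", "laplace", "point-normal", "equal"):
            raise ValueError(f"unknown effect distribution {self.effect_distribution!r}")
        if self.qtl_placement not in ("random", "evenly"):
            raise ValueError(f"unknown qtl placement {self.qtl_placement!r}")


def random_layout(
    chrom_lengths: list[tuple[str, int]],
    n_snps: int,
    seed: int = 0,
) -> GenomeLayout:
    """Scatter ``n_snps`` marker positions over chromosomes, proportional to length.

    Positions are sorted, unique, 1-based.  Apportionment across chromosomes
    is proportional to chromosome length with largest-remainder rounding.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([ln for _, ln in chrom_lengths], dtype=float)
    quota_f = n_snps * lengths / lengths.sum()
    quotas = np.floor(quota_f).astype(int)
    rem = n_snps - quotas.sum()
    if rem > 0:
        order = np.argsort(-(quota_f - quotas), kind="stable")
        quotas[order[:rem]] += 1
    positions = []
    for (name, length), q in zip(chrom_lengths, quotas):
        if q > length:
            raise ValueError(f"chromosome {name!r} too short for {q} markers")
        q = max(int(q), 1)
        pos = rng.choice(length, size=q, replace=False) + 1
        positions.append(np.sort(pos))
    return GenomeLayout(tuple(chrom_lengths), tuple(positions))


def _draw_maf(rng: np.random.Generator, p: int, spectrum) -> np.ndarray:
    """Draw per-marker ancestral minor-allele frequencies."""
    if isinstance(spectrum, np.ndarray) or isinstance(spectrum, (list,)):
        maf = np.asarray(spectrum, dtype=float)
        if maf.size != p:
            raise ValueError("maf spectrum array length must equal panel size")
    else:
        kind, *args = spectrum
        if kind == "uniform":
            lo, hi = args
            if lo <= 0.0 or hi > 0.5 or lo >= hi:
                raise ValueError("uniform maf spectrum needs 0 < lo < hi <= 0.5")
            maf = rng.uniform(lo, hi, size=p)
        elif kind == "beta":
            a, b = args
            maf = 0.5 * rng.beta(a, b, size=p)
        else:
            raise ValueError(f"unknown maf spectrum {kind!r}")
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("maf spectrum must be bounded away from 0 and at most 0.5")
    return maf


def simulate_genotypes(
    n: int,
    layout: GenomeLayout,
    maf_spectrum=("uniform", 0.05, 0.5),
    ld_decay: float = 0.0,
    n_subpops: int = 1,
    fst: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a complete diploid 0/1/2 genotype panel.

    Parameters
    ----------
    n
        Number of diploid individuals (>= 2).
    layout
        Genomic coordinate frame; every position receives a marker.
    maf_spectrum
        ``("uniform", lo, hi)``, ``("beta", a, b)`` (scaled to (0, 0.5]),
        or an explicit array of ancestral frequencies.
    ld_decay
        Per-bp decay rate of the latent haplotype correlation
        ``exp(-ld_decay * distance)``; 0 gives linkage equilibrium.
    n_subpops, fst
        With ``n_subpops > 1``, individuals are split evenly into
        subpopulations whose allele frequencies are Balding-Nichols draws
        at differentiation ``fst``.
    seed
        Seed for all randomness; identical seeds give identical panels.

    Returns
    -------
    GenotypeMatrix
        Complete panel, minor-allele oriented against the realized sample
        (ties at frequency 0.5 keep the simulated reference orientation).
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if ld_decay < 0:
        raise ValueError("ld_decay must be non-negative")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    p = layout.n_snps
    ancestral = _draw_maf(rng, p, maf_spectrum)

    # Per-subpopulation allele frequencies (Balding-Nichols).
    subpop_of = np.arange(n) % n_subpops
    if n_subpops > 1 and fst > 0:
        c = (1.0 - fst) / fst
        freqs = rng.beta(ancestral * c, (1.0 - ancestral) * c, size=(n_subpops, p))
        freqs = np.clip(freqs, 1e-6, 1.0 - 1e-6)
    else:
        freqs = np.tile(ancestral, (n_subpops, 1))

    # Latent-Gaussian AR(1) haplotypes: 2n haplotypes x p sites.
    n_hap = 2 * n
    z = np.empty((n_hap, p))
    col = 0
    for (_, _), pos in zip(layout.chromosomes, layout.positions):
        m = pos.size
        z[:, col] = rng.standard_normal(n_hap)
        if m > 1:
            rho = np.exp(-ld_decay * np.diff(pos)) if ld_decay > 0 else np.zeros(m - 1)
            eps = rng.standard_normal((n_hap, m - 1))
            if ld_decay > 0:
                for j in range(1, m):
                    r = rho[j - 1]
                    z[:, col + j] = r * z[:, col + j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
            else:
                z[:, col + 1 : col + m] = eps
        col += m
    u = norm.cdf(z)
    hap_subpop = np.repeat(subpop_of, 2)
    alleles = (u < freqs[hap_subpop]).astype(np.int8)
    geno = alleles[0::2] + alleles[1::2]

    # Re-orient to the realized minor allele; ties keep simulated orientation.
    freq = geno.mean(axis=0) / 2.0
    flip = freq > 0.5
    geno[:, flip] = 2 - geno[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)

    sample_ids = [f"ind_{i:04d}" for i in range(n)]
    return GenotypeMatrix(values=geno, sample_ids=sample_ids, layout=layout, maf=maf)


def _draw_effects(rng: np.random.Generator, arch: TraitArchitecture) -> np.ndarray:
    if arch.effect_distribution == "gaussian":
        eff = rng.standard_normal(arch.n_qtl)
    elif arch.effect_distribution == "laplace":
        eff = rng.laplace(0.0, 1.0, size=arch.n_qtl)
    elif arch.effect_distribution == "point-normal":
        eff = rng.standard_normal(arch.n_qtl)
        eff[rng.random(arch.n_qtl) < arch.sparsity] = 0.0
    else:  # equal: fixed magnitude, random sign
        eff = rng.choice([-1.0, 1.0], size=arch.n_qtl)
    return eff


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    mean: float = TRAIT_MEAN,
    sd: float = TRAIT_SD,
) -> PhenotypeSet | tuple[PhenotypeSet, GenotypeMatrix]:
    """Simulate a polygenic quantitative trait on a genotype panel.

    ``y = mean + g + e`` with the additive genetic value ``g`` (a sum of QTL
    effects times genotype, centered) scaled to variance ``h2 * sd**2`` and
    gaussian noise to ``(1 - h2) * sd**2``, so the expected narrow-sense
    heritability equals ``arch.h2``.  The realized ratio
    ``var(g) / var(g + e)`` of the actual draw is recorded.

    Returns the :class:`PhenotypeSet`; with ``arch.hide_qtl`` the causal
    columns are dropped from the panel and ``(phenotypes, visible_panel)``
    is returned instead.
    """
    if arch.n_qtl > genotypes.p:
        raise ValueError("n_qtl exceeds panel size")
    rng = np.random.default_rng(arch.seed)
    n, p = genotypes.n, genotypes.p

    if arch.qtl_placement == "random":
        qtl_idx = np.sort(rng.choice(p, size=arch.n_qtl, replace=False))
    else:
        qtl_idx = np.unique(np.linspace(0, p - 1, arch.n_qtl).round().astype(int))

    if arch.h2 == 0.0:
        g = np.zeros(n)
    else:
        effects = _draw_effects(rng, arch)
        x = genotypes.values[:, qtl_idx].astype(float)
        g = x @ effects
        g = g - g.mean()
        if np.var(g) == 0.0:
            # degenerate draw (all-zero effects or monomorphic QTLs): one re-draw
            effects = _draw_effects(rng, arch)
            g = x @ effects
            g = g - g.mean()
            if np.var(g) == 0.0:
                raise ValueError(
                    "simulated genetic values have zero variance after re-draw; "
                    "check QTL placement and effect distribution"
                )
        g = g * np.sqrt(arch.h2) * sd / np.std(g)

    if arch.h2 == 1.0:
        e = np.zeros(n)
    else:
        e = rng.standard_normal(n) * np.sqrt(1.0 - arch.h2) * sd

    y = mean + g + e
    var_tot = np.var(g + e)
    realized_h2 = float(np.var(g) / var_tot) if var_tot > 0 else 0.0
    all_keys = genotypes.keys()
    phen = PhenotypeSet(
        sample_ids=list(genotypes.sample_ids),
        y=y,
        true_gebv=g,
        realized_h2=realized_h2,
        qtl_keys=[all_keys[j] for j in qtl_idx],
    )

    if arch.hide_qtl:
        keep = np.setdiff1d(np.arange(p), qtl_idx)
        visible = genotypes.subset_snps([genotypes.keys()[j] for j in keep])
        return phen, visible
    return phen
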