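"""Core data containers shared across the pipeline.

The genotype panel is held as an ``n x p`` integer matrix of minor-allele
counts (0/1/2) with a genomic coordinate frame (:class:`GenomeLayout`)
mapping every column to a chromosome and 1-based position.  Phenotypes are
a plain vector aligned to the panel's sample order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SnpKey",
    "GenomeLayout",
    "GenotypeMatrix",
    "PhenotypeSet",
    "KinshipMatrix",
    "VarianceComponents",
]


@dataclass(frozen=True, order=True)
class SnpKey:
    """Identity of one marker: chromosome, 1-based bp position, id string."""

    chromosome: str
    position: int
    id: str = ""

    def __str__(self) -> str:  # genio snp-list dialect
        return f"{self.chromosome}:{self.position}:{self.id}"


@dataclass(frozen=True)
class GenomeLayout:
    """Coordinate frame of a marker panel.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    positions
        Per-chromosome sorted 1-based marker positions, same order as
        ``chromosomes``.
    snp_ids
        Optional per-chromosome marker id lists (defaults to
        ``"<chrom>_<pos>"``).
    """

    chromosomes: tuple[tuple[str, int], ...]
    positions: tuple[np.ndarray, ...]
    snp_ids: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("layout needs at least one chromosome")
        if len(self.positions) != len(self.chromosomes):
            raise ValueError("positions must match chromosomes one-to-one")
        object.__setattr__(
            self,
            "positions",
            tuple(np.asarray(p, dtype=np.int64) for p in self.positions),
        )
        for (name, length), pos in zip(self.chromosomes, self.positions):
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if pos.size == 0:
                raise ValueError(f"chromosome {name!r} carries no markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on {name!r} not strictly increasing")
            if pos[0] < 1 or pos[-1] > length:
                raise ValueError(f"positions on {name!r} outside [1, {length}]")
        if not self.snp_ids:
            ids = tuple(
                tuple(f"{name}_{p}" for p in pos)
                for (name, _), pos in zip(self.chromosomes, self.positions)
            )
            object.__setattr__(self, "snp_ids", ids)
        else:
            for (name, _), pos, ids in zip(self.chromosomes, self.positions, self.snp_ids):
                if len(ids) != pos.size:
                    raise ValueError(f"snp_ids length mismatch on {name!r}")

    @property
    def n_snps(self) -> int:
        return int(sum(p.size for p in self.positions))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def snps_per_chromosome(self) -> dict[str, int]:
        return {name: int(p.size) for (name, _), p in zip(self.chromosomes, self.positions)}

    def keys(self) -> list[SnpKey]:
        """All markers in genome order (chromosome order, then position)."""
        out: list[SnpKey] = []
        for (name, _), pos, ids in zip(self.chromosomes, self.positions, self.snp_ids):
            out.extend(SnpKey(name, int(p), i) for p, i in zip(pos, ids))
        return out

    def column_index(self) -> dict[SnpKey, int]:
        return {k: j for j, k in enumerate(self.keys())}

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome in the concatenated panel."""
        out: dict[str, slice] = {}
        start = 0
        for (name, _), pos in zip(self.chromosomes, self.positions):
            out[name] = slice(start, start + pos.size)
            start += pos.size
        return out

    def subset(self, keys: Sequence[SnpKey]) -> "GenomeLayout":
        """Layout restricted to ``keys`` (keys re-sorted to genome order)."""
        order = {name: i for i, name in enumerate(self.chrom_names)}
        keys = sorted(keys, key=lambda k: (order[k.chromosome], k.position))
        by_chrom: dict[str, list[SnpKey]] = {}
        for k in keys:
            by_chrom.setdefault(k.chromosome, []).append(k)
        chroms, positions, ids = [], [], []
        for name, length in self.chromosomes:
            if name in by_chrom:
                chroms.append((name, length))
                positions.append(np.array([k.position for k in by_chrom[name]]))
                ids.append(tuple(k.id for k in by_chrom[name]))
        return GenomeLayout(tuple(chroms), tuple(positions), tuple(ids))


@dataclass
class GenotypeMatrix:
    """``n x p`` biallelic SNP panel coded as minor-allele counts.

    ``values`` holds integers in {0, 1, 2}; ``mask`` (optional) marks
    missing calls that were present in the source file — simulation and
    post-QC panels carry ``mask=None`` meaning complete.  ``maf`` is the
    per-SNP empirical minor-allele frequency.
    """

    values: np.ndarray
    sample_ids: list[str]
    layout: GenomeLayout
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if p != self.layout.n_snps:
            raise ValueError("column count does not match layout")
        if self.maf is None:
            self.maf = self.empirical_maf()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing calls."""
        if self.mask is None:
            return self.values.mean(axis=0) / 2.0
        called = (~self.mask).sum(axis=0)
        totals = np.where(self.mask, 0, self.values).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = totals / (2.0 * called)
        return freq

    def keys(self) -> list[SnpKey]:
        return self.layout.keys()

    def subset_snps(self, keys: Sequence[SnpKey]) -> "GenotypeMatrix":
        """Panel restricted to ``keys`` (genome-order columns)."""
        sub_layout = self.layout.subset(keys)
        index = self.layout.column_index()
        cols = np.array([index[k] for k in sub_layout.keys()], dtype=int)
        return GenotypeMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            layout=sub_layout,
            maf=self.maf[cols],
            mask=None if self.mask is None else self.mask[:, cols],
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            layout=self.layout,
            maf=None,
            mask=None if self.mask is None else self.mask[idx],
        )


@dataclass
class PhenotypeSet:
    """Continuous trait values aligned to a panel's sample order.

    ``true_gebv`` holds the simulated additive genetic values when the
    phenotypes come from the simulator (absent for real data) and
    ``realized_h2`` the realized genetic fraction of variance of that draw.
    """

    sample_ids: list[str]
    y: np.ndarray
    true_gebv: np.ndarray | None = None
    realized_h2: float | None = None
    qtl_keys: list | None = None  # simulation truth; None for real data

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.sample_ids) != self.y.size:
            raise ValueError("phenotype length does not match sample ids")
        if self.true_gebv is not None and len(self.true_gebv) != self.y.size:
            raise ValueError("true_gebv length mismatch")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx: np.ndarray) -> "PhenotypeSet":
        idx = np.asarray(idx)
        return PhenotypeSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            y=self.y[idx],
            true_gebv=None if self.true_gebv is None else self.true_gebv[idx],
            realized_h2=self.realized_h2,
            qtl_keys=self.qtl_keys,
        )


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix with its scaling denominator."""

    values: np.ndarray
    denominator: float
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceComponents:
    """REML additive (sigma_g2) and residual (sigma_e2) variances."""

    sigma_g2: float
    sigma_e2: float
    loglik: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0
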