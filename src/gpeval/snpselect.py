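"""Marker-panel selection strategies.

Three ways to pick ``k`` SNPs from a QC-passed panel, mirroring how
low-density genotyping panels are designed for breeding programs:

* **gwas** — the ``k`` markers with the smallest association p-values
  (ranking supplied by a :class:`~gpeval.gwas.GwasResult`; when used inside
  cross-validation the scan must come from the training fold only);
* **evenly** — chromosomes are apportioned a quota proportional to their
  marker counts, each chromosome's marker index range is cut into quota
  equal segments and the middle marker of each segment is taken
  (deterministic, seed-free);
* **random** — a uniform sample without replacement.

All strategies return genome-coordinate-sorted :class:`SnpKey` lists of
exactly ``k`` distinct panel members.
"""

from __future__ import annotations

import numpy as np

from .containers import GenomeLayout, SnpKey
from .gwas import GwasResult

__all__ = ["select_gwas", "select_evenly", "select_random"]


def _check_k(k: int, total: int) -> None:
    if not 1 <= k <= total:
        raise ValueError(f"k={k} outside [1, {total}] for this panel")


def _sort_genome(keys: list[SnpKey], layout: GenomeLayout) -> list[SnpKey]:
    order = {name: i for i, name in enumerate(layout.chrom_names)}
    return sorted(keys, key=lambda s: (order[s.chromosome], s.position))


def select_gwas(result: GwasResult, k: int, layout: GenomeLayout | None = None) -> list[SnpKey]:
    """The ``k`` SNPs with smallest p-values.

    Ties are broken by genome coordinate (chromosome order, then position);
    the returned list is genome-sorted.
    """
    t = result.table
    _check_k(k, len(t))
    if layout is not None:
        chrom_rank = {name: i for i, name in enumerate(layout.chrom_names)}
    else:
        chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(t["chrom"]))}
    order = sorted(
        range(len(t)),
        key=lambda i: (t["p"].iat[i], chrom_rank[t["chrom"].iat[i]], t["pos"].iat[i]),
    )
    chosen = order[:k]
    keys = [SnpKey(t["chrom"].iat[i], int(t["pos"].iat[i]), str(t["id"].iat[i])) for i in chosen]
    return sorted(keys, key=lambda s: (chrom_rank[s.chromosome], s.position))


def _apportion(counts: np.ndarray, k: int) -> np.ndarray:
    """Largest-remainder quotas proportional to ``counts``, summing to k."""
    quota_f = k * counts / counts.sum()
    quotas = np.floor(quota_f).astype(int)
    rem = k - quotas.sum()
    if rem > 0:
        order = np.argsort(-(quota_f - quotas), kind="stable")
        quotas[order[:rem]] += 1
    # a quota can exceed a chromosome's supply only if k > total, ruled out upstream;
    # largest-remainder on proportional shares never over-allocates: quota <= ceil(share)
    return quotas


def select_evenly(layout: GenomeLayout, k: int) -> list[SnpKey]:
    """Evenly spaced markers: per-chromosome quotas, segment midpoints.

    Each chromosome's SNP index range is divided into ``quota`` equal-count
    segments and the middle SNP of each segment is selected (lower-middle
    index for even-length segments).  Pure function of ``(layout, k)``.
    """
    _check_k(k, layout.n_snps)
    counts = np.array([p.size for p in layout.positions], dtype=float)
    quotas = _apportion(counts, k)
    keys: list[SnpKey] = []
    for (name, _), pos, ids, q in zip(layout.chromosomes, layout.positions, layout.snp_ids, quotas):
        m = pos.size
        for i in range(int(q)):
            lo = (i * m) // int(q)
            hi = ((i + 1) * m) // int(q)  # exclusive
            mid = (lo + hi - 1) // 2
            keys.append(SnpKey(name, int(pos[mid]), ids[mid]))
    return keys  # already genome-ordered by construction


def select_random(layout: GenomeLayout, k: int, seed: int) -> list[SnpKey]:
    """Uniform sample of ``k`` markers without replacement, genome-sorted."""
    _check_k(k, layout.n_snps)
    all_keys = layout.keys()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_keys), size=k, replace=False)
    return _sort_genome([all_keys[i] for i in idx], layout)
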