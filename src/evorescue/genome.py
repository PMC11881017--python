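"""Polygenic genetic architecture: QTL alleles, recombination, mutation.

The genome is modelled after a standard multi-linkage-group map: 20 linkage
groups of 50,000 sites each, of which 10 groups carry the quantitative trait
loci (QTLs) that are actually simulated; the other 10 are reserved for
neutral variation and deliberately not tracked. Each QTL allele has a fixed
additive effect drawn from Normal(0, sigma_qtl) at creation; an individual's
phenotype is the sum of effects over both haplotypes (homozygotes count
twice).

Haplotypes are immutable tuples of per-group tuples of allele ids, sorted by
site within a group; a global :class:`AlleleRegistry` maps ids to (group,
site, effect) and keeps live copy counts so the number of segregating
alleles is available in O(1) at every census.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AlleleRegistry", "empty_haplotype", "make_gamete", "phenotype_of", "flat_allele_ids"]


class AlleleRegistry:
    """Append-only table of QTL alleles with live copy counts."""

    def __init__(self, n_qtl_groups: int = 10):
        self.n_qtl_groups = n_qtl_groups
        self.group: list[int] = []
        self.site: list[int] = []
        self._effects: list[float] = []
        self._effect_arr = np.empty(0)
        self.counts = np.zeros(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._effects)

    def add(self, group: int, site: int, effect: float) -> int:
        """Register a new allele; returns its id."""
        self.group.append(int(group))
        self.site.append(int(site))
        self._effects.append(float(effect))
        return len(self._effects) - 1

    @property
    def effects(self) -> np.ndarray:
        if self._effect_arr.size != len(self._effects):
            self._effect_arr = np.asarray(self._effects, dtype=float)
        return self._effect_arr

    def sync_counts(self) -> None:
        if self.counts.size != len(self._effects):
            grown = np.zeros(len(self._effects), dtype=np.int64)
            grown[: self.counts.size] = self.counts
            self.counts = grown

    def add_copies(self, ids: np.ndarray) -> None:
        self.sync_counts()
        np.add.at(self.counts, ids, 1)

    def remove_copies(self, ids: np.ndarray) -> None:
        np.subtract.at(self.counts, ids, 1)

    def n_segregating(self) -> int:
        """Number of distinct alleles currently carried by living individuals."""
        self.sync_counts()
        return int((self.counts > 0).sum())

    def clone_counts(self) -> "AlleleRegistry":
        """Shallow clone sharing the allele table but with independent counts.

        Valid once mutation has stopped (the table no longer grows), which is
        exactly the post-burn-in regime where burned-in states are re-used
        across scenarios.
        """
        out = AlleleRegistry(self.n_qtl_groups)
        out.group = self.group
        out.site = self.site
        out._effects = self._effects
        out._effect_arr = self.effects
        self.sync_counts()
        out.counts = self.counts.copy()
        return out


def empty_haplotype(n_qtl_groups: int = 10) -> tuple:
    return tuple(() for _ in range(n_qtl_groups))


def _recombine_group(
    ids_a: tuple, ids_b: tuple, breakpoints: np.ndarray, registry: AlleleRegistry
) -> tuple:
    """Assemble one linkage group from two parental groups given crossovers.

    Sites before the first breakpoint come from haplotype ``a``; the source
    haplotype alternates at each breakpoint.
    """
    site = registry.site
    merged: list[tuple[int, int]] = []
    for ids, parity_wanted in ((ids_a, 0), (ids_b, 1)):
        for aid in ids:
            s = site[aid]
            if np.searchsorted(breakpoints, s, side="right") % 2 == parity_wanted:
                merged.append((s, aid))
    merged.sort()
    return tuple(aid for _, aid in merged)


def make_gamete(
    haplotypes: tuple,
    registry: AlleleRegistry,
    rng: np.random.Generator,
    recomb_rate: float,
    sites_per_group: int,
    sigma_qtl: float,
    mutation_rate_per_site: float,
    mutate: bool,
) -> tuple:
    """One recombinant (optionally mutated) gamete from a parent's genome.

    Linkage groups assort freely; within a group, crossovers occur at the
    per-site rate ``recomb_rate``. New QTL mutations arise only while
    ``mutate`` is true (the burn-in mutation regime) at
    ``mutation_rate_per_site`` per site per gamete, with effects drawn from
    Normal(0, sigma_qtl).
    """
    hap_a, hap_b = haplotypes
    g = registry.n_qtl_groups
    picks = rng.integers(0, 2, size=g)
    n_cross_total = rng.poisson(recomb_rate * (sites_per_group - 1) * g)
    if n_cross_total == 0:
        gamete = [hap_a[k] if picks[k] == 0 else hap_b[k] for k in range(g)]
    else:
        cross_groups = rng.integers(0, g, size=n_cross_total)
        gamete = []
        for k in range(g):
            n_k = int((cross_groups == k).sum())
            if n_k == 0 or (len(hap_a[k]) == 0 and len(hap_b[k]) == 0):
                gamete.append(hap_a[k] if picks[k] == 0 else hap_b[k])
            else:
                bps = np.sort(rng.integers(1, sites_per_group, size=n_k))
                a, b = (hap_a[k], hap_b[k]) if picks[k] == 0 else (hap_b[k], hap_a[k])
                gamete.append(_recombine_group(a, b, bps, registry))
    if mutate:
        n_mut = rng.poisson(mutation_rate_per_site * sites_per_group * g)
        for _ in range(n_mut):
            k = int(rng.integers(0, g))
            s = int(rng.integers(0, sites_per_group))
            eff = float(rng.normal(0.0, sigma_qtl))
            aid = registry.add(k, s, eff)
            grp = list(gamete[k])
            grp.append(aid)
            grp.sort(key=lambda a: (registry.site[a], a))
            gamete[k] = tuple(grp)
    return tuple(gamete)


def flat_allele_ids(haplotypes: tuple) -> np.ndarray:
    """All allele ids carried by a genome, both haplotypes, with multiplicity."""
    ids = [aid for hap in haplotypes for grp in hap for aid in grp]
    return np.asarray(ids, dtype=np.intp)


def phenotype_of(haplotypes: tuple, registry: AlleleRegistry) -> float:
    """Additive phenotype: sum of allele effects over both haplotypes."""
    ids = flat_allele_ids(haplotypes)
    if ids.size == 0:
        return 0.0
    return float(registry.effects[ids].sum())
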